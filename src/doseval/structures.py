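"""Geometric operations on structures.

Contour-to-mask rasterization (voxel-center-in-polygon, even-odd rule),
mask-to-contour extraction (marching squares at the 0.5 iso-level),
3D outlier removal, polygon smoothing, signed Euclidean distance fields and
anisotropic CTV-to-PTV margin expansion.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage, signal
from skimage import measure

from .grid import ContourSlice, ContourStack, Grid3D, MarginSpec, StructureMask

__all__ = [
    "contours_to_mask",
    "mask_to_contours",
    "remove_3d_outliers",
    "smooth_contours",
    "expand_margin",
    "signed_distance",
]


def contours_to_mask(contours: ContourStack, grid: Grid3D) -> StructureMask:
    """Rasterize closed planar polygons onto a voxel grid.

    A voxel is set iff its center lies inside an odd number of the slice's
    polygons (even-odd rule), matching DICOM RTSTRUCT practice.  There is no
    partial-volume weighting.

    Raises
    ------
    ValueError
        If any contour's z position does not map to a grid slice (within
        half a slice thickness) or a polygon is degenerate.
    """
    out = np.zeros(grid.shape, dtype=bool)
    ys = grid.axis_coords(1)
    xs = grid.axis_coords(2)
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    for sl in contours.slices:
        try:
            k = grid.z_index(sl.z_mm)
        except ValueError as e:
            raise ValueError(f"contour slice of {contours.name!r}: {e}") from e
        inside = np.zeros(pts.shape[0], dtype=bool)
        for poly in sl.polygons:
            # polygons are (y, x) with implicit closure; MplPath wants (x, y)
            # and, for closed=True, the first vertex repeated at the end
            verts = np.vstack([poly[:, ::-1], poly[:1, ::-1]])
            path = MplPath(verts, closed=True)
            inside ^= path.contains_points(pts)
        out[k] |= inside.reshape(grid.shape[1], grid.shape[2])
    return StructureMask(contours.name, grid, out)


def _polygon_signed_area(poly_yx: np.ndarray) -> float:
    """Shoelace signed area in the (x, y) plane; positive = counter-clockwise."""
    y = poly_yx[:, 0]
    x = poly_yx[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _point_in_polygon(point_yx: np.ndarray, poly_yx: np.ndarray) -> bool:
    verts = np.vstack([poly_yx[:, ::-1], poly_yx[:1, ::-1]])
    return bool(MplPath(verts, closed=True).contains_point(point_yx[::-1]))


def mask_to_contours(mask: StructureMask) -> ContourStack:
    """Extract per-slice iso-contours of a binary mask (marching squares, level 0.5).

    Vertices are returned in patient mm.  Outer boundaries are oriented
    counter-clockwise in the (x, y) plane; holes clockwise.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    if mask.is_empty:
        raise ValueError(f"cannot extract contours from empty mask {mask.name!r}")
    grid = mask.grid
    dz, dy, dx = grid.spacing
    oz, oy, ox = grid.origin
    slices: list[ContourSlice] = []
    for k in range(grid.shape[0]):
        img = mask.voxels[k]
        if not img.any():
            continue
        # pad so boundaries at the image edge close properly
        padded = np.pad(img.astype(float), 1)
        raw = measure.find_contours(padded, 0.5)
        polys: list[np.ndarray] = []
        for c in raw:
            c = c - 1.0  # undo padding offset; (row=y index, col=x index)
            if np.allclose(c[0], c[-1]):
                c = c[:-1]
            if c.shape[0] < 3:
                continue
            poly = np.column_stack([oy + c[:, 0] * dy, ox + c[:, 1] * dx])
            polys.append(poly)
        # orientation: a polygon nested in an odd number of the others is a
        # hole (clockwise); otherwise an outer boundary (counter-clockwise)
        oriented: list[np.ndarray] = []
        for i, p in enumerate(polys):
            depth = sum(
                1
                for j, q in enumerate(polys)
                if j != i and _point_in_polygon(p[0], q)
            )
            want_ccw = depth % 2 == 0
            is_ccw = _polygon_signed_area(p) > 0
            oriented.append(p if is_ccw == want_ccw else p[::-1])
        slices.append(ContourSlice(z_mm=oz + k * dz, polygons=oriented))
    return ContourStack(mask.name, slices)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def remove_3d_outliers(mask: StructureMask) -> StructureMask:
    """Keep only the largest 26-connected 3D component.

    Ties are broken by the component containing the lexicographically
    smallest (z, y, x) voxel index.  Empty input passes through unchanged.
    The operation is idempotent.
    """
    if mask.is_empty:
        return mask.with_voxels(mask.voxels.copy())
    labels, n = ndimage.label(mask.voxels, structure=_CONN26)
    if n == 1:
        return mask.with_voxels(mask.voxels.copy())
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # first occurrence in C (row-major) order == smallest lexicographic index
        flat = labels.ravel()
        firsts = {int(lab): int(np.argmax(flat == lab)) for lab in candidates}
        keep = min(firsts, key=firsts.get)
    return mask.with_voxels(labels == keep)


def smooth_contours(contours: ContourStack, window: int = 3) -> ContourStack:
    """Circular moving-average smoothing of polygon vertices.

    ``window`` must be odd and >= 1; ``window=1`` is the identity.  Vertex
    counts are preserved.  Corners are pulled inward, so perimeters of
    convex polygons strictly decrease for window > 1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1:
        return ContourStack(
            contours.name,
            [ContourSlice(s.z_mm, [p.copy() for p in s.polygons]) for s in contours.slices],
        )
    kernel = np.ones(window) / window
    out_slices = []
    for s in contours.slices:
        polys = []
        for p in s.polygons:
            sm = np.column_stack(
                [
                    signal.convolve(np.concatenate([p[:, c]] * 3), kernel, mode="same")[
                        len(p) : 2 * len(p)
                    ]
                    for c in (0, 1)
                ]
            )
            polys.append(sm)
        out_slices.append(ContourSlice(s.z_mm, polys))
    return ContourStack(contours.name, out_slices)


def _margin_footprint(margins: MarginSpec, spacing: tuple[float, float, float]) -> np.ndarray:
    """Binary footprint of the anisotropic ellipsoidal margin on the voxel lattice.

    A lattice offset d (mm) belongs to the footprint iff
    sum_i (d_i / m_i(sign d_i))^2 <= 1, where the per-axis margin depends on
    the sign of the offset component (posterior vs. anterior etc.).  A zero
    margin admits only zero displacement along that half-axis.
    """
    half = margins.as_half_axes()  # ((neg, pos) per z, y, x)
    n = [int(np.floor(max(h) / sp + 1e-9)) for h, sp in zip(half, spacing)]
    grids = np.meshgrid(
        *[np.arange(-k, k + 1) * sp for k, sp in zip(n, spacing)], indexing="ij"
    )
    s = np.zeros(grids[0].shape)
    ok = np.ones(grids[0].shape, dtype=bool)
    for ax, d in enumerate(grids):
        neg, pos = half[ax]
        m = np.where(d >= 0, pos, neg)
        zero_m = m == 0
        ok &= ~(zero_m & (d != 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(zero_m, 0.0, (d / np.where(zero_m, 1.0, m)) ** 2)
        s += term
    return ok & (s <= 1.0 + 1e-12)


def expand_margin(ctv: StructureMask, margins: MarginSpec) -> StructureMask:
    """Anisotropic CTV-to-PTV expansion.

    The PTV contains every voxel whose center lies inside the
    ellipsoidal-metric dilation of the CTV with the six per-direction
    margins (the union over CTV voxels of an "egg" whose half-axes are the
    per-direction margins).  PTV is always a superset of the CTV, and the
    result is monotone in every margin component.

    Raises
    ------
    ValueError
        If the CTV is empty.
    """
    if ctv.is_empty:
        raise ValueError("cannot expand an empty CTV")
    fp = _margin_footprint(margins, ctv.grid.spacing)
    if fp.size == 1:
        return ctv.with_voxels(ctv.voxels.copy(), name="PTV")
    # convolution (A * B)(t) > 0 iff t = a + b for some a in A, b in B: exactly
    # the Minkowski dilation with the (possibly asymmetric) footprint, where a
    # +y footprint offset applies the posterior margin as intended.  True
    # overlaps contribute >= 1, so 0.5 is a safe threshold against FFT noise.
    conv = signal.fftconvolve(ctv.voxels.astype(np.float32), fp.astype(np.float32), mode="same")
    out = conv > 0.5
    out |= ctv.voxels
    return ctv.with_voxels(out, name="PTV")


def signed_distance(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance field of a mask, in mm.

    Negative inside, positive outside; for an outside voxel the value is the
    distance to the nearest inside voxel *center* (and vice versa), so the
    zero crossing sits between the boundary voxel layers.  Anisotropic
    spacing is respected.  Thresholding at 0 reproduces the mask;
    thresholding at +m equals :func:`expand_margin` with isotropic margin m.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    if mask.is_empty:
        raise ValueError(f"signed distance of empty mask {mask.name!r} is undefined")
    sp = mask.grid.spacing
    outside = ndimage.distance_transform_edt(~mask.voxels, sampling=sp)
    inside = ndimage.distance_transform_edt(mask.voxels, sampling=sp)
    return np.where(mask.voxels, -inside, outside)
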