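"""Geometric agreement metrics between two segmentations.

Dice similarity coefficient (percent), symmetric Hausdorff distance (max and
95th percentile) and average surface distance (mm), and signed relative
volume difference (percent).  Surface distances are measured between the
center points of boundary voxels (a voxel in the mask with at least one
face neighbour outside, the grid border counting as outside), with
anisotropic spacing respected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import StructureMask

__all__ = [
    "GeometryReport",
    "dice",
    "relative_volume_difference",
    "surface_distances",
    "boundary_voxels",
    "geometry_report",
]


@dataclass(frozen=True)
class GeometryReport:
    """Agreement between a test and a reference structure."""

    dsc: float  # percent, [0, 100]
    hd: float  # mm, maximum symmetric surface distance
    hd95: float  # mm, 95th percentile (linear interpolation)
    asd: float  # mm, mean symmetric surface distance
    rvd: float  # percent, signed (test vs reference), >= -100

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient as a percentage: 100 * 2|A∩B| / (|A|+|B|).

    Raises
    ------
    ValueError
        If both masks are empty (0/0 undefined).
    GridCompatibilityError
        If the masks live on different lattices.
    """
    a.grid.require_compatible(b.grid, "masks")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise ValueError("DSC of two empty masks is undefined (0/0)")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 100.0 * 2.0 * inter / (na + nb)


def relative_volume_difference(test: StructureMask, ref: StructureMask) -> float:
    """Signed percent volume difference, 100 * (V_test - V_ref) / V_ref."""
    test.grid.require_compatible(ref.grid, "masks")
    if ref.is_empty:
        raise ValueError("RVD undefined for an empty reference mask")
    return 100.0 * (test.volume_mm3 - ref.volume_mm3) / ref.volume_mm3


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: StructureMask) -> np.ndarray:
    """(N, 3) mm coordinates of boundary-voxel centers.

    A boundary voxel is inside the mask with >= 1 face neighbour outside;
    voxels touching the grid border count as boundary.
    """
    eroded = ndimage.binary_erosion(mask.voxels, structure=_FACE_STRUCT, border_value=0)
    boundary = mask.voxels & ~eroded
    idx = np.argwhere(boundary)
    return idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def surface_distances(a: StructureMask, b: StructureMask) -> tuple[float, float, float]:
    """Symmetric surface distances (hd, hd95, asd) in mm.

    Both directed nearest-neighbour distance sets (a→b and b→a) are pooled;
    hd is their maximum, hd95 the 95th percentile with linear interpolation
    between order statistics, asd the mean.

    Raises
    ------
    ValueError
        If either mask is empty.
    """
    a.grid.require_compatible(b.grid, "masks")
    if a.is_empty or b.is_empty:
        raise ValueError("surface distances require two nonempty masks")
    pa = boundary_voxels(a)
    pb = boundary_voxels(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return (
        float(pooled.max()),
        float(np.percentile(pooled, 95)),
        float(pooled.mean()),
    )


def geometry_report(test: StructureMask, ref: StructureMask) -> GeometryReport:
    """Full geometric agreement report of a test structure against a reference."""
    hd, hd95, asd = surface_distances(test, ref)
    return GeometryReport(
        dsc=dice(test, ref),
        hd=hd,
        hd95=hd95,
        asd=asd,
        rvd=relative_volume_difference(test, ref),
    )
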