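"""3D global gamma-index analysis of two dose distributions.

For every reference voxel above the low-dose cutoff, the gamma index is the
minimum over search displacements r (|r| <= search_radius_factor * dta) of

    sqrt( (|r| / dta)^2 + ((De(x + r) - Dr(x)) / (tol/100 * Dn))^2 )

where De is the evaluated dose, trilinearly interpolated on a sub-voxel
lattice with step interpolation_step * dta, Dr the reference dose, and Dn
the global normalization dose (the prescription, since the low-dose cutoff
is also defined in percent of prescription).  A voxel passes when
gamma <= 1 (the boundary counts as a pass).

The search iterates displacements in order of increasing magnitude and
retires a voxel once its current best gamma cannot be improved by any
farther displacement (the spatial term alone already exceeds it), which
makes well-agreeing distributions cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "pass_rate"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma acceptance criteria; defaults are the clinical 3%/3 mm global test."""

    dose_tolerance: float = 3.0  # percent of the normalization dose
    dta: float = 3.0  # distance-to-agreement, mm
    cutoff: float = 10.0  # percent of prescription below which ref voxels are skipped
    normalization: float | None = None  # Gy; None = the reference prescription
    search_radius_factor: float = 3.0  # search truncated at factor * dta
    interpolation_step: float = 0.1  # sub-voxel step as a fraction of dta

    def __post_init__(self) -> None:
        for f in ("dose_tolerance", "dta", "cutoff", "search_radius_factor", "interpolation_step"):
            if not (getattr(self, f) > 0):
                raise ValueError(f"gamma criterion {f!r} must be > 0")
        if self.cutoff >= 100:
            raise ValueError("cutoff must be < 100% of prescription")


@dataclass
class GammaResult:
    """Per-voxel gamma values (NaN where not evaluated) and the evaluated mask."""

    gamma: np.ndarray
    evaluated: np.ndarray
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())

    @property
    def values(self) -> np.ndarray:
        return self.gamma[self.evaluated]

    @property
    def pass_rate(self) -> float:
        return pass_rate(self)


def _search_offsets(crit: GammaCriteria, spacing: tuple[float, float, float]) -> np.ndarray:
    """Displacements (mm, (z,y,x)) within the search ball, sorted by magnitude."""
    step = crit.interpolation_step * crit.dta
    radius = crit.search_radius_factor * crit.dta
    n = int(np.floor(radius / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    r = np.linalg.norm(offs, axis=1)
    keep = r <= radius + 1e-9
    offs, r = offs[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order]


def gamma_map(
    ref: DoseGrid,
    eval_: DoseGrid,
    crit: GammaCriteria = GammaCriteria(),
    region: np.ndarray | None = None,
) -> GammaResult:
    """Compute the 3D global gamma map of ``eval_`` against ``ref``.

    ``region`` optionally restricts the evaluated voxels further (e.g. to a
    PTV mask); the low-dose cutoff always applies to the *reference* dose.

    Raises
    ------
    GridCompatibilityError
        If the two doses are on different lattices.
    ValueError
        If the normalization dose is zero.
    """
    ref.grid.require_compatible(eval_.grid, "dose grids")
    norm = crit.normalization if crit.normalization is not None else ref.prescription
    if not (norm > 0):
        raise ValueError("gamma normalization dose must be > 0 Gy")
    delta_d = crit.dose_tolerance / 100.0 * norm

    evaluated = ref.dose >= crit.cutoff / 100.0 * ref.prescription
    if region is not None:
        evaluated &= np.asarray(region, dtype=bool)

    gamma = np.full(ref.grid.shape, np.nan)
    idx = np.argwhere(evaluated)
    if idx.shape[0] == 0:
        return GammaResult(gamma, evaluated, crit)

    spacing = np.asarray(ref.grid.spacing)
    ref_vals = ref.dose[evaluated]

    # gamma^2 at zero displacement
    g2 = ((eval_.dose[evaluated] - ref_vals) / delta_d) ** 2

    # Banded lower bounds on the dose term: trilinear samples within a ball
    # of radius r stay inside the local min/max of the evaluated dose over a
    # covering box, so |De(x+r) - Dr(x)| is at least the distance of Dr(x)
    # from that local range.  Bands at 1, 2, 3 x dta let voxels retire as
    # soon as no remaining displacement can improve their current gamma.
    radius = crit.search_radius_factor * crit.dta
    dta2 = crit.dta**2
    band_radii = [min(k * crit.dta, radius) for k in (1, 2, 3)]
    if band_radii[-1] < radius:
        band_radii.append(radius)
    gap2_bands = []
    for r in band_radii:
        size = [2 * int(np.ceil(r / sp)) + 3 for sp in ref.grid.spacing]
        locmin = ndimage.minimum_filter(eval_.dose, size=size, mode="nearest")[evaluated]
        locmax = ndimage.maximum_filter(eval_.dose, size=size, mode="nearest")[evaluated]
        gap = np.maximum(0.0, np.maximum(ref_vals - locmax, locmin - ref_vals))
        gap2_bands.append((gap / delta_d) ** 2)

    # pad the evaluated dose with NaN so out-of-grid samples never win
    pad = [int(np.ceil(radius / sp)) + 1 for sp in ref.grid.spacing]
    padded = np.pad(eval_.dose, [(p, p) for p in pad], constant_values=np.nan)
    strides = np.array(
        [padded.shape[1] * padded.shape[2], padded.shape[2], 1], dtype=np.int64
    )
    pf = padded.ravel()
    base_flat = (idx + np.asarray(pad)) @ strides

    offsets = _search_offsets(crit, ref.grid.spacing)[1:]  # origin already done
    # per-offset trilinear corner flat-offsets and constant weights
    o_vox = offsets / spacing
    f_int = np.floor(o_vox).astype(np.int64)
    t = o_vox - f_int
    corner_flat = np.empty((offsets.shape[0], 8), dtype=np.int64)
    corner_w = np.empty((offsets.shape[0], 8))
    c = 0
    for cz in (0, 1):
        for cy in (0, 1):
            for cx in (0, 1):
                corner_flat[:, c] = (f_int + np.array([cz, cy, cx])) @ strides
                corner_w[:, c] = (
                    (t[:, 0] if cz else 1 - t[:, 0])
                    * (t[:, 1] if cy else 1 - t[:, 1])
                    * (t[:, 2] if cx else 1 - t[:, 2])
                )
                c += 1
    spatial2 = (offsets**2).sum(axis=1) / dta2
    band_r2 = np.array([r**2 for r in band_radii])
    gap2 = np.vstack(gap2_bands)

    search = _numba_search() or _numpy_search
    g2 = search(
        pf, base_flat, ref_vals, g2, corner_flat, corner_w, spatial2,
        (offsets**2).sum(axis=1), band_r2, gap2, dta2, delta_d,
    )

    gamma[evaluated] = np.sqrt(g2)
    return GammaResult(gamma, evaluated, crit)


def _numpy_search(
    pf, base_flat, ref_vals, g2, corner_flat, corner_w, spatial2, r2, band_r2, gap2, dta2, delta_d
):
    """Vectorized search over displacements with a shrinking active set."""
    g2 = g2.copy()
    active = np.arange(base_flat.size)
    for m in range(corner_flat.shape[0]):
        # lower bound on any candidate at displacement >= |r_m|
        fb = np.full(active.size, np.inf)
        lower2 = r2[m]
        for b in range(band_r2.size):
            if band_r2[b] <= r2[m]:
                continue
            np.minimum(fb, lower2 / dta2 + gap2[b, active], out=fb)
            lower2 = band_r2[b]
        active = active[g2[active] > fb]
        if active.size == 0:
            break
        vals = np.zeros(active.size)
        for c in range(8):
            w = corner_w[m, c]
            if w == 0:
                continue
            vals += w * pf[base_flat[active] + corner_flat[m, c]]
        cand = spatial2[m] + ((vals - ref_vals[active]) / delta_d) ** 2
        g2[active] = np.fmin(g2[active], cand)  # fmin ignores NaN samples
    return g2


_NUMBA_KERNEL = None


def _numba_search():
    """Compile (once) the per-voxel search kernel; None if numba is unavailable."""
    global _NUMBA_KERNEL
    if _NUMBA_KERNEL is not None:
        return _NUMBA_KERNEL
    try:
        import numba
    except ImportError:
        return None

    @numba.njit(cache=False, fastmath=False)
    def kernel(
        pf, base_flat, ref_vals, g2_init, corner_flat, corner_w, spatial2, r2, band_r2, gap2, dta2, delta_d
    ):
        n = base_flat.size
        m_tot = corner_flat.shape[0]
        n_bands = band_r2.size
        out = g2_init.copy()
        for v in range(n):
            g2v = out[v]
            base = base_flat[v]
            rv = ref_vals[v]
            for m in range(m_tot):
                # retire as soon as no remaining displacement can improve:
                # candidates in band b cost at least lower_edge^2/dta^2 +
                # the voxel's dose-gap bound for that band
                fb = 1e300
                lower2 = r2[m]
                for b in range(n_bands):
                    if band_r2[b] <= r2[m]:
                        continue
                    cand_b = lower2 / dta2 + gap2[b, v]
                    if cand_b < fb:
                        fb = cand_b
                    lower2 = band_r2[b]
                if g2v <= fb:
                    break
                val = 0.0
                for c in range(8):
                    w = corner_w[m, c]
                    if w != 0.0:
                        val += w * pf[base + corner_flat[m, c]]
                if not np.isnan(val):
                    dd = (val - rv) / delta_d
                    cand = spatial2[m] + dd * dd
                    if cand < g2v:
                        g2v = cand
            out[v] = g2v
        return out

    _NUMBA_KERNEL = kernel
    return _NUMBA_KERNEL


def pass_rate(result: GammaResult) -> float:
    """Percent of evaluated voxels with gamma <= 1 (boundary passes).

    Raises
    ------
    ValueError
        If no voxel was evaluated (entire reference below the cutoff).
    """
    vals = result.values
    if vals.size == 0:
        raise ValueError("no evaluated voxels: reference dose everywhere below cutoff")
    return 100.0 * float(np.count_nonzero(vals <= 1.0)) / vals.size
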