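"""Exact cumulative dose-volume histograms and the Dx%/VdGy query layer.

The DVH is stored as the full sorted vector of in-structure voxel doses —
no histogram binning, so there is no bin-width parameter and queries are
exact.  Dose-at-volume (Dx%) uses the midpoint-rank quantile convention
with linear interpolation: for sorted ascending doses d_1..d_n the query
position is q*n + 0.5 with q = 1 - x/100, clamped to [1, n].  Clinical TPSs
differ in this convention; it is documented here because it matters at
small n.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import DoseGrid, StructureMask

__all__ = [
    "DVH",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dose_summary",
    "plot_dvhs",
]


@dataclass
class DVH:
    """Cumulative DVH of one structure: sorted voxel doses + voxel volume."""

    structure: str
    doses: np.ndarray  # Gy, ascending
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float).ravel()
        if d.size == 0:
            raise ValueError(f"DVH of {self.structure!r} has no voxels")
        self.doses = np.sort(d)

    @property
    def n(self) -> int:
        return int(self.doses.size)

    @property
    def volume_mm3(self) -> float:
        return self.n * self.voxel_volume_mm3

    # -- queries ---------------------------------------------------------

    def dose_at_volume(self, x: float) -> float:
        """Dx%: dose (Gy) received by at least x% of the structure volume."""
        return dose_at_volume(self, x)

    def volume_at_dose(self, d: float) -> float:
        """Vd: percent of the structure volume receiving >= d Gy."""
        return volume_at_dose(self, d)

    @property
    def dmean(self) -> float:
        return float(self.doses.mean())

    @property
    def dmax(self) -> float:
        return float(self.doses[-1])

    @property
    def dmin(self) -> float:
        return float(self.doses[0])

    def curve(self, step_gy: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative curve sampled at ``step_gy``: (dose Gy, volume %)."""
        dmax = self.doses[-1]
        grid = np.arange(0.0, dmax + 2 * step_gy, step_gy)
        vol = np.array([volume_at_dose(self, d) for d in grid])
        return grid, vol

    def to_csv(self, step_gy: float = 0.1) -> str:
        """Two-column CSV export (dose_gy, volume_pct) at ``step_gy`` sampling."""
        d, v = self.curve(step_gy)
        buf = io.StringIO()
        buf.write("dose_gy,volume_pct\n")
        for di, vi in zip(d, v):
            buf.write(f"{di:.6g},{vi:.10g}\n")
        return buf.getvalue()


def compute_dvh(dose: DoseGrid, mask: StructureMask) -> DVH:
    """Exact DVH over precisely the voxels set in ``mask``.

    Raises
    ------
    ValueError
        If the mask is empty.
    GridCompatibilityError
        If dose and mask are on different lattices.
    """
    dose.grid.require_compatible(mask.grid, "dose/mask grids")
    if mask.is_empty:
        raise ValueError(f"cannot compute DVH of empty mask {mask.name!r}")
    return DVH(mask.name, dose.dose[mask.voxels], mask.grid.voxel_volume_mm3)


def dose_at_volume(dvh: DVH, x: float) -> float:
    """Dx%: the (1 - x/100) midpoint-rank quantile of the voxel doses.

    Query position p = q*n + 0.5 (q = 1 - x/100) in 1-based rank space,
    clamped to [1, n], with linear interpolation between order statistics.
    """
    if not (0 < x <= 100):
        raise ValueError(f"volume percentage must be in (0, 100], got {x}")
    q = 1.0 - x / 100.0
    n = dvh.n
    pos = np.clip(q * n + 0.5, 1.0, float(n))
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float((1 - frac) * dvh.doses[lo - 1] + frac * dvh.doses[hi - 1])


def volume_at_dose(dvh: DVH, d: float) -> float:
    """Vd: percent of structure volume receiving at least d Gy (closed bound)."""
    if d < 0:
        raise ValueError(f"dose level must be >= 0 Gy, got {d}")
    # doses sorted ascending: count of entries >= d
    count = dvh.n - int(np.searchsorted(dvh.doses, d, side="left"))
    return 100.0 * count / dvh.n


def dose_summary(dose: DoseGrid, mask: StructureMask) -> tuple[float, float, float]:
    """(Dmean, Dmax, Dmin) in Gy over the voxels inside ``mask``."""
    dose.grid.require_compatible(mask.grid, "dose/mask grids")
    if mask.is_empty:
        raise ValueError(f"dose summary of empty mask {mask.name!r} is undefined")
    vals = dose.dose[mask.voxels]
    return float(vals.mean()), float(vals.max()), float(vals.min())


def plot_dvhs(dvhs: list[DVH], path: str | Path, step_gy: float = 0.25) -> Path:
    """Plot cumulative DVH curves for several structures to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for dvh in dvhs:
        d, v = dvh.curve(step_gy)
        ax.plot(d, v, label=dvh.structure)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 102)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
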