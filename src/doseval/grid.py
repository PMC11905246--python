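"""Core geometric data model shared by dose distributions and structure masks.

All spatial quantities are in patient-space millimetres.  Arrays use 0-based
voxel indices in ``(z, y, x)`` axis order, with the patient-coordinate
convention x = left(+)/right(-), y = posterior(+)/anterior(-),
z = superior(+)/inferior(-) (DICOM LPS).  Dose and mask grids participating
in a comparison must live on the same lattice; there is no on-the-fly
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Grid3D",
    "StructureMask",
    "ContourStack",
    "ContourSlice",
    "MarginSpec",
    "DoseGrid",
    "GridCompatibilityError",
]

#: tolerance (mm) within which two grids are considered geometrically equal
GRID_TOL_MM = 1e-6


class GridCompatibilityError(ValueError):
    """Raised when two objects do not share the same voxel lattice."""


@dataclass(frozen=True)
class Grid3D:
    """A regular 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (z, y, x); every entry >= 1.
    spacing
        Voxel pitch in mm along (z, y, x); strictly positive.
    origin
        Patient-space position (mm) of the *center* of voxel (0, 0, 0),
        ordered (z, y, x).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def axis_coords(self, axis: int) -> np.ndarray:
        """Patient-space mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def z_index(self, z_mm: float) -> int:
        """Map a z position (mm) to its slice index.

        Raises
        ------
        ValueError
            If ``z_mm`` is farther than half a slice thickness from every
            slice center.
        """
        dz = self.spacing[0]
        idx = int(round((z_mm - self.origin[0]) / dz))
        if idx < 0 or idx >= self.shape[0] or abs(z_mm - (self.origin[0] + idx * dz)) > dz / 2 + GRID_TOL_MM:
            raise ValueError(
                f"z = {z_mm} mm does not map to a slice of grid with origin_z = "
                f"{self.origin[0]}, dz = {dz}, nz = {self.shape[0]}"
            )
        return idx

    def compatible_with(self, other: "Grid3D") -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= GRID_TOL_MM for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= GRID_TOL_MM for a, b in zip(self.origin, other.origin))
        )

    def require_compatible(self, other: "Grid3D", what: str = "grids") -> None:
        if not self.compatible_with(other):
            raise GridCompatibilityError(
                f"incompatible {what}: {self} vs {other}; comparisons require one lattice"
            )


def _as_bool_array(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    arr = np.asarray(voxels, dtype=bool)
    if arr.shape != shape:
        raise ValueError(f"voxel array shape {arr.shape} != grid shape {shape}")
    return arr


@dataclass
class StructureMask:
    """A named organ/target as a binary occupancy mask on a :class:`Grid3D`."""

    name: str
    grid: Grid3D
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = _as_bool_array(self.voxels, self.grid.shape)

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def with_voxels(self, voxels: np.ndarray, name: str | None = None) -> "StructureMask":
        return StructureMask(name if name is not None else self.name, self.grid, voxels)

    def center_coords_mm(self) -> np.ndarray:
        """(N, 3) array of occupied voxel-center positions, mm, (z, y, x)."""
        idx = np.argwhere(self.voxels)
        return idx * np.asarray(self.grid.spacing) + np.asarray(self.grid.origin)


@dataclass
class ContourSlice:
    """All closed planar polygons of one structure on one axial slice.

    Each polygon is an (N, 2) float array of (y, x) vertices in mm with
    N >= 3; closure is implicit (the last vertex connects back to the first
    and is not repeated).
    """

    z_mm: float
    polygons: list[np.ndarray]

    def __post_init__(self) -> None:
        polys = []
        for p in self.polygons:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(
                    f"polygon on slice z={self.z_mm} mm must be (N>=3, 2), got {arr.shape}"
                )
            polys.append(arr)
        self.polygons = polys


@dataclass
class ContourStack:
    """A structure as per-slice closed polygons (the RT Structure Set view)."""

    name: str
    slices: list[ContourSlice]

    def __iter__(self) -> Iterator[ContourSlice]:
        return iter(self.slices)

    @property
    def n_polygons(self) -> int:
        return sum(len(s.polygons) for s in self.slices)


@dataclass(frozen=True)
class MarginSpec:
    """Anisotropic CTV-to-PTV margins in mm, one per patient-space direction.

    ``posterior`` commonly differs from the rest (smaller, to spare the
    rectum).  All margins must be >= 0.
    """

    anterior: float = 7.0
    posterior: float = 5.0
    left: float = 7.0
    right: float = 7.0
    superior: float = 7.0
    inferior: float = 7.0

    def __post_init__(self) -> None:
        for f in ("anterior", "posterior", "left", "right", "superior", "inferior"):
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"margin {f!r} must be finite and >= 0, got {v}")

    @classmethod
    def isotropic(cls, m: float) -> "MarginSpec":
        return cls(m, m, m, m, m, m)

    def as_half_axes(self) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
        """Half-axis lengths per (z, y, x) axis as (negative-side, positive-side).

        Axis signs follow LPS: +z superior, +y posterior, +x left.
        """
        return (
            (self.inferior, self.superior),
            (self.anterior, self.posterior),
            (self.right, self.left),
        )


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) per voxel plus the plan's prescription dose."""

    grid: Grid3D
    dose: np.ndarray
    prescription: float

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(f"dose shape {self.dose.shape} != grid shape {self.grid.shape}")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        if not (self.prescription > 0):
            raise ValueError(f"prescription must be > 0 Gy, got {self.prescription}")
        self.prescription = float(self.prescription)
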