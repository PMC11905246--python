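"""Shared fixtures and small-geometry helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from doseval.grid import DoseGrid, Grid3D, StructureMask


def make_grid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Grid3D:
    return Grid3D(shape, spacing, origin)


def make_mask(grid: Grid3D, coords, name: str = "m") -> StructureMask:
    v = np.zeros(grid.shape, dtype=bool)
    for c in coords:
        v[tuple(c)] = True
    return StructureMask(name, grid, v)


def random_blob(grid: Grid3D, rng: np.random.Generator, scale: float = 2.0) -> StructureMask:
    """A solid, opened random blob (no single-voxel-thin features)."""
    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=scale)
    v = noise > np.quantile(noise, 0.8)
    v = ndimage.binary_opening(v, structure=ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(v)
    if n == 0:  # pragma: no cover - regenerate on degenerate draw
        return random_blob(grid, rng, scale)
    sizes = np.bincount(labels.ravel())[1:]
    v = labels == (int(np.argmax(sizes)) + 1)
    return StructureMask("blob", grid, v)


def uniform_dose(grid: Grid3D, value: float, prescription: float) -> DoseGrid:
    return DoseGrid(grid, np.full(grid.shape, float(value)), prescription)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
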