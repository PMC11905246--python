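"""Plan-quality indices and clinical dose-constraint checking.

Homogeneity index  HI = (D2% - D98%) / D50%  — 0 for a perfectly uniform
target dose; lower is better.

Conformity index   CI = (TV_RI / TV) * (TV_RI / V_RI)  — TV is the target
volume, V_RI the volume of the reference isodose (by default 95% of the
prescription dose), TV_RI their intersection.  The first factor is target
coverage, the second healthy-tissue sparing; CI is in [0, 1] with 1 the
optimum (reference isodose exactly conformal to the target).

Constraint checking evaluates a JSON-configurable list of per-structure
rules (Dx%, VdGy, V at %PD, Dmean, Dmax) against computed DVHs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dvh import DVH, compute_dvh
from .grid import DoseGrid, StructureMask

__all__ = [
    "ConformityInputs",
    "homogeneity_index",
    "conformity_index",
    "DoseCriteria",
    "Rule",
    "evaluate_criteria",
    "load_criteria",
    "default_criteria",
]


def homogeneity_index(dvh: DVH) -> float:
    """HI = (D2% - D98%) / D50%; invariant to uniform dose scaling.

    Raises
    ------
    ValueError
        If D50% is zero (no meaningful normalization).
    """
    d2 = dvh.dose_at_volume(2)
    d98 = dvh.dose_at_volume(98)
    d50 = dvh.dose_at_volume(50)
    if d50 == 0:
        raise ValueError(f"HI undefined: D50% of {dvh.structure!r} is 0 Gy")
    return (d2 - d98) / d50


@dataclass(frozen=True)
class ConformityInputs:
    """Volumes entering the conformity index, in mm^3."""

    tv: float  # target volume
    tv_ri: float  # target volume inside the reference isodose
    v_ri: float  # total reference isodose volume
    reference_dose_gy: float

    def __post_init__(self) -> None:
        if not (0 <= self.tv_ri <= min(self.tv, self.v_ri) + 1e-9):
            raise ValueError(f"inconsistent conformity volumes: {self}")


def conformity_index(
    target: StructureMask,
    dose: DoseGrid,
    ref_fraction: float = 95.0,
) -> tuple[float, ConformityInputs]:
    """CI = (TV_RI/TV) * (TV_RI/V_RI) with the reference isodose at
    ``ref_fraction`` percent of the prescription dose.

    The reference isodose volume V_RI is counted over the whole dose grid
    (no external/body contour is modelled).  If no voxel reaches the
    reference dose, CI is defined as 0.
    """
    dose.grid.require_compatible(target.grid, "dose/target grids")
    if target.is_empty:
        raise ValueError("conformity index requires a nonempty target")
    level = ref_fraction / 100.0 * dose.prescription
    ri = dose.dose >= level
    vv = target.grid.voxel_volume_mm3
    tv = target.voxel_count * vv
    v_ri = int(np.count_nonzero(ri)) * vv
    tv_ri = int(np.count_nonzero(ri & target.voxels)) * vv
    inputs = ConformityInputs(tv=tv, tv_ri=tv_ri, v_ri=v_ri, reference_dose_gy=level)
    if v_ri == 0:
        return 0.0, inputs
    return (tv_ri / tv) * (tv_ri / v_ri), inputs


# ---------------------------------------------------------------------------
# clinical criteria
# ---------------------------------------------------------------------------

_OPS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class Rule:
    """One clinical dose rule for one structure.

    ``metric`` is one of:

    - ``{"kind": "D", "volume_pct": x}``          — Dx% in Gy
    - ``{"kind": "V", "dose_gy": d}``             — Vd in % volume
    - ``{"kind": "V", "dose_pct_pd": p}``         — V at p% of prescription
    - ``{"kind": "Dmean"} / {"kind": "Dmax"} / {"kind": "Dmin"}`` — Gy
    """

    structure: str
    metric: dict[str, Any]
    op: str
    limit: float
    units: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparison operator {self.op!r}")
        if not (self.limit > 0):
            raise ValueError(f"rule threshold must be positive, got {self.limit}")

    def metric_label(self) -> str:
        m = self.metric
        kind = m["kind"]
        if kind == "D":
            return f"D{m['volume_pct']:g}%/Gy"
        if kind == "V":
            if "dose_gy" in m:
                return f"V{m['dose_gy']:g}Gy/%"
            return f"V({m['dose_pct_pd']:g}%PD)/%"
        return f"{kind}/Gy"

    def achieved(self, dvh: DVH, prescription: float) -> float:
        m = self.metric
        kind = m["kind"]
        if kind == "D":
            return dvh.dose_at_volume(float(m["volume_pct"]))
        if kind == "V":
            d = float(m["dose_gy"]) if "dose_gy" in m else float(m["dose_pct_pd"]) / 100.0 * prescription
            return dvh.volume_at_dose(d)
        if kind == "Dmean":
            return dvh.dmean
        if kind == "Dmax":
            return dvh.dmax
        if kind == "Dmin":
            return dvh.dmin
        raise ValueError(f"unknown metric kind {kind!r}")


@dataclass
class DoseCriteria:
    """A named set of clinical rules (one treatment technique's Table)."""

    name: str
    rules: list[Rule] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DoseCriteria":
        rules = [
            Rule(
                structure=r["structure"],
                metric=r["metric"],
                op=r["op"],
                limit=float(r["limit"]),
                units=r.get("units", ""),
                note=r.get("note", ""),
            )
            for r in d.get("rules", [])
        ]
        return cls(name=d.get("name", "criteria"), rules=rules)

    def structures(self) -> set[str]:
        return {r.structure for r in self.rules}


def load_criteria(path: str | Path) -> DoseCriteria:
    """Load a criteria set from a JSON file."""
    with open(path) as f:
        return DoseCriteria.from_dict(json.load(f))


def default_criteria(technique: str = "box4") -> DoseCriteria:
    """The clinical objectives shipped with the package.

    ``technique`` is ``"box4"`` (3D-CRT-style, 70 Gy) or ``"imrt_like"``
    (78 Gy).  The rectum V65 threshold in the 3D-CRT set is flagged in its
    ``note``: the source table cell is ambiguous and < 25% is an encoding
    choice, not a verified clinical limit.
    """
    fname = {"box4": "criteria_3dcrt.json", "imrt_like": "criteria_imrt.json"}.get(technique)
    if fname is None:
        raise ValueError(f"unknown technique {technique!r}")
    with resources.files("doseval.data").joinpath(fname).open() as f:
        return DoseCriteria.from_dict(json.load(f))


def evaluate_criteria(
    dose: DoseGrid,
    structures: dict[str, StructureMask],
    criteria: DoseCriteria,
) -> pd.DataFrame:
    """Evaluate every rule of a criteria set against one plan.

    Returns a DataFrame with one row per rule (structure, metric, achieved,
    operator, limit, passed) plus ``.attrs["overall"]`` — the AND of all
    rules (vacuously True, with a warning, for an empty rule list).

    Raises
    ------
    KeyError
        If a rule references a structure not supplied.
    """
    missing = sorted(criteria.structures() - set(structures))
    if missing:
        raise KeyError(f"criteria reference missing structures: {missing}")
    if not criteria.rules:
        warnings.warn("empty criteria list: plan passes vacuously", stacklevel=2)
    dvhs = {
        name: compute_dvh(dose, structures[name]) for name in criteria.structures()
    }
    rows = []
    for r in criteria.rules:
        achieved = r.achieved(dvhs[r.structure], dose.prescription)
        ok = bool(_OPS[r.op](achieved, r.limit))
        rows.append(
            {
                "structure": r.structure,
                "metric": r.metric_label(),
                "achieved": achieved,
                "op": r.op,
                "limit": r.limit,
                "passed": ok,
                "note": r.note,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["structure", "metric", "achieved", "op", "limit", "passed", "note"],
    )
    df.attrs["overall"] = bool(df["passed"].all()) if len(df) else True
    return df
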