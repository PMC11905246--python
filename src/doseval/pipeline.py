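"""End-to-end evaluation pipeline: contours -> plans -> DVH/gamma -> statistics.

For every case and contour set the pipeline computes geometric agreement
against the reference set, the technique's DVH parameter panel, HI/CI and
clinical-criteria verdicts for each plan, and the 3D gamma pass rate of the
auto-contour plan's dose against the reference plan's dose; it then runs
the cohort-level paired statistics and writes the report tables.

Each plan's DVH metrics are evaluated on its own contour set's structures
(the planning view: an AC plan is the plan a clinic would deliver if it
trusted the auto contours).  Everything is deterministic given the cohort.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import DVH, compute_dvh
from .gamma import GammaCriteria, gamma_map
from .geometry import geometry_report
from .grid import DoseGrid, StructureMask
from .io import load_dose, load_mask, read_manifest
from .phantom import Case
from .quality import DoseCriteria, conformity_index, default_criteria, evaluate_criteria, homogeneity_index
from .stats import compare_contour_sets, mann_whitney_u

__all__ = ["run_pipeline", "dvh_metric_panel", "PipelineResult"]

log = logging.getLogger("doseval")

# DVH parameter panels per technique, following institutional convention:
# Dx% in Gy, VdGy in percent volume.
_PANEL_BOX4: dict[str, list[str]] = {
    "PTV": ["D98%", "D95%", "D2%", "Dmax", "Dmean", "HI", "CI"],
    "bladder": ["V50Gy", "V65Gy", "Dmax", "Dmean"],
    "rectum": ["V50Gy", "V65Gy", "Dmax", "Dmean"],
    "RFH": ["Dmax", "Dmean"],
    "LFH": ["Dmax", "Dmean"],
}
_PANEL_IMRT: dict[str, list[str]] = {
    "PTV": ["D98%", "D95%", "D2%", "V78Gy", "Dmean", "Dmax", "HI", "CI"],
    "bladder": ["V65Gy", "V70Gy", "V75Gy", "Dmean"],
    "rectum": ["V50Gy", "V60Gy", "V65Gy", "V70Gy", "V75Gy", "Dmax", "Dmean"],
    "RFH": ["Dmax", "Dmean"],
    "LFH": ["Dmax", "Dmean"],
}


def dvh_metric_panel(technique: str) -> dict[str, list[str]]:
    """The per-structure DVH parameter list reported for a technique."""
    if technique == "box4":
        return {k: list(v) for k, v in _PANEL_BOX4.items()}
    if technique == "imrt_like":
        return {k: list(v) for k, v in _PANEL_IMRT.items()}
    raise ValueError(f"unknown technique {technique!r}")


def _eval_metric(
    label: str, dvh: DVH, dose: DoseGrid, target: StructureMask
) -> float:
    if label == "HI":
        return homogeneity_index(dvh)
    if label == "CI":
        return conformity_index(target, dose)[0]
    if label == "Dmax":
        return dvh.dmax
    if label == "Dmean":
        return dvh.dmean
    if label == "Dmin":
        return dvh.dmin
    if label.startswith("D") and label.endswith("%"):
        return dvh.dose_at_volume(float(label[1:-1]))
    if label.startswith("V") and label.endswith("Gy"):
        return dvh.volume_at_dose(float(label[1:-2]))
    raise ValueError(f"unknown DVH metric label {label!r}")


@dataclass
class _Bundle:
    """Normalized per-case inputs (from memory or from a manifest)."""

    case_id: str
    prescription: float
    technique: str
    structures: dict[str, dict[str, StructureMask]]
    ptv: dict[str, StructureMask]
    dose: dict[str, DoseGrid]


def _bundle_from_case(case: Case) -> _Bundle:
    return _Bundle(
        case.case_id,
        case.prescription,
        case.technique,
        case.structures,
        case.ptv,
        case.dose,
    )


def _bundle_from_manifest_entry(entry: dict) -> _Bundle:
    structures = {}
    ptv = {}
    dose = {}
    for cs, sets in entry["sets"].items():
        structures[cs] = {organ: load_mask(p) for organ, p in sets["structures"].items()}
        ptv[cs] = load_mask(sets["ptv"])
        if sets.get("dose") is not None:
            dose[cs] = load_dose(sets["dose"])
    return _Bundle(
        entry["id"], entry["prescription"], entry["technique"], structures, ptv, dose
    )


@dataclass
class PipelineResult:
    """All cohort-level tables produced by one pipeline run."""

    geometry: pd.DataFrame  # per case x organ x pair
    dsc_summary: pd.DataFrame  # per organ: DSC mean/SD per pair + Mann-Whitney p
    dosimetry: pd.DataFrame  # tidy per case x structure x metric x set
    comparison: pd.DataFrame  # per structure x metric with deltas and Wilcoxon p
    gamma: pd.DataFrame  # per case pass rate
    criteria: pd.DataFrame  # per case x set x rule verdicts

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.geometry.to_csv(out / "geometry_per_case.csv", index=False)
        self.dsc_summary.to_csv(out / "dsc_summary.csv", index=False)
        self.dosimetry.to_csv(out / "dosimetry_per_case.csv", index=False)
        self.comparison.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.json").write_text(
            json.dumps(json.loads(self.comparison.to_json(orient="records")), indent=1)
        )
        self.gamma.to_csv(out / "gamma_per_case.csv", index=False)
        self.criteria.to_csv(out / "criteria_verdicts.csv", index=False)
        return out


_PAIRS = (("EC", "OC"), ("AC", "OC"), ("AC", "EC"))


def run_pipeline(
    cohort,
    criteria: DoseCriteria | None = None,
    gamma_criteria: GammaCriteria = GammaCriteria(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Evaluate a cohort end to end and (optionally) write the report files.

    Parameters
    ----------
    cohort
        A list of in-memory cases (from :func:`doseval.phantom.generate_cohort`)
        or a path to a cohort ``manifest.json``.
    criteria
        Clinical rules to check per plan; defaults to the shipped set for
        the cohort's technique.
    gamma_criteria
        Gamma test settings (default 3%/3 mm global, 10% cutoff).
    out_dir
        If given, report CSV/JSON files are written there.

    Incomplete cases (missing a contour set, PTV or plan) are skipped with a
    logged reason; if every case is skipped a :class:`RuntimeError` is raised.
    """
    if isinstance(cohort, (str, Path)):
        bundles = [_bundle_from_manifest_entry(e) for e in read_manifest(cohort)]
    else:
        bundles = [_bundle_from_case(c) for c in cohort]

    geometry_rows = []
    dosimetry_rows = []
    gamma_rows = []
    criteria_frames = []

    n_done = 0
    for b in bundles:
        t0 = time.perf_counter()
        missing = [
            cs for cs in ("OC", "EC", "AC") if cs not in b.structures or cs not in b.dose
        ]
        if missing:
            log.warning("skipping %s: incomplete sets %s", b.case_id, missing)
            continue
        crit = criteria if criteria is not None else default_criteria(b.technique)
        panel = dvh_metric_panel(b.technique)

        # geometric agreement vs the reference (and between AC and EC)
        for test, ref in _PAIRS:
            for organ in b.structures[ref]:
                rep = geometry_report(b.structures[test][organ], b.structures[ref][organ])
                geometry_rows.append(
                    {"case": b.case_id, "structure": organ, "pair": f"{test}-{ref}", **rep.as_dict()}
                )

        # per-plan dosimetric panel + criteria verdicts
        for cs in ("EC", "OC", "AC"):
            dose = b.dose[cs]
            structs = dict(b.structures[cs])
            structs["PTV"] = b.ptv[cs]
            for organ, labels in panel.items():
                dvh = compute_dvh(dose, structs[organ])
                for label in labels:
                    dosimetry_rows.append(
                        {
                            "case": b.case_id,
                            "structure": organ,
                            "metric": label,
                            "set": cs,
                            "value": _eval_metric(label, dvh, dose, structs["PTV"]),
                        }
                    )
            verdicts = evaluate_criteria(dose, structs, crit)
            verdicts.insert(0, "set", cs)
            verdicts.insert(0, "case", b.case_id)
            criteria_frames.append(verdicts)

        # dose-distribution agreement: AC plan vs OC plan
        res = gamma_map(b.dose["OC"], b.dose["AC"], gamma_criteria)
        gamma_rows.append(
            {
                "case": b.case_id,
                "pair": "AC-OC",
                "pass_rate_pct": res.pass_rate,
                "n_evaluated": res.n_evaluated,
                "mean_gamma": float(np.nanmean(res.values)),
            }
        )
        n_done += 1
        log.info("case %s evaluated in %.2f s", b.case_id, time.perf_counter() - t0)

    if n_done == 0:
        raise RuntimeError("no complete case bundle could be evaluated")

    geometry = pd.DataFrame(geometry_rows)
    dosimetry = pd.DataFrame(dosimetry_rows)
    criteria_df = pd.concat(criteria_frames, ignore_index=True)
    gamma_df = pd.DataFrame(gamma_rows)

    # DSC summary per organ with Mann-Whitney tests between pairs
    dsc_rows = []
    for organ, grp in geometry.groupby("structure", sort=False):
        row: dict[str, object] = {"structure": organ}
        samples = {}
        for test, ref in _PAIRS:
            pair = f"{test}-{ref}"
            vals = grp.loc[grp["pair"] == pair, "dsc"].to_numpy()
            samples[pair] = vals
            row[f"dsc_{pair}_mean"] = vals.mean()
            row[f"dsc_{pair}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        for other in ("AC-OC", "AC-EC"):
            if np.allclose(samples["EC-OC"], samples[other]) and np.ptp(
                np.concatenate([samples["EC-OC"], samples[other]])
            ) == 0:
                row[f"p_ecoc_vs_{other.replace('-', '').lower()}"] = np.nan
            else:
                _, p = mann_whitney_u(samples["EC-OC"], samples[other])
                row[f"p_ecoc_vs_{other.replace('-', '').lower()}"] = p
        dsc_rows.append(row)
    dsc_summary = pd.DataFrame(dsc_rows)

    comparison = compare_contour_sets(dosimetry)

    result = PipelineResult(
        geometry=geometry,
        dsc_summary=dsc_summary,
        dosimetry=dosimetry,
        comparison=comparison,
        gamma=gamma_df,
        criteria=criteria_df,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
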