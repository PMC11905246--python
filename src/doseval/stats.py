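"""Paired nonparametric statistics and contour-set comparison tables.

Wilcoxon signed-rank: exact two-sided p by enumeration of all 2^n sign
assignments when n <= 20 after dropping zero differences (realized as a
dynamic-programming convolution over doubled midranks, which handles ties
exactly); tie- and continuity-corrected normal approximation otherwise.

Mann-Whitney U: exact two-sided p when n + m <= 16 and there are no ties;
tie-corrected, continuity-corrected normal approximation otherwise.

The comparison-report builder assembles, per structure x metric, the
mean +/- SD of each contour set (expert EC, reference OC, automated AC),
the per-case absolute differences |EC-OC| and |AC-OC|, and Wilcoxon
signed-rank p-values, mirroring a clinical dosimetric comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "abs_diff_summary",
    "compare_contour_sets",
    "WILCOXON_EXACT_MAX_N",
    "MANNWHITNEY_EXACT_MAX_NM",
]

#: exact-enumeration switchover thresholds (desk-scale runtime)
WILCOXON_EXACT_MAX_N = 20
MANNWHITNEY_EXACT_MAX_NM = 16


@dataclass
class PairedSample:
    """Per-case values of one metric under two labels, same cases, same order."""

    label_a: str
    label_b: str
    a: np.ndarray
    b: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.a.size != self.b.size:
            raise ValueError(
                f"paired sample lengths differ: {self.a.size} vs {self.b.size}"
            )
        if self.a.size < 1:
            raise ValueError("paired sample must contain at least one case")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by full enumeration.

    Enumerates the null distribution of W+ over all 2^n sign assignments via
    a DP convolution on doubled ranks (midranks are multiples of 1/2, so
    doubling makes them integers).  p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired: PairedSample, exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment).  Exact enumeration for n <= ``exact_max_n``; otherwise the
    tie-corrected normal approximation with continuity correction.

    Raises
    ------
    ValueError
        If every difference is zero (the test is undefined).
    """
    d = paired.differences
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("Wilcoxon signed-rank undefined: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        _, p = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        p = float(p)
    return w_plus, p


def mann_whitney_u(
    x: np.ndarray,
    y: np.ndarray,
    exact_max_nm: int = MANNWHITNEY_EXACT_MAX_NM,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent samples; returns (U, p).

    Exact p by enumeration over the C(n+m, n) rank arrangements when
    n + m <= ``exact_max_nm`` and there are no ties; tie-corrected,
    continuity-corrected normal approximation otherwise.  U is the statistic
    of the first sample; swapping the samples maps U to n*m - U and leaves p
    unchanged.

    Raises
    ------
    ValueError
        If either sample is empty.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two nonempty samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= exact_max_nm and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def abs_diff_summary(paired: PairedSample) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the per-case |A - B|.

    Raises
    ------
    ValueError
        If fewer than two cases (SD undefined).
    """
    d = np.abs(paired.differences)
    if d.size < 2:
        raise ValueError("SD of absolute differences requires n >= 2 cases")
    return float(d.mean()), float(d.std(ddof=1))


def compare_contour_sets(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Build the per-structure, per-metric comparison table for three contour sets.

    Parameters
    ----------
    metrics
        Tidy per-case table with columns ``case``, ``structure``, ``metric``,
        ``set`` (values ``EC``, ``OC``, ``AC``) and ``value``.  All three
        sets must cover the same cases for every structure x metric.
    alpha
        Significance threshold for the flag columns.
    holm
        Apply a Holm step-down correction across all rows (off by default,
        matching a per-metric 0.05 threshold).

    Returns
    -------
    pandas.DataFrame
        One row per structure x metric with the set means/SDs, the
        |EC-OC| and |AC-OC| summaries, Wilcoxon p-values and significance
        flags.  When all per-case differences are zero the p-value is NaN
        and the ``p_*_defined`` flag is False.

    Raises
    ------
    ValueError
        If the three sets do not cover identical case lists.
    """
    required = {"case", "structure", "metric", "set", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    rows = []
    for (structure, metric), grp in metrics.groupby(["structure", "metric"], sort=False):
        pivot = grp.pivot_table(index="case", columns="set", values="value")
        for s in ("EC", "OC", "AC"):
            if s not in pivot.columns:
                raise ValueError(f"contour set {s!r} missing for {structure}/{metric}")
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()
        if missing:
            raise ValueError(
                f"cases missing values for {structure}/{metric}: {missing}"
            )
        row: dict[str, object] = {"structure": structure, "metric": metric}
        for s in ("EC", "OC", "AC"):
            row[f"{s.lower()}_mean"] = pivot[s].mean()
            row[f"{s.lower()}_sd"] = pivot[s].std(ddof=1) if len(pivot) > 1 else np.nan
        for test_set, tag in (("EC", "ec_oc"), ("AC", "ac_oc")):
            ps = PairedSample(test_set, "OC", pivot[test_set].values, pivot["OC"].values)
            d = np.abs(ps.differences)
            row[f"d_{tag}_mean"] = d.mean()
            row[f"d_{tag}_sd"] = d.std(ddof=1) if d.size > 1 else np.nan
            try:
                _, p = wilcoxon_signed_rank(ps)
                row[f"p_{tag}"] = p
                row[f"p_{tag}_defined"] = True
            except ValueError:
                row[f"p_{tag}"] = np.nan
                row[f"p_{tag}_defined"] = False
        rows.append(row)
    report = pd.DataFrame(rows)
    for tag in ("ec_oc", "ac_oc"):
        pvals = report[f"p_{tag}"]
        if holm:
            adj = _holm(pvals.values)
            report[f"p_{tag}"] = adj
            pvals = report[f"p_{tag}"]
        report[f"sig_{tag}"] = pvals < alpha
    return report


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    adj = np.full_like(p, np.nan)
    if m == 0:
        return adj
    order = np.argsort(p[ok])
    scaled = p[ok][order] * (m - np.arange(m))  # (m - rank + 1) * p_(rank)
    stepped = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = stepped
    adj[ok] = out
    return adj
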