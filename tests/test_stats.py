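"""Paired nonparametric tests (exact and approximate paths) and report tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from doseval.stats import (
    PairedSample,
    abs_diff_summary,
    compare_contour_sets,
    mann_whitney_u,
    wilcoxon_signed_rank,
)


def paired(a, b):
    return PairedSample("A", "B", np.asarray(a, float), np.asarray(b, float))


def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact p by literal enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_five_positive_differences(self):
        w, p = wilcoxon_signed_rank(paired([1, 2, 3, 4, 5], [0, 0, 0, 0, 0]))
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    def test_six_same_sign(self):
        _, p = wilcoxon_signed_rank(paired([0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6]))
        assert p == pytest.approx(2 / 64)

    def test_antisymmetric_ties_give_p_one(self):
        _, p = wilcoxon_signed_rank(paired([1, -1], [0, 0]))
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(paired([1, 2], [1, 2]))

    def test_zero_differences_dropped_before_ranking(self):
        # the three zero pairs must not influence the statistic
        a = [5, 6, 7, 1, 2, 3]
        b = [5, 6, 7, 0, 0, 0]
        _, p = wilcoxon_signed_rank(paired(a, b))
        _, p_ref = wilcoxon_signed_rank(paired([1, 2, 3], [0, 0, 0]))
        assert p == pytest.approx(p_ref)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.3, 1.0, 9), 1)  # rounded -> occasional ties
        d = d[d != 0]
        _, p = wilcoxon_signed_rank(paired(d, np.zeros_like(d)))
        assert p == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_exact_and_approx_agree_for_moderate_n(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            d = rng.normal(0.2, 1.0, 18)
            ps = paired(d, np.zeros_like(d))
            _, p_exact = wilcoxon_signed_rank(ps)  # n=18 <= 20 -> exact
            _, p_approx = wilcoxon_signed_rank(ps, exact_max_n=0)  # force approximation
            assert p_approx == pytest.approx(p_exact, abs=0.02)


class TestMannWhitney:
    def test_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))
        assert px == pytest.approx(py)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0])

    def test_exact_matches_full_enumeration(self):
        # C(6,3)=20 arrangements enumerated literally
        x, y = [1.2, 3.4, 0.5], [2.2, 4.1, 5.0]
        _, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        n = len(x)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        us = []
        for combo in itertools.combinations(range(6), n):
            r = ranks[list(combo)]
            us.append(r.sum() - n * (n + 1) / 2)
        us = np.asarray(us)
        p_or = min(1.0, 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
        assert p == pytest.approx(p_or, abs=1e-12)


class TestAbsDiffSummary:
    def test_identical_sets(self):
        assert abs_diff_summary(paired([1, 2, 3], [1, 2, 3])) == pytest.approx((0.0, 0.0))

    def test_closed_form(self):
        mean, sd = abs_diff_summary(paired([1, 3], [0, 0]))
        assert (mean, sd) == pytest.approx((2.0, np.sqrt(2.0)))

    def test_swap_invariance(self):
        a, b = [3.0, 1.0, 4.0], [1.0, 5.0, 9.0]
        assert abs_diff_summary(paired(a, b)) == pytest.approx(abs_diff_summary(paired(b, a)))

    def test_single_case_sd_undefined(self):
        with pytest.raises(ValueError, match="n >= 2"):
            abs_diff_summary(paired([1], [2]))


def tidy(values_by_set, structure="PTV", metric="D95%"):
    rows = []
    for s, vals in values_by_set.items():
        for i, v in enumerate(vals):
            rows.append({"case": f"c{i}", "structure": structure, "metric": metric, "set": s, "value": v})
    return pd.DataFrame(rows)


class TestCompareContourSets:
    def test_identical_tables_flagged_undefined(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        report = compare_contour_sets(tidy({"EC": vals, "OC": vals, "AC": vals}))
        row = report.iloc[0]
        assert row["d_ec_oc_mean"] == 0.0 and row["d_ac_oc_mean"] == 0.0
        assert not row["p_ec_oc_defined"] and not row["p_ac_oc_defined"]
        assert np.isnan(row["p_ec_oc"])

    def test_constant_offset_matches_wilcoxon_example(self):
        oc = [10.0, 11.0, 12.0, 13.0, 14.0]
        ac = [v + 1.0 for v in oc]
        report = compare_contour_sets(tidy({"EC": oc, "OC": oc, "AC": ac}))
        row = report.iloc[0]
        assert (row["d_ac_oc_mean"], row["d_ac_oc_sd"]) == pytest.approx((1.0, 0.0))
        assert row["p_ac_oc"] == pytest.approx(0.0625)
        assert not row["sig_ac_oc"]

    def test_schema_columns(self):
        vals = [1.0, 2.0, 3.0]
        report = compare_contour_sets(tidy({"EC": vals, "OC": [2.0, 2.5, 3.5], "AC": [1.5, 2.1, 3.2]}))
        expected = {
            "structure", "metric",
            "ec_mean", "ec_sd", "oc_mean", "oc_sd", "ac_mean", "ac_sd",
            "d_ec_oc_mean", "d_ec_oc_sd", "d_ac_oc_mean", "d_ac_oc_sd",
            "p_ec_oc", "p_ac_oc", "p_ec_oc_defined", "p_ac_oc_defined",
            "sig_ec_oc", "sig_ac_oc",
        }
        assert expected <= set(report.columns)

    def test_missing_set_or_case_rejected(self):
        df = tidy({"EC": [1.0, 2.0], "OC": [1.0, 2.0]})
        with pytest.raises(ValueError, match="AC"):
            compare_contour_sets(df)
        df2 = tidy({"EC": [1.0, 2.0], "OC": [1.0, 2.0], "AC": [1.0, 2.0]})
        df2 = df2.drop(df2[(df2["set"] == "AC") & (df2["case"] == "c1")].index)
        with pytest.raises(ValueError, match="c1"):
            compare_contour_sets(df2)

    def test_holm_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(4)
        frames = []
        for metric in ("D95%", "D2%", "Dmean"):
            oc = rng.normal(70, 1, 8)
            frames.append(tidy({"EC": oc + rng.normal(0.5, 0.3, 8), "OC": oc, "AC": oc + rng.normal(0, 0.3, 8)}, metric=metric))
        df = pd.concat(frames, ignore_index=True)
        plain = compare_contour_sets(df)
        holm = compare_contour_sets(df, holm=True)
        assert np.all(holm["p_ec_oc"].values >= plain["p_ec_oc"].values - 1e-12)
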