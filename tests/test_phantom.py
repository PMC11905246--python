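"""Synthetic phantom: organs, observer perturbation, dose surrogates, cohorts."""

import numpy as np
import pytest

from doseval.dvh import compute_dvh
from doseval.geometry import dice
from doseval.grid import MarginSpec
from doseval.phantom import (
    ORGANS,
    DoseModel,
    ObserverModel,
    PhantomSpec,
    generate_cohort,
    generate_dose,
    generate_phantom,
    perturb_structure,
)
from doseval.structures import expand_margin, signed_distance


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="module")
def ptv(phantom):
    return expand_margin(phantom["CTV"], MarginSpec(7, 5.5, 7, 7, 7, 7))


class TestGeneratePhantom:
    def test_deterministic_given_seed(self, phantom):
        again = generate_phantom(PhantomSpec(seed=1))
        for organ in ORGANS:
            assert np.array_equal(phantom[organ].voxels, again[organ].voxels)

    def test_different_seed_differs(self, phantom):
        other = generate_phantom(PhantomSpec(seed=2))
        assert not np.array_equal(phantom["CTV"].voxels, other["CTV"].voxels)

    @pytest.mark.parametrize("seed", range(12))
    def test_organs_pairwise_disjoint(self, seed):
        masks = generate_phantom(PhantomSpec(seed=seed))
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert not np.any(masks[a].voxels & masks[b].voxels), (a, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_ctv_volume_in_plausible_band(self, seed):
        v = generate_phantom(PhantomSpec(seed=seed))["CTV"].volume_cm3
        assert 20.0 <= v <= 80.0

    def test_organ_overflow_rejected(self):
        big = PhantomSpec(seed=0, femoral_lateral_x=95.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_phantom(big)


class TestPerturbStructure:
    def test_zero_amplitude_zero_shift_is_identity(self, phantom):
        m = phantom["CTV"]
        out = perturb_structure(m, ObserverModel(amplitude=0.0, seed=3))
        assert np.array_equal(out.voxels, m.voxels)

    def test_deterministic_given_seed(self, phantom):
        m = phantom["bladder"]
        a = perturb_structure(m, ObserverModel(amplitude=2.0, seed=9))
        b = perturb_structure(m, ObserverModel(amplitude=2.0, seed=9))
        assert np.array_equal(a.voxels, b.voxels)

    def test_dsc_decreases_with_amplitude_in_expectation(self, phantom):
        m = phantom["CTV"]
        sdf = signed_distance(m)
        means = []
        for amp in (0.5, 2.0, 4.0):
            vals = [
                dice(perturb_structure(m, ObserverModel(amplitude=amp, seed=s), _sdf=sdf), m)
                for s in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_systematic_shift_moves_structure(self, phantom):
        m = phantom["CTV"]
        out = perturb_structure(m, ObserverModel(amplitude=0.0, systematic_shift=(0, 4.0, 0), seed=0))
        com_in = np.argwhere(m.voxels).mean(axis=0)
        com_out = np.argwhere(out.voxels).mean(axis=0)
        assert com_out[1] - com_in[1] == pytest.approx(2.0, abs=0.3)  # +4 mm = +2 voxels

    def test_perturbation_emptying_mask_is_an_error(self, phantom):
        m = phantom["CTV"]
        with pytest.raises(ValueError, match="emptied|shift"):
            perturb_structure(m, ObserverModel(amplitude=0.0, systematic_shift=(0, 500.0, 0), seed=0))


class TestGenerateDose:
    @pytest.mark.parametrize("tech,pd_", [("box4", 70.0), ("imrt_like", 78.0)])
    def test_mean_ptv_dose_equals_prescription(self, ptv, tech, pd_):
        dose = generate_dose(ptv, DoseModel(technique=tech, prescription=pd_))
        mean = dose.dose[ptv.voxels].mean()
        assert mean == pytest.approx(pd_, rel=1e-3)

    @pytest.mark.parametrize("tech,pd_", [("box4", 70.0), ("imrt_like", 78.0)])
    def test_ptv_coverage_objective_met(self, ptv, tech, pd_):
        dose = generate_dose(ptv, DoseModel(technique=tech, prescription=pd_))
        v95 = compute_dvh(dose, ptv).volume_at_dose(0.95 * pd_)
        assert v95 > 95.0

    def test_imrt_far_field_limited_to_bath(self, ptv):
        model = DoseModel(technique="imrt_like", prescription=78.0)
        dose = generate_dose(ptv, model)
        sd = signed_distance(ptv)
        far = sd > model.coverage_margin + 5 * model.falloff
        assert far.any()
        assert dose.dose[far].max() <= (model.bath_fraction + 0.01) * 78.0

    def test_deterministic(self, ptv):
        m = DoseModel()
        a = generate_dose(ptv, m)
        b = generate_dose(ptv, m)
        assert np.array_equal(a.dose, b.dose)

    def test_coverage_violation_raises_with_diagnostics(self, ptv):
        bad = DoseModel(technique="box4", aperture_margin=0.5, penumbra_sigma=20.0)
        with pytest.raises(ValueError, match="coverage"):
            generate_dose(ptv, bad)

    def test_empty_ptv_rejected(self, phantom):
        empty = phantom["CTV"].with_voxels(np.zeros(phantom["CTV"].grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            generate_dose(empty, DoseModel())


class TestGenerateCohort:
    def test_counts_three_plans_per_case(self):
        cohort = generate_cohort(2, seed=3)
        assert len(cohort) == 2
        assert sum(len(c.dose) for c in cohort) == 6
        for c in cohort:
            assert set(c.contour_sets) == {"OC", "EC", "AC"}
            assert set(c.structures["OC"]) == set(ORGANS)

    def test_fully_deterministic(self):
        a = generate_cohort(1, seed=12)[0]
        b = generate_cohort(1, seed=12)[0]
        assert np.array_equal(a.structures["EC"]["CTV"].voxels, b.structures["EC"]["CTV"].voxels)
        assert np.array_equal(a.dose["AC"].dose, b.dose["AC"].dose)
        assert a.margins == b.margins

    def test_margins_sampled_in_clinical_range(self):
        for c in generate_cohort(4, seed=8, with_doses=False):
            m = c.margins
            assert 6.0 <= m.anterior <= 10.0
            assert m.anterior == m.left == m.right == m.superior == m.inferior
            assert 5.0 <= m.posterior <= 6.0
            assert m.posterior < m.anterior

    def test_degenerate_cohort_sets_identical(self):
        c = generate_cohort(1, seed=4, degenerate=True)[0]
        for organ in ORGANS:
            assert np.array_equal(c.structures["EC"][organ].voxels, c.structures["OC"][organ].voxels)
            assert np.array_equal(c.structures["AC"][organ].voxels, c.structures["OC"][organ].voxels)

    def test_each_ptv_from_own_ctv(self):
        c = generate_cohort(1, seed=6, with_doses=False)[0]
        for cs in ("OC", "EC", "AC"):
            expected = expand_margin(c.structures[cs]["CTV"], c.margins)
            assert np.array_equal(c.ptv[cs].voxels, expected.voxels)
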