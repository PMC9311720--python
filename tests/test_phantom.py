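import numpy as np
import pytest
from scipy import ndimage

from spacerstrat.grids import DoseGrid
from spacerstrat.phantom import (
    FalloffConfig,
    PhantomError,
    PhantomSpec,
    generate_phantom,
    label_plan,
    simulate_plan_dose,
)
from spacerstrat.radiobiology import FractionationScheme
from spacerstrat.stratify import default_constraint_table


class TestSpecValidation:
    def test_negative_volume_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(seed=0, prostate_volume_cc=-5.0)

    def test_wrong_boost_count_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(seed=0, boost_positions=(30.0, 60.0))

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(seed=0, spacing_mm=(0.0, 2.5, 2.5))

    def test_negative_margin_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(seed=0, margin_ptv68_mm=-1.0)


class TestGeneratePhantom:
    def test_seeded_determinism(self):
        spec = PhantomSpec.desk(11)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert a.masks.keys() == b.masks.keys()
        for name in a.masks:
            np.testing.assert_array_equal(a.masks[name], b.masks[name])

    def test_grid_too_small_names_structure(self):
        spec = PhantomSpec(seed=0, grid_shape=(16, 24, 24), spacing_mm=(3.0, 2.5, 2.5))
        with pytest.raises(PhantomError, match="grid too small|outside"):
            generate_phantom(spec)

    def test_rectum_posterior_to_prostate(self, ensemble30):
        for _, anatomy, _, _, _ in ensemble30[:10]:
            rect_y = ndimage.center_of_mass(anatomy.masks["rectum"])[1]
            pro_y = ndimage.center_of_mass(anatomy.masks["prostate"])[1]
            assert rect_y > pro_y

    def test_ptv68_nested_in_ptv60(self, ensemble30):
        for _, anatomy, _, _, _ in ensemble30[:10]:
            for name in anatomy.boost_names():
                assert np.all(~anatomy.masks[name] | anatomy.masks["ptv60"])

    def test_rectum_ptv68_overlap_is_small(self, ensemble30):
        for _, anatomy, _, _, _ in ensemble30[:10]:
            rectum = anatomy.masks["rectum"]
            for name in anatomy.boost_names():
                overlap = np.sum(rectum & anatomy.masks[name]) / rectum.sum()
                assert overlap < 0.20

    def test_ptv68_volumes_within_reported_range(self, ensemble30):
        """All boost PTV volumes fall inside the 3.0-31.7 cc clinical range."""
        for _, anatomy, _, _, _ in ensemble30:
            for name in anatomy.boost_names():
                assert 3.0 <= anatomy.volume_cc(name) <= 31.7

    def test_default_rectum_volume_near_cohort_mean(self):
        anatomy = generate_phantom(PhantomSpec(seed=3))
        assert anatomy.volume_cc("rectum") == pytest.approx(69.3, rel=0.20)

    def test_sampled_volumes_match_their_spec(self, ensemble30):
        for spec, anatomy, _, _, _ in ensemble30[:10]:
            assert anatomy.volume_cc("rectum") == pytest.approx(spec.rectum_volume_cc, rel=0.25)


class TestSimulatePlanDose:
    def test_zero_falloff_width_rejected(self):
        with pytest.raises(PhantomError):
            FalloffConfig(w53_mm=0.0)

    def test_seeded_determinism(self, desk_phantom):
        _, anatomy, boost, _ = desk_phantom
        cfg = FalloffConfig.sample(5)
        a = simulate_plan_dose(anatomy, boost, cfg)
        b = simulate_plan_dose(anatomy, boost, cfg)
        np.testing.assert_array_equal(a.dose_gy, b.dose_gy)

    def test_ptv68_median_within_band(self, ensemble30):
        for _, anatomy, boost, _, dose in ensemble30:
            ptv68 = anatomy.select_boost(boost).masks["ptv68"]
            assert 67.7 <= np.median(dose.dose_gy[ptv68]) <= 68.3

    def test_ptv60_coverage_by_direct_voxel_count(self, ensemble30):
        for _, anatomy, _, _, dose in ensemble30:
            ptv60 = anatomy.masks["ptv60"]
            covered = np.sum(dose.dose_gy[ptv60] >= 60.0)
            assert covered / ptv60.sum() >= 0.95

    def test_sparing_weight_monotonically_reduces_rectal_dmean(self, desk_phantom):
        _, anatomy, boost, _ = desk_phantom
        rectum = anatomy.masks["rectum"]
        means = []
        for s in (0.0, 0.8, 1.6, 2.4):
            cfg = FalloffConfig(spare_weight=s, noise_sigma_gy=0.0)
            dose = simulate_plan_dose(anatomy, boost, cfg)
            means.append(dose.dose_gy[rectum].mean())
        assert np.all(np.diff(means) <= 1e-9)

    def test_concave_isodoses_in_rectum(self, desk_phantom):
        """Sparing pushes mid-level isodose lines out of the rectum: the rectal
        volume above 40 Gy shrinks when the sparing term is switched on."""
        _, anatomy, boost, _ = desk_phantom
        rectum = anatomy.masks["rectum"]
        unspared = simulate_plan_dose(anatomy, boost, FalloffConfig(spare_weight=0.0, noise_sigma_gy=0.0))
        spared = simulate_plan_dose(anatomy, boost, FalloffConfig(spare_weight=1.5, noise_sigma_gy=0.0))
        assert np.sum(spared.dose_gy[rectum] >= 40.0) < np.sum(unspared.dose_gy[rectum] >= 40.0)


class TestLabelPlan:
    def test_zero_dose_is_low_risk(self, desk_phantom):
        _, anatomy, boost, _ = desk_phantom
        plan = anatomy.select_boost(boost)
        zero = DoseGrid(np.zeros(anatomy.shape), anatomy.spacing_mm)
        label = label_plan(plan, zero, default_constraint_table())
        assert not label.exceeds_optimal and not label.exceeds_mandatory
        # zero dose sits at the probit floor Phi(-1/m), ~0.01% for bleeding
        assert label.risk_lrb < 2e-4

    def test_uniform_80_gy_exceeds_both_levels(self, desk_phantom):
        _, anatomy, boost, _ = desk_phantom
        plan = anatomy.select_boost(boost)
        hot = DoseGrid(np.full(anatomy.shape, 80.0), anatomy.spacing_mm)
        label = label_plan(plan, hot, default_constraint_table())
        assert label.exceeds_optimal and label.exceeds_mandatory

    def test_empty_rectum_rejected(self, desk_phantom):
        _, anatomy, boost, _ = desk_phantom
        plan = anatomy.select_boost(boost)
        broken = {k: v for k, v in plan.masks.items() if k != "rectum"}
        from spacerstrat.grids import StructureSet

        zero = DoseGrid(np.zeros(anatomy.shape), anatomy.spacing_mm)
        with pytest.raises((PhantomError, KeyError)):
            label_plan(StructureSet(broken, anatomy.spacing_mm), zero, default_constraint_table())

    def test_both_label_classes_populated(self, ensemble30):
        """Across the jittered-fall-off ensemble both high- and low-risk plans
        occur, with the exceedance rate near the reported 9-of-14 split."""
        table = default_constraint_table()
        fx = FractionationScheme()
        labels = [
            label_plan(anatomy.select_boost(boost), dose, table, fx)
            for _, anatomy, boost, _, dose in ensemble30
        ]
        n_opt = sum(lab.exceeds_optimal for lab in labels)
        n_mand = sum(lab.exceeds_mandatory for lab in labels)
        assert 0 < n_opt < len(labels)
        assert 0.35 <= n_opt / len(labels) <= 0.90
        assert n_mand <= n_opt

    def test_mandatory_exceedance_implies_optimal(self, ensemble30):
        table = default_constraint_table()
        fx = FractionationScheme()
        for _, anatomy, boost, _, dose in ensemble30:
            label = label_plan(anatomy.select_boost(boost), dose, table, fx)
            if label.exceeds_mandatory:
                assert label.exceeds_optimal

    def test_optimal_failures_concentrate_at_highest_doses(self, ensemble30):
        """Constraint violations occur primarily at the higher dose levels."""
        from spacerstrat.dvh import compute_dvh, dvh_metric

        table = default_constraint_table()
        entries = sorted(table.at_level("optimal"), key=lambda e: e.dose_gy)
        failures = {e.dose_gy: 0 for e in entries}
        for _, anatomy, boost, _, dose in ensemble30:
            curve = compute_dvh(dose, anatomy.masks["rectum"])
            for e in entries:
                if dvh_metric(curve, e.metric) > e.max_volume_pct:
                    failures[e.dose_gy] += 1
        total = sum(failures.values())
        assert total > 0
        top_two = sorted(failures)[-3:-1]  # 57 and 60 Gy (68 Gy is never reached)
        assert sum(failures[d] for d in top_two) / total >= 0.8
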