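"""Phantom generator: geometry, ground-truth deformations, cohort structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from jdmorph.phantom import (
    AtrophySpec,
    PhantomSpec,
    SubjectRecord,
    build_template_phantom,
    draw_subject_deformation,
    simulate_cohort,
    simulate_neuropsych,
    simulate_summary_dataset,
    synthesize_pair,
)
from jdmorph.registration import jacobian_map


def _record(**kw):
    base = dict(
        id="s0", group="case", age_years=40.0, sex="M", scanner="A",
        interval_years=1.0,
    )
    base.update(kw)
    return SubjectRecord(**base)


class TestTemplate:
    def test_deterministic(self):
        spec = PhantomSpec(seed=3)
        t1, l1 = build_template_phantom(spec)
        t2, l2 = build_template_phantom(spec)
        assert np.array_equal(t1.data, t2.data)
        assert np.array_equal(l1.data, l2.data)

    def test_classes_partition_brain(self, phantom48):
        _, _, labels = phantom48
        brain = labels.brain_mask
        gm = labels.mask_of_class("gyrus", "sulcus", "subcortical-GM")
        wm = labels.mask_of_class("WM")
        csf = labels.mask_of_class("CSF")
        assert gm.sum() + wm.sum() + csf.sum() == brain.sum()
        assert not (gm & wm).any() and not (gm & csf).any() and not (wm & csf).any()

    def test_has_six_labels_per_cortical_class(self, phantom48):
        _, _, labels = phantom48
        assert len(labels.ids_of_class("gyrus")) >= 6
        assert len(labels.ids_of_class("sulcus")) >= 6

    def test_zero_folding_equalizes_class_radii(self):
        spec = PhantomSpec(cortical_fold_count=0)
        _, labels = build_template_phantom(spec)
        center = (np.asarray(spec.grid_shape) - 1) / 2
        grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        gy = r[labels.mask_of_class("gyrus")].mean()
        su = r[labels.mask_of_class("sulcus")].mean()
        assert abs(gy - su) < 0.2

    def test_folding_makes_sulci_deeper(self, phantom48):
        _, _, labels = phantom48
        spec = labels.meta["spec"]
        center = (np.asarray(spec.grid_shape) - 1) / 2
        grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        assert r[labels.mask_of_class("sulcus")].mean() < r[labels.mask_of_class("gyrus")].mean()

    def test_grid_too_small_for_ribbon_fails(self):
        with pytest.raises(ValueError, match="ribbon"):
            build_template_phantom(PhantomSpec(grid_shape=(24, 24, 24)))

    def test_intensities_distinct_per_class(self, phantom48):
        _, template, labels = phantom48
        wm = template.data[labels.mask_of_class("WM")].mean()
        gm = template.data[labels.mask_of_class("gyrus", "sulcus")].mean()
        csf = template.data[labels.mask_of_class("CSF")].mean()
        assert wm > gm > csf


class TestDeformation:
    def test_zero_rates_give_identity(self, phantom48):
        _, _, labels = phantom48
        atrophy = AtrophySpec(
            case_gm=(0, 0), case_wm=(0, 0), sulcal_excess=1.0, lesion_prob=0
        )
        fwd, gt = draw_subject_deformation(atrophy, _record(), labels, seed=0)
        assert np.allclose(fwd.data, 0)
        assert np.allclose(gt.annual_jd.data, 1.0)

    def test_uniform_minus2_gives_098_analytic_jd(self, phantom48):
        _, _, labels = phantom48
        atrophy = AtrophySpec(
            case_gm=(-2, 0), case_wm=(-2, 0), sulcal_excess=1.0, lesion_prob=0
        )
        _, gt = draw_subject_deformation(atrophy, _record(), labels, seed=0)
        gm = labels.mask_of_class("gyrus", "sulcus")
        assert np.allclose(gt.annual_jd.data[gm], 0.98, atol=1e-6)
        assert gt.rates["gyral"] == pytest.approx(-2.0)

    def test_two_year_interval_compounds_geometrically(self, phantom48):
        """-2 %/yr over 2 years: total compartment ratio 0.98^2 = 0.9604,
        checked by numerically integrating the JD of the composed warp."""
        _, _, labels = phantom48
        atrophy = AtrophySpec(
            case_gm=(-2, 0), case_wm=(-2, 0), sulcal_excess=1.0, lesion_prob=0
        )
        rec = _record(interval_years=2.0)
        fwd, gt = draw_subject_deformation(atrophy, rec, labels, seed=0)
        wm = labels.mask_of_class("WM")
        total_jd = jacobian_map(fwd, mask=labels.brain_mask)
        ratio = float(total_jd.data[wm].mean())
        assert ratio == pytest.approx(0.9604, abs=0.002)
        assert gt.annual_jd.data[wm].mean() == pytest.approx(0.98, abs=1e-6)

    def test_ground_truth_consistency(self, phantom48):
        """Integrated numeric JD of the drawn field reproduces the analytic
        compartment ratio within 0.5%."""
        _, _, labels = phantom48
        atrophy = AtrophySpec(lesion_prob=0)
        fwd, gt = draw_subject_deformation(atrophy, _record(), labels, seed=11)
        numeric = jacobian_map(fwd, mask=labels.brain_mask)
        for classes in (("gyrus",), ("sulcus",), ("WM",)):
            m = labels.mask_of_class(*classes)
            analytic = gt.annual_jd.data[m].mean() ** gt.interval_years
            got = numeric.data[m].mean()
            assert got == pytest.approx(analytic, rel=0.005)

    def test_analytic_jd_positive(self, phantom48):
        _, _, labels = phantom48
        for seed in range(5):
            _, gt = draw_subject_deformation(AtrophySpec(), _record(), labels, seed=seed)
            assert (gt.annual_jd.data > 0).all()

    def test_deterministic_given_seed(self, phantom48):
        _, _, labels = phantom48
        a1 = draw_subject_deformation(AtrophySpec(), _record(), labels, seed=9)
        a2 = draw_subject_deformation(AtrophySpec(), _record(), labels, seed=9)
        assert np.array_equal(a1[0].data, a2[0].data)
        assert a1[1].rates == a2[1].rates


class TestSynthesis:
    def test_zero_field_zero_noise_identical(self, phantom48):
        spec0 = PhantomSpec(noise_sd=0.0, scanner_bias=0.0)
        template, labels = build_template_phantom(spec0)
        atrophy = AtrophySpec(case_gm=(0, 0), case_wm=(0, 0), sulcal_excess=1.0, lesion_prob=0)
        _, gt = draw_subject_deformation(atrophy, _record(), labels, seed=0)
        bl, fu = synthesize_pair(template, gt.resample_field, _record(), spec0, seed=0)
        assert np.array_equal(bl.data, fu.data)

    def test_noise_deterministic(self, phantom48):
        spec, template, labels = phantom48
        atrophy = AtrophySpec(lesion_prob=0)
        _, gt = draw_subject_deformation(atrophy, _record(), labels, seed=4)
        p1 = synthesize_pair(template, gt.resample_field, _record(), spec, seed=7)
        p2 = synthesize_pair(template, gt.resample_field, _record(), spec, seed=7)
        assert np.array_equal(p1[0].data, p2[0].data)
        assert np.array_equal(p1[1].data, p2[1].data)

    def test_lesion_darkens_sphere(self, phantom48):
        spec, template, labels = phantom48
        atrophy = AtrophySpec(case_gm=(0, 0), case_wm=(0, 0), sulcal_excess=1.0, lesion_prob=1.0)
        rec = _record(lesion=True)
        _, gt = draw_subject_deformation(atrophy, rec, labels, seed=0)
        bl, fu = synthesize_pair(template, gt.resample_field, rec, spec, seed=3)
        bl0, _ = synthesize_pair(template, gt.resample_field, _record(), spec, seed=3)
        tissue = labels.brain_mask & (template.data > 0.3)
        ratio = np.where(tissue, bl.data / np.maximum(bl0.data, 0.1), 1.0)
        core = ratio < 0.6
        assert core.sum() > 10  # a resolvable hypointense focus exists
        # mean intensity in the focus is below half its unlesioned value
        assert bl.data[core].mean() < 0.5 * bl0.data[core].mean()
        # the lesion is present at both time points
        fu_ratio = np.where(tissue, fu.data / np.maximum(bl0.data, 0.1), 1.0)
        assert (fu_ratio < 0.6).sum() > 10


class TestCohort:
    def test_rate_calibration_at_n200(self, phantom48):
        spec, _, _ = phantom48
        atrophy = AtrophySpec(lesion_prob=0)
        sim = simulate_cohort(200, 2, atrophy, spec, seed=7, with_fields=False)
        rates = [
            sim.ground_truths[r.id].rates["gyral"]
            for r in sim.records if r.group == "case"
        ]
        bound = 2 * atrophy.case_gm[1] / np.sqrt(200)
        assert abs(np.mean(rates) - atrophy.case_gm[0]) < bound

    def test_zero_sd_rates_hit_means_exactly(self, phantom48):
        spec, _, _ = phantom48
        atrophy = AtrophySpec(
            case_gm=(-1.5, 0), case_wm=(-1.0, 0),
            control_gm=(-0.5, 0), control_wm=(0.2, 0),
            sulcal_excess=1.0, lesion_prob=0,
        )
        sim = simulate_cohort(2, 2, atrophy, spec, seed=1, with_fields=False)
        for r in sim.records:
            gt = sim.ground_truths[r.id]
            want = -1.5 if r.group == "case" else -0.5
            assert gt.rates["gyral"] == pytest.approx(want, abs=1e-12)

    def test_scanner_shares_balanced(self, phantom48):
        spec, _, _ = phantom48
        sim = simulate_cohort(200, 200, AtrophySpec(), spec, seed=8, with_fields=False)
        share = (sim.table.scanner == "A").mean()
        assert 0.40 < share < 0.60

    def test_table_schema_and_invariants(self, phantom48):
        spec, _, _ = phantom48
        sim = simulate_cohort(30, 20, AtrophySpec(), spec, seed=2, with_fields=False)
        t = sim.table
        assert (t.interval_years > 0).all()
        assert (t.icv_mm3 > 0).all()
        gcs = t.gcs.dropna()
        assert ((gcs >= 3) & (gcs <= 15)).all()
        assert t.loc[t.group == "control", "tsi_months"].isna().all()
        assert (t.loc[t.group == "control", "lesion"] == 0).all()


class TestNeuropsych:
    @staticmethod
    def _cohort(n, seed):
        spec = PhantomSpec()
        sim = simulate_cohort(n, 2, AtrophySpec(lesion_prob=0), spec, seed=seed,
                              with_fields=False)
        cases = [r for r in sim.records if r.group == "case"]
        summary = np.array([1 + sim.ground_truths[r.id].rates["gm"] / 100 for r in cases])
        return cases, summary

    def test_null_coupling_small_rho(self):
        cases, summary = self._cohort(200, 3)
        panel = simulate_neuropsych(
            cases, summary, target_rho={}, seed=1, missing_rates={}
        )
        sub = panel[(panel.test == "people_recall") & (panel.visit == "baseline")]
        rho = spearmanr(sub.score.to_numpy(), summary).statistic
        assert abs(rho) < 0.2

    def test_perfect_coupling_exact(self):
        cases, summary = self._cohort(100, 3)
        panel = simulate_neuropsych(
            cases, summary,
            target_rho={("tmt_b_minus_a_s", "baseline"): 1.0},
            seed=1, missing_rates={},
        )
        sub = panel[(panel.test == "tmt_b_minus_a_s") & (panel.visit == "baseline")]
        assert spearmanr(sub.score.to_numpy(), summary).statistic == pytest.approx(1.0)

    def test_half_coupling_recovered(self):
        cases, summary = self._cohort(500, 5)
        panel = simulate_neuropsych(
            cases, summary,
            target_rho={("people_recall", "followup"): 0.5},
            seed=3, missing_rates={},
        )
        sub = panel[(panel.test == "people_recall") & (panel.visit == "followup")]
        rho = spearmanr(sub.score.to_numpy(), summary).statistic
        assert rho == pytest.approx(0.5, abs=0.1)

    def test_missingness_reproducible(self):
        cases, summary = self._cohort(60, 7)
        p1 = simulate_neuropsych(cases, summary, seed=11)
        p2 = simulate_neuropsych(cases, summary, seed=11)
        assert (p1.missing == p2.missing).all()
        assert p1.missing.any()  # default rates produce some missing cells


def test_summary_dataset_reflects_group_structure():
    cohort, summ, roi = simulate_summary_dataset(100, 100, seed=5)
    merged = summ.merge(cohort[["id", "group"]], on="id")
    case = merged.loc[merged.group == "case", "gm_mean_jd"].mean()
    ctrl = merged.loc[merged.group == "control", "gm_mean_jd"].mean()
    assert case < ctrl  # cases atrophy faster
    assert set(roi.roi_class) == {"gyrus", "sulcus"}
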