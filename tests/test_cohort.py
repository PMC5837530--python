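"""Cohort statistics: adjusted group models, R^2 partitioning, the
sulcus/gyrus mixed model, neuropsych correlations and subgroup reruns."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from jdmorph.cohort import (
    fit_group_adjusted,
    fit_sulcal_interaction,
    hierarchical_partition,
    hierarchical_partition_bruteforce,
    lesion_free,
    neuropsych_correlations,
    score_change_models,
    subgroup_rerun,
)
from jdmorph.phantom import AtrophySpec, simulate_neuropsych, simulate_summary_dataset

EQ_RATES = AtrophySpec(
    case_gm=(-0.55, 1.13), case_wm=(0.26, 1.11), sulcal_excess=1.0, lesion_prob=0.0
)


class TestGroupAdjusted:
    def test_parameter_recovery_coverage(self):
        """Planted group JD offset of -0.010 (equal base rates) is inside its
        own 95% CI in at least 90 of 100 replicate fits."""
        covered = 0
        for rep in range(100):
            cohort, summ, _ = simulate_summary_dataset(
                100, 100, EQ_RATES, seed=rep, n_gyral=1, n_sulcal=1,
                group_jd_shift=-0.010,
            )
            c = fit_group_adjusted(summ, cohort, "gm_mean_jd").coef()
            covered += abs(c["b"] - (-0.010)) <= 1.96 * c["se"]
        assert covered >= 90

    def test_type_one_error_near_nominal(self):
        rejections = 0
        for rep in range(200):
            cohort, summ, _ = simulate_summary_dataset(
                100, 100, EQ_RATES, seed=3000 + rep, n_gyral=1, n_sulcal=1
            )
            rejections += fit_group_adjusted(summ, cohort, "gm_mean_jd").coef()["p"] < 0.05
        assert 0.01 <= rejections / 200 <= 0.09

    def test_collinear_covariate_fails_with_names(self):
        cohort, summ, _ = simulate_summary_dataset(20, 20, EQ_RATES, seed=0)
        cohort = cohort.copy()
        cohort["scanner"] = np.where(cohort.group == "case", "B", "A")  # scanner == group
        with pytest.raises(ValueError, match="collinear"):
            fit_group_adjusted(summ, cohort, "gm_mean_jd")

    def test_constant_outcome_fails(self):
        cohort, summ, _ = simulate_summary_dataset(10, 10, EQ_RATES, seed=1)
        summ = summ.copy()
        summ["gm_mean_jd"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_group_adjusted(summ, cohort, "gm_mean_jd")


class TestHierarchicalPartition:
    def test_single_predictor_gets_full_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=80)
        y = 2 * x + rng.normal(size=80)
        res = hierarchical_partition(y, pd.DataFrame({"x": x}))
        assert res.independent["x"] == pytest.approx(res.full_r2, abs=1e-12)
        assert res.joint["x"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_predictors_have_no_joint_part(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(1)
        y = x1 + 0.5 * x2 + rng.normal(size=n)
        res = hierarchical_partition(y, pd.DataFrame({"a": x1, "b": x2}))
        for k in ("a", "b"):
            assert res.joint[k] == pytest.approx(0.0, abs=1e-10)
        assert res.independent.sum() == pytest.approx(res.full_r2, abs=1e-12)

    def test_matches_bruteforce_orderings_k3(self):
        rng = np.random.default_rng(5)
        P = rng.multivariate_normal(
            np.zeros(3), [[1, 0.6, 0.3], [0.6, 1, 0.5], [0.3, 0.5, 1]], size=120
        )
        y = P @ [1.0, -0.5, 0.25] + rng.normal(size=120)
        pred = pd.DataFrame(P, columns=list("abc"))
        fast = hierarchical_partition(y, pred)
        brute = hierarchical_partition_bruteforce(y, pred)
        assert np.abs(fast.independent - brute.independent).max() < 1e-10
        assert fast.full_r2 == pytest.approx(brute.full_r2, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 4, 5])
    def test_partition_identity_random_inputs(self, k):
        rng = np.random.default_rng(10 + k)
        P = rng.normal(size=(60, k))
        y = P @ rng.normal(size=k) + rng.normal(size=60)
        res = hierarchical_partition(y, pd.DataFrame(P, columns=[f"p{i}" for i in range(k)]))
        assert abs(res.independent.sum() - res.full_r2) < 1e-10

    def test_too_few_observations_fails(self):
        with pytest.raises(ValueError):
            hierarchical_partition(np.ones(3), pd.DataFrame(np.eye(3)))


def _mirrored_cohort(seed=3, n=12, n_case=8, k=4):
    """Cohort whose gyral and sulcal ROI values are identical per subject."""
    rng = np.random.default_rng(seed)
    rows, cohort_rows = [], []
    for i in range(n):
        grp = "case" if i < n_case else "control"
        cohort_rows.append(dict(
            id=f"s{i}", group=grp, age_years=float(rng.uniform(20, 60)),
            sex="M" if i % 2 else "F", scanner="A" if i % 3 else "B",
            interval_years=1.0, tsi_months=None, lesion=0, microbleed=0,
            pta=0, gcs=None, icv_mm3=float(rng.normal(1.45e6, 1e5)),
        ))
        base = 0.98 + 0.01 * rng.standard_normal()
        for j in range(k):
            v = base + 0.004 * rng.standard_normal()
            rows.append(dict(id=f"s{i}", roi_id=10 + j, roi_name=f"g{j}",
                             roi_class="gyrus", mean_jd=v, voxel_count=50))
            rows.append(dict(id=f"s{i}", roi_id=30 + j, roi_name=f"s{j}",
                             roi_class="sulcus", mean_jd=v, voxel_count=50))
    return pd.DataFrame(rows), pd.DataFrame(cohort_rows)


class TestSulcalInteraction:
    def test_mirrored_classes_give_zero_interaction(self):
        roi, cohort = _mirrored_cohort()
        _, inter, _ = fit_sulcal_interaction(roi, cohort)
        assert abs(inter.coef()["b"]) < 1e-8

    def test_interaction_recovery_coverage(self, interaction_replicates):
        assert interaction_replicates["coverage"] >= 0.90
        # the replicate-mean estimate centers on the ~0.001 truth
        assert np.mean(interaction_replicates["estimates"]) == pytest.approx(
            interaction_replicates["truth"], abs=3e-4
        )

    def test_null_lrt_p_uniform(self, null_lrt_pvalues):
        assert kstest(null_lrt_pvalues, "uniform").pvalue > 0.01

    def test_requires_two_rois_per_class(self):
        roi, cohort = _mirrored_cohort(k=1)
        with pytest.raises(ValueError, match="2 ROIs"):
            fit_sulcal_interaction(roi, cohort)


def _panel_and_summaries(n=60, seed=0, rho=None):
    atrophy = AtrophySpec(lesion_prob=0.0)
    cohort, summ, _ = simulate_summary_dataset(n, 2, atrophy, seed=seed)
    case_ids = cohort.loc[cohort.group == "case", "id"].tolist()
    summ_cases = summ[summ["id"].isin(case_ids)].reset_index(drop=True)
    from jdmorph.phantom import SubjectRecord

    records = [
        SubjectRecord(id=i, group="case", age_years=40, sex="M", scanner="A",
                      interval_years=1.0)
        for i in summ_cases["id"]
    ]
    panel = simulate_neuropsych(
        records, summ_cases["gm_mean_jd"].to_numpy(),
        target_rho=rho, seed=seed + 1, missing_rates={},
    )
    return panel, summ_cases


class TestNeuropsychCorrelations:
    def test_monotone_score_gives_rho_one(self):
        panel, summ = _panel_and_summaries(
            rho={("people_recall", v): 1.0 for v in ("baseline", "followup")}
        )
        out = neuropsych_correlations(panel, summ)
        row = out[(out.test == "people_recall") & (out.visit == "baseline")
                  & (out.tissue == "gm_mean_jd")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.p_raw < 1e-10

    def test_family_is_twelve_cells_per_tissue(self):
        panel, summ = _panel_and_summaries()
        out = neuropsych_correlations(panel, summ)
        counts = out.groupby("tissue").size()
        assert (counts == 12).all()

    def test_bh_adjustment_matches_step_up_arithmetic(self):
        panel, summ = _panel_and_summaries(seed=4)
        out = neuropsych_correlations(panel, summ)
        sub = out[out.tissue == "gm_mean_jd"].sort_values("p_raw").reset_index(drop=True)
        m = len(sub)
        stepped = sub.p_raw * m / (np.arange(m) + 1)
        expect = np.minimum.accumulate(stepped[::-1])[::-1].clip(upper=1.0)
        assert np.allclose(sub.p_fdr.to_numpy(), expect, atol=1e-12)
        assert (out.p_fdr >= out.p_raw - 1e-12).all()

    def test_spearman_invariance_under_monotone_transform(self):
        # transform the JD side: change scores are differences, so only a
        # monotone transform of the summary leaves every cell's rho intact
        panel, summ = _panel_and_summaries(seed=6)
        out1 = neuropsych_correlations(panel, summ)
        warped = summ.copy()
        warped["gm_mean_jd"] = np.exp(10.0 * warped["gm_mean_jd"])
        warped["wm_mean_jd"] = warped["wm_mean_jd"] ** 3
        out2 = neuropsych_correlations(panel, warped)
        assert np.allclose(out1.rho.to_numpy(), out2.rho.to_numpy(), atol=1e-12)

    def test_copula_target_recovered(self):
        panel, summ = _panel_and_summaries(
            n=500, seed=9, rho={("people_recall", "followup"): 0.5}
        )
        out = neuropsych_correlations(panel, summ)
        row = out[(out.test == "people_recall") & (out.visit == "followup")
                  & (out.tissue == "gm_mean_jd")].iloc[0]
        assert row.rho == pytest.approx(0.5, abs=0.1)


class TestScoreChange:
    @staticmethod
    def _two_visit_panel(delta, n=20, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = 30 + 5 * rng.standard_normal()
            rows.append(dict(id=f"s{i}", visit="baseline", test="people_recall",
                             score=base, missing=False))
            rows.append(dict(id=f"s{i}", visit="followup", test="people_recall",
                             score=base + delta + sd * rng.standard_normal(),
                             missing=False))
        return pd.DataFrame(rows)

    def test_no_change_zero_effect(self):
        fits = score_change_models(self._two_visit_panel(0.0))
        assert abs(fits["people_recall"].coef()["b"]) < 1e-8

    def test_constant_shift_recovered_exactly(self):
        fits = score_change_models(self._two_visit_panel(2.0))
        assert fits["people_recall"].coef()["b"] == pytest.approx(2.0, abs=1e-8)

    def test_noisy_change_recovered_within_2se(self):
        fits = score_change_models(self._two_visit_panel(2.0, n=41, sd=8.2, seed=3))
        c = fits["people_recall"].coef()
        assert abs(c["b"] - 2.0) <= 2 * c["se"]


class TestSubgroupRerun:
    def test_noop_filter_identical(self):
        cohort, summ, _ = simulate_summary_dataset(30, 20, seed=2)
        direct = fit_group_adjusted(summ, cohort, "gm_mean_jd").coef()
        rerun, excluded = subgroup_rerun(
            lambda t: np.ones(len(t), bool), fit_group_adjusted, cohort, summ,
            outcome="gm_mean_jd",
        )
        assert excluded == 0
        assert rerun.coef() == direct

    def test_lesion_free_estimate_stable(self):
        """Lesions are intensity-only: excluding them moves the group
        estimate by less than 2 SE."""
        cohort, summ, _ = simulate_summary_dataset(61, 32, seed=12)
        full = fit_group_adjusted(summ, cohort, "gm_mean_jd").coef()
        sub, excluded = subgroup_rerun(
            lesion_free, fit_group_adjusted, cohort, summ, outcome="gm_mean_jd"
        )
        assert excluded > 0
        assert abs(sub.coef()["b"] - full["b"]) <= 2 * full["se"]

    def test_filter_emptying_a_group_fails(self):
        cohort, summ, _ = simulate_summary_dataset(10, 10, seed=2)
        with pytest.raises(ValueError, match="empties"):
            subgroup_rerun(
                lambda t: (t.group == "control").to_numpy(), fit_group_adjusted,
                cohort, summ, outcome="gm_mean_jd",
            )
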