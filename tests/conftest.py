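"""Shared fixtures.

The expensive computations (demons registrations of phantom pairs, the
permutation null calibration, the mixed-model replicate studies) are
session-scoped so unit tests and the end-to-end validation tests reuse one
computation.
"""

import warnings

import numpy as np
import pytest

from jdmorph.grids import LabelVolume, ScalarVolume
from jdmorph.inference import DesignMatrix, PermutationScheme, TFCEParams, permutation_correct
from jdmorph.phantom import (
    AtrophySpec,
    PhantomSpec,
    SubjectRecord,
    build_template_phantom,
    draw_subject_deformation,
    synthesize_pair,
)
from jdmorph.registration import annualize_jd, jacobian_map, register_symmetric

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def phantom48():
    spec = PhantomSpec()
    template, labels = build_template_phantom(spec)
    return spec, template, labels


@pytest.fixture(scope="session")
def uniform_minus2(phantom48):
    """A -2 %/yr uniform-compartment subject: truth, images, both-direction
    registrations and recovered annualized JD statistics."""
    spec, template, labels = phantom48
    atrophy = AtrophySpec(
        case_gm=(-2.0, 0.0), case_wm=(-2.0, 0.0), sulcal_excess=1.0, lesion_prob=0.0
    )
    rec = SubjectRecord(
        id="u2", group="case", age_years=40.0, sex="M", scanner="A", interval_years=1.0
    )
    fwd, gt = draw_subject_deformation(atrophy, rec, labels, seed=1)
    baseline, followup = synthesize_pair(template, gt.resample_field, rec, spec, seed=2)
    res_fwd = register_symmetric(baseline, followup)
    res_rev = register_symmetric(followup, baseline)
    mask = labels.brain_mask
    jd_fwd = jacobian_map(res_fwd.full_warp, mask=mask)
    jd_rev = jacobian_map(res_rev.full_warp, mask=mask)
    annual = annualize_jd(jd_fwd, rec.interval_years)
    gm = labels.mask_of_class("gyrus", "sulcus")
    wm = labels.mask_of_class("WM")
    return dict(
        spec=spec, labels=labels, record=rec, truth=gt,
        baseline=baseline, followup=followup,
        result=res_fwd, result_swapped=res_rev,
        jd=jd_fwd, jd_swapped=jd_rev, annual_jd=annual,
        gm_mean=float(np.nanmean(annual.data[gm])),
        wm_mean=float(np.nanmean(annual.data[wm])),
        antisymmetry=float(
            np.mean(np.abs(np.log(jd_fwd.data[mask]) + np.log(jd_rev.data[mask])))
        ),
    )


@pytest.fixture(scope="session")
def identity_registration(phantom48):
    spec, template, _ = phantom48
    return register_symmetric(template, template.copy())


@pytest.fixture(scope="session")
def null_fwer():
    """Familywise rejection rate over 100 replicate null cohorts (6+6
    subjects, 8^3 maps, 99 permutations, alpha = 0.05, one tail)."""
    g = np.array([1.0] * 6 + [0.0] * 6)
    design = DesignMatrix(np.column_stack([np.ones(12), g]), 1)
    rejections = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        stack = 1.0 + 0.02 * rng.standard_normal((12, 8, 8, 8))
        res = permutation_correct(
            stack, design, PermutationScheme(m=99, seed=rep),
            TFCEParams(n_steps=20), two_sided=False,
        )
        rejections += res["corrected_p"].min() < 0.05
    return rejections / 100


@pytest.fixture(scope="session")
def planted_signal():
    """3% JD deficit in a 5-voxel-radius ball, 20+20 subjects, 199 perms."""
    g = np.array([1.0] * 20 + [0.0] * 20)
    design = DesignMatrix(np.column_stack([np.ones(40), g]), 1)
    ax = np.arange(16) - 7.5
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    ball, core = r <= 5, r <= 2
    rng = np.random.default_rng(42)
    stack = 1.0 + 0.02 * rng.standard_normal((40, 16, 16, 16))
    stack[:20][:, ball] -= 0.03
    res = permutation_correct(
        stack, design, PermutationScheme(m=199, seed=5), TFCEParams(n_steps=50)
    )
    return dict(result=res, ball=ball, core=core)


@pytest.fixture(scope="session")
def exhaustive_toy():
    """4+4 toy: exact enumeration (70 labelings) vs sampled permutations."""
    rng = np.random.default_rng(1)
    stack = rng.normal(size=(8, 6, 6, 6))
    design = DesignMatrix(np.column_stack([np.ones(8), [1, 1, 1, 1, 0, 0, 0, 0.0]]), 1)
    tf = TFCEParams(n_steps=30)
    exact = permutation_correct(
        stack, design, PermutationScheme(m=100, exhaustive=True), tf, two_sided=False
    )
    sampled = permutation_correct(
        stack, design, PermutationScheme(m=69, seed=3), tf, two_sided=False
    )
    return dict(exact=exact, sampled=sampled)


@pytest.fixture(scope="session")
def interaction_replicates():
    """100 replicate cohorts (60+30) at the default sulcal excess: CI
    coverage of the group x class interaction (true value ~0.001)."""
    from jdmorph.cohort import fit_sulcal_interaction
    from jdmorph.phantom import simulate_summary_dataset

    atrophy = AtrophySpec(lesion_prob=0.0)
    truth = -atrophy.case_gm[0] * (atrophy.sulcal_excess - 1) / 100.0
    covered = 0
    estimates = []
    for rep in range(100):
        cohort, _, roi = simulate_summary_dataset(60, 30, atrophy, seed=rep)
        _, inter, _ = fit_sulcal_interaction(roi, cohort)
        c = inter.coef()
        estimates.append(c["b"])
        covered += abs(c["b"] - truth) <= 1.96 * c["se"]
    return dict(coverage=covered / 100, truth=truth, estimates=np.array(estimates))


@pytest.fixture(scope="session")
def null_lrt_pvalues():
    """200 null cohorts (no class effect): LRT p values for uniformity."""
    from jdmorph.cohort import fit_sulcal_interaction
    from jdmorph.phantom import simulate_summary_dataset

    atrophy = AtrophySpec(sulcal_excess=1.0, lesion_prob=0.0)
    pvals = []
    for rep in range(200):
        cohort, _, roi = simulate_summary_dataset(
            20, 10, atrophy, seed=500 + rep, n_gyral=4, n_sulcal=4
        )
        _, _, p = fit_sulcal_interaction(roi, cohort)
        pvals.append(p)
    return np.array(pvals)
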