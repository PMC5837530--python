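"""Subject-level cohort statistics.

Covariate-adjusted group comparisons of summary JD, hierarchical (Shapley)
partitioning of model R^2, the sulcus-vs-gyrus linear mixed model with a
group x region-class interaction tested by likelihood ratio, Spearman
neuropsychology correlations with Benjamini-Hochberg FDR, and generic
subgroup (e.g. lesion-free) reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import chi2, spearmanr
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelFit",
    "PartitionResult",
    "fit_group_adjusted",
    "hierarchical_partition",
    "hierarchical_partition_bruteforce",
    "fit_sulcal_interaction",
    "neuropsych_correlations",
    "score_change_models",
    "subgroup_rerun",
    "lesion_free",
]

_COVARIATES = ("age_years", "sex", "scanner", "icv_mm3")


@dataclass
class ModelFit:
    """Coefficients, SEs, t and p per term, plus log-likelihood and n."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    term: str | None = None

    @classmethod
    def from_result(cls, res, term: str | None = None, n: int | None = None):
        return cls(
            params=res.params, se=res.bse, tvalues=res.tvalues,
            pvalues=res.pvalues, llf=float(res.llf),
            n=int(n if n is not None else res.nobs), term=term,
        )

    def coef(self, term: str | None = None) -> dict:
        t = term or self.term
        return dict(
            b=float(self.params[t]), se=float(self.se[t]),
            t=float(self.tvalues[t]), p=float(self.pvalues[t]),
        )


def _prepare_frame(summaries: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.merge(summaries, on="id", validate="one_to_one").copy()
    df["group_case"] = (df["group"] == "case").astype(float)
    df["sex_m"] = (df["sex"] == "M").astype(float)
    df["scanner_b"] = (df["scanner"] == "B").astype(float)
    df["icv_l"] = df["icv_mm3"] / 1e6  # litres, keeps the design well-scaled
    return df


def fit_group_adjusted(
    summaries: pd.DataFrame, cohort: pd.DataFrame, outcome: str = "gm_mean_jd"
) -> ModelFit:
    """OLS: outcome ~ group + age + sex + ICV + scanner; reports the group term."""
    df = _prepare_frame(summaries, cohort)
    if outcome not in df.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = df[outcome].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    X = df[["group_case", "age_years", "sex_m", "icv_l", "scanner_b"]]
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
        bad = [
            (X.columns[1 + i], X.columns[1 + j])
            for i, j in zip(*np.where(np.triu(np.abs(corr) > 0.999, 1)))
        ]
        raise ValueError(f"collinear covariates: {bad or 'intercept-confounded'}")
    res = sm.OLS(y, X).fit()
    return ModelFit.from_result(res, term="group_case")


# ---------------------------------------------------------------------------
# hierarchical partitioning


@dataclass
class PartitionResult:
    """Independent (I) and joint (J) R^2 contributions per predictor.

    I_k is the Shapley value of predictor k over all entry orderings;
    sum(I) equals the full-model R^2 exactly. J_k = marginal R^2_k - I_k.
    """

    independent: pd.Series
    joint: pd.Series
    full_r2: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"I": self.independent, "J": self.joint})


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient predictor subset")
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / tss


def _subset_r2(y, P):
    """R^2 of every predictor subset (empty subset has R^2 = 0)."""
    k = P.shape[1]
    out = {(): 0.0}
    for size in range(1, k + 1):
        for S in combinations(range(k), size):
            out[S] = _r2(y, P[:, list(S)])
    return out


def hierarchical_partition(outcome, predictors: pd.DataFrame) -> PartitionResult:
    """Decompose model R^2 into per-predictor independent contributions.

    Fits all 2^k predictor subsets by least squares and averages each
    predictor's incremental R^2 over entry orderings using the subset-size
    weighting identity w(s) = s!(k-s-1)!/k! (no explicit ordering
    enumeration).
    """
    y = np.asarray(outcome, dtype=float)
    P = predictors.to_numpy(dtype=float)
    k = P.shape[1]
    if k < 1:
        raise ValueError("need at least one predictor")
    if len(y) <= k + 1:
        raise ValueError("need n > k + 1 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    r2 = _subset_r2(y, P)
    full = r2[tuple(range(k))]

    I = np.zeros(k)
    others = set(range(k))
    for j in range(k):
        rest = sorted(others - {j})
        for size in range(0, k):
            w = factorial(size) * factorial(k - size - 1) / factorial(k)
            for S in combinations(rest, size):
                I[j] += w * (r2[tuple(sorted(S + (j,)))] - r2[S])
    marg = np.array([r2[(j,)] for j in range(k)])
    J = marg - I
    names = list(predictors.columns)
    return PartitionResult(pd.Series(I, index=names), pd.Series(J, index=names), full)


def hierarchical_partition_bruteforce(outcome, predictors: pd.DataFrame) -> PartitionResult:
    """Reference implementation averaging over all k! explicit orderings."""
    y = np.asarray(outcome, dtype=float)
    P = predictors.to_numpy(dtype=float)
    k = P.shape[1]
    r2 = _subset_r2(y, P)
    I = np.zeros(k)
    for order in permutations(range(k)):
        seen: tuple = ()
        for j in order:
            new = tuple(sorted(seen + (j,)))
            I[j] += r2[new] - r2[seen]
            seen = new
    I /= factorial(k)
    marg = np.array([r2[(j,)] for j in range(k)])
    names = list(predictors.columns)
    return PartitionResult(
        pd.Series(I, index=names), pd.Series(marg - I, index=names),
        r2[tuple(range(k))],
    )


# ---------------------------------------------------------------------------
# sulcus vs gyrus mixed model


def _fit_mixedlm(model, reml: bool = False):
    """ML fit with optimizer fallbacks; raises the last failure."""
    last = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=reml, method=method, maxiter=300)
        except (np.linalg.LinAlgError, ValueError) as e:
            last = e
    raise last


def fit_sulcal_interaction(
    roi_table: pd.DataFrame, cohort: pd.DataFrame
) -> tuple[ModelFit, ModelFit, float]:
    """Linear mixed model of ROI mean JD with a group x region-class term.

    ROI JD ~ group + class + covariates with a per-subject random intercept
    and random class slope; the interaction model adds group x class and is
    compared to the main-effects model by a likelihood-ratio test of
    maximum-likelihood fits (1 df). Returns (main fit, interaction fit,
    LRT p). A singular random-effects covariance triggers a refit with a
    random intercept only.
    """
    df = roi_table.merge(cohort, on="id", validate="many_to_one").copy()
    counts = df.groupby(["id", "roi_class"]).size().unstack(fill_value=0)
    if (counts < 2).any().any():
        raise ValueError("every subject needs >= 2 ROIs of each class")
    df["group_case"] = (df["group"] == "case").astype(float)
    df["gyrus"] = (df["roi_class"] == "gyrus").astype(float)
    df["sex_m"] = (df["sex"] == "M").astype(float)
    df["scanner_b"] = (df["scanner"] == "B").astype(float)
    df["icv_l"] = df["icv_mm3"] / 1e6

    base = "mean_jd ~ group_case + gyrus + age_years + sex_m + icv_l + scanner_b"
    full = base + " + group_case:gyrus"

    def _fit(formula, re_formula):
        model = smf.mixedlm(formula, df, groups=df["id"], re_formula=re_formula)
        return _fit_mixedlm(model)

    re_form = "~gyrus"
    try:
        res_main = _fit(base, re_form)
        res_full = _fit(full, re_form)
        singular = (
            not np.all(np.isfinite(res_full.cov_re))
            or np.linalg.det(np.asarray(res_full.cov_re)) <= 1e-14
        )
    except (np.linalg.LinAlgError, ValueError):
        singular = True
    if singular:
        warnings.warn(
            "singular random-effects covariance; refitting with random intercept only",
            RuntimeWarning,
        )
        res_main = _fit(base, "1")
        res_full = _fit(full, "1")

    lrt = 2.0 * (res_full.llf - res_main.llf)
    p = float(chi2.sf(max(lrt, 0.0), df=1))
    main_fit = ModelFit.from_result(res_main, term="group_case", n=df["id"].nunique())
    inter_fit = ModelFit.from_result(
        res_full, term="group_case:gyrus", n=df["id"].nunique()
    )
    return main_fit, inter_fit, p


# ---------------------------------------------------------------------------
# neuropsychology


def neuropsych_correlations(
    panel: pd.DataFrame, summaries: pd.DataFrame, tissues=("gm_mean_jd", "wm_mean_jd")
) -> pd.DataFrame:
    """Spearman rho of each test x visit cell against tissue summary JD.

    Visits are baseline, follow-up and change (follow-up - baseline);
    Benjamini-Hochberg FDR is applied across the 12 cells separately per
    tissue. Pairwise-complete observations; all-tied cells are flagged with
    NaN rho.
    """
    wide = panel.pivot_table(index="id", columns=["test", "visit"], values="score")
    tests = sorted({t for t, _ in wide.columns})
    rows = []
    for tissue in tissues:
        merged = summaries.set_index("id")[tissue]
        cells = []
        for test in tests:
            for visit in ("baseline", "followup", "change"):
                if visit == "change":
                    try:
                        s = wide[(test, "followup")] - wide[(test, "baseline")]
                    except KeyError:
                        continue
                else:
                    if (test, visit) not in wide.columns:
                        continue
                    s = wide[(test, visit)]
                joined = pd.concat([s, merged], axis=1, join="inner").dropna()
                n = len(joined)
                if n < 5:
                    raise ValueError(f"cell {test}/{visit}: fewer than 5 complete pairs")
                x = joined.iloc[:, 0].to_numpy()
                if np.ptp(x) == 0:
                    cells.append(dict(test=test, visit=visit, tissue=tissue,
                                      rho=np.nan, p_raw=np.nan, n=n, degenerate=True))
                    continue
                rho, p = spearmanr(x, joined.iloc[:, 1].to_numpy())
                cells.append(dict(test=test, visit=visit, tissue=tissue,
                                  rho=float(rho), p_raw=float(p), n=n, degenerate=False))
        ok = [c for c in cells if not c["degenerate"]]
        if ok:
            adj = multipletests([c["p_raw"] for c in ok], method="fdr_bh")[1]
            for c, a in zip(ok, adj):
                c["p_fdr"] = float(a)
        for c in cells:
            c.setdefault("p_fdr", np.nan)
        rows.extend(cells)
    return pd.DataFrame(rows)


def score_change_models(panel: pd.DataFrame) -> dict[str, ModelFit]:
    """Per-test mixed model score ~ visit + (1 | subject); visit effect."""
    out = {}
    for test, sub in panel.dropna(subset=["score"]).groupby("test"):
        sub = sub.copy()
        both = sub.groupby("id")["visit"].nunique()
        if (both >= 2).sum() < 5:
            raise ValueError(f"{test}: fewer than 5 subjects with both visits")
        sub["visit_fu"] = (sub["visit"] == "followup").astype(float)
        model = smf.mixedlm("score ~ visit_fu", sub, groups=sub["id"])
        res = _fit_mixedlm(model)
        out[test] = ModelFit.from_result(res, term="visit_fu", n=sub["id"].nunique())
    return out


def subgroup_rerun(predicate, stats_op, cohort: pd.DataFrame, *tables, **kwargs):
    """Re-run any cohort statistic on a filtered subset of subjects.

    ``predicate`` maps the cohort table to a boolean keep-mask (e.g.
    lesion-free: ``lambda t: ~(t.lesion.astype(bool) & (t.group == "case"))``).
    Positional ``tables`` are filtered to the kept ids and passed through to
    ``stats_op(*tables, filtered_cohort, **kwargs)``. Returns
    (result, n_excluded).
    """
    keep = np.asarray(predicate(cohort), dtype=bool)
    sub = cohort[keep]
    for g in ("case", "control"):
        if (sub["group"] == g).sum() == 0:
            raise ValueError(f"filter empties the {g} group")
    ids = set(sub["id"])
    filtered = [t[t["id"].isin(ids)] for t in tables]
    n_excluded = int(len(cohort) - len(sub))
    return stats_op(*filtered, sub, **kwargs), n_excluded


def lesion_free(cohort: pd.DataFrame) -> np.ndarray:
    """Keep controls and lesion-free cases (the sensitivity-rerun filter)."""
    return ~(cohort["lesion"].astype(bool) & (cohort["group"] == "case")).to_numpy()
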