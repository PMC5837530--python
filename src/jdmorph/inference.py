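"""Voxelwise group inference: GLM, TFCE and max-stat permutation correction.

The Randomise-style stage: an ordinary-least-squares GLM per voxel with a
single group contrast and nuisance covariates, threshold-free cluster
enhancement (TFCE) of the t map, and familywise-error correction from the
permutation distribution of the maximum TFCE statistic. Nuisance covariates
are handled by the Freedman-Lane scheme (permute residuals of the reduced,
nuisance-only model). Two-sided inference enhances each sign separately and
Bonferroni-corrects over the two tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

__all__ = [
    "DesignMatrix",
    "TFCEParams",
    "PermutationScheme",
    "fit_voxel_glm",
    "tfce_enhance",
    "permutation_correct",
]

log = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Subjects-by-predictors design with a single group-effect contrast.

    ``X`` rows must follow the image stack order. ``contrast_index`` names
    the column tested (the group indicator); the remaining columns,
    including the intercept, are nuisance.
    """

    X: np.ndarray
    contrast_index: int
    column_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design must be 2-D (subjects x predictors)")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            cols = self.column_names or tuple(f"col{i}" for i in range(self.X.shape[1]))
            raise ValueError(f"design matrix rank-deficient; check columns {cols}")
        if not 0 <= self.contrast_index < self.X.shape[1]:
            raise ValueError("contrast_index out of range")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_cohort(cls, cohort, covariates=("age_years", "sex", "scanner", "icv_mm3")):
        """Intercept + group indicator + standard covariates from a cohort table."""
        cols = [np.ones(len(cohort)), (cohort["group"] == "case").to_numpy(float)]
        names = ["intercept", "group"]
        for c in covariates:
            v = cohort[c]
            if v.dtype == object:
                v = (v == v.iloc[0]).astype(float)
            arr = np.asarray(v, dtype=float)
            if np.ptp(arr) == 0:  # constant covariate carries no information
                log.info("dropping constant covariate %r", c)
                continue
            cols.append(arr)
            names.append(c)
        return cls(np.column_stack(cols), contrast_index=1, column_names=tuple(names))


@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings: extent exponent E, height exponent H, step rule and
    neighbourhood connectivity (26 = faces+edges+corners)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100  # dh = max(stat)/n_steps unless dh is fixed below
    connectivity: int = 26
    dh: float | None = None  # explicit step height overriding the max rule

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0 when given")


@dataclass(frozen=True)
class PermutationScheme:
    m: int = 10_000
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")


def _glm_t(Y: np.ndarray, X: np.ndarray, ci: int) -> np.ndarray:
    """t statistic of column ``ci`` for each response column of Y (n x V)."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    var_b = xtx_inv[ci, ci] * sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_b > 0, beta[ci] / np.sqrt(var_b), 0.0)
    return t


def fit_voxel_glm(stack: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None):
    """Voxelwise OLS t map for the design's contrast column.

    ``stack`` is (n_subjects, nx, ny, nz). Returns (t_map, dof); voxels
    outside ``mask`` are zero.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.shape[0] != design.n:
        raise ValueError("stack / design row mismatch")
    vol_shape = stack.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    Y = stack.reshape(design.n, -1)[:, mask.ravel()]
    t = _glm_t(Y, design.X, design.contrast_index)
    out = np.zeros(vol_shape)
    out[mask] = t
    return out, design.n - design.p


def _tfce_one_sign(pos: np.ndarray, params: TFCEParams, structure) -> np.ndarray:
    out = np.zeros_like(pos)
    hmax = float(pos.max())
    if hmax <= 0:
        return out
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    n_steps = int(np.ceil(hmax / dh - 1e-12))
    for k in range(1, n_steps + 1):
        h = k * dh
        sup = pos >= h
        if not sup.any():
            break
        lab, nlab = ndimage.label(sup, structure=structure)
        sizes = np.bincount(lab.ravel())
        ext = sizes[lab]  # extent of each voxel's component
        out[sup] += (ext[sup] ** params.E) * (h**params.H) * dh
    return out


def tfce_enhance(
    stat: np.ndarray, params: TFCEParams | None = None, mask: np.ndarray | None = None
) -> np.ndarray:
    """Threshold-free cluster enhancement, sign-split for two-sided maps.

    TFCE(p) = sum over thresholds h of e(h, p)^E * h^H * dh, where e(h, p)
    is the voxel count of the suprathreshold component containing p.
    Negative statistics are enhanced on the negated map and returned with
    negative sign.
    """
    params = params or TFCEParams()
    stat = np.asarray(stat, dtype=np.float64)
    if not np.all(np.isfinite(stat)):
        raise ValueError("non-finite statistics")
    if mask is not None:
        if not mask.any():
            raise ValueError("empty mask")
        stat = np.where(mask, stat, 0.0)
    structure = ndimage.generate_binary_structure(stat.ndim, 3 if params.connectivity == 26 else 1)
    pos = _tfce_one_sign(np.clip(stat, 0, None), params, structure)
    neg = _tfce_one_sign(np.clip(-stat, 0, None), params, structure)
    return pos - neg


def _distinct_labelings(groups: np.ndarray):
    """All distinct assignments of the case labels over subjects."""
    n = len(groups)
    k = int(groups.sum())
    for idx in combinations(range(n), k):
        g = np.zeros(n)
        g[list(idx)] = 1.0
        yield g


def permutation_correct(
    stack: np.ndarray,
    design: DesignMatrix,
    scheme: PermutationScheme | None = None,
    tfce_params: TFCEParams | None = None,
    mask: np.ndarray | None = None,
    two_sided: bool = True,
):
    """FWE-corrected voxelwise p values from the max-TFCE permutation null.

    Sampled mode uses Freedman-Lane: residuals of the nuisance-only model
    are row-permuted, the nuisance fit added back, and the full model refit;
    the null is the distribution of the maximum TFCE value per tail.
    Exhaustive mode enumerates all distinct group labelings (supported for
    intercept + group designs) so p values are exact multiples of
    1/(#labelings). Corrected p = (1 + #{null max >= observed}) / (m + 1);
    two-sided inference is Bonferroni over the two tails.

    Returns a dict with t map, tfce map, corrected p map and the null maxima.
    """
    scheme = scheme or PermutationScheme()
    tfce_params = tfce_params or TFCEParams()
    stack = np.asarray(stack, dtype=np.float64)
    vol_shape = stack.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)

    X = design.X
    ci = design.contrast_index
    t_obs, dof = fit_voxel_glm(stack, design, mask)
    tfce_obs = tfce_enhance(t_obs, tfce_params, mask)

    Y = stack.reshape(design.n, -1)[:, mask.ravel()]
    nuis_idx = [j for j in range(design.p) if j != ci]

    def tail_maxima(t_flat):
        vol = np.zeros(vol_shape)
        vol[mask] = t_flat
        enh = tfce_enhance(vol, tfce_params, mask)
        return enh[mask].max(initial=0.0), (-enh[mask]).max(initial=0.0)

    if scheme.exhaustive:
        if any(np.ptp(X[:, j]) > 0 for j in nuis_idx):
            raise ValueError(
                "exhaustive enumeration supports intercept + group designs only"
            )
        labelings = list(_distinct_labelings(X[:, ci]))
        if scheme.m < len(labelings):
            log.info("exhaustive mode: using all %d labelings", len(labelings))
        perms = []
        for g in labelings:
            Xp = X.copy()
            Xp[:, ci] = g
            perms.append(_glm_t(Y, Xp, ci))
        m_eff = len(labelings)
    else:
        rng = np.random.default_rng(scheme.seed)
        Z = X[:, nuis_idx]
        gamma = np.linalg.pinv(Z) @ Y
        fit_z = Z @ gamma
        R = Y - fit_z
        perms = []
        for _ in range(scheme.m):
            pi = rng.permutation(design.n)
            Ystar = fit_z + R[pi]
            perms.append(_glm_t(Ystar, X, ci))
        m_eff = scheme.m

    max_pos = np.empty(m_eff)
    max_neg = np.empty(m_eff)
    for i, t_flat in enumerate(perms):
        max_pos[i], max_neg[i] = tail_maxima(t_flat)

    obs = tfce_obs[mask]
    sp, sn = np.sort(max_pos), np.sort(max_neg)
    if scheme.exhaustive:
        # the identity labeling is enumerated, so counts are exact: p = #/m
        p_pos = (m_eff - np.searchsorted(sp, obs, side="left")) / m_eff
        p_neg = (m_eff - np.searchsorted(sn, -obs, side="left")) / m_eff
    else:
        p_pos = (1 + m_eff - np.searchsorted(sp, obs, side="left")) / (m_eff + 1)
        p_neg = (1 + m_eff - np.searchsorted(sn, -obs, side="left")) / (m_eff + 1)
    p_flat = np.where(obs >= 0, p_pos, p_neg)
    if two_sided:
        p_flat = np.minimum(1.0, 2.0 * p_flat)

    p_map = np.ones(vol_shape)
    p_map[mask] = p_flat
    return {
        "t_map": t_obs,
        "dof": dof,
        "tfce_map": tfce_obs,
        "corrected_p": p_map,
        "uncorrected_p": _uncorrected_p(t_obs, dof, mask, two_sided),
        "null_max_pos": max_pos,
        "null_max_neg": max_neg,
        "n_permutations": m_eff,
        "exhaustive": scheme.exhaustive,
    }


def _uncorrected_p(t_map, dof, mask, two_sided):
    p = np.ones_like(t_map)
    tv = t_map[mask]
    p[mask] = (2 if two_sided else 1) * t_dist.sf(np.abs(tv) if two_sided else tv, dof)
    np.clip(p, 0, 1, out=p)
    return p
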