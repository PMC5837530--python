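"""Synthetic longitudinal brain phantoms with known ground-truth atrophy.

The generator emulates the statistical structure of a two-group longitudinal
morphometry study — a TBI-like "case" group losing grey and white matter
volume at roughly -1.5 %/yr with large between-subject spread, and a
control-like group near zero change — on a simple geometric brain: an
ellipsoidal brain mask with a folded cortical ribbon (gyral crowns and
sulcal troughs), a white-matter interior, two subcortical nuclei and a
central CSF ventricle.

Ground-truth deformations are radial maps in normalized ellipsoidal
coordinates constructed so that the Jacobian determinant is exactly the
prescribed per-compartment volume ratio along each ray; both the forward
(baseline -> follow-up) displacement and the resampling (pull-back) warp are
available in closed form, so registration accuracy can be scored against an
analytic truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .grids import DisplacementField, LabelVolume, ScalarVolume, make_affine

__all__ = [
    "PhantomSpec",
    "AtrophySpec",
    "SubjectRecord",
    "GroundTruth",
    "SimulatedCohort",
    "build_template_phantom",
    "draw_subject_deformation",
    "synthesize_pair",
    "simulate_cohort",
    "simulate_summary_dataset",
    "simulate_neuropsych",
    "subject_seed",
    "NEUROPSYCH_TESTS",
    "NEUROPSYCH_MARGINALS",
    "NEUROPSYCH_MISSING",
    "NEUROPSYCH_TARGET_RHO",
]

# intensity per tissue class (arbitrary T1-like units, WM brightest)
_CLASS_INTENSITY = {
    "background": 0.05,
    "CSF": 0.25,
    "gyrus": 0.65,
    "sulcus": 0.65,
    "subcortical-GM": 0.65,
    "WM": 1.0,
}

# normalized-radius geometry constants (fractions of the brain ellipsoid)
_R_VENT = 0.28       # CSF ventricle outer radius
_R_RIBBON = 0.78     # unfolded GM/WM boundary
_FOLD_DEPTH = 0.10   # sinusoidal modulation amplitude of the GM/WM boundary
_SEMIAXES_FRAC = (0.84, 0.88, 0.80)  # semiaxes as fraction of half grid extent


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject RNG seed derived from the master seed."""
    return zlib.crc32(f"{master_seed}:{subject_id}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 3.0
    cortical_fold_count: int = 6
    noise_sd: float = 0.02
    scanner_bias: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape axes must all be >= 16")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cortical_fold_count < 0:
            raise ValueError("cortical_fold_count must be >= 0")


@dataclass(frozen=True)
class AtrophySpec:
    """Ground-truth atrophy model: annual rates in %/yr per group x tissue.

    Defaults are calibrated at the case/control grey-matter and white-matter
    annualized volume-change distributions the generator emulates
    (case GM -1.55 +/- 2.19, WM -1.49 +/- 2.20; control GM -0.55 +/- 1.13,
    WM +0.26 +/- 1.11 %/yr). ``sulcal_excess`` multiplies the case cortical
    rate inside sulcal labels; its default is set so the group x region-class
    interaction on the JD scale is about 0.001. ``scanner_offset`` shifts
    observed summary JD on scanner B relative to A, sized so scanner explains
    roughly 9% of summary-JD variance.
    """

    case_gm: tuple[float, float] = (-1.55, 2.19)
    case_wm: tuple[float, float] = (-1.49, 2.20)
    control_gm: tuple[float, float] = (-0.55, 1.13)
    control_wm: tuple[float, float] = (0.26, 1.11)
    rate_correlation: float = 0.8  # GM/WM rate correlation within subject
    sulcal_excess: float = 1.065
    lesion_prob: float = 41.0 / 61.0
    lesion_radius_mm: float = 7.5
    lesion_deformation: bool = False
    lesion_contraction: float = 0.15
    scanner_offset: float = 0.012
    summary_noise_sd: float = 0.004
    roi_noise_sd: float = 0.005
    class_slope_sd: float = 0.002
    gyrus_offset: float = 0.002
    # optional linear age/sex modulation of rates; zero per study finding
    age_slope: float = 0.0
    sex_offset: float = 0.0

    def __post_init__(self):
        for pair in (self.case_gm, self.case_wm, self.control_gm, self.control_wm):
            if pair[1] < 0:
                raise ValueError("rate SDs must be >= 0")
        if self.sulcal_excess < 1:
            raise ValueError("sulcal_excess must be >= 1")
        if not 0 <= self.lesion_prob <= 1:
            raise ValueError("lesion_prob must be in [0, 1]")

    def rate_params(self, group: str) -> tuple[tuple[float, float], tuple[float, float]]:
        if group == "case":
            return self.case_gm, self.case_wm
        if group == "control":
            return self.control_gm, self.control_wm
        raise ValueError(f"unknown group {group!r}")


@dataclass
class SubjectRecord:
    """Per-subject demographics, scan metadata and clinical flags."""

    id: str
    group: str  # "case" | "control"
    age_years: float
    sex: str  # "M" | "F"
    scanner: str  # "A" | "B"
    interval_years: float
    tsi_months: float | None = None  # time since injury, cases only
    lesion: bool = False
    microbleed: bool = False
    pta: bool = False
    gcs: float | None = None
    icv_mm3: float = 1.45e6

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")
        if self.icv_mm3 <= 0:
            raise ValueError("icv_mm3 must be > 0")
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ValueError("gcs must be in [3, 15] when present")


@dataclass
class GroundTruth:
    """Analytic truth for one subject's simulated deformation.

    ``annual_jd`` is the analytic annualized Jacobian map (> 0 everywhere by
    construction); ``rates`` holds the applied %/yr volume-change rate per
    compartment; ``forward_field`` maps baseline coordinates toward
    follow-up (Jacobian < 1 under atrophy) and ``resample_field`` is its
    inverse, used to pull the template back when rendering the follow-up.
    """

    subject_id: str
    interval_years: float
    rates: dict[str, float]
    annual_jd: ScalarVolume | None = None
    forward_field: DisplacementField | None = None
    resample_field: DisplacementField | None = None
    lesion_center_mm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry helpers


class _Geometry:
    """Normalized ellipsoidal coordinates of the phantom grid."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        shape = spec.grid_shape
        vs = spec.voxel_size_mm
        self.affine = make_affine(vs, shape)
        ax = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        center_vox = (np.asarray(shape) - 1) / 2.0
        self.center_mm = np.zeros(3)  # affine puts world origin at grid centre
        self.semiaxes_mm = np.array(
            [f * (n - 1) / 2.0 * vs for f, n in zip(_SEMIAXES_FRAC, shape)]
        )
        # world mm coordinates
        self.pos_mm = np.stack([(a - c) * vs for a, c in zip(ax, center_vox)])
        y = self.pos_mm / self.semiaxes_mm[:, None, None, None]
        self.rho = np.sqrt((y**2).sum(axis=0))
        self.phi = np.arctan2(y[1], y[0])  # azimuth in [-pi, pi]
        with np.errstate(invalid="ignore"):
            costh = np.where(self.rho > 0, y[2] / np.maximum(self.rho, 1e-12), 1.0)
        self.sin_theta_sq = 1.0 - np.clip(costh, -1, 1) ** 2

        n = spec.cortical_fold_count
        self.n_pairs = n if n > 0 else 6
        u = (np.mod(self.phi, 2 * np.pi) / (2 * np.pi)) * self.n_pairs
        self.lobe = np.minimum(np.floor(u).astype(np.int32), self.n_pairs - 1)
        self.lobe_frac = u - self.lobe
        # fold modulation: 0 when cortical_fold_count == 0
        if n > 0:
            mod = np.sin(n * self.phi) * self.sin_theta_sq
        else:
            mod = np.zeros_like(self.phi)
        self.r_inner = _R_RIBBON + _FOLD_DEPTH * mod

    def ribbon_thickness_voxels(self) -> float:
        min_semiax_vox = self.semiaxes_mm.min() / self.spec.voxel_size_mm
        return (1.0 - (_R_RIBBON + _FOLD_DEPTH)) * min_semiax_vox


def _nuclei_masks(geom: _Geometry) -> list[np.ndarray]:
    """Two spherical subcortical nuclei embedded in the WM shell."""
    out = []
    for side in (-1.0, 1.0):
        c = np.array([side * 0.45, 0.12, -0.05]) * geom.semiaxes_mm
        d = np.sqrt(((geom.pos_mm - c[:, None, None, None]) ** 2).sum(axis=0))
        out.append(d < 0.16 * geom.semiaxes_mm.min())
    return out


def build_template_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, LabelVolume]:
    """Deterministic template image and label volume for a phantom spec.

    Labels: 1 = CSF ventricle, 2 = WM, 10+k = gyral sector k, 30+k = sulcal
    sector k, 50/51 = subcortical nuclei. Gyral and sulcal sectors alternate
    around the azimuth; with folding enabled the sulcal ribbon extends deeper
    (smaller mean radius) than the gyral crowns.
    """
    geom = _Geometry(spec)
    if geom.ribbon_thickness_voxels() < 2.0:
        raise ValueError(
            "grid too small: cortical ribbon would be thinner than 2 voxels "
            f"({geom.ribbon_thickness_voxels():.2f})"
        )

    rho = geom.rho
    brain = rho < 1.0
    csf = rho < _R_VENT
    gm_ribbon = brain & (rho >= geom.r_inner)
    wm = brain & ~csf & ~gm_ribbon

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[csf] = 1
    labels[wm] = 2

    table: dict[int, tuple[str, str]] = {
        0: ("background", "background"),
        1: ("ventricle", "CSF"),
        2: ("white-matter", "WM"),
    }
    gyral = gm_ribbon & (geom.lobe_frac < 0.5)
    sulcal = gm_ribbon & ~gyral
    for k in range(geom.n_pairs):
        gm_k = geom.lobe == k
        labels[gyral & gm_k] = 10 + k
        labels[sulcal & gm_k] = 30 + k
        table[10 + k] = (f"gyrus-{k}", "gyrus")
        table[30 + k] = (f"sulcus-{k}", "sulcus")

    for i, nuc in enumerate(_nuclei_masks(geom)):
        m = nuc & (labels == 2)
        labels[m] = 50 + i
        table[50 + i] = (f"nucleus-{'lr'[i]}", "subcortical-GM")

    intensity = np.full(spec.grid_shape, _CLASS_INTENSITY["background"], dtype=np.float64)
    for lab, (_, cls) in table.items():
        if lab == 0:
            continue
        intensity[labels == lab] = _CLASS_INTENSITY[cls]
    # mild smoothing gives the intensity gradients registration needs
    intensity = gaussian_filter(intensity, sigma=0.6)

    vol = ScalarVolume(intensity, geom.affine)
    lab_vol = LabelVolume(labels, geom.affine, table)
    lab_vol.meta = {"spec": spec}  # geometry is recoverable from the spec
    return vol, lab_vol


# ---------------------------------------------------------------------------
# ground-truth deformation


def _radial_maps(geom: _Geometry, v_wm: float, v_gm_map: np.ndarray):
    """Forward and inverse radial maps with piecewise-constant Jacobian.

    The radial map g is defined through g(rho)^3 piecewise linear in rho^3
    with slope equal to the shell's total volume ratio, so det(Dphi) equals
    the shell ratio exactly along each ray. ``v_gm_map`` gives the (possibly
    sulcal-enhanced) total GM ratio per voxel's ray.
    """
    rho3 = geom.rho**3
    r_in3 = geom.r_inner**3
    g1_3 = _R_VENT**3  # CSF shell ratio 1
    g2_3 = g1_3 + v_wm * (r_in3 - _R_VENT**3)
    g3_3 = g2_3 + v_gm_map * (1.0 - r_in3)

    g3 = np.where(
        rho3 < g1_3,
        rho3,
        np.where(
            rho3 < r_in3,
            g1_3 + v_wm * (rho3 - _R_VENT**3),
            np.where(rho3 < 1.0, g2_3 + v_gm_map * (rho3 - r_in3), g3_3 + (rho3 - 1.0)),
        ),
    )
    g = np.cbrt(np.maximum(g3, 0.0))

    # inverse: solve g(s) = rho for s
    s3 = np.where(
        rho3 < g1_3,
        rho3,
        np.where(
            rho3 < g2_3,
            _R_VENT**3 + (rho3 - g1_3) / v_wm,
            np.where(rho3 < g3_3, r_in3 + (rho3 - g2_3) / v_gm_map, 1.0 + (rho3 - g3_3)),
        ),
    )
    s = np.cbrt(np.maximum(s3, 0.0))
    return g, s


def _taper(rho: np.ndarray, lo: float = 1.05, hi: float = 1.5) -> np.ndarray:
    """Smoothstep from 1 (inside lo) to 0 (outside hi)."""
    t = np.clip((rho - lo) / (hi - lo), 0.0, 1.0)
    return 1.0 - t * t * (3 - 2 * t)


def _scale_to_displacement(geom: _Geometry, scale: np.ndarray) -> np.ndarray:
    """u(x) = (g/rho - 1) * (x - c), tapered to zero outside the brain."""
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(geom.rho > 1e-9, scale / np.maximum(geom.rho, 1e-9) - 1.0, 0.0)
    fac = fac * _taper(geom.rho)
    return fac[None] * geom.pos_mm


def _lesion_displacement(pos_mm, center, k, sigma):
    d = pos_mm - center[:, None, None, None]
    r2 = (d**2).sum(axis=0)
    e = np.exp(-r2 / (2 * sigma**2))
    w = -k * e[None] * d
    # closed-form det(I + grad w) for the Gaussian radial field
    jd = (1 - k * e) ** 2 * (1 - k * e * (1 - r2 / sigma**2))
    return w, jd


def draw_subject_deformation(
    atrophy: AtrophySpec,
    record: SubjectRecord,
    labels: LabelVolume,
    seed: int,
    with_fields: bool = True,
) -> tuple[DisplacementField | None, GroundTruth]:
    """Draw a subject's ground-truth deformation from the group model.

    Annual rates for GM and WM are drawn from the group's (mean, SD) with
    within-subject correlation; sulcal cortex in cases atrophies faster by
    ``sulcal_excess``. Volume change compounds geometrically over the scan
    interval: total ratio = (1 + r/100) ** interval_years.
    """
    spec = getattr(labels, "meta", {}).get("spec")
    if spec is None:
        raise ValueError("labels must come from build_template_phantom")
    geom = _Geometry(spec)
    rng = np.random.default_rng(seed)

    (gm_mu, gm_sd), (wm_mu, wm_sd) = atrophy.rate_params(record.group)
    cov = atrophy.rate_correlation * gm_sd * wm_sd
    mean = np.array([gm_mu, wm_mu])
    cov_m = np.array([[gm_sd**2, cov], [cov, wm_sd**2]])
    excess = atrophy.sulcal_excess if record.group == "case" else 1.0

    T = record.interval_years
    for _ in range(10):
        gm_rate, wm_rate = rng.multivariate_normal(mean, cov_m)
        gm_rate += atrophy.age_slope * (record.age_years - 40.0)
        gm_rate += atrophy.sex_offset * (record.sex == "M")
        worst = min(gm_rate, gm_rate * excess, wm_rate)
        if 1.0 + worst / 100.0 > 0.05:  # annual JD must stay positive
            break
    else:
        raise RuntimeError("could not draw rates implying a positive Jacobian")

    sulcal_rate = gm_rate * excess
    v_gm, v_sulcal, v_wm = (
        (1.0 + r / 100.0) ** T for r in (gm_rate, sulcal_rate, wm_rate)
    )

    sulcal_ray = geom.lobe_frac >= 0.5  # ray-wise class, valid at all radii
    v_gm_map = np.where(sulcal_ray, v_sulcal, v_gm)

    # analytic annualized JD, piecewise by shell
    rho = geom.rho
    annual = np.ones(spec.grid_shape)
    wm_shell = (rho >= _R_VENT) & (rho < geom.r_inner)
    gm_shell = (rho >= geom.r_inner) & (rho < 1.0)
    annual[wm_shell] = 1.0 + wm_rate / 100.0
    annual[gm_shell] = np.where(
        sulcal_ray[gm_shell], 1.0 + sulcal_rate / 100.0, 1.0 + gm_rate / 100.0
    )

    lesion_center = None
    forward = resample = None
    if with_fields:
        g, s = _radial_maps(geom, v_wm, v_gm_map)
        u_fwd = _scale_to_displacement(geom, g)
        u_inv = _scale_to_displacement(geom, s)
        if record.lesion and atrophy.lesion_deformation:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            lesion_center = 0.55 * direction * geom.semiaxes_mm
            sigma = atrophy.lesion_radius_mm / 1.2
            w, jd_les = _lesion_displacement(
                geom.pos_mm, lesion_center, atrophy.lesion_contraction, sigma
            )
            # compose: phi_total = phi_lesion o phi_atrophy
            u_fwd = u_fwd + _sample_vec(w, u_fwd, spec.voxel_size_mm)
            # inverse composed the other way; fixed-point invert the lesion part
            u_les_inv = _invert_fixed_point(w, spec.voxel_size_mm)
            u_inv = u_les_inv + _sample_vec(u_inv, u_les_inv, spec.voxel_size_mm)
            annual = annual * jd_les ** (1.0 / T)
        forward = DisplacementField(u_fwd, geom.affine)
        resample = DisplacementField(u_inv, geom.affine)
    elif record.lesion and atrophy.lesion_deformation:
        rng.normal(size=3)  # keep the stream aligned with the with_fields path

    counts = {
        cls: int(labels.mask_of_class(cls).sum())
        for cls in ("gyrus", "sulcus", "subcortical-GM", "WM", "CSF")
    }
    n_cort = counts["gyrus"] + counts["sulcus"]
    gm_all = n_cort + counts["subcortical-GM"]
    # nuclei ride with the WM shell deformation
    gm_mean_rate = (
        counts["gyrus"] * gm_rate
        + counts["sulcus"] * sulcal_rate
        + counts["subcortical-GM"] * wm_rate
    ) / gm_all
    wb_n = gm_all + counts["WM"] + counts["CSF"]
    wb_rate = (
        gm_mean_rate * gm_all + wm_rate * counts["WM"] + 0.0 * counts["CSF"]
    ) / wb_n
    rates = {
        "gm": gm_mean_rate,
        "wm": wm_rate,
        "brain": wb_rate,
        "gyral": gm_rate,
        "sulcal": sulcal_rate,
    }

    gt = GroundTruth(
        subject_id=record.id,
        interval_years=T,
        rates=rates,
        annual_jd=ScalarVolume(annual, geom.affine) if with_fields else None,
        forward_field=forward,
        resample_field=resample,
        lesion_center_mm=lesion_center,
    )
    return forward, gt


def _sample_vec(vec: np.ndarray, disp: np.ndarray, voxel_size: float) -> np.ndarray:
    """Sample vector field ``vec`` at x + disp(x) (both in mm)."""
    shape = vec.shape[1:]
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [g + d / voxel_size for g, d in zip(grid, disp)]
    return np.stack(
        [map_coordinates(vec[i], coords, order=1, mode="nearest") for i in range(3)]
    )


def _invert_fixed_point(u: np.ndarray, voxel_size: float, iters: int = 8) -> np.ndarray:
    """Approximate inverse displacement by fixed-point iteration."""
    v = -u.copy()
    for _ in range(iters):
        v = -_sample_vec(u, v, voxel_size)
    return v


# ---------------------------------------------------------------------------
# image synthesis


def _scanner_bias_field(spec: PhantomSpec, scanner: str, shape) -> np.ndarray:
    if spec.scanner_bias == 0:
        return np.ones(shape)
    t = np.meshgrid(
        *[np.linspace(-1, 1, n) for n in shape], indexing="ij"
    )
    if scanner == "A":
        return 1.0 + spec.scanner_bias * np.sin(0.5 * np.pi * t[0]) * np.cos(0.4 * np.pi * t[1])
    return 1.0 - spec.scanner_bias * np.sin(0.5 * np.pi * t[1]) * np.cos(0.4 * np.pi * t[2])


def _apply_lesion(img: np.ndarray, geom: _Geometry, radius_mm: float, rng) -> np.ndarray:
    """Spherical intensity drop at a deterministic WM-shell location."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    center = 0.55 * direction * geom.semiaxes_mm
    d = np.sqrt(((geom.pos_mm - center[:, None, None, None]) ** 2).sum(axis=0))
    # near-flat 85% drop with a smooth rim so the in-sphere mean falls well
    # below half the surrounding tissue intensity
    f = np.clip((1.0 - d / radius_mm) / 0.3, 0.0, 1.0)
    drop = 1.0 - 0.85 * f * f * (3 - 2 * f)
    return img * drop


def synthesize_pair(
    template: ScalarVolume,
    field: DisplacementField,
    record: SubjectRecord,
    spec: PhantomSpec,
    seed: int,
    lesion_radius_mm: float = 7.5,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Render a baseline/follow-up image pair from the template and warp.

    ``field`` is the resampling (pull-back) warp: the follow-up image is the
    template sampled at x + u(x). Baseline gets the subject's scanner bias
    plus noise; follow-up is resampled, then receives the same bias and an
    independent noise draw. When ``record.lesion`` a spherical intensity
    drop is stamped into the template before both time points.
    """
    template.same_grid(field)
    rng = np.random.default_rng(seed)
    geom = _Geometry(spec)

    img = template.data.astype(np.float64)
    if record.lesion:
        img = _apply_lesion(img, geom, lesion_radius_mm, rng)

    shape = img.shape
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [g + u / spec.voxel_size_mm for g, u in zip(grid, field.data)]
    # margin check: warped sampling must not leave the grid where there is content
    content = img > _CLASS_INTENSITY["background"] + 0.05
    for ax, c in enumerate(coords):
        over = np.maximum(c - (shape[ax] - 1), -c)[content]
        if over.size and over.max() > 0.5:
            raise ValueError(
                f"field pushes content outside grid on axis {ax} by "
                f"{over.max():.2f} voxels"
            )
    warped = map_coordinates(img, coords, order=1, mode="nearest")

    bias = _scanner_bias_field(spec, record.scanner, shape)
    baseline = img * bias
    followup = warped * bias
    if spec.noise_sd > 0:
        baseline = baseline + rng.normal(0, spec.noise_sd, shape)
        followup = followup + rng.normal(0, spec.noise_sd, shape)
    aff = template.affine
    return ScalarVolume(baseline, aff), ScalarVolume(followup, aff)


# ---------------------------------------------------------------------------
# cohort simulation


_CASE_DEMOG = dict(age=(41.55, 12.77), male_p=49 / 61, scanner_a_p=36 / 61)
_CONTROL_DEMOG = dict(age=(34.22, 10.29), male_p=18 / 32, scanner_a_p=13 / 32)
# inter-scan interval (years): lognormal matched to median [IQR] 13.08
# [9.00-15.24] months (cases) and 12.72 [12.09-14.22] (controls)
_CASE_INTERVAL = (np.log(13.08 / 12), 0.39)
_CONTROL_INTERVAL = (np.log(12.72 / 12), 0.12)
_TSI_LOGNORM = (np.log(11.71), 1.27)  # months since injury
_GCS_AVAILABLE_P = 28 / 61
_PTA_P = 56 / 61
_MICROBLEED_P = 29 / 61


@dataclass
class SimulatedCohort:
    table: pd.DataFrame
    records: list[SubjectRecord]
    template: ScalarVolume
    labels: LabelVolume
    ground_truths: dict[str, GroundTruth]
    images: dict[str, tuple[ScalarVolume, ScalarVolume]] = field(default_factory=dict)


def _draw_record(rng, sid: str, group: str) -> SubjectRecord:
    demog = _CASE_DEMOG if group == "case" else _CONTROL_DEMOG
    age = float(np.clip(rng.normal(*demog["age"]), 18, 85))
    sex = "M" if rng.random() < demog["male_p"] else "F"
    scanner = "A" if rng.random() < demog["scanner_a_p"] else "B"
    mu, sd = _CASE_INTERVAL if group == "case" else _CONTROL_INTERVAL
    interval = float(np.exp(rng.normal(mu, sd)))
    icv = float(rng.normal(1.45e6, 1.3e5) + (8e4 if sex == "M" else 0.0))
    rec = SubjectRecord(
        id=sid, group=group, age_years=age, sex=sex, scanner=scanner,
        interval_years=max(interval, 0.2), icv_mm3=max(icv, 1e6),
    )
    if group == "case":
        rec.tsi_months = float(np.exp(rng.normal(*_TSI_LOGNORM)))
        rec.microbleed = bool(rng.random() < _MICROBLEED_P)
        rec.pta = bool(rng.random() < _PTA_P)
        if rng.random() < _GCS_AVAILABLE_P:
            rec.gcs = float(np.clip(np.round(rng.normal(8.36, 4.92)), 3, 15))
    return rec


def records_to_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                id=r.id, group=r.group, age_years=r.age_years, sex=r.sex,
                scanner=r.scanner, interval_years=r.interval_years,
                tsi_months=r.tsi_months, lesion=int(r.lesion),
                microbleed=int(r.microbleed), pta=int(r.pta), gcs=r.gcs,
                icv_mm3=r.icv_mm3,
            )
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_case: int,
    n_control: int,
    atrophy: AtrophySpec | None = None,
    phantom: PhantomSpec | None = None,
    seed: int = 0,
    render_images: bool = False,
    with_fields: bool | None = None,
) -> SimulatedCohort:
    """Simulate a two-group longitudinal cohort with known ground truth.

    Subject records carry group-specific age/sex/scanner/interval
    distributions; each subject gets a ground-truth deformation drawn from
    the group's rate model. Images are rendered only when ``render_images``
    (fields are then required); with ``with_fields=False`` only analytic
    rates are produced, which is what the summary-level statistics need.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    atrophy = atrophy or AtrophySpec()
    phantom = phantom or PhantomSpec()
    if with_fields is None:
        with_fields = render_images
    if render_images and not with_fields:
        raise ValueError("render_images requires with_fields")

    template, labels = build_template_phantom(phantom)
    rng = np.random.default_rng(seed)

    records: list[SubjectRecord] = []
    for i in range(n_case):
        records.append(_draw_record(rng, f"case{i:03d}", "case"))
    for i in range(n_control):
        records.append(_draw_record(rng, f"ctrl{i:03d}", "control"))
    # lesion flags for cases from the cohort stream
    for r in records:
        if r.group == "case":
            r.lesion = bool(rng.random() < atrophy.lesion_prob)

    gts: dict[str, GroundTruth] = {}
    images: dict[str, tuple[ScalarVolume, ScalarVolume]] = {}
    for r in records:
        s = subject_seed(seed, r.id)
        _, gt = draw_subject_deformation(atrophy, r, labels, s, with_fields=with_fields)
        gts[r.id] = gt
        if render_images:
            images[r.id] = synthesize_pair(
                template, gt.resample_field, r, phantom,
                subject_seed(seed, r.id + ":img"),
                lesion_radius_mm=atrophy.lesion_radius_mm,
            )
    return SimulatedCohort(records_to_table(records), records, template, labels, gts, images)


# ---------------------------------------------------------------------------
# summary-level simulation (fast path for replicate statistics)


def simulate_summary_dataset(
    n_case: int,
    n_control: int,
    atrophy: AtrophySpec | None = None,
    seed: int = 0,
    n_gyral: int = 6,
    n_sulcal: int = 6,
    group_jd_shift: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort table, per-subject summary JD table and long ROI table.

    Observed tissue-mean JD = true annual JD + scanner offset + measurement
    noise; ROI rows add a gyrus/sulcus class contrast, a per-subject random
    class slope and ROI-level noise, reproducing the mixed-model structure
    (random intercept through the subject's own rate, random class slope).
    ``group_jd_shift`` adds an extra case-group offset on all JD summaries
    (for power/type-I studies with a known planted effect).
    """
    atrophy = atrophy or AtrophySpec()
    rng = np.random.default_rng(seed)
    records = [_draw_record(rng, f"case{i:03d}", "case") for i in range(n_case)]
    records += [_draw_record(rng, f"ctrl{i:03d}", "control") for i in range(n_control)]
    for r in records:
        if r.group == "case":
            r.lesion = bool(rng.random() < atrophy.lesion_prob)

    sum_rows, roi_rows = [], []
    for r in records:
        srng = np.random.default_rng(subject_seed(seed, r.id + ":sum"))
        (gm_mu, gm_sd), (wm_mu, wm_sd) = atrophy.rate_params(r.group)
        cov = atrophy.rate_correlation * gm_sd * wm_sd
        gm_rate, wm_rate = srng.multivariate_normal(
            [gm_mu, wm_mu], [[gm_sd**2, cov], [cov, wm_sd**2]]
        )
        excess = atrophy.sulcal_excess if r.group == "case" else 1.0
        shift = group_jd_shift * (r.group == "case")
        scan = atrophy.scanner_offset * (r.scanner == "B")

        jd_gy = 1.0 + gm_rate / 100.0
        jd_su = 1.0 + gm_rate * excess / 100.0
        jd_gm = 0.5 * (jd_gy + jd_su)
        jd_wm = 1.0 + wm_rate / 100.0
        jd_wb = 0.55 * jd_gm + 0.45 * jd_wm

        noise = srng.normal(0, atrophy.summary_noise_sd, 3)
        sum_rows.append(
            dict(
                id=r.id, gm_mean_jd=jd_gm + scan + shift + noise[0],
                wm_mean_jd=jd_wm + scan + shift + noise[1],
                brain_mean_jd=jd_wb + scan + shift + noise[2],
                gm_rate_pct_yr=100 * (jd_gm - 1.0 + shift + noise[0]),
                wm_rate_pct_yr=100 * (jd_wm - 1.0 + shift + noise[1]),
                brain_rate_pct_yr=100 * (jd_wb - 1.0 + shift + noise[2]),
            )
        )
        slope = srng.normal(0, atrophy.class_slope_sd)
        for k in range(n_gyral):
            roi_rows.append(
                dict(
                    id=r.id, roi_id=10 + k, roi_name=f"gyrus-{k}", roi_class="gyrus",
                    mean_jd=jd_gy + atrophy.gyrus_offset / 2 + slope / 2 + scan + shift
                    + srng.normal(0, atrophy.roi_noise_sd),
                    voxel_count=100,
                )
            )
        for k in range(n_sulcal):
            roi_rows.append(
                dict(
                    id=r.id, roi_id=30 + k, roi_name=f"sulcus-{k}", roi_class="sulcus",
                    mean_jd=jd_su - atrophy.gyrus_offset / 2 - slope / 2 + scan + shift
                    + srng.normal(0, atrophy.roi_noise_sd),
                    voxel_count=100,
                )
            )
    return records_to_table(records), pd.DataFrame(sum_rows), pd.DataFrame(roi_rows)


# ---------------------------------------------------------------------------
# neuropsychology


NEUROPSYCH_TESTS = ("tmt_b_minus_a_s", "people_recall", "wasi_similarities", "choice_rt_ms")

# (mean, sd) per test x visit, matching the cohort the generator emulates
NEUROPSYCH_MARGINALS = {
    ("tmt_b_minus_a_s", "baseline"): (37.9, 29.2),
    ("people_recall", "baseline"): (23.5, 7.7),
    ("wasi_similarities", "baseline"): (36.7, 5.0),
    ("choice_rt_ms", "baseline"): (497.0, 102.0),
    ("tmt_b_minus_a_s", "followup"): (33.1, 29.0),
    ("people_recall", "followup"): (25.6, 8.8),
    ("wasi_similarities", "followup"): (34.7, 5.9),
    ("choice_rt_ms", "followup"): (541.0, 112.0),
}

# per-cell missingness = 1 - n/61 observed completions
NEUROPSYCH_MISSING = {
    ("tmt_b_minus_a_s", "baseline"): 1 - 57 / 61,
    ("people_recall", "baseline"): 1 - 57 / 61,
    ("wasi_similarities", "baseline"): 1 - 36 / 61,
    ("choice_rt_ms", "baseline"): 1 - 47 / 61,
    ("tmt_b_minus_a_s", "followup"): 1 - 44 / 61,
    ("people_recall", "followup"): 1 - 44 / 61,
    ("wasi_similarities", "followup"): 1 - 23 / 61,
    ("choice_rt_ms", "followup"): 1 - 17 / 61,
}

# Spearman coupling of each score to the subject's GM summary JD
NEUROPSYCH_TARGET_RHO = {
    ("tmt_b_minus_a_s", "baseline"): 0.09,
    ("people_recall", "baseline"): 0.14,
    ("wasi_similarities", "baseline"): 0.36,
    ("choice_rt_ms", "baseline"): 0.01,
    ("tmt_b_minus_a_s", "followup"): 0.07,
    ("people_recall", "followup"): 0.51,
    ("wasi_similarities", "followup"): -0.06,
    ("choice_rt_ms", "followup"): 0.43,
}


def _normal_scores(x: np.ndarray, rng) -> np.ndarray:
    """Rank-based inverse-normal transform (random tie-break via jitter)."""
    from scipy.stats import norm, rankdata

    jitter = rng.normal(0, 1e-9, x.shape)
    ranks = rankdata(x + jitter)
    return norm.ppf(ranks / (len(x) + 1.0))


def simulate_neuropsych(
    records: list[SubjectRecord],
    atrophy_summary: np.ndarray,
    target_rho: dict | None = None,
    seed: int = 0,
    missing_rates: dict | None = None,
    marginals: dict | None = None,
) -> pd.DataFrame:
    """Neuropsych panel rank-coupled to each subject's atrophy summary.

    A Gaussian copula couples every score's latent normal to the normal
    scores of ``atrophy_summary`` so the population Spearman rho equals the
    target (latent Pearson r = 2 sin(pi rho / 6)); rho = 1 degenerates to an
    exact monotone transform. Missing cells are NaN with a per-cell
    indicator column.
    """
    target_rho = NEUROPSYCH_TARGET_RHO if target_rho is None else target_rho
    missing_rates = NEUROPSYCH_MISSING if missing_rates is None else missing_rates
    marginals = NEUROPSYCH_MARGINALS if marginals is None else marginals
    for rho in target_rho.values():
        if abs(rho) > 1:
            raise ValueError("|target_rho| must be <= 1")

    rng = np.random.default_rng(seed)
    summary = np.asarray(atrophy_summary, dtype=float)
    if len(summary) != len(records):
        raise ValueError("atrophy_summary must align with records")
    za = _normal_scores(summary, rng)

    rows = []
    for visit in ("baseline", "followup"):
        for test in NEUROPSYCH_TESTS:
            rho_s = target_rho.get((test, visit), 0.0)
            rho_l = 2.0 * np.sin(np.pi * rho_s / 6.0)
            eps = rng.standard_normal(len(records))
            z = rho_l * za + np.sqrt(max(0.0, 1.0 - rho_l**2)) * eps
            mu, sd = marginals[(test, visit)]
            score = mu + sd * z
            if test in ("choice_rt_ms",):
                score = np.maximum(score, 150.0)
            if test == "people_recall":
                score = np.clip(score, 0.0, 44.0)
            miss = rng.random(len(records)) < missing_rates.get((test, visit), 0.0)
            for r, sc, m in zip(records, score, miss):
                rows.append(
                    dict(
                        id=r.id, visit=visit, test=test,
                        score=(np.nan if m else float(sc)), missing=bool(m),
                    )
                )
    return pd.DataFrame(rows)
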