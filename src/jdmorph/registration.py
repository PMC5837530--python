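"""Symmetric within-subject registration and Jacobian-determinant maps.

The longitudinal core: a stationary-velocity-field demons registration in
which one velocity field v is estimated and the two time points are warped
by exp(v/2) and exp(-v/2) toward a midpoint "temporal average". The full
warp exp(v) maps baseline coordinates toward follow-up; its Jacobian
determinant is the voxelwise volume-change ratio (JD < 1 = tissue loss).
Interval correction is geometric: the annualized map is exp(log JD / years),
so volume change compounds across years.

Velocity and displacement fields are stored in mm on the image grid;
exponentiation uses scaling and squaring, and spatial gradients fold in the
voxel size so the Jacobian is unit-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .grids import DisplacementField, JacobianMap, ScalarVolume

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "exp_velocity",
    "register_symmetric",
    "jacobian_map",
    "annualize_jd",
    "smooth_volume",
    "compose_displacements",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RegistrationParams:
    """Demons registration settings.

    Defaults: 3 pyramid levels at 50/50/25 iterations, fluid (update)
    smoothing 2 mm, diffusion (field) smoothing 1.5 mm, 6 scaling-and-
    squaring steps. ``tolerance`` stops a level when the relative decrease
    of the masked mean-squared difference falls below it.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (50, 50, 25)
    fluid_sigma_mm: float = 2.0
    diffusion_sigma_mm: float = 1.5
    squaring_steps: int = 6
    step_size: float = 1.8
    tolerance: float = 1e-6
    force: str = "demons"  # "demons" (normalized SSD) update
    # suppress updates where the image gradient magnitude (1/mm, intensity
    # units) is below this floor: flat regions carry no matching information
    # and would otherwise accumulate noise-driven drift
    gradient_floor: float = 0.03

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.squaring_steps < 1:
            raise ValueError("squaring_steps must be >= 1")
        if self.fluid_sigma_mm < 0 or self.diffusion_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if len(self.iterations) < self.levels:
            raise ValueError("need an iteration count per level")


@dataclass
class RegistrationResult:
    midpoint: ScalarVolume
    forward_half: DisplacementField   # applied to follow-up (pull-back by exp(+v/2))
    backward_half: DisplacementField  # applied to baseline (pull-back by exp(-v/2))
    full_warp: DisplacementField      # exp(v): baseline -> follow-up map
    velocity: np.ndarray
    objective_trace: list[list[float]] = field(default_factory=list)
    converged_identity: bool = False


def _sample_field(vec: np.ndarray, disp: np.ndarray, voxel_size: float) -> np.ndarray:
    """Sample each component of ``vec`` at x + disp(x); both fields in mm."""
    shape = vec.shape[1:]
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [g + d / voxel_size for g, d in zip(grid, disp)]
    return np.stack(
        [map_coordinates(vec[c], coords, order=1, mode="nearest") for c in range(3)]
    )


def _warp_image(img: np.ndarray, disp: np.ndarray, voxel_size: float) -> np.ndarray:
    shape = img.shape
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [g + d / voxel_size for g, d in zip(grid, disp)]
    return map_coordinates(img, coords, order=1, mode="nearest")


def compose_displacements(u: np.ndarray, w: np.ndarray, voxel_size: float) -> np.ndarray:
    """Displacement of the composed warp (x + u) after (x + w): w(x) + u(x + w(x))."""
    return w + _sample_field(u, w, voxel_size)


def _exp_velocity_arr(v: np.ndarray, steps: int, voxel_size: float) -> np.ndarray:
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite velocity field")
    u = v / (2.0**steps)
    for _ in range(steps):
        u = compose_displacements(u, u, voxel_size)
    return u


def exp_velocity(v, steps: int = 6, voxel_size_mm: float | None = None):
    """Flow at time 1 of a stationary velocity field, by scaling and squaring.

    Accepts a raw ``(3, nx, ny, nz)`` array (with ``voxel_size_mm``) or a
    DisplacementField-like container and returns the matching type.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if isinstance(v, DisplacementField):
        u = _exp_velocity_arr(v.data.astype(np.float64), steps, v.voxel_size_mm)
        return DisplacementField(u, v.affine)
    if voxel_size_mm is None:
        raise ValueError("voxel_size_mm required for array input")
    return _exp_velocity_arr(np.asarray(v, dtype=np.float64), steps, voxel_size_mm)


def _gradient(img: np.ndarray, voxel_size: float) -> np.ndarray:
    return np.stack(np.gradient(img, voxel_size))


def _demons_update(fixed, moving_warped, grad, voxel_size, gradient_floor=0.0):
    """Normalized SSD (Thirion) force pushing the moving image toward fixed."""
    diff = fixed - moving_warped
    g2 = (grad**2).sum(axis=0)
    denom = g2 + (diff**2) / (voxel_size**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(denom > 1e-12, diff / denom, 0.0)
    if gradient_floor > 0:
        scale = np.where(g2 > gradient_floor**2, scale, 0.0)
    return scale[None] * grad


def register_symmetric(
    baseline: ScalarVolume,
    followup: ScalarVolume,
    params: RegistrationParams | None = None,
    mask: np.ndarray | None = None,
) -> RegistrationResult:
    """Estimate the symmetric within-subject warp between two time points.

    One stationary velocity v is optimized so that the follow-up pulled back
    by exp(v/2) matches the baseline pulled back by exp(-v/2); the midpoint
    image is their voxel mean and the returned full warp exp(v) satisfies
    followup(x + u(x)) ~= baseline(x), i.e. it is the baseline -> follow-up
    spatial map whose JD measures local volume change. The masked
    mean-squared difference is non-increasing over accepted iterations at
    each pyramid level (uphill steps are rejected and the step halved).
    """
    params = params or RegistrationParams()
    baseline.same_grid(followup)
    if not (np.all(np.isfinite(baseline.data)) and np.all(np.isfinite(followup.data))):
        raise ValueError("non-finite image input")
    vs = baseline.voxel_size_mm
    b0 = baseline.data.astype(np.float64)
    f0 = followup.data.astype(np.float64)

    if np.array_equal(b0, f0):
        zero = np.zeros((3, *baseline.shape3), dtype=np.float64)
        aff = baseline.affine
        return RegistrationResult(
            midpoint=ScalarVolume(b0, aff),
            forward_half=DisplacementField(zero, aff),
            backward_half=DisplacementField(zero.copy(), aff),
            full_warp=DisplacementField(zero.copy(), aff),
            velocity=zero.copy(),
            converged_identity=True,
        )

    factors = [2 ** (params.levels - 1 - l) for l in range(params.levels)]
    v = None
    trace_all: list[list[float]] = []
    improved_any = False

    for level, factor in enumerate(factors):
        if factor > 1:
            b = zoom(b0, 1.0 / factor, order=1)
            f = zoom(f0, 1.0 / factor, order=1)
        else:
            b, f = b0, f0
        lvs = vs * factor
        if v is None:
            v = np.zeros((3, *b.shape), dtype=np.float64)
        else:
            v = np.stack([zoom(v[c], np.array(b.shape) / v.shape[1:], order=1) for c in range(3)])
        if mask is not None:
            m = zoom(mask.astype(np.float64), np.array(b.shape) / np.array(mask.shape), order=0) > 0.5
        else:
            m = np.ones(b.shape, dtype=bool)

        fluid_sig = params.fluid_sigma_mm / lvs
        diff_sig = params.diffusion_sigma_mm / lvs
        step = params.step_size
        trace: list[float] = []
        obj_prev = np.inf
        n_iter = params.iterations[level]

        for _ in range(n_iter):
            half_f = _exp_velocity_arr(v / 2.0, params.squaring_steps, lvs)
            half_b = _exp_velocity_arr(-v / 2.0, params.squaring_steps, lvs)
            ib = _warp_image(b, half_b, lvs)   # baseline toward midpoint
            if_ = _warp_image(f, half_f, lvs)  # follow-up toward midpoint
            obj = float(np.mean((ib - if_)[m] ** 2))

            if obj >= obj_prev:
                v = v_prev  # reject, shrink step
                step *= 0.5
                if step < 1e-3:
                    break
                continue
            if trace and (obj_prev - obj) < params.tolerance * max(obj_prev, 1e-30):
                trace.append(obj)
                break
            trace.append(obj)
            obj_prev = obj
            v_prev = v

            grad = 0.5 * (_gradient(ib, lvs) + _gradient(if_, lvs))
            upd = _demons_update(ib, if_, grad, lvs, params.gradient_floor)
            if fluid_sig > 0:
                upd = np.stack([gaussian_filter(upd[c], fluid_sig) for c in range(3)])
            v = v + step * upd
            if diff_sig > 0:
                v = np.stack([gaussian_filter(v[c], diff_sig) for c in range(3)])

        trace_all.append(trace)
        if len(trace) > 1 and trace[-1] < trace[0]:
            improved_any = True

    if not improved_any:
        warnings.warn(
            "registration could not reduce the objective; returning identity",
            RuntimeWarning,
        )
        v = np.zeros((3, *baseline.shape3), dtype=np.float64)

    # upsample final velocity to full resolution if the last level was coarse
    if v.shape[1:] != baseline.shape3:
        v = np.stack([zoom(v[c], np.array(baseline.shape3) / v.shape[1:], order=1) for c in range(3)])

    aff = baseline.affine
    half_f = _exp_velocity_arr(v / 2.0, params.squaring_steps, vs)
    half_b = _exp_velocity_arr(-v / 2.0, params.squaring_steps, vs)
    full = _exp_velocity_arr(v, params.squaring_steps, vs)
    mid = 0.5 * (_warp_image(b0, half_b, vs) + _warp_image(f0, half_f, vs))
    return RegistrationResult(
        midpoint=ScalarVolume(mid, aff),
        forward_half=DisplacementField(half_f, aff),
        backward_half=DisplacementField(half_b, aff),
        full_warp=DisplacementField(full, aff),
        velocity=v,
        objective_trace=trace_all,
    )


def jacobian_map(fieldv: DisplacementField, mask: np.ndarray | None = None) -> JacobianMap:
    """Voxelwise determinant of the spatial map phi(x) = x + u(x).

    Central differences in the interior, one-sided at the faces, with the
    voxel size folded in so the result is a unit-free volume ratio. Any
    non-positive determinant inside ``mask`` triggers a folding warning
    (the map is still returned; downstream summaries should exclude those
    voxels rather than clamp them).
    """
    u = fieldv.data.astype(np.float64)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite displacement field")
    vs = fieldv.voxel_size_mm
    J = np.empty((3, 3, *fieldv.shape3))
    for i in range(3):
        gi = np.gradient(u[i], vs)
        for j in range(3):
            J[i, j] = gi[j] + (1.0 if i == j else 0.0)
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    check = det if mask is None else det[mask]
    n_fold = int((check <= 0).sum())
    if n_fold:
        warnings.warn(
            f"folding: {n_fold} voxel(s) with non-positive Jacobian determinant",
            RuntimeWarning,
        )
    return JacobianMap(det, fieldv.affine, annualized=False)


def annualize_jd(jd: JacobianMap, interval_years: float) -> JacobianMap:
    """Geometric interval correction: exp(log JD / years)."""
    if interval_years <= 0:
        raise ValueError("interval_years must be > 0")
    if jd.annualized:
        raise ValueError("map is already annualized")
    data = jd.data.astype(np.float64)
    bad = data <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive JD voxel(s) excluded from annualization",
            RuntimeWarning,
        )
    out = np.full_like(data, np.nan)
    ok = ~bad
    out[ok] = np.exp(np.log(data[ok]) / interval_years)
    return JacobianMap(out, jd.affine, annualized=True, interval_years=interval_years)


def smooth_volume(image: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return image.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / image.voxel_size_mm
    return ScalarVolume(gaussian_filter(image.data.astype(np.float64), sigma_vox), image.affine)
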