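"""Synthetic giant-slalom generator: course, terrain and a balanced skier.

The generator builds a *stated world* in which the pendulum estimator's own
model assumptions hold exactly, so estimators can be validated by parameter
recovery:

* an inclined planar slope with pitch ``atan(drop/length)`` (the default
  350 m / 99 m course gives ≈ 15.8°) carrying 12 gates at equal along-slope
  intervals with alternating lateral offsets;
* a ground-contact path splined through the gates, traversed with a
  monotone speed ramp clipped at a maximum;
* a skier whose lean angle satisfies the dynamic balance equation
  l_g·θ̈ + a_r·cosθ − (a_z+g)·sinθ = 0 at every sample, with (a_r, a_z) the
  COM's own accelerations — found by a fixed-point iteration over the whole
  series; the lean plane is the vertical plane containing the horizontal
  radial direction toward the instantaneous turn center;
* skis at ±stance/2 across the direction of travel, on the mesh;
* optional "style" perturbations (lean bias, fore-aft COM offset, knee
  flexion) that emulate distinct subjects and break the balance assumption;
* a GNSS degradation step: decimation to 20 Hz plus i.i.d. Gaussian noise at
  the RTK accuracy level (95% error bounds ≈ 2σ: σ_h 3.5 mm, σ_v 8 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DataError, GenerationError, NoSolutionError
from .filtering import BALANCE_CUTOFF_HZ, band_limited_deriv2
from .ip import G_DEFAULT, balance_residual, solve_theta_series
from .terrain import SlopeMesh, elevation
from .trajio import PoseSeries, Trajectory3D

__all__ = ["CourseSpec", "SkierSpec", "GnssNoiseSpec", "SkierStyle",
           "make_course", "make_run", "degrade_to_gnss",
           "run_balance_residual", "make_cohort"]


@dataclass
class CourseSpec:
    """Giant-slalom course geometry and the skier's speed model."""

    length_m: float = 350.0
    drop_m: float = 99.0
    n_gates: int = 12
    gate_lateral_offset_m: float = 4.0
    v0: float = 8.0            # entry speed, m/s
    v_max: float = 16.0        # terminal speed clip, m/s
    accel: float = 1.2         # ramp acceleration, m/s²
    mesh_spacing_m: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.length_m, self.drop_m) <= 0 or self.n_gates <= 0:
            raise DataError("course length, drop and gate count must be positive")
        if self.drop_m >= self.length_m:
            raise DataError("drop must be smaller than course length")
        if self.v0 <= 0 or self.v_max < self.v0 or self.accel < 0:
            raise DataError("invalid speed model")

    @property
    def pitch(self) -> float:
        return float(np.arctan2(self.drop_m, self.length_m))


@dataclass
class SkierStyle:
    """Deviations from the perfectly balanced pendulum (one 'technique')."""

    lean_bias_rad: float = 0.0
    fore_aft_m: float = 0.0
    flexion_m: float = 0.0


@dataclass
class SkierSpec:
    """Skier geometry: bar length, COM fraction, stance and style."""

    l: float = 1.40            # ground-to-antenna distance along the body axis
    k: float = 0.56            # COM height fraction (0.57 female / 0.55 male)
    stance_width_m: float = 0.30
    style: SkierStyle = field(default_factory=SkierStyle)
    balanced: bool = True

    def __post_init__(self):
        if not 0 < self.k < 1:
            raise DataError("k must be in (0, 1)")
        if self.l <= 0 or self.stance_width_m < 0:
            raise DataError("l must be positive and stance non-negative")


@dataclass
class GnssNoiseSpec:
    """RTK GNSS accuracy model (per-axis Gaussian, 95% bounds ≈ 2σ)."""

    sigma_h: float = 0.0035
    sigma_v: float = 0.008
    rate_hz: float = 20.0

    def __post_init__(self):
        if self.sigma_h < 0 or self.sigma_v < 0 or self.rate_hz <= 0:
            raise DataError("noise sigmas must be >= 0 and rate positive")


def make_course(spec: CourseSpec):
    """Planar inclined mesh plus gate ground positions.

    Gates sit at equal ``length/(n_gates−1)`` along-slope intervals with
    alternating ±lateral offsets (a single gate sits at the start).
    Returns ``(mesh, gates)`` with gates of shape (n_gates, 3).
    """
    pitch = spec.pitch
    slope = np.tan(pitch)
    x_len = spec.length_m * np.cos(pitch)
    margin = 25.0
    half_w = spec.gate_lateral_offset_m + margin
    dx = spec.mesh_spacing_m
    xs = np.arange(-margin, x_len + margin + dx, dx)
    ys = np.arange(-half_w, half_w + dx, dx)
    zz = -slope * xs[None, :] + np.zeros((ys.size, 1))
    mesh = SlopeMesh(xs[0], ys[0], dx, dx, zz)
    if spec.n_gates == 1:
        s_gates = np.array([0.0])
    else:
        s_gates = np.linspace(0.0, spec.length_m, spec.n_gates)
    gx = s_gates * np.cos(pitch)
    gy = spec.gate_lateral_offset_m * (-1.0) ** np.arange(spec.n_gates)
    gz = elevation(mesh, gx, gy)
    gates = np.column_stack([gx, gy, gz])
    return mesh, gates


def _ground_path(mesh: SlopeMesh, gates: np.ndarray, spec: CourseSpec):
    """Smooth ground path through the gates, parameterized by 3-D arc length."""
    pitch = spec.pitch
    xi_g = gates[:, 0] / np.cos(pitch)  # along-slope coordinate of each gate
    y_g = gates[:, 1]
    uniform = (len(xi_g) >= 2
               and np.ptp(np.diff(xi_g)) < 1e-9 * max(xi_g[-1] - xi_g[0], 1.0)
               and np.allclose(y_g, y_g[0] * (-1.0) ** np.arange(len(y_g))))
    if len(xi_g) < 2:
        y_of_xi = lambda v: np.full_like(np.asarray(v, dtype=float), y_g[0])
    elif uniform:
        # Uniformly spaced gates with alternating ±offset: the C^inf
        # interpolant is a cosine (the giant-slalom turn rhythm).  A
        # piecewise-polynomial path would put jerk discontinuities at every
        # gate, which the balanced-lean construction cannot absorb (the
        # balance equation needs a continuous θ̈).
        delta = xi_g[1] - xi_g[0]
        amp = y_g[0]
        y_of_xi = lambda v: amp * np.cos(np.pi * (np.asarray(v) - xi_g[0]) / delta)
    else:
        y_of_xi = CubicSpline(xi_g, y_g, bc_type="natural")
    xi = np.linspace(xi_g[0], xi_g[-1], 20001)
    x = xi * np.cos(pitch)
    y = np.asarray(y_of_xi(xi), dtype=float)
    z = elevation(mesh, x, y)
    seg = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2 + np.diff(z) ** 2)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    xi_of_s = CubicSpline(s, xi)
    def position(s_query):
        xq = np.asarray(xi_of_s(s_query)) * np.cos(pitch)
        yq = np.asarray(y_of_xi(np.asarray(xi_of_s(s_query))))
        return np.column_stack([xq, yq, elevation(mesh, xq, yq)])
    return position, float(s[-1])


def _speed_profile(spec: CourseSpec, s_total: float, rate_hz: float):
    """Sample times and arc-length positions for the saturating speed ramp.

    The monotone ramp approaches ``v_max`` smoothly (exponentially, as a
    drag-limited skier would) with initial slope ``accel``:
    ``v(t) = v_max − (v_max − v0)·exp(−λt)``, ``λ = accel/(v_max − v0)``.
    A hard clip would kink the acceleration and break the C² smoothness the
    balanced-lean construction relies on.
    """
    v0, vmax, a = spec.v0, spec.v_max, spec.accel
    if a <= 0 or vmax == v0:
        t_end = s_total / v0
        t = np.arange(0.0, t_end, 1.0 / rate_hz)
        return t, np.clip(v0 * t, 0.0, s_total)
    lam = a / (vmax - v0)

    def arclen(tq):
        return vmax * tq + (vmax - v0) / lam * (np.exp(-lam * tq) - 1.0)

    from scipy.optimize import brentq
    t_end = brentq(lambda tq: arclen(tq) - s_total, 0.0, 10.0 * s_total / v0)
    t = np.arange(0.0, t_end, 1.0 / rate_hz)
    return t, np.clip(arclen(t), 0.0, s_total)


def _fd_deriv2(t: np.ndarray, x: np.ndarray):
    """Second time derivative by repeated central differences.

    Repeated one-sided differences underestimate the boundary curvature by
    up to a factor two, which the balance fixed point amplifies; the two
    samples at each end therefore copy the nearest uncontaminated interior
    value.  Unlike a not-a-knot spline this operator cannot ring when the
    series is fed back on itself.
    """
    d2 = np.gradient(np.gradient(x, t, axis=0), t, axis=0)
    d2[0] = d2[1] = d2[2]
    d2[-1] = d2[-2] = d2[-3]
    return d2


def _smooth_deriv2(t: np.ndarray, x: np.ndarray,
                   cutoff_hz: float = BALANCE_CUTOFF_HZ):
    """Band-limited second time derivative (the balance-loop operator).

    The pointwise balance fixed point is violently unstable for
    sample-scale modes (their feedback gain scales as l_g/(g·dt²)), so
    every series that feeds back on itself is differentiated through the
    shared band-limited operator; see :mod:`skipose.filtering`.
    """
    return band_limited_deriv2(t, x, cutoff_hz)


def make_run(course, skier: SkierSpec, rate_hz: float = 120.0,
             speed_spec: CourseSpec | None = None,
             max_fixed_point_iter: int = 400) -> PoseSeries:
    """Generate one ski run whose geometry satisfies the pendulum model.

    ``course`` is either a :class:`CourseSpec` or a prebuilt
    ``(mesh, gates)`` pair (in which case ``speed_spec`` supplies the speed
    model, defaulting to :class:`CourseSpec` defaults).  When
    ``skier.balanced`` the lean angle series is the exact fixed point of the
    balance equation evaluated with the COM path's own
    (spline-differentiated) accelerations; style offsets are added instead
    when the balanced flag is unset.
    """
    if isinstance(course, CourseSpec):
        spec = course
        mesh, gates = make_course(spec)
    else:
        mesh, gates = course
        spec = speed_spec or CourseSpec()
    position, s_total = _ground_path(mesh, gates, spec)
    t, s = _speed_profile(spec, s_total, rate_hz)
    if t.size < 10:
        raise GenerationError("run too short; check speed model and course")
    ground = position(s)
    dt = 1.0 / rate_hz

    # ground-path kinematics and the lean-plane direction (left of travel)
    vel = np.gradient(ground, t, axis=0)
    vh = vel[:, :2]
    vh_norm = np.linalg.norm(vh, axis=1)
    if np.any(vh_norm < 1e-9):
        raise GenerationError("degenerate ground path: zero horizontal speed")
    n_hat = np.column_stack([-vh[:, 1], vh[:, 0]]) / vh_norm[:, None]

    def lean_unit(theta):
        return np.column_stack([np.sin(theta)[:, None] * n_hat, np.cos(theta)])

    # fixed point: θ consistent with the COM path it generates
    theta = np.zeros(t.size)
    l_g = skier.k * skier.l
    relax = 0.4
    converged = False
    for _ in range(max_fixed_point_iter):
        com = ground + l_g * lean_unit(theta)
        a_com = _smooth_deriv2(t, com)
        a_r = (a_com[:, :2] * n_hat).sum(axis=1)
        a_z = a_com[:, 2]
        theta_ddot = _smooth_deriv2(t, theta)
        # keep transient iterates inside the solvable region
        cap = 0.99 * np.sqrt(a_r ** 2 + (a_z + G_DEFAULT) ** 2) / l_g
        theta_ddot = np.clip(theta_ddot, -cap, cap)
        try:
            theta_new = solve_theta_series(a_r, a_z, theta_ddot, l_g, G_DEFAULT)
        except NoSolutionError as exc:
            raise GenerationError(
                "speed model yields radial accelerations with no balanced "
                "lean solution") from exc
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta + relax * (theta_new - theta)
        # floor set by filter roundoff; residual sensitivity is ~g per rad,
        # so 1e-10 rad leaves the balance residual near 1e-9
        if delta < 1e-10:
            converged = True
            break
    if not converged:
        raise GenerationError("balanced-lean fixed point did not converge")

    # style perturbations emulate individual technique (unbalanced skiers)
    l_series = np.full(t.size, skier.l)
    fore_aft = np.zeros((t.size, 3))
    if not skier.balanced:
        st = skier.style
        theta = theta + st.lean_bias_rad
        if st.flexion_m:
            amp = np.max(np.abs(theta))
            crouch = np.abs(theta) / amp if amp > 0 else np.zeros(t.size)
            l_series = l_series - st.flexion_m * crouch
        if st.fore_aft_m:
            t_hat = np.column_stack([vh / vh_norm[:, None], np.zeros(t.size)])
            fore_aft = st.fore_aft_m * t_hat

    u = lean_unit(theta)
    antenna = ground + l_series[:, None] * u
    com = ground + (skier.k * l_series)[:, None] * u + fore_aft

    # skis across the local direction of travel, feet on the mesh
    half = 0.5 * skier.stance_width_m
    left_xy = ground[:, :2] + half * n_hat
    right_xy = ground[:, :2] - half * n_hat
    ski_left = np.column_stack([left_xy, elevation(mesh, left_xy[:, 0], left_xy[:, 1])])
    ski_right = np.column_stack([right_xy, elevation(mesh, right_xy[:, 0], right_xy[:, 1])])
    return PoseSeries(t, antenna, com, ski_left, ski_right, rate_hz=rate_hz)


def run_balance_residual(run: PoseSeries, k: float,
                         g: float = G_DEFAULT) -> np.ndarray:
    """Balance-equation residual of a generated run, recomputed from geometry.

    Reconstructs θ and l from the antenna/mid-ski geometry, differentiates
    the COM path for (a_r, a_z) and the angle series for θ̈ with the same
    band-limited operator the generator iterates with, and evaluates
    l_g·θ̈ + a_r·cosθ − (a_z+g)·sinθ.  Balanced runs satisfy |residual| < 1e-8
    at interior samples.
    """
    ground = run.mid_ski()
    bar = run.antenna - ground
    l = np.linalg.norm(bar, axis=1)
    vel = np.gradient(ground, run.t, axis=0)
    vh = vel[:, :2]
    n_hat = np.column_stack([-vh[:, 1], vh[:, 0]])
    n_hat /= np.linalg.norm(n_hat, axis=1, keepdims=True)
    sin_th = (bar[:, :2] * n_hat).sum(axis=1) / l
    theta = np.arctan2(sin_th, bar[:, 2] / l)
    a_com = _smooth_deriv2(run.t, run.com)
    a_r = (a_com[:, :2] * n_hat).sum(axis=1)
    a_z = a_com[:, 2]
    theta_ddot = _smooth_deriv2(run.t, theta)
    return balance_residual(theta, a_r, a_z, theta_ddot, k * l, g)


def degrade_to_gnss(pose: PoseSeries, noise: GnssNoiseSpec,
                    seed: int | None = 0) -> Trajectory3D:
    """Decimate the antenna track to the GNSS rate and add RTK-level noise."""
    if pose.rate_hz is None or pose.rate_hz < noise.rate_hz:
        raise DataError("pose rate must be at least the GNSS rate")
    step = pose.rate_hz / noise.rate_hz
    if abs(step - round(step)) > 1e-6:
        raise DataError("pose rate must be an integer multiple of the GNSS rate")
    idx = np.arange(0, len(pose), int(round(step)))
    t = pose.t[idx]
    p = pose.antenna[idx].copy()
    rng = np.random.default_rng(seed)
    p[:, 0] += rng.normal(0.0, noise.sigma_h, idx.size)
    p[:, 1] += rng.normal(0.0, noise.sigma_h, idx.size)
    p[:, 2] += rng.normal(0.0, noise.sigma_v, idx.size)
    return Trajectory3D(t, p, rate_hz=noise.rate_hz)


# ---------------------------------------------------------------------------
# Synthetic cohorts for cross-validation experiments
# ---------------------------------------------------------------------------

def make_cohort(n_skiers: int = 5, runs_per_skier=(3, 4, 4, 3, 4),
                course: CourseSpec | None = None, seed: int = 0,
                rate_hz: float = 120.0, balanced: bool = False):
    """Generate a cohort of synthetic subjects with distinct techniques.

    Each skier gets a style drawn bounded away from zero (individual
    techniques are visibly distinct) and per-run speed-profile jitter; the
    default layout (5 skiers, 3–4 runs, 18 total) mirrors a typical
    instrumented field campaign.  Returns ``(mesh, records)`` where each
    record is a dict with ``skier``, ``run`` and ``pose`` keys.
    """
    rng = np.random.default_rng(seed)
    course = course or CourseSpec()
    mesh, gates = make_course(course)
    if np.isscalar(runs_per_skier):
        runs_per_skier = [int(runs_per_skier)] * n_skiers
    if len(runs_per_skier) != n_skiers:
        raise DataError("runs_per_skier must have one entry per skier")
    records = []
    for si in range(n_skiers):
        style = SkierStyle(
            lean_bias_rad=float(rng.choice([-1, 1]) * rng.uniform(0.03, 0.08)),
            fore_aft_m=float(rng.choice([-1, 1]) * rng.uniform(0.05, 0.12)),
            flexion_m=float(rng.uniform(0.08, 0.20)),
        )
        skier = SkierSpec(
            l=float(rng.uniform(1.32, 1.48)),
            k=float(rng.uniform(0.55, 0.57)),
            stance_width_m=float(rng.uniform(0.26, 0.34)),
            style=style, balanced=balanced)
        for ri in range(runs_per_skier[si]):
            run_course = CourseSpec(
                length_m=course.length_m, drop_m=course.drop_m,
                n_gates=course.n_gates,
                gate_lateral_offset_m=course.gate_lateral_offset_m,
                v0=float(course.v0 + rng.normal(0.0, 0.3)),
                v_max=float(course.v_max + rng.normal(0.0, 0.5)),
                accel=course.accel, mesh_spacing_m=course.mesh_spacing_m)
            pose = make_run((mesh, gates), skier, rate_hz=rate_hz,
                            speed_spec=run_course)
            records.append({"skier": f"S{si + 1}", "run": f"R{ri + 1}",
                            "pose": pose, "spec": skier})
    return mesh, records
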