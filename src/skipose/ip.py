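"""Inverted-pendulum estimation of COM and ground-contact trajectories.

The skier is modelled as an unactuated inverted pendulum on a cart: a single
bar from the snow-contact (ground) point through the COM to the GNSS antenna,
kept dynamically balanced by gravity and the radial force of the turn.  With
``θ`` the lean angle from the global vertical, ``l_g = k·l`` the COM height
along the bar, and ``(a_r, a_z)`` the radial/vertical COM accelerations, the
balance equation is

    l_g·θ̈ + a_r·cos(θ) − (a_z + g)·sin(θ) = 0,

solved for θ per sample via the tangent half-angle substitution.  Neither θ̈
nor l is known in advance, so a fixed-point loop alternates: solve for θ,
intersect the lean ray with the slope mesh to get l, smooth θ with a Kalman
filter to get θ̇/θ̈, and transfer the antenna accelerations to the COM through
the rigid-pendulum kinematics.  The driving torque τ is taken as zero and the
pendulum inertia as a point mass at the COM, so the mass cancels everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .errors import DataError, NoSolutionError
from .filtering import band_limited_deriv2
from .terrain import SlopeMesh, ray_intersect_many
from .trajio import PoseSeries, Trajectory3D

__all__ = ["PendulumParams", "PendulumSeries", "IPResult",
           "kalman_theta", "solve_theta", "solve_theta_series",
           "com_accel_from_antenna", "InvertedPendulumEstimator", "estimate_ip"]

G_DEFAULT = 9.81


@dataclass
class PendulumParams:
    """Physical parameters of the pendulum model.

    k is the COM height fraction of standing height (0.57 female / 0.55 male,
    0.56 by default); the mass only matters for force reporting
    (F_r = m·a_r, F_g = m·g) since it cancels in the balance equation.
    """

    k: float = 0.56
    g: float = G_DEFAULT
    m: float = 80.0
    tau: float = 0.0  # unactuated pendulum

    def __post_init__(self):
        if not 0 < self.k < 1:
            raise DataError("COM fraction k must be in (0, 1)")
        if self.g <= 0:
            raise DataError("g must be positive")

    def inertia(self, l_g) -> np.ndarray:
        """Point-mass moment of inertia J = m·l_g² about the ground pivot."""
        return self.m * np.asarray(l_g) ** 2


@dataclass
class PendulumSeries:
    """Per-sample pendulum state and derived COM / ground trajectories."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray
    l: np.ndarray
    l_dot: np.ndarray
    l_ddot: np.ndarray
    l_g: np.ndarray
    a_r_star: np.ndarray
    a_z_star: np.ndarray
    a_r: np.ndarray
    a_z: np.ndarray
    com: np.ndarray
    ground: np.ndarray


@dataclass
class IPResult:
    """Output of the fixed-point optimization."""

    pendulum: PendulumSeries
    n_iterations: int
    converged: bool
    residuals: list = field(default_factory=list)  # max|Δθ| per iteration

    @property
    def com_trajectory(self) -> Trajectory3D:
        return Trajectory3D(self.pendulum.t.copy(), self.pendulum.com.copy())

    @property
    def ground_trajectory(self) -> Trajectory3D:
        return Trajectory3D(self.pendulum.t.copy(), self.pendulum.ground.copy())


# ---------------------------------------------------------------------------
# Kalman smoothing of the lean angle
# ---------------------------------------------------------------------------

def kalman_theta(theta_meas, dt: float, q: float = 10.0, r_meas: float = 1e-4):
    """Kalman smoother of the lean angle: returns (θ, θ̇, θ̈) series.

    State [θ, θ̇, θ̈] with a constant-acceleration (white-jerk) process of
    spectral density ``q`` (rad²/s⁶·s) and position-only measurements of
    variance ``r_meas`` (rad²).  A forward filter is followed by a
    Rauch-Tung-Striebel backward pass, which is the optimal offline estimate
    of the angular acceleration from the noisy angle series.
    """
    y = np.asarray(theta_meas, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise DataError("kalman_theta needs a 1-D series of >= 10 samples")
    if dt <= 0:
        raise DataError("dt must be positive and uniform")
    F = np.array([[1, dt, 0.5 * dt * dt], [0, 1, dt], [0, 0, 1]])
    Q = q * np.array([
        [dt ** 5 / 20, dt ** 4 / 8, dt ** 3 / 6],
        [dt ** 4 / 8, dt ** 3 / 3, dt ** 2 / 2],
        [dt ** 3 / 6, dt ** 2 / 2, dt],
    ])
    H = np.array([1.0, 0.0, 0.0])
    n = y.size
    x = np.array([y[0], (y[1] - y[0]) / dt, 0.0])
    P = np.diag([r_meas, 1.0, 10.0])
    xs_pred = np.empty((n, 3))
    Ps_pred = np.empty((n, 3, 3))
    xs_filt = np.empty((n, 3))
    Ps_filt = np.empty((n, 3, 3))
    for i in range(n):
        if i == 0:
            xp, Pp = x, P
        else:
            xp = F @ xs_filt[i - 1]
            Pp = F @ Ps_filt[i - 1] @ F.T + Q
        S = Pp[0, 0] + r_meas
        K = Pp[:, 0] / S
        xs_pred[i], Ps_pred[i] = xp, Pp
        xs_filt[i] = xp + K * (y[i] - xp[0])
        Ps_filt[i] = Pp - np.outer(K, Pp[0, :])
    # RTS backward smoothing
    xs = xs_filt.copy()
    Ps = Ps_filt.copy()
    for i in range(n - 2, -1, -1):
        C = Ps_filt[i] @ F.T @ np.linalg.inv(Ps_pred[i + 1])
        xs[i] = xs_filt[i] + C @ (xs[i + 1] - xs_pred[i + 1])
        Ps[i] = Ps_filt[i] + C @ (Ps[i + 1] - Ps_pred[i + 1]) @ C.T
    return xs[:, 0], xs[:, 1], xs[:, 2]


# ---------------------------------------------------------------------------
# Closed-form balance solution
# ---------------------------------------------------------------------------

def balance_residual(theta, a_r, a_z, theta_ddot, l_g, g: float = G_DEFAULT):
    """Residual of the balance equation l_g·θ̈ + a_r·cosθ − (a_z+g)·sinθ."""
    theta = np.asarray(theta, dtype=float)
    return (np.asarray(l_g) * np.asarray(theta_ddot) + np.asarray(a_r) * np.cos(theta)
            - (np.asarray(a_z) + g) * np.sin(theta))


def kalman_theta_padded(y, dt: float, q: float = 10.0, r_meas: float = 1e-4,
                        pad_s: float = 1.5, fit_s: float = 0.5):
    """Kalman smoothing with quadratic-extrapolation padding at both ends.

    The RTS smoother has only one-sided information near the series edges,
    which biases the acceleration estimate there.  Extending the series
    with a quadratic fitted to the outermost ``fit_s`` seconds continues it
    exactly as the smoother's own constant-acceleration process model
    would, and the padding is trimmed from the returned series.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    npad = min(int(round(pad_s / dt)), n - 1)
    nfit = max(min(int(round(fit_s / dt)), n // 2), 3)
    i = np.arange(nfit, dtype=float)
    ph = np.polyfit(i, y[:nfit], 2)
    pt = np.polyfit(np.arange(n - nfit, n, dtype=float), y[-nfit:], 2)
    ye = np.concatenate([np.polyval(ph, np.arange(-npad, 0, dtype=float)),
                         y,
                         np.polyval(pt, np.arange(n, n + npad, dtype=float))])
    th, td, tdd = kalman_theta(ye, dt, q, r_meas)
    sl = slice(npad, npad + n)
    return th[sl], td[sl], tdd[sl]


def solve_theta_series(a_r, a_z, theta_ddot, l_g, g: float = G_DEFAULT,
                       on_unsolvable: str = "raise"):
    """Vectorized tangent-half-angle solution of the balance equation.

    Substituting t = tan(θ/2) turns the balance equation into the quadratic
    ``(l_g·θ̈ − a_r)·t² − 2(a_z+g)·t + (l_g·θ̈ + a_r) = 0``.  Of its two
    roots, the physical branch is the one with |θ| < π/2 (skier upright);
    when θ̈ = 0 it reduces to θ = atan(a_r / (a_z + g)).

    ``on_unsolvable`` controls samples where no upright root exists (which
    happens on data violating the balanced-pendulum model, e.g. transient
    near-free-fall accelerations with a_z + g ≤ 0): ``"raise"`` enforces the
    strict contract, ``"quasistatic"`` substitutes the θ̈ = 0 lean
    atan2(a_r, a_z + g) clipped to the upright range.
    """
    a_r = np.asarray(a_r, dtype=float)
    A = np.asarray(a_z, dtype=float) + g
    tdd = np.asarray(theta_ddot, dtype=float)
    l_g = np.asarray(l_g, dtype=float)
    a = l_g * tdd - a_r
    b = -2.0 * A
    c = l_g * tdd + a_r
    disc = b * b - 4.0 * a * c  # = 4(a_r² + A² − l_g²θ̈²)
    if np.any(disc < 0):
        raise NoSolutionError(
            "negative discriminant: |l_g·θ̈| exceeds sqrt(a_r² + (a_z+g)²); "
            "dampen θ̈ and retry")
    sq = np.sqrt(disc)
    # numerically stable quadratic roots
    qq = -0.5 * (b + np.where(b >= 0, sq, -sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(a != 0, qq / np.where(a != 0, a, 1.0), np.inf)
        t2 = np.where(qq != 0, c / np.where(qq != 0, qq, 1.0), 0.0)
    # linear degenerate case a == 0: single root c / (2A)
    lin = np.abs(a) < 1e-300
    if np.any(lin):
        t_lin = c / (2.0 * A)
        t1 = np.where(lin, t_lin, t1)
        t2 = np.where(lin, t_lin, t2)
    ok1 = np.abs(t1) < 1.0
    ok2 = np.abs(t2) < 1.0
    unsolvable = ~(ok1 | ok2)
    if np.any(unsolvable):
        if on_unsolvable != "quasistatic":
            raise NoSolutionError("no balance solution with |θ| < π/2")
    th1 = 2.0 * np.arctan(np.where(np.isfinite(t1), t1, 1e300))
    th2 = 2.0 * np.arctan(t2)
    # prefer the in-range root; when both qualify take the smaller |θ|
    both = ok1 & ok2
    pick1 = ok1 & (~ok2 | (np.abs(th1) <= np.abs(th2)))
    theta = np.where(pick1, th1, th2)
    if np.any(both):
        # tie-break guard: both roots solve the quadratic exactly, keep min |θ|
        theta = np.where(both & (np.abs(th2) < np.abs(th1)), th2, theta)
    if np.any(unsolvable):
        lim = 0.5 * np.pi - 0.05
        qs = np.clip(np.arctan2(a_r, A), -lim, lim)
        theta = np.where(unsolvable, qs, theta)
    return theta


def solve_theta(a_r: float, a_z: float, theta_ddot: float, l_g: float,
                g: float = G_DEFAULT) -> float:
    """Scalar balance-equation solution (see :func:`solve_theta_series`)."""
    return float(solve_theta_series([a_r], [a_z], [theta_ddot], [l_g], g)[0])


# ---------------------------------------------------------------------------
# Antenna -> COM acceleration transfer
# ---------------------------------------------------------------------------

def _derivs(x: np.ndarray, dt: float):
    d1 = np.gradient(x, dt)
    d2 = np.gradient(d1, dt)
    return d1, d2


def com_accel_from_antenna(a_r_star, a_z_star, theta, l, k, dt=None, *,
                           theta_dot=None, theta_ddot=None,
                           l_dot=None, l_ddot=None):
    """Transfer antenna accelerations to the COM through the pendulum.

    The COM sits a distance (1−k)·l below the antenna along the lean
    direction u(θ) = (sinθ, cosθ) in the lean plane, so

        a_com = a_antenna − (1−k)·d²/dt²(l·u)
              = a_antenna − (1−k)[(l̈ − l·θ̇²)·u + (l·θ̈ + 2·l̇·θ̇)·w],

    with w = (cosθ, −sinθ) the unit vector ahead of u.  The radial term
    (−θ̇²), tangential term (θ̈) and extension/Coriolis terms (l̈, 2·l̇·θ̇)
    are decomposed onto the lean plane's radial and vertical axes.
    Derivatives are computed by central differences when not supplied.
    """
    a_r_star = np.asarray(a_r_star, dtype=float)
    a_z_star = np.asarray(a_z_star, dtype=float)
    theta = np.asarray(theta, dtype=float)
    l = np.asarray(l, dtype=float)
    if not (a_r_star.shape == a_z_star.shape == theta.shape == l.shape):
        raise DataError("series length mismatch in acceleration transfer")
    if theta_dot is None or theta_ddot is None:
        if dt is None:
            raise DataError("dt required when θ derivatives are not supplied")
        theta_dot, tdd = _derivs(theta, dt)
        theta_ddot = tdd if theta_ddot is None else np.asarray(theta_ddot)
    if l_dot is None or l_ddot is None:
        if dt is None:
            raise DataError("dt required when l derivatives are not supplied")
        l_dot, l_ddot = _derivs(l, dt)
    theta_dot = np.asarray(theta_dot, dtype=float)
    theta_ddot = np.asarray(theta_ddot, dtype=float)
    l_dot = np.asarray(l_dot, dtype=float)
    l_ddot = np.asarray(l_ddot, dtype=float)
    s, c = np.sin(theta), np.cos(theta)
    radial = l_ddot - l * theta_dot ** 2
    tangential = l * theta_ddot + 2.0 * l_dot * theta_dot
    a_r = a_r_star - (1.0 - k) * (radial * s + tangential * c)
    a_z = a_z_star - (1.0 - k) * (radial * c - tangential * s)
    return a_r, a_z


# ---------------------------------------------------------------------------
# Fixed-point estimator
# ---------------------------------------------------------------------------

class InvertedPendulumEstimator(BaseEstimator):
    """Fixed-point inverted-pendulum reconstruction from an antenna track.

    Parameters
    ----------
    k : float
        COM height fraction (0.57 female / 0.55 male).
    g : float
        Gravitational acceleration, m/s².
    tol : float
        Convergence tolerance on max|Δθ| between outer iterations, rad.
    max_iter : int
        Outer-iteration cap (typical convergence is 5–10 iterations).
    kalman_q, kalman_r : float
        Jerk spectral density (rad²/s⁵) and angle measurement variance
        (rad²) of the θ smoother.  The defaults put the smoother bandwidth
        (q/r)^{1/6} ≈ 3.2 rad/s just below the pendulum's natural frequency
        √(g/l_g) ≈ 3.5 rad/s: lean modes faster than that cannot be
        balanced and only destabilize the fixed point.
    smooth_window_s : float or None
        Optional Savitzky-Golay (poly 3) pre-smoothing window applied to the
        antenna positions before differentiation.  Leave ``None`` for clean
        reference-grade input; ~1 s is appropriate for RTK GNSS noise.

    The estimator learns nothing from data; ``estimate`` maps an antenna
    trajectory plus slope mesh to COM and ground trajectories.
    """

    def __init__(self, k: float = 0.56, g: float = G_DEFAULT,
                 tol: float = 1e-3, max_iter: int = 20,
                 kalman_q: float = 10.0, kalman_r: float = 1e-2,
                 smooth_window_s: float | None = None,
                 max_lean: float = 1.134):
        self.k = k
        self.g = g
        self.tol = tol
        self.max_iter = max_iter
        self.kalman_q = kalman_q
        self.kalman_r = kalman_r
        self.smooth_window_s = smooth_window_s
        self.max_lean = max_lean

    # -- helpers ----------------------------------------------------------

    def _prepare(self, antenna: Trajectory3D):
        t = antenna.t
        dts = np.diff(t)
        dt = float(np.median(dts))
        if np.max(np.abs(dts - dt)) > 1e-6 * dt:
            raise DataError("estimate_ip requires a uniformly sampled trajectory")
        if antenna.duration < 3.0:
            raise DataError("need at least 3 s of antenna data")
        p = antenna.p
        if self.smooth_window_s:
            win = int(round(self.smooth_window_s / dt)) | 1  # odd
            win = max(win, 5)
            if win >= len(t):
                raise DataError("smoothing window exceeds series length")
            p = savgol_filter(p, win, 3, axis=0)
        return Trajectory3D(t, p, antenna.rate_hz), dt

    def estimate(self, antenna: Trajectory3D, mesh: SlopeMesh) -> IPResult:
        """Run the fixed-point loop; returns pendulum series + diagnostics."""
        params = PendulumParams(k=self.k, g=self.g)
        traj, dt = self._prepare(antenna)
        t, p = traj.t, traj.p

        # (i) antenna accelerations and turn geometry.  Accelerations are
        # differentiated through the band-limited operator: content above
        # the pendulum's natural frequency is not balanceable and only
        # perturbs the fixed point (see skipose.filtering).
        vel = np.gradient(p, dt, axis=0)
        acc = band_limited_deriv2(t, p)
        a_z_star = acc[:, 2]
        vh = vel[:, :2]
        vh_norm = np.linalg.norm(vh, axis=1)
        if np.any(vh_norm < 1e-9):
            raise DataError("antenna must be moving throughout the run")
        # left-of-travel horizontal unit vector: lean plane normal direction
        n_hat = np.column_stack([-vh[:, 1], vh[:, 0]]) / vh_norm[:, None]
        a_r_star = (acc[:, :2] * n_hat).sum(axis=1)
        # differentiation still degrades over the outermost samples; hold
        # them at the nearest interior estimate
        ne = min(4, len(t) // 4)
        for arr in (a_r_star, a_z_star, n_hat):
            arr[:ne] = arr[ne]
            arr[-ne:] = arr[-ne - 1]

        # (ii) first COM-acceleration approximation = antenna accelerations
        a_r, a_z = a_r_star.copy(), a_z_star.copy()
        theta_ddot = np.zeros_like(a_r)
        theta_dot = np.zeros_like(a_r)
        # initial length: vertical drop to the surface
        _, l = ray_intersect_many(
            mesh, p, np.tile([0.0, 0.0, -1.0], (len(t), 1)), max_range=60.0)
        theta = np.zeros_like(a_r)
        l_dot = np.zeros_like(a_r)
        l_ddot = np.zeros_like(a_r)
        residuals: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # (iii) closed-form balance solution, with θ̈ damped into the
            # feasible region if needed (caller-side damping contract)
            l_g = params.k * l
            cap = 0.99 * np.sqrt(a_r ** 2 + (a_z + self.g) ** 2)
            tdd = np.clip(theta_ddot, -cap / np.maximum(l_g, 1e-9),
                          cap / np.maximum(l_g, 1e-9))
            theta_new = solve_theta_series(a_r, a_z, tdd, l_g, self.g,
                                           on_unsolvable="quasistatic")
            # lean beyond ~65° is outside the model's validity and would
            # cast near-horizontal rays that may never meet the slope
            theta_new = np.clip(theta_new, -self.max_lean, self.max_lean)
            delta = float(np.max(np.abs(theta_new - theta)))
            residuals.append(delta)
            theta = theta_new
            # (iv) pendulum length from the lean-ray / mesh intersection
            dirs = np.column_stack([
                -np.sin(theta)[:, None] * n_hat,
                -np.cos(theta),
            ])
            ground, l = ray_intersect_many(mesh, p, dirs, max_range=60.0)
            if delta < self.tol:
                converged = True
                break
            # (v) θ̈ from Kalman smoothing of the angle series; the length
            # series gets the same smoother, since raw double differences of
            # l would feed unphysical extension accelerations into (vi)
            theta_s, theta_dot, theta_ddot = kalman_theta_padded(
                theta, dt, self.kalman_q, self.kalman_r)
            l_s, l_dot, l_ddot = kalman_theta_padded(
                l, dt, self.kalman_q, self.kalman_r)
            # (vi) transfer antenna accelerations to the COM
            a_r, a_z = com_accel_from_antenna(
                a_r_star, a_z_star, theta_s, l_s, params.k,
                theta_dot=theta_dot, theta_ddot=theta_ddot,
                l_dot=l_dot, l_ddot=l_ddot)

        u = np.column_stack([np.sin(theta)[:, None] * n_hat, np.cos(theta)])
        com = ground + (params.k * l)[:, None] * u
        series = PendulumSeries(
            t=t.copy(), theta=theta, theta_dot=theta_dot,
            theta_ddot=theta_ddot, l=l, l_dot=l_dot, l_ddot=l_ddot,
            l_g=params.k * l, a_r_star=a_r_star, a_z_star=a_z_star,
            a_r=a_r, a_z=a_z, com=com, ground=ground)
        return IPResult(series, n_iter, converged, residuals)

    def estimate_pose(self, antenna: Trajectory3D, mesh: SlopeMesh) -> PoseSeries:
        """Convenience: pose series with both 'skis' at the ground point."""
        res = self.estimate(antenna, mesh)
        pend = res.pendulum
        return PoseSeries(pend.t.copy(), antenna.at(pend.t), pend.com.copy(),
                          pend.ground.copy(), pend.ground.copy())


def estimate_ip(antenna: Trajectory3D, mesh: SlopeMesh,
                params: PendulumParams | None = None, **opts) -> IPResult:
    """Functional wrapper over :class:`InvertedPendulumEstimator`."""
    params = params or PendulumParams()
    est = InvertedPendulumEstimator(k=params.k, g=params.g, **opts)
    return est.estimate(antenna, mesh)
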