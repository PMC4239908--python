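"""Model query computation: radial acceleration, speed and skiing angle.

The learned pose models and the inverted-pendulum estimator both consume the
same per-sample description of the antenna motion:

* ``a_r`` — signed radial (centripetal) acceleration in the horizontal plane,
  ``v_h² / r`` with ``r`` the radius of the circle through three adjacent
  horizontally-projected samples.  The sign follows the turn direction:
  positive when the turn center lies to the left of the direction of travel
  (z-component of the horizontal velocity × acceleration cross product), so
  it alternates across linked turns.
* ``v`` — absolute speed ``|dp/dt|``.
* ``alpha`` — skiing angle: the direction of travel expressed in the local
  tangent plane of the slope, measured from the projected site X axis
  (fall-line proxy), in (−π, π].

``r`` (curvature radius) and ``omega = v_h / r`` (angular velocity about the
turn center) are kept as intermediates for the pendulum estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .terrain import SlopeMesh, surface_frame
from .trajio import Trajectory3D

__all__ = ["QuerySeries", "circumradius_3pt", "speed",
           "radial_acceleration", "skiing_angle", "build_query"]


@dataclass
class QuerySeries:
    """Per-sample model inputs (a_r, v, alpha) plus intermediates (r, omega)."""

    t: np.ndarray
    a_r: np.ndarray
    v: np.ndarray
    alpha: np.ndarray
    r: np.ndarray
    omega: np.ndarray
    mean: np.ndarray | None = field(default=None)
    sd: np.ndarray | None = field(default=None)

    def __post_init__(self):
        n = np.asarray(self.t).size
        for name in ("t", "a_r", "v", "alpha", "r", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DataError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.t.size

    def as_matrix(self) -> np.ndarray:
        """The (n, 3) query matrix in model input order (a_r, v, alpha)."""
        return np.column_stack([self.a_r, self.v, self.alpha])

    def standardized(self) -> np.ndarray:
        """Per-feature z-scores; fits and stores mean/sd on first call."""
        x = self.as_matrix()
        if self.mean is None:
            self.mean = x.mean(axis=0)
            self.sd = x.std(axis=0)
            if np.any(self.sd == 0):
                raise DataError("zero-variance query feature; cannot standardize")
        return (x - self.mean) / self.sd

    def destandardize(self, xs) -> np.ndarray:
        if self.mean is None:
            raise DataError("standardization parameters not fitted")
        return np.asarray(xs) * self.sd + self.mean


def circumradius_3pt(p1, p2, p3) -> float:
    """Circumradius of the triangle (p1, p2, p3) in metres.

    ``R = |p1p2|·|p2p3|·|p1p3| / (4·area)``; collinear points give ``+inf``
    (a straight segment), coincident points are rejected.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if min(a, b, c) == 0.0:
        raise DataError("duplicated points have no circumradius")
    cross = np.cross(p2 - p1, p3 - p1)
    area2 = float(np.linalg.norm(cross))  # 2x triangle area
    if area2 < 1e-14 * a * c:
        return float("inf")
    return float(a * b * c / (2.0 * area2))


def _circumradius_series(ph: np.ndarray) -> np.ndarray:
    """Vectorized circumradius through adjacent horizontal samples (interior)."""
    p1, p2, p3 = ph[:-2], ph[1:-1], ph[2:]
    a = np.linalg.norm(p2 - p1, axis=1)
    b = np.linalg.norm(p3 - p2, axis=1)
    c = np.linalg.norm(p3 - p1, axis=1)
    cross = ((p2[:, 0] - p1[:, 0]) * (p3[:, 1] - p1[:, 1])
             - (p2[:, 1] - p1[:, 1]) * (p3[:, 0] - p1[:, 0]))
    area2 = np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[area2 < 1e-14 * np.maximum(a * c, 1e-300)] = np.inf
    return r


def speed(traj: Trajectory3D) -> np.ndarray:
    """Absolute speed |dp/dt| via central differences (one-sided at the ends)."""
    if len(traj) < 3:
        raise DataError("speed needs at least 3 samples")
    v = np.gradient(traj.p, traj.t, axis=0)
    return np.linalg.norm(v, axis=1)


def radial_acceleration(traj: Trajectory3D):
    """Signed radial acceleration, curvature radius and angular velocity.

    Curvature is computed on the horizontal projection of the track (the
    turn geometry lives in the X–Y plane); ``a_r = v_h²/r`` with the sign of
    the z-component of the horizontal velocity × acceleration.  End samples
    copy their interior neighbours.  Straight segments give ``a_r = 0``,
    ``omega = 0`` and ``r = +inf``.
    """
    if len(traj) < 3:
        raise DataError("radial acceleration needs at least 3 samples")
    ph = traj.p[:, :2]
    r = np.empty(len(traj))
    r[1:-1] = _circumradius_series(ph)
    r[0], r[-1] = r[1], r[-2]
    vh = np.gradient(ph, traj.t, axis=0)
    ah = np.gradient(vh, traj.t, axis=0)
    v_h = np.linalg.norm(vh, axis=1)
    sign = np.sign(vh[:, 0] * ah[:, 1] - vh[:, 1] * ah[:, 0])
    with np.errstate(divide="ignore"):
        a_mag = np.where(np.isinf(r), 0.0, v_h ** 2 / r)
        omega = np.where(np.isinf(r), 0.0, v_h / r) * sign
    a_r = sign * a_mag
    return a_r, r, omega


def skiing_angle(traj: Trajectory3D, mesh: SlopeMesh) -> np.ndarray:
    """Direction of travel in the local tangent plane, from the fall-line axis.

    The velocity at each sample is projected onto the tangent plane of the
    slope at the ground point vertically below the antenna;
    ``alpha = atan2(v·ey, v·ex)`` in radians.  Samples with (numerically)
    zero velocity carry the previous angle forward.
    """
    v = np.gradient(traj.p, traj.t, axis=0)
    n, ex, ey = surface_frame(mesh, traj.x, traj.y)
    vt = v - (v * n).sum(axis=1, keepdims=True) * n
    cx = (vt * ex).sum(axis=1)
    cy = (vt * ey).sum(axis=1)
    alpha = np.arctan2(cy, cx)
    still = np.hypot(cx, cy) < 1e-9
    alpha[still] = np.nan
    if np.any(still):
        # forward-fill undefined angles; leading NaNs become 0
        idx = np.where(~np.isnan(alpha), np.arange(alpha.size), -1)
        np.maximum.accumulate(idx, out=idx)
        alpha = np.where(idx >= 0, alpha[np.maximum(idx, 0)], 0.0)
    return alpha


def build_query(traj: Trajectory3D, mesh: SlopeMesh,
                standardize: bool = False) -> QuerySeries:
    """Assemble the (a_r, v, alpha) query series for an antenna trajectory."""
    a_r, r, omega = radial_acceleration(traj)
    v = speed(traj)
    alpha = skiing_angle(traj, mesh)
    q = QuerySeries(traj.t.copy(), a_r, v, alpha, r, omega)
    if standardize:
        q.standardized()  # fit and store mean/sd
    return q
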