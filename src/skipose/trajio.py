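"""Trajectory containers, CSV I/O, spline resampling and squat-based time sync.

All positions live in a fixed right-handed *site frame*: X is the horizontal
projection of the mean downhill (fall-line) direction, Y points across the
slope, Z is up.  Time is in seconds from run start.  The on-disk dialect is
plain UTF-8 CSV with a header, '.' decimal separator, and 9-decimal fixed
formatting so files are bit-stable.

Columns
-------
trajectory CSV : ``t,x,y,z``
pose CSV       : ``t,ax,ay,az,cx,cy,cz,lx,ly,lz,rx,ry,rz``
                 (antenna, center of mass, left ski, right ski)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DataError, FormatError, SyncError

__all__ = [
    "Trajectory3D",
    "PoseSeries",
    "RelativePose9D",
    "TRAJ_COLUMNS",
    "POSE_COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "read_pose",
    "write_pose",
    "upsample_spline",
    "sync_by_squat",
]

log = logging.getLogger(__name__)

TRAJ_COLUMNS = ["t", "x", "y", "z"]
POSE_COLUMNS = ["t", "ax", "ay", "az", "cx", "cy", "cz",
                "lx", "ly", "lz", "rx", "ry", "rz"]

_FLOAT_FMT = "%.9f"


def _as_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise DataError("time vector must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(t)):
        raise DataError("time vector contains non-finite values")
    if np.any(np.diff(t) <= 0):
        raise DataError("time vector must be strictly increasing")
    return t


def _as_points(p, n: int, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n, 3):
        raise DataError(f"{name} must have shape ({n}, 3), got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise DataError(f"{name} contains non-finite coordinates")
    return p


@dataclass
class Trajectory3D:
    """A timestamped 3-D position series (antenna, COM or ski) in the site frame.

    Parameters
    ----------
    t : (n,) array
        Strictly increasing sample times in seconds.
    p : (n, 3) array
        Positions in metres.
    rate_hz : float, optional
        Nominal sampling frequency; inferred from the median time step when
        omitted.
    """

    t: np.ndarray
    p: np.ndarray
    rate_hz: float | None = None

    def __post_init__(self):
        self.t = _as_time(self.t)
        self.p = _as_points(self.p, self.t.size)
        if self.rate_hz is None:
            self.rate_hz = float(1.0 / np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return self.t.size

    @property
    def x(self) -> np.ndarray:
        return self.p[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.p[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.p[:, 2]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def at(self, t_new) -> np.ndarray:
        """Linear interpolation of the positions at new time instants."""
        t_new = np.asarray(t_new, dtype=float)
        return np.column_stack(
            [np.interp(t_new, self.t, self.p[:, i]) for i in range(3)]
        )


@dataclass
class RelativePose9D:
    """COM / left-ski / right-ski offsets from the antenna (the 9-D model output).

    Each offset is ``absolute position − antenna position`` in metres, so
    adding the antenna track back reproduces the absolute pose exactly.
    """

    d_com: np.ndarray
    d_ski_left: np.ndarray
    d_ski_right: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.d_com).shape[0]
        self.d_com = _as_points(self.d_com, n, "d_com")
        self.d_ski_left = _as_points(self.d_ski_left, n, "d_ski_left")
        self.d_ski_right = _as_points(self.d_ski_right, n, "d_ski_right")

    def __len__(self) -> int:
        return self.d_com.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Stack to the (n, 9) target matrix: COM, left ski, right ski."""
        return np.hstack([self.d_com, self.d_ski_left, self.d_ski_right])

    @classmethod
    def from_matrix(cls, m) -> "RelativePose9D":
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[1] != 9:
            raise DataError(f"relative pose matrix must be (n, 9), got {m.shape}")
        return cls(m[:, 0:3], m[:, 3:6], m[:, 6:9])


@dataclass
class PoseSeries:
    """Antenna + COM + both-ski position series on a shared time base."""

    t: np.ndarray
    antenna: np.ndarray
    com: np.ndarray
    ski_left: np.ndarray
    ski_right: np.ndarray
    rate_hz: float | None = field(default=None)

    def __post_init__(self):
        self.t = _as_time(self.t)
        n = self.t.size
        self.antenna = _as_points(self.antenna, n, "antenna")
        self.com = _as_points(self.com, n, "com")
        self.ski_left = _as_points(self.ski_left, n, "ski_left")
        self.ski_right = _as_points(self.ski_right, n, "ski_right")
        if self.rate_hz is None:
            self.rate_hz = float(1.0 / np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def check_upright(self, tol: float = 0.0) -> bool:
        """True when COM sits below the antenna and skis below the COM in Z."""
        return bool(
            np.all(self.com[:, 2] <= self.antenna[:, 2] + tol)
            and np.all(self.ski_left[:, 2] <= self.com[:, 2] + tol)
            and np.all(self.ski_right[:, 2] <= self.com[:, 2] + tol)
        )

    def antenna_trajectory(self) -> Trajectory3D:
        return Trajectory3D(self.t.copy(), self.antenna.copy(), self.rate_hz)

    def mid_ski(self) -> np.ndarray:
        return 0.5 * (self.ski_left + self.ski_right)

    def to_relative(self) -> RelativePose9D:
        return RelativePose9D(
            self.com - self.antenna,
            self.ski_left - self.antenna,
            self.ski_right - self.antenna,
        )

    @classmethod
    def from_relative(cls, antenna: Trajectory3D, rel: RelativePose9D) -> "PoseSeries":
        if len(antenna) != len(rel):
            raise DataError("antenna and relative pose lengths differ")
        a = antenna.p
        return cls(antenna.t.copy(), a.copy(), a + rel.d_com,
                   a + rel.d_ski_left, a + rel.d_ski_right, antenna.rate_hz)

    def at(self, t_new) -> "PoseSeries":
        """Linearly resample every series onto a new time base."""
        t_new = np.asarray(t_new, dtype=float)

        def interp(arr):
            return np.column_stack(
                [np.interp(t_new, self.t, arr[:, i]) for i in range(3)]
            )

        return PoseSeries(t_new, interp(self.antenna), interp(self.com),
                          interp(self.ski_left), interp(self.ski_right))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path, columns):
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df[columns].apply(pd.to_numeric, errors="coerce")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        log.info("%s: dropped %d rows with NaN values", path, n_bad)
        df = df.dropna()
    if len(df) < 3:
        raise DataError(f"{path}: fewer than 3 valid rows")
    return df


def read_trajectory(path) -> Trajectory3D:
    """Read a ``t,x,y,z`` CSV file into a validated :class:`Trajectory3D`."""
    df = _read_csv(path, TRAJ_COLUMNS)
    return Trajectory3D(df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy())


def write_trajectory(traj: Trajectory3D, path) -> None:
    """Write a trajectory as CSV (columns ``t,x,y,z``, 9-decimal fixed)."""
    df = pd.DataFrame(np.column_stack([traj.t, traj.p]), columns=TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pose(path) -> PoseSeries:
    """Read a 13-column pose CSV into a :class:`PoseSeries`."""
    df = _read_csv(path, POSE_COLUMNS)
    pose = PoseSeries(
        df["t"].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        df[["cx", "cy", "cz"]].to_numpy(),
        df[["lx", "ly", "lz"]].to_numpy(),
        df[["rx", "ry", "rz"]].to_numpy(),
    )
    if not pose.check_upright(tol=1e-9):
        log.warning("%s: pose violates the vertical antenna>COM>ski ordering", path)
    return pose


def write_pose(pose: PoseSeries, path) -> None:
    data = np.column_stack([pose.t, pose.antenna, pose.com,
                            pose.ski_left, pose.ski_right])
    pd.DataFrame(data, columns=POSE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Resampling and synchronization
# ---------------------------------------------------------------------------

def upsample_spline(traj: Trajectory3D, target_hz: float) -> Trajectory3D:
    """Cubic-spline upsampling of a trajectory to a higher uniform rate.

    A not-a-knot cubic spline is fitted per coordinate and evaluated on a
    uniform grid at ``target_hz`` spanning ``[t0, tN]``; as an interpolant it
    reproduces the original values at the original sample instants.
    """
    if len(traj) < 4:
        raise DataError("cubic spline upsampling needs at least 4 samples")
    if traj.rate_hz is not None and target_hz <= traj.rate_hz:
        raise DataError(
            f"target rate {target_hz} Hz must exceed source rate {traj.rate_hz} Hz")
    t0, t1 = traj.t[0], traj.t[-1]
    n_new = int(np.floor((t1 - t0) * target_hz + 1e-9)) + 1
    t_new = t0 + np.arange(n_new) / target_hz
    spl = CubicSpline(traj.t, traj.p, axis=0)  # not-a-knot boundary
    return Trajectory3D(t_new, spl(t_new), rate_hz=float(target_hz))


def _squat_crossing(t: np.ndarray, vz: np.ndarray) -> float:
    """Time of the upward zero-crossing of vz nearest the lowest squat point."""
    t = np.asarray(t, dtype=float)
    vz = np.asarray(vz, dtype=float)
    if t.size != vz.size or t.size < 3:
        raise DataError("time and velocity series must match and have >= 3 samples")
    # Height relative to start: the squat bottom is the global minimum of the
    # integrated vertical velocity.
    z = np.concatenate([[0.0], np.cumsum(0.5 * (vz[1:] + vz[:-1]) * np.diff(t))])
    i_min = int(np.argmin(z))
    up = np.nonzero((vz[:-1] <= 0) & (vz[1:] > 0))[0]
    if up.size == 0:
        raise SyncError("no upward zero-crossing of vertical velocity found")
    # linear sub-sample interpolation of each crossing instant
    denom = vz[up + 1] - vz[up]
    frac = np.where(denom != 0, -vz[up] / denom, 0.0)
    t_cross = t[up] + frac * (t[up + 1] - t[up])
    return float(t_cross[np.argmin(np.abs(t_cross - t[i_min]))])


def sync_by_squat(t_a, vz_a, t_b, vz_b) -> float:
    """Time offset between two recordings of the same synchronization squat.

    Both systems record the isolated explosive squat performed before the run;
    the landmark is the upward zero-crossing of vertical velocity nearest each
    series' lowest point.  Returns ``t_a(landmark) − t_b(landmark)`` in
    seconds, i.e. the amount by which series *a* lags series *b*.
    """
    return _squat_crossing(t_a, vz_a) - _squat_crossing(t_b, vz_b)
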