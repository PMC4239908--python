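"""Evaluation protocol: path-normalized error curves, cross-validation
tables and the paired t-test comparison of pose models.

Errors are 3-D Euclidean distances between estimated and reference points.
To aggregate across runs of different lengths, each run is re-expressed as a
function of the path fraction s ∈ [0, 1] (0 = start, 1 = finish) defined by
cumulative horizontal arc length (a duration-based grid is available via
``by='duration'``; the two coincide at constant speed), then averaged
pointwise across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .features import build_query
from .ip import IPResult, InvertedPendulumEstimator
from .lwpr import LWPRRegressor, predict_pose
from .mlp import BackpropMLP
from .trajio import PoseSeries

__all__ = ["ErrorCurve", "CrossValTable", "path_normalize", "pose_error",
           "ip_ground_error", "aggregate_runs", "cross_validate",
           "paired_t_test", "TTestResult"]


@dataclass
class ErrorCurve:
    """Mean ± SD error as a function of the path fraction s."""

    s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_run: np.ndarray  # (n_runs, n_points)


@dataclass
class CrossValTable:
    """Run-by-model error grid mirroring the field-study cross-validation.

    Rows are (skier, run) pairs; columns are the skiers whose runs trained
    each model; each cell holds the mean (and SD) over all samples of the
    run of the per-sample error.
    """

    rows: list          # [(skier, run), ...]
    cols: list          # [skier, ...]
    mean: np.ndarray    # (n_rows, n_cols)
    sd: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.rows, names=["skier", "run"])
        cells = np.vectorize(lambda m, s: f"{m:.3f} ({s:.3f})")(self.mean, self.sd)
        df = pd.DataFrame(cells, index=idx, columns=self.cols)
        for j, c in enumerate(self.cols):
            df[f"{c}_mean"] = self.mean[:, j]
            df[f"{c}_sd"] = self.sd[:, j]
        return df

    def diagonal_mask(self) -> np.ndarray:
        """True where the model was trained on the run's own skier."""
        row_skiers = np.array([r[0] for r in self.rows])
        return row_skiers[:, None] == np.asarray(self.cols)[None, :]

    def offdiagonal_values(self) -> np.ndarray:
        """Off-diagonal cell means in row-major order (the t-test cases)."""
        return self.mean[~self.diagonal_mask()]

    def diagonal_is_row_minimum(self) -> np.ndarray:
        """Per-row flag: is the own-skier model the best for that run?"""
        diag = self.diagonal_mask()
        out = np.empty(len(self.rows), dtype=bool)
        for i in range(len(self.rows)):
            out[i] = self.mean[i, diag[i]].min() <= self.mean[i].min() + 1e-12
        return out


# ---------------------------------------------------------------------------
# Path normalization and error series
# ---------------------------------------------------------------------------

def path_normalize(values, positions=None, t=None, n_points: int = 200,
                   by: str = "arclength"):
    """Resample a per-sample series onto a uniform path-fraction grid.

    ``by='arclength'`` (default) defines s as cumulative horizontal arc
    length of ``positions`` divided by the total; ``by='duration'`` uses
    elapsed time from ``t``.  Linear interpolation onto ``n_points`` equally
    spaced s values; returns ``(s_grid, resampled values)``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise DataError("need at least 3 samples to normalize")
    if by == "arclength":
        if positions is None:
            raise DataError("positions required for arc-length normalization")
        ph = np.asarray(positions, dtype=float)[:, :2]
        seg = np.linalg.norm(np.diff(ph, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
    elif by == "duration":
        if t is None:
            raise DataError("t required for duration normalization")
        cum = np.asarray(t, dtype=float) - t[0]
    else:
        raise DataError("by must be 'arclength' or 'duration'")
    total = cum[-1]
    if total <= 0:
        raise DataError("zero total path length/duration")
    s = cum / total
    s_grid = np.linspace(0.0, 1.0, n_points)
    # s may contain repeats (stationary samples); np.interp handles plateaus
    return s_grid, np.interp(s_grid, s, values)


def pose_error(est: PoseSeries, ref: PoseSeries) -> dict:
    """Per-sample Euclidean errors for COM and both skis.

    Both series must share a time base (resample with ``PoseSeries.at``
    first).  ``ski_mean`` is the average of the left and right ski errors.
    """
    if len(est) != len(ref) or np.max(np.abs(est.t - ref.t)) > 1e-9:
        raise DataError("pose series must share a time base; resample first")
    com = np.linalg.norm(est.com - ref.com, axis=1)
    left = np.linalg.norm(est.ski_left - ref.ski_left, axis=1)
    right = np.linalg.norm(est.ski_right - ref.ski_right, axis=1)
    return {"com": com, "ski_left": left, "ski_right": right,
            "ski_mean": 0.5 * (left + right)}


def ip_ground_error(ip: IPResult, ref: PoseSeries) -> dict:
    """Errors of the pendulum estimate against the reference pose.

    The pendulum's single ground point is compared against the mid-point of
    the two reference skis (equal weight on both skis); the COM is compared
    directly.
    """
    pend = ip.pendulum
    ref_i = ref.at(pend.t)
    com = np.linalg.norm(pend.com - ref_i.com, axis=1)
    ground = np.linalg.norm(pend.ground - ref_i.mid_ski(), axis=1)
    return {"com": com, "ground_vs_midski": ground}


def aggregate_runs(errors, positions=None, ts=None, n_points: int = 200,
                   by: str = "arclength") -> ErrorCurve:
    """Path-normalize each run's error series, then average across runs."""
    if len(errors) < 1:
        raise DataError("need at least one run")
    per_run = []
    for i, e in enumerate(errors):
        pos = positions[i] if positions is not None else None
        t = ts[i] if ts is not None else None
        s_grid, v = path_normalize(e, pos, t, n_points, by)
        per_run.append(v)
    per_run = np.asarray(per_run)
    return ErrorCurve(s_grid, per_run.mean(axis=0), per_run.std(axis=0), per_run)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _make_model(method: str, seed: int | None, model_kwargs: dict | None):
    kwargs = dict(model_kwargs or {})
    if method == "lwpr":
        return LWPRRegressor(seed=seed, **kwargs)
    if method in ("nn", "mlp"):
        return BackpropMLP(seed=0 if seed is None else seed, **kwargs)
    raise DataError(f"unknown method {method!r}; use 'lwpr' or 'nn'")


def cross_validate(records, mesh, method: str = "lwpr", seed: int | None = 0,
                   model_kwargs: dict | None = None):
    """Train one pose model per skier and score it on every run.

    ``records`` is a list of dicts with keys ``skier``, ``run`` and ``pose``
    (as produced by ``simulate.make_cohort``).  Each skier's model is
    trained on all of that skier's runs; every model is then evaluated on
    every run.  Returns ``(com_table, ski_table)`` with cells the mean (SD)
    over samples of the per-sample COM / mean-ski errors in metres.
    """
    skiers = sorted({r["skier"] for r in records})
    if len(skiers) < 1 or len(records) < 2:
        raise DataError("need at least one skier with at least two runs")
    # precompute per-run queries and targets
    prepared = []
    for rec in records:
        pose = rec["pose"]
        antenna = pose.antenna_trajectory()
        q = build_query(antenna, mesh)
        prepared.append({**rec, "antenna": antenna, "query": q,
                         "targets": pose.to_relative()})
    models = {}
    for sk in skiers:
        own = [p for p in prepared if p["skier"] == sk]
        X = np.vstack([p["query"].as_matrix() for p in own])
        Y = np.vstack([p["targets"].as_matrix() for p in own])
        models[sk] = _make_model(method, seed, model_kwargs).fit(X, Y)
    rows = [(p["skier"], p["run"]) for p in prepared]
    shape = (len(rows), len(skiers))
    com_mean = np.empty(shape); com_sd = np.empty(shape)
    ski_mean = np.empty(shape); ski_sd = np.empty(shape)
    for i, p in enumerate(prepared):
        for j, sk in enumerate(skiers):
            est = predict_pose(models[sk], p["query"], p["antenna"])
            err = pose_error(est, p["pose"])
            com_mean[i, j] = err["com"].mean()
            com_sd[i, j] = err["com"].std()
            ski_mean[i, j] = err["ski_mean"].mean()
            ski_sd[i, j] = err["ski_mean"].std()
    return (CrossValTable(rows, skiers, com_mean, com_sd),
            CrossValTable(rows, skiers, ski_mean, ski_sd))


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def paired_t_test(errors_a, errors_b) -> TTestResult:
    """Two-sided paired-samples t-test on per-case mean errors.

    ``t = mean(d) / (sd(d)/√n)`` with d the paired differences, df = n − 1,
    sd the n−1 sample standard deviation.  Degenerate conventions: all pairs
    equal → t = 0, p = 1; zero-variance differences with nonzero mean →
    p = 0 (infinite t).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DataError("paired samples must be equal-length 1-D arrays, n >= 2")
    d = a - b
    n = d.size
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if md == 0 else float(np.sign(md)) * np.inf
        p = 1.0 if md == 0 else 0.0
    else:
        t_stat = md / (sd / np.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), n - 1))
    return TTestResult(float(t_stat), n - 1, float(p),
                       float(a.mean()), float(a.std(ddof=1)),
                       float(b.mean()), float(b.std(ddof=1)))
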