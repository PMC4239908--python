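"""Locally weighted regression with Gaussian receptive fields.

A deliberately compact locally-weighted-learning variant for the 3-D pose
query: each receptive field k carries a center c_k, a shared fixed positive
semi-definite distance metric D, and a local linear map fitted by weighted
(ridge-regularised) least squares on the centred inputs.  The activation of a
field is

    w_k(x) = exp(−½ (x − c_k)ᵀ D (x − c_k)),

and the prediction is the activation-weighted convex combination of the local
linear models.  Fields are created on the fly during a single deterministic
pass over the training data (temporal order) whenever no existing field
activates above ``w_gen``.  The metric D is *not* adapted online: larger
diagonal values shrink the region of validity and therefore increase the
number of local models.  Inputs and outputs are z-scored internally so that
D has a consistent meaning across runs; the default D = 10·I in
standardized units corresponds to roughly 0.1·I on the raw query scales
(radial acceleration in m/s², speed in m/s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError
from .features import QuerySeries
from .trajio import PoseSeries, RelativePose9D, Trajectory3D

__all__ = ["ReceptiveField", "LWPRRegressor", "lwpr_fit", "lwpr_predict",
           "predict_pose"]


@dataclass
class ReceptiveField:
    """One Gaussian receptive field with its local linear model."""

    c: np.ndarray                       # center, standardized query space
    D: np.ndarray                       # distance metric (PSD)
    # weighted sufficient statistics of the local regression
    W: float = 0.0
    Sx: np.ndarray = None
    Sxx: np.ndarray = None
    Sy: np.ndarray = None
    Sxy: np.ndarray = None
    beta: np.ndarray = None             # (d, m) local slope
    intercept: np.ndarray = None        # (m,)

    def activation(self, X: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(X) - self.c
        return np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, self.D, d))

    def accumulate(self, X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> None:
        d = X - self.c
        self.W += float(w.sum())
        self.Sx += w @ d
        self.Sxx += (d * w[:, None]).T @ d
        self.Sy += w @ Y
        self.Sxy += (d * w[:, None]).T @ Y

    def solve(self, ridge: float) -> None:
        """Weighted ridge regression on the centred inputs."""
        ddim = self.c.size
        xm = self.Sx / self.W
        ym = self.Sy / self.W
        cov = self.Sxx / self.W - np.outer(xm, xm)
        cxy = self.Sxy / self.W - np.outer(xm, ym)
        self.beta = np.linalg.solve(cov + ridge * np.eye(ddim), cxy)
        self.intercept = ym - self.beta.T @ xm

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + (np.atleast_2d(X) - self.c) @ self.beta


class LWPRRegressor(RegressorMixin, BaseEstimator):
    """Locally weighted pose regression (fixed metric, ridge local models).

    Parameters
    ----------
    D : float or (d, d) array, default 10.0
        Distance metric in *standardized* query units; a scalar means
        ``D·I``.  Must be symmetric PSD.  Raw query features have scales of
        order 10 (radial acceleration in m/s², speed in m/s), so the default
        corresponds to ~0.1·I in raw units; larger diagonals shrink each
        field's region of validity and increase the local-model count.
    w_gen : float, default 0.2
        Field-creation threshold: a training point seeing no activation
        above ``w_gen`` spawns a new field at its location.
    w_cutoff : float, default 1e-4
        Activation below which a field neither trains on nor contributes to
        a point.
    ridge : float, default 1e-9
        Ridge regularisation of each local regression; a numerical guard
        only (larger values visibly bias the local slopes).
    standardize : bool, default True
        Z-score inputs and outputs internally.
    seed : int, optional
        Unused by the deterministic temporal-order pass; kept so the model
        composes with seeded experiment harnesses.
    """

    def __init__(self, D=10.0, w_gen: float = 0.2, w_cutoff: float = 1e-4,
                 ridge: float = 1e-9, standardize: bool = True,
                 seed: int | None = None):
        self.D = D
        self.w_gen = w_gen
        self.w_cutoff = w_cutoff
        self.ridge = ridge
        self.standardize = standardize
        self.seed = seed

    # -- internals --------------------------------------------------------

    def _metric(self, ddim: int) -> np.ndarray:
        D = np.asarray(self.D, dtype=float)
        if D.ndim == 0:
            D = float(D) * np.eye(ddim)
        if D.shape != (ddim, ddim) or not np.allclose(D, D.T):
            raise DataError("D must be a scalar or a symmetric (d, d) matrix")
        if np.any(np.linalg.eigvalsh(D) < -1e-12):
            raise DataError("D must be positive semi-definite")
        return D

    def _standardize_fit(self, X, Y):
        if self.standardize:
            self.x_mean_, self.x_scale_ = X.mean(0), X.std(0)
            self.y_mean_, self.y_scale_ = Y.mean(0), Y.std(0)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1])
            self.y_scale_ = np.ones(Y.shape[1])
        if np.any(self.x_scale_ == 0):
            raise DataError(
                "zero-variance input feature; standardize or drop the feature")
        self.y_scale_ = np.where(self.y_scale_ == 0, 1.0, self.y_scale_)
        return ((X - self.x_mean_) / self.x_scale_,
                (Y - self.y_mean_) / self.y_scale_)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or len(X) != len(Y):
            raise DataError("X must be (n, d) and aligned with y")
        if len(X) < 10:
            raise DataError("need at least 10 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise DataError("training data contain non-finite values")
        Xs, Ys = self._standardize_fit(X, Y)
        ddim, m = X.shape[1], Y.shape[1]
        D = self._metric(ddim)
        # single deterministic creation pass in temporal (row) order: a
        # point seeing no activation above w_gen spawns a field there
        centers = np.empty((0, ddim))
        for i in range(len(Xs)):
            x = Xs[i]
            if centers.shape[0]:
                d = centers - x
                w_max = np.exp(
                    -0.5 * np.einsum("ni,ij,nj->n", d, D, d)).max()
            else:
                w_max = 0.0
            if w_max < self.w_gen:
                centers = np.vstack([centers, x])
        # each local regression then accumulates the complete training set
        # (sufficient statistics make this identical to running the weighted
        # recursive least-squares update over every point)
        fields: list[ReceptiveField] = []
        for c in centers:
            rf = ReceptiveField(
                c=c.copy(), D=D, W=0.0, Sx=np.zeros(ddim),
                Sxx=np.zeros((ddim, ddim)), Sy=np.zeros(m),
                Sxy=np.zeros((ddim, m)))
            w = rf.activation(Xs)
            active = w > self.w_cutoff
            rf.accumulate(Xs[active], Ys[active], w[active])
            rf.solve(self.ridge)
            fields.append(rf)
        self.fields_ = fields
        self.centers_ = centers
        self.n_fields_ = len(fields)
        self.n_features_in_ = ddim
        self.n_outputs_ = m
        return self

    def predict(self, X, return_extrapolation=False):
        """Activation-weighted blend of the local linear models.

        Points activating no field above ``w_cutoff`` fall back to the
        nearest field alone and are flagged as extrapolation when
        ``return_extrapolation`` is set.
        """
        check_is_fitted(self, "fields_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean_) / self.x_scale_
        n = len(Xs)
        W = np.empty((self.n_fields_, n))
        preds = np.empty((self.n_fields_, n, self.n_outputs_))
        for j, rf in enumerate(self.fields_):
            W[j] = rf.activation(Xs)
            preds[j] = rf.predict(Xs)
        active = W > self.w_cutoff
        extrapolated = ~active.any(axis=0)
        Wa = np.where(active, W, 0.0)
        if np.any(extrapolated):
            # nearest field alone; its activation may underflow to zero far
            # from the data, so give it unit blending weight
            nearest = W[:, extrapolated].argmax(axis=0)
            Wa[nearest, np.nonzero(extrapolated)[0]] = 1.0
        Ys = (Wa[:, :, None] * preds).sum(axis=0) / Wa.sum(axis=0)[:, None]
        Y = Ys * self.y_scale_ + self.y_mean_
        if return_extrapolation:
            return Y, extrapolated
        return Y

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "fields_")
        return {
            "model": "lwpr",
            "params": {"D": np.asarray(self.D).tolist(), "w_gen": self.w_gen,
                       "w_cutoff": self.w_cutoff, "ridge": self.ridge,
                       "standardize": self.standardize},
            "x_mean": self.x_mean_.tolist(), "x_scale": self.x_scale_.tolist(),
            "y_mean": self.y_mean_.tolist(), "y_scale": self.y_scale_.tolist(),
            "fields": [{"c": rf.c.tolist(), "D": rf.D.tolist(),
                        "beta": rf.beta.tolist(),
                        "intercept": rf.intercept.tolist()}
                       for rf in self.fields_],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LWPRRegressor":
        p = doc["params"]
        D = np.asarray(p["D"])
        model = cls(D=float(D) if D.ndim == 0 else D, w_gen=p["w_gen"],
                    w_cutoff=p["w_cutoff"], ridge=p["ridge"],
                    standardize=p["standardize"])
        model.x_mean_ = np.asarray(doc["x_mean"])
        model.x_scale_ = np.asarray(doc["x_scale"])
        model.y_mean_ = np.asarray(doc["y_mean"])
        model.y_scale_ = np.asarray(doc["y_scale"])
        model.fields_ = [
            ReceptiveField(c=np.asarray(f["c"]), D=np.asarray(f["D"]),
                           beta=np.asarray(f["beta"]),
                           intercept=np.asarray(f["intercept"]))
            for f in doc["fields"]]
        model.centers_ = np.array([rf.c for rf in model.fields_])
        model.n_fields_ = len(model.fields_)
        model.n_features_in_ = model.x_mean_.size
        model.n_outputs_ = model.y_mean_.size
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "LWPRRegressor":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Functional module surface
# ---------------------------------------------------------------------------

def lwpr_fit(queries: QuerySeries, targets: RelativePose9D,
             D_default=10.0, w_gen: float = 0.2,
             seed: int | None = None, **kwargs) -> LWPRRegressor:
    """Train a locally weighted pose model on one or more runs' data."""
    model = LWPRRegressor(D=D_default, w_gen=w_gen, seed=seed, **kwargs)
    return model.fit(queries.as_matrix(), targets.as_matrix())


def lwpr_predict(model: LWPRRegressor, x) -> np.ndarray:
    """Predict the 9-D relative pose for a single query 3-vector."""
    return model.predict(np.atleast_2d(x))[0]


def predict_pose(model, queries: QuerySeries,
                 antenna: Trajectory3D) -> PoseSeries:
    """Absolute pose reconstruction: antenna track + predicted offsets.

    Works for any fitted regressor mapping the (n, 3) query matrix to the
    (n, 9) relative pose (LWPR or the backprop network).
    """
    if len(queries) != len(antenna):
        raise DataError("queries and antenna trajectory must be aligned")
    rel = RelativePose9D.from_matrix(model.predict(queries.as_matrix()))
    return PoseSeries.from_relative(antenna, rel)
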