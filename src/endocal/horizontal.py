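"""Pixel-to-mm conversion models for horizontal (in-plane) measurement.

Two models map image measurements into scene millimetres:

* the *non-uniform* model, a bivariate polynomial surface
  ``r_mm = F_{M,N}(w, r_p) = sum_{k=1..M} sum_{l=1..N} a_{l,k} w^k r_p^l``
  capturing both the working-distance and spatial-location dependence of
  pixel size (no intercept and no pure-w / pure-r_p terms, so F(w, 0) = 0
  identically);
* the *uniform* model, a single pixel size ``gamma(w) = gamma0 + gamma1 w``
  (mm/px) applied everywhere in the image -- the parallel-laser-style
  baseline.

Model orders (M, N) are selected by 10-fold cross-validation grouped by
recording, scoring mean absolute error over all held-out circles.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "NonUniformRadialModel",
    "UniformPixelSizeModel",
    "build_calib_samples",
    "assign_folds",
    "cross_val_errors",
    "select_model",
    "fit_nonuniform",
    "fit_uniform",
    "predict_rmm",
    "predict_gamma",
    "model_to_json",
    "model_from_json",
]

SAMPLE_COLUMNS = ["recording_id", "w_mm", "r_px", "r_mm"]


class NonUniformRadialModel(BaseEstimator, RegressorMixin):
    """Polynomial surface F_{M,N}(w, r_p) -> r_mm.

    Inputs are scaled (``w / w_scale``, ``r_p / r_scale``) before building
    the monomial basis, purely for numerical conditioning; coefficients are
    stored in scaled space and applied transparently.  ``X`` columns are
    ``(w_mm, r_px)``.
    """

    def __init__(self, M: int = 5, N: int = 5,
                 w_scale: float | None = None, r_scale: float | None = None):
        self.M = M
        self.N = N
        self.w_scale = w_scale
        self.r_scale = r_scale

    def _design(self, w, r):
        wt = np.asarray(w, dtype=float) / self.w_scale_
        rt = np.asarray(r, dtype=float) / self.r_scale_
        cols = [
            wt**k * rt**l for k in range(1, self.M + 1) for l in range(1, self.N + 1)
        ]
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (w_mm, r_px)")
        if len(X) < self.M * self.N:
            raise ValueError(
                f"need at least M*N={self.M * self.N} samples, got {len(X)}"
            )
        self.w_scale_ = self.w_scale or float(np.max(np.abs(X[:, 0]))) or 1.0
        self.r_scale_ = self.r_scale or float(np.max(np.abs(X[:, 1]))) or 1.0
        A = self._design(X[:, 0], X[:, 1])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            raise ValueError(
                f"rank-deficient design for degrees M={self.M}, N={self.N}"
            )
        self.coef_ = coef
        self.domain_ = {
            "w_min": float(X[:, 0].min()),
            "w_max": float(X[:, 0].max()),
            "r_p_max": float(X[:, 1].max()),
        }
        self.n_features_in_ = 2
        return self

    def _check_domain(self, w, r):
        d = self.domain_
        span = d["w_max"] - d["w_min"]
        low = d["w_min"] - 0.1 * span
        high = d["w_max"] + 0.1 * span
        if np.any(np.asarray(w) < low) or np.any(np.asarray(w) > high) or np.any(
            np.asarray(r) > 1.1 * d["r_p_max"]
        ):
            warnings.warn(
                "prediction more than 10% outside the training domain", stacklevel=3
            )

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("working distance and pixel radius must be non-negative")
        w, r = X[:, 0], X[:, 1]
        self._check_domain(w, r)
        return self._design(w, r) @ self.coef_

    def predict_one(self, w: float, r_px: float) -> float:
        return float(self.predict(np.array([[w, r_px]]))[0])


class UniformPixelSizeModel(BaseEstimator, RegressorMixin):
    """Single pixel size gamma(w) = intercept + slope * w (mm/px)."""

    def fit(self, X, y):
        w = np.asarray(X, dtype=float).reshape(-1)
        g = np.asarray(y, dtype=float)
        if len(w) < 2:
            raise ValueError("need at least two recordings to fit gamma(w)")
        slope, intercept = np.polyfit(w, g, 1)
        self.intercept_ = float(intercept)
        self.slope_ = float(slope)
        self.domain_ = {"w_min": float(w.min()), "w_max": float(w.max())}
        if self.predict(np.array([w.min(), w.max()])).min() <= 0:
            warnings.warn("gamma(w) is not positive over the training domain",
                          stacklevel=2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        w = np.asarray(X, dtype=float).reshape(-1)
        d = self.domain_
        span = d["w_max"] - d["w_min"]
        if np.any(w < d["w_min"] - 0.1 * span) or np.any(w > d["w_max"] + 0.1 * span):
            warnings.warn(
                "prediction more than 10% outside the training domain", stacklevel=2
            )
        return self.intercept_ + self.slope_ * w

    def predict_one(self, w: float) -> float:
        return float(self.predict(np.array([w]))[0])


# ---------------------------------------------------------------------------
# Calibration samples
# ---------------------------------------------------------------------------

def build_calib_samples(detections_per_recording) -> pd.DataFrame:
    """Assemble (recording_id, w_mm, r_px, r_mm) calibration samples.

    ``detections_per_recording`` is an iterable of
    ``(recording_id, w_mm, spacing_mm, radii_px)`` with radii of the
    detected circles; ring index (1-based, by increasing radius) times the
    grid spacing gives the mm radius.
    """
    rows = []
    for rec_id, w, spacing, radii in detections_per_recording:
        radii = sorted(float(r) for r in radii)
        if not radii:
            raise ValueError(f"recording {rec_id!r} has no detected circles")
        for k, r_px in enumerate(radii, start=1):
            rows.append((rec_id, float(w), r_px, k * float(spacing)))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def assign_folds(samples: pd.DataFrame, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold label per sample, grouped by recording_id."""
    ids = np.asarray(sorted(samples["recording_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    fold_of = {rid: i % folds for i, rid in enumerate(ids)}
    return samples["recording_id"].map(fold_of).to_numpy()


def cross_val_errors(
    samples: pd.DataFrame,
    model_factory,
    folds: int = 10,
    seed: int = 0,
    largest_only_train: bool = False,
    eval_train_smaller: bool = False,
) -> pd.DataFrame:
    """Held-out predictions of a radial model under recording-grouped CV.

    ``model_factory()`` returns an unfitted estimator.  With
    ``largest_only_train`` the model is trained on the largest circle of
    each training recording (the uniform-model protocol, where the target
    is gamma = r_mm / r_px); predictions are always evaluated on every
    held-out circle.  ``eval_train_smaller`` additionally evaluates each
    fold's model on the training recordings' smaller circles (which the
    gamma fit never saw) -- the uniform-model evaluation protocol of the
    benchtop study.
    """
    if eval_train_smaller and not largest_only_train:
        raise ValueError("eval_train_smaller only applies to the uniform protocol")
    fold = assign_folds(samples, folds=folds, seed=seed)
    out = []
    for f in range(folds):
        train = samples[fold != f]
        test = samples[fold == f]
        if train.empty:
            raise ValueError(f"fold {f} has an empty training set")
        if test.empty:
            continue
        model = model_factory()
        if largest_only_train:
            largest_idx = train.groupby("recording_id")["r_px"].idxmax()
            largest = train.loc[largest_idx]
            gamma = largest["r_mm"] / largest["r_px"]
            model.fit(largest[["w_mm"]].to_numpy(), gamma.to_numpy())
            if eval_train_smaller:
                test = pd.concat([test, train.drop(largest_idx)])
            pred = model.predict(test["w_mm"].to_numpy()) * test["r_px"].to_numpy()
        else:
            model.fit(train[["w_mm", "r_px"]].to_numpy(), train["r_mm"].to_numpy())
            pred = model.predict(test[["w_mm", "r_px"]].to_numpy())
        chunk = test.copy()
        chunk["fold"] = f
        chunk["pred_mm"] = pred
        chunk["error_mm"] = pred - test["r_mm"].to_numpy()
        out.append(chunk)
    return pd.concat(out, ignore_index=True)


def select_model(
    samples: pd.DataFrame,
    M_range=range(1, 9),
    N_range=range(1, 9),
    folds: int = 10,
    seed: int = 0,
):
    """Cross-validated (M, N) selection by mean absolute error.

    Returns ``(M_star, N_star, table)`` where ``table`` is a DataFrame of
    CV MAE per degree pair (NaN where the fit was infeasible).
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for M in M_range:
            for N in N_range:
                try:
                    cv = cross_val_errors(
                        samples,
                        lambda M=M, N=N: NonUniformRadialModel(M=M, N=N),
                        folds=folds,
                        seed=seed,
                    )
                    mae = float(cv["error_mm"].abs().mean())
                except (ValueError, np.linalg.LinAlgError):
                    mae = np.nan
                rows.append({"M": M, "N": N, "cv_mae_mm": mae})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["cv_mae_mm"])
    if valid.empty:
        raise ValueError("no feasible model in the searched ranges")
    best = valid.sort_values(["cv_mae_mm", "M", "N"]).iloc[0]
    return int(best["M"]), int(best["N"]), table


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_nonuniform(samples: pd.DataFrame, M: int, N: int) -> NonUniformRadialModel:
    model = NonUniformRadialModel(M=M, N=N)
    return model.fit(samples[["w_mm", "r_px"]].to_numpy(), samples["r_mm"].to_numpy())


def fit_uniform(samples: pd.DataFrame) -> UniformPixelSizeModel:
    """Fit gamma(w) on the largest circle of each recording."""
    largest = samples.loc[samples.groupby("recording_id")["r_px"].idxmax()]
    gamma = largest["r_mm"] / largest["r_px"]
    model = UniformPixelSizeModel()
    return model.fit(largest[["w_mm"]].to_numpy(), gamma.to_numpy())


def predict_rmm(model: NonUniformRadialModel, w: float, r_px: float) -> float:
    return model.predict_one(w, r_px)


def predict_gamma(model: UniformPixelSizeModel, w: float) -> float:
    return model.predict_one(w)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def model_to_json(model, cv_info: dict | None = None) -> str:
    if isinstance(model, NonUniformRadialModel):
        data = {
            "type": "nonuniform",
            "M": model.M,
            "N": model.N,
            "coeffs": list(model.coef_),
            "scaling": {"w_scale": model.w_scale_, "r_scale": model.r_scale_},
            "domain": model.domain_,
        }
    elif isinstance(model, UniformPixelSizeModel):
        data = {
            "type": "uniform",
            "intercept": model.intercept_,
            "slope": model.slope_,
            "domain": model.domain_,
        }
    else:
        raise TypeError(f"unsupported model {type(model)!r}")
    if cv_info:
        data["cv"] = cv_info
    return json.dumps(data, indent=1)


def model_from_json(text: str):
    data = json.loads(text)
    if data["type"] == "nonuniform":
        model = NonUniformRadialModel(M=data["M"], N=data["N"])
        model.w_scale_ = data["scaling"]["w_scale"]
        model.r_scale_ = data["scaling"]["r_scale"]
        model.coef_ = np.asarray(data["coeffs"], dtype=float)
        model.domain_ = data["domain"]
        model.n_features_in_ = 2
        return model
    if data["type"] == "uniform":
        model = UniformPixelSizeModel()
        model.intercept_ = data["intercept"]
        model.slope_ = data["slope"]
        model.domain_ = data["domain"]
        model.n_features_in_ = 1
        return model
    raise ValueError(f"unknown model type {data['type']!r}")
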