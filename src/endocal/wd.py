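"""Decoding the working distance from the 7x7 laser-dot pattern.

Once frames are normalized to a common template, each laser point traces a
1-D trajectory as the working distance ``w`` changes.  Two decoders are
provided:

* the *original* method regresses ``w`` on the polar radius of each point
  with a double-exponential curve ``G(r) = b1 exp(b2 r) + b3 exp(b4 r)``;
* the *PCA* method first projects each point's track onto its leading
  principal direction and regresses ``w`` on that signed projection with
  the same curve family, which makes the decoder invariant to the template
  rotation (the "standard angle").

Per-point estimates are aggregated (median by default) into a single
working-distance estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .segment import (
    DEFAULT_REFERENCE_RADIUS_PX,
    FOVGeometry,
    LaserDotSet,
    normalize_to_template,
)

__all__ = [
    "PointTrack",
    "PCAPointModel",
    "OriginalPointModel",
    "WorkingDistanceEstimator",
    "fit_pca_direction",
    "project_track",
    "fit_double_exponential",
    "double_exponential",
    "dotsets_to_matrix",
    "fit_wd_model",
    "predict_wd",
    "model_to_json",
    "model_from_json",
]

TOP_ROW_INDICES = tuple(range(1, 8))


@dataclass(frozen=True)
class PointTrack:
    """Template-frame trajectory of one laser point across working distances."""

    index: int
    positions: np.ndarray  # (2, n)
    distances: np.ndarray  # (n,) mm

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        if p.ndim != 2 or p.shape[0] != 2 or p.shape[1] != d.shape[0]:
            raise ValueError("positions must be 2 x n aligned with distances")


@dataclass(frozen=True)
class PCAPointModel:
    index: int
    mean: tuple[float, float]
    direction: tuple[float, float]
    betas: tuple[float, float, float, float]
    fit_rmse: float
    v_range: tuple[float, float]


@dataclass(frozen=True)
class OriginalPointModel:
    index: int
    betas: tuple[float, float, float, float]
    fit_rmse: float
    r_range: tuple[float, float]


# ---------------------------------------------------------------------------
# PCA direction
# ---------------------------------------------------------------------------

def fit_pca_direction(track: PointTrack):
    """Mean and leading principal direction of a 2 x n track.

    The direction maximizes ``u' Q Q' u`` over unit vectors, where Q is the
    centred track.  Its sign is fixed so the projection increases as the
    working distance decreases; isotropic ties break toward +x.
    """
    P = np.asarray(track.positions, dtype=float)
    if P.shape[1] < 2:
        raise ValueError("need at least two observations")
    mean = P.mean(axis=1)
    Q = P - mean[:, None]
    if np.allclose(Q, 0.0):
        raise ValueError("degenerate track: zero variance")
    C = Q @ Q.T
    evals, evecs = np.linalg.eigh(C)
    u = evecs[:, int(np.argmax(evals))]
    v = u @ Q
    w = np.asarray(track.distances, dtype=float)
    cov = float(np.dot(v - v.mean(), w - w.mean()))
    if cov > 0:
        u = -u
    elif cov == 0:
        if u[0] < 0 or (u[0] == 0 and u[1] < 0):
            u = -u
    return (float(mean[0]), float(mean[1])), (float(u[0]), float(u[1]))


def project_track(positions, mean, direction) -> np.ndarray:
    """Signed projections v_j = u . (p_j - mean) of track points."""
    P = np.asarray(positions, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    mu = np.asarray(mean, dtype=float)
    u = np.asarray(direction, dtype=float)
    return u @ (P - mu[:, None])


# ---------------------------------------------------------------------------
# Double-exponential regression
# ---------------------------------------------------------------------------

def double_exponential(v, betas):
    b1, b2, b3, b4 = betas
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        out = b1 * np.exp(np.clip(b2 * v, -700, 700)) + b3 * np.exp(
            np.clip(b4 * v, -700, 700)
        )
    return out if out.ndim else float(out)


def _initial_starts(v, w):
    """Deterministic multi-start seeds for the double-exponential fit.

    Start 1 comes from a log-linear fit of w on v (dominant term), with the
    second term seeded from the residual mean; the rest are sign/scale
    perturbations of it.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    slope, intercept = np.polyfit(v, np.log(np.clip(w, 1e-9, None)), 1)
    b1, b2 = float(np.exp(intercept)), float(slope)
    resid = w - b1 * np.exp(np.clip(b2 * v, -700, 700))
    b3 = float(np.mean(resid))
    scale = max(np.ptp(v), 1.0)
    starts = [
        (b1, b2, b3, 0.0),
        (0.7 * b1, b2, 0.3 * b1, b2 / 3.0),
        (b1, b2, -0.1 * abs(b1) - 1e-3, -b2),
        (0.5 * np.mean(w), -1.0 / scale, 0.5 * np.mean(w), 1.0 / scale),
    ]
    return starts


def fit_double_exponential(v, w, max_nfev: int = 400):
    """Nonlinear least squares of w = b1 e^{b2 v} + b3 e^{b4 v}.

    Returns ``(betas, rmse)``; raises on degenerate input or if no start
    converges to a finite optimum.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("v and w must be aligned 1-D arrays")
    if len(v) < 4:
        raise ValueError("need at least 4 samples (model has 4 parameters)")
    if np.ptp(w) == 0:
        raise ValueError("degenerate fit: constant working distance")

    def resid(b):
        return double_exponential(v, b) - w

    best = None
    for x0 in _initial_starts(v, w):
        try:
            sol = least_squares(resid, x0=np.asarray(x0), max_nfev=max_nfev)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise RuntimeError("double-exponential fit failed to converge from all starts")
    sse, betas = best
    rmse = float(np.sqrt(sse / len(v)))
    return tuple(float(b) for b in betas), rmse


def _is_monotone(betas, lo, hi, n=200):
    g = double_exponential(np.linspace(lo, hi, n), betas)
    d = np.diff(g)
    return bool(np.all(d >= -1e-9) or np.all(d <= 1e-9))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class WorkingDistanceEstimator(BaseEstimator, RegressorMixin):
    """Decode working distance (mm) from template-normalized laser dots.

    Parameters
    ----------
    method : {"pca", "original"}
        Per-point decoder: PCA projection (rotation-robust) or polar radius.
    standard_angle_deg : float
        Template standard angle the input coordinates were normalized at.
        Recorded for provenance; the PCA decoder is insensitive to it.
    aggregation : {"median", "mean"}
        How per-point estimates combine into one working distance.
    exclude_top_row : bool or None
        Drop points 1-7.  ``None`` resolves to True for the original method
        (its top-row points are unreliable) and False for PCA.
    min_observations : int
        Minimum present observations for a point model to be fitted.

    The design matrix ``X`` has 98 columns (x1, y1, ..., x49, y49) of
    template coordinates with NaN marking absent dots; ``y`` is the working
    distance in mm.
    """

    def __init__(
        self,
        method: str = "pca",
        standard_angle_deg: float = 30.0,
        aggregation: str = "median",
        exclude_top_row: bool | None = None,
        min_observations: int = 4,
    ):
        self.method = method
        self.standard_angle_deg = standard_angle_deg
        self.aggregation = aggregation
        self.exclude_top_row = exclude_top_row
        self.min_observations = min_observations

    def _excluded(self):
        if self.exclude_top_row is None:
            return set(TOP_ROW_INDICES) if self.method == "original" else set()
        return set(TOP_ROW_INDICES) if self.exclude_top_row else set()

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 98:
            raise ValueError("X must be (n_frames, 98): x/y pairs of 49 dots")
        if self.method not in ("pca", "original"):
            raise ValueError("method must be 'pca' or 'original'")
        if self.aggregation not in ("median", "mean"):
            raise ValueError("aggregation must be 'median' or 'mean'")
        excluded = self._excluded()
        self.point_models_ = {}
        self.skipped_points_ = []
        for i in range(1, 50):
            if i in excluded:
                continue
            P = X[:, 2 * (i - 1) : 2 * i].T  # (2, n_frames)
            ok = np.all(np.isfinite(P), axis=0)
            if ok.sum() < self.min_observations:
                self.skipped_points_.append(i)
                continue
            track = PointTrack(index=i, positions=P[:, ok], distances=y[ok])
            try:
                model = self._fit_point(track)
            except (ValueError, RuntimeError):
                self.skipped_points_.append(i)
                continue
            self.point_models_[i] = model
        if not self.point_models_:
            raise ValueError("no usable per-point models could be fitted")
        self.n_features_in_ = 98
        return self

    def _fit_point(self, track: PointTrack):
        if self.method == "pca":
            mean, direction = fit_pca_direction(track)
            v = project_track(track.positions, mean, direction)
            betas, rmse = fit_double_exponential(v, track.distances)
            return PCAPointModel(
                index=track.index, mean=mean, direction=direction,
                betas=betas, fit_rmse=rmse,
                v_range=(float(v.min()), float(v.max())),
            )
        r = np.hypot(track.positions[0], track.positions[1])
        betas, rmse = fit_double_exponential(r, track.distances)
        return OriginalPointModel(
            index=track.index, betas=betas, fit_rmse=rmse,
            r_range=(float(r.min()), float(r.max())),
        )

    def predict_per_point(self, X) -> np.ndarray:
        """(n_frames, 49) per-point estimates, NaN where unavailable."""
        X = np.asarray(X, dtype=float)
        out = np.full((X.shape[0], 49), np.nan)
        for i, model in self.point_models_.items():
            P = X[:, 2 * (i - 1) : 2 * i]
            ok = np.all(np.isfinite(P), axis=1)
            if not ok.any():
                continue
            if isinstance(model, PCAPointModel):
                v = project_track(P[ok].T, model.mean, model.direction)
            else:
                v = np.hypot(P[ok, 0], P[ok, 1])
            out[ok, i - 1] = double_exponential(v, model.betas)
        return out

    def predict(self, X) -> np.ndarray:
        per_point = self.predict_per_point(X)
        agg = np.nanmedian if self.aggregation == "median" else np.nanmean
        with np.errstate(all="ignore"):
            est = agg(per_point, axis=1)
        if np.any(~np.isfinite(est)):
            raise ValueError("no usable dots in at least one frame")
        return est

    def monotone_fraction_(self) -> float:
        """Fraction of retained point models with monotone G over training range."""
        flags = []
        for m in self.point_models_.values():
            lo, hi = m.v_range if isinstance(m, PCAPointModel) else m.r_range
            flags.append(_is_monotone(m.betas, lo, hi))
        return float(np.mean(flags))


# ---------------------------------------------------------------------------
# Convenience wrappers on segmentation outputs
# ---------------------------------------------------------------------------

def dotsets_to_matrix(
    dotsets,
    fovs,
    standard_angle_deg: float = 30.0,
    reference_radius_px: float = DEFAULT_REFERENCE_RADIUS_PX,
) -> np.ndarray:
    """Stack LaserDotSets into the (n_frames, 98) template-coordinate matrix."""
    if isinstance(fovs, FOVGeometry):
        fovs = [fovs] * len(dotsets)
    rows = []
    for ds, fov in zip(dotsets, fovs):
        pos = ds.positions()
        tmpl = np.full((49, 2), np.nan)
        ok = np.all(np.isfinite(pos), axis=1)
        if ok.any():
            tmpl[ok] = normalize_to_template(
                pos[ok], fov, standard_angle_deg, reference_radius_px
            )
        rows.append(tmpl.reshape(-1))
    return np.asarray(rows)


def fit_wd_model(
    dotsets,
    distances_mm,
    fovs,
    method: str = "pca",
    standard_angle_deg: float = 30.0,
) -> WorkingDistanceEstimator:
    X = dotsets_to_matrix(dotsets, fovs, standard_angle_deg)
    est = WorkingDistanceEstimator(method=method, standard_angle_deg=standard_angle_deg)
    return est.fit(X, np.asarray(distances_mm, dtype=float))


def predict_wd(model: WorkingDistanceEstimator, dots: LaserDotSet, fov: FOVGeometry):
    """Single-frame working-distance estimate with per-point detail."""
    X = dotsets_to_matrix([dots], fov, model.standard_angle_deg)
    est = float(model.predict(X)[0])
    return est, model.predict_per_point(X)[0]


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def model_to_json(model: WorkingDistanceEstimator) -> str:
    points = []
    for i, m in sorted(model.point_models_.items()):
        rec = {"i": i, "betas": list(m.betas), "rmse": m.fit_rmse}
        if isinstance(m, PCAPointModel):
            rec.update({"mu": list(m.mean), "u": list(m.direction),
                        "v_range": list(m.v_range)})
        else:
            rec["r_range"] = list(m.r_range)
        points.append(rec)
    return json.dumps(
        {
            "method": model.method,
            "standard_angle_deg": model.standard_angle_deg,
            "aggregation": model.aggregation,
            "points": points,
        },
        indent=1,
    )


def model_from_json(text: str) -> WorkingDistanceEstimator:
    data = json.loads(text)
    est = WorkingDistanceEstimator(
        method=data["method"],
        standard_angle_deg=data["standard_angle_deg"],
        aggregation=data["aggregation"],
    )
    est.point_models_ = {}
    for rec in data["points"]:
        if data["method"] == "pca":
            est.point_models_[rec["i"]] = PCAPointModel(
                index=rec["i"], mean=tuple(rec["mu"]), direction=tuple(rec["u"]),
                betas=tuple(rec["betas"]), fit_rmse=rec["rmse"],
                v_range=tuple(rec["v_range"]),
            )
        else:
            est.point_models_[rec["i"]] = OriginalPointModel(
                index=rec["i"], betas=tuple(rec["betas"]), fit_rmse=rec["rmse"],
                r_range=tuple(rec["r_range"]),
            )
    est.skipped_points_ = []
    est.n_features_in_ = 98
    return est
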