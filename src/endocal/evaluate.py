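"""Evaluation harnesses: error statistics, correlation tables, robust ANOVA,
and the four benchtop experiments run on synthetic recording sets.

Experiment 1 compares the original and PCA working-distance decoders by
10-fold cross-validation on Set 2.  Experiment 2 cross-validates the
uniform and non-uniform radial models on Set 1 and tabulates error
correlations and per-interval statistics.  Experiment 3 checks central
angles against the 15-degree sectors of Set 3.  Experiment 4 measures the
Set-4 line segments end-to-end with the working distance decoded from the
laser dots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import horizontal, pipeline, segment, wd

__all__ = [
    "StatsSummary",
    "error_stats",
    "correlations",
    "interval_table",
    "robust_anova",
    "abs_error_slope",
    "run_experiment",
]

DEFAULT_BIN_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class StatsSummary:
    mean: float
    std: float
    mae: float
    mag_mean: float
    mag_std: float
    n: int


def error_stats(errors) -> StatsSummary:
    """Mean/std of signed errors and of their magnitudes (sample std, ddof=1)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sample")
    mag = np.abs(e)
    std = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    mag_std = float(np.std(mag, ddof=1)) if e.size > 1 else 0.0
    return StatsSummary(
        mean=float(e.mean()), std=std, mae=float(mag.mean()),
        mag_mean=float(mag.mean()), mag_std=mag_std, n=int(e.size),
    )


def correlations(x, y) -> dict:
    """Pearson r, tie-adjusted Kendall tau-b and Spearman rho with p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    pr = stats.pearsonr(x, y)
    kt = stats.kendalltau(x, y, variant="b")
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "kendall_tau": float(kt.statistic), "kendall_p": float(kt.pvalue),
        "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
    }


def interval_table(
    records: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    w_col: str = "w_mm",
    method_col: str = "method",
    error_col: str = "error_mm",
) -> pd.DataFrame:
    """Per working-distance-interval error summaries for each method.

    Bins are half-open ``[lo, hi)`` (the first bin is ``(0, hi)``, i.e.
    strictly positive distances).  Empty bins are flagged rather than
    dropped.
    """
    rows = []
    for method in sorted(records[method_col].unique()):
        sub = records[records[method_col] == method]
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
            sel = sub[(sub[w_col] >= lo) & (sub[w_col] < hi) & (sub[w_col] > 0)]
            if sel.empty:
                rows.append({"method": method, "w_lo": lo, "w_hi": hi, "n": 0,
                             "empty": True})
                continue
            s = error_stats(sel[error_col].to_numpy())
            rows.append({
                "method": method, "w_lo": lo, "w_hi": hi, "n": s.n, "empty": False,
                "error_mean_mm": s.mean, "error_std_mm": s.std,
                "mag_mean_mm": s.mag_mean, "mag_std_mm": s.mag_std,
            })
    return pd.DataFrame(rows)


def _trimmed_f_stat(groups, trim: float) -> float:
    """Heteroscedastic one-way F-like statistic on trimmed means.

    Weights each group by the inverse of the squared standard error of its
    trimmed mean (winsorized variance over effective sample size).
    """
    J = len(groups)
    h, xbar, d = [], [], []
    for g in groups:
        g = np.sort(np.asarray(g, dtype=float))
        n = len(g)
        cut = int(np.floor(trim * n))
        if n - 2 * cut < 2:
            raise ValueError("group too small for the requested trimming level")
        hj = n - 2 * cut
        wins = np.clip(g, g[cut], g[n - cut - 1])
        sw2 = np.var(wins, ddof=1)
        h.append(hj)
        xbar.append(np.mean(g[cut : n - cut]))
        d.append((n - 1) * sw2 / (hj * (hj - 1)))
    h, xbar, d = np.asarray(h), np.asarray(xbar), np.asarray(d)
    if np.any(d <= 0):
        d = np.maximum(d, 1e-300)
    wgt = 1.0 / d
    U = wgt.sum()
    xt = (wgt * xbar).sum() / U
    A = (wgt * (xbar - xt) ** 2).sum() / (J - 1)
    B = 2.0 * (J - 2) / (J**2 - 1) * ((1 - wgt / U) ** 2 / (h - 1)).sum()
    return float(A / (1.0 + B))


def robust_anova(groups, trim: float = 0.2, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap test of equal 20%-trimmed means across groups.

    Groups are centred at their trimmed means and resampled with
    replacement ``n_boot`` times; the p-value is the fraction of bootstrap
    trimmed-means F statistics at least as large as the observed one.
    Deterministic under a fixed seed.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    min_n = 1.0 / (2.0 * trim)
    if any(len(g) < min_n for g in groups):
        raise ValueError(
            f"every group needs at least {min_n:.1f} observations at trim={trim}"
        )
    f_obs = _trimmed_f_stat(groups, trim)
    rng = np.random.default_rng(seed)
    centred = [g - stats.trim_mean(g, trim) for g in groups]
    count = 0
    for _ in range(n_boot):
        boot = [g[rng.integers(0, len(g), len(g))] for g in centred]
        try:
            if _trimmed_f_stat(boot, trim) >= f_obs:
                count += 1
        except ValueError:
            count += 1
    return float((count + 1) / (n_boot + 1))


def abs_error_slope(w, abs_errors) -> float:
    """Least-squares slope of |error| on working distance (mm per mm)."""
    w = np.asarray(w, dtype=float)
    e = np.asarray(abs_errors, dtype=float)
    if np.ptp(w) == 0:
        raise ValueError("slope undefined for constant working distance")
    return float(np.polyfit(w, e, 1)[0])


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _wd_cross_val(X, w, method, folds, seed, standard_angle_deg=30.0):
    """Per-point held-out working-distance errors under k-fold CV."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(w))
    fold = np.empty(len(w), dtype=int)
    fold[idx] = np.arange(len(w)) % folds
    rows = []
    for f in range(folds):
        tr, te = fold != f, fold == f
        est = wd.WorkingDistanceEstimator(
            method=method, standard_angle_deg=standard_angle_deg
        ).fit(X[tr], w[tr])
        per_point = est.predict_per_point(X[te])
        for row, w_true in zip(per_point, w[te]):
            for i in range(49):
                if np.isfinite(row[i]):
                    rows.append({"point": i + 1, "w_true": float(w_true),
                                 "w_pred": float(row[i]),
                                 "error_mm": float(row[i] - w_true),
                                 "method": method, "fold": f})
    return pd.DataFrame(rows)


def run_experiment(exp_id: int, datasets: dict, seed: int = 0) -> dict:
    """Run one of the four evaluation experiments on synthetic recording sets.

    ``datasets`` maps set ids (1..4) to lists of dataset records; only the
    sets an experiment needs must be present.  Returns a dict with an
    ``errors`` DataFrame and experiment-specific tables.
    """
    if exp_id == 1:
        records = _require(datasets, 2)
        X, w, _, _ = pipeline.prepare_set2(records)
        out = {}
        frames = []
        for method in ("original", "pca"):
            cv = _wd_cross_val(X, w, method, folds=10, seed=seed)
            frames.append(cv)
            out[f"slope_{method}"] = abs_error_slope(
                cv["w_true"], cv["error_mm"].abs()
            )
            out[f"mae_{method}"] = float(cv["error_mm"].abs().mean())
        errors = pd.concat(frames, ignore_index=True)
        per_point = (
            errors.assign(abs_error=errors["error_mm"].abs())
            .groupby(["method", "point"])["abs_error"].mean().reset_index()
        )
        out.update({"errors": errors, "per_point_mae": per_point})
        return out

    if exp_id == 2:
        records = _require(datasets, 1)
        samples = pipeline.segment_set1(records)
        M, N, table = horizontal.select_model(samples, seed=seed)
        cv_nu = horizontal.cross_val_errors(
            samples, lambda: horizontal.NonUniformRadialModel(M=M, N=N), seed=seed
        )
        cv_u = horizontal.cross_val_errors(
            samples, horizontal.UniformPixelSizeModel, seed=seed,
            largest_only_train=True, eval_train_smaller=True,
        )
        errors = pd.concat(
            [cv_nu.assign(method="nonuniform"), cv_u.assign(method="uniform")],
            ignore_index=True,
        )
        corr = {
            method: {
                "vs_w": correlations(sub["error_mm"].abs(), sub["w_mm"]),
                "vs_length": correlations(sub["error_mm"].abs(), sub["r_mm"]),
            }
            for method, sub in errors.groupby("method")
        }
        return {
            "errors": errors, "samples": samples,
            "selected": (M, N), "selection_table": table,
            "cv_mae_nonuniform": float(cv_nu["error_mm"].abs().mean()),
            "cv_mae_uniform": float(cv_u["error_mm"].abs().mean()),
            "correlations": corr,
            "interval_table": interval_table(errors),
        }

    if exp_id == 3:
        records = _require(datasets, 3)
        rows = []
        for rec in records:
            pre = segment.preprocess([rec["image"]])
            fov = segment.estimate_fov(pre)
            angles = segment.detect_radial_lines(pre, fov)
            diffs = np.diff(np.concatenate([angles, [angles[0] + 180.0]]))
            for d in diffs:
                rows.append({"w_mm": rec["truth"]["w_mm"],
                             "error_deg": float(d - 15.0)})
        errors = pd.DataFrame(rows)
        groups = [g["error_deg"].to_numpy() for _, g in errors.groupby("w_mm")]
        return {
            "errors": errors,
            "mean_error_deg": float(errors["error_deg"].mean()),
            "std_error_deg": float(errors["error_deg"].std(ddof=1)),
            "anova_p": robust_anova(groups, seed=seed),
        }

    if exp_id == 4:
        set1 = _require(datasets, 1)
        set2 = _require(datasets, 2)
        set4 = _require(datasets, 4)
        samples = pipeline.segment_set1(set1)
        M, N, _ = horizontal.select_model(samples, seed=seed)
        nonuni = horizontal.fit_nonuniform(samples, M, N)
        uni = horizontal.fit_uniform(samples)
        X, w, _, _ = pipeline.prepare_set2(set2)
        wd_model = wd.WorkingDistanceEstimator(method="pca").fit(X, w)
        df = pipeline.measure_set4(set4, wd_model, nonuni, uniform=uni)
        out = {"errors": df}
        for method in ("nonuniform", "uniform"):
            e = df[f"error_{method}_mm"].to_numpy()
            out[f"stats_{method}"] = error_stats(e)
            by_len = [g.to_numpy() for _, g in df[df["w_true"] == 20.18]
                      .groupby("len_true_mm")[f"error_{method}_mm"]]
            by_w = [g.to_numpy() for _, g in df[df["len_true_mm"] == 5.0]
                    .groupby("w_true")[f"error_{method}_mm"]]
            out[f"anova_length_p_{method}"] = robust_anova(by_len, seed=seed)
            out[f"anova_w_p_{method}"] = robust_anova(by_w, seed=seed + 1)
        return out

    raise ValueError(f"unknown experiment id {exp_id!r}")


def _require(datasets: dict, set_id: int):
    try:
        return datasets[set_id]
    except KeyError:
        raise ValueError(f"experiment requires dataset Set {set_id}") from None
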