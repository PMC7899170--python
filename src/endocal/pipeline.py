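"""End-to-end glue: dataset records -> detections -> fitted models -> errors.

These helpers connect the synthetic (or loaded) recording sets to the
segmentation, calibration and measurement stages, and are shared by the
evaluation experiments, the command-line interface and the acceptance
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import horizontal, measure, segment, wd

__all__ = [
    "segment_circles",
    "segment_set1",
    "prepare_set2",
    "measure_set4",
]


def segment_circles(image, fov=None):
    """Two-stage circle segmentation of one preprocessed grid image."""
    pre = segment.preprocess([image])
    fov = fov or segment.estimate_fov(pre)
    coarse = segment.detect_circles_coarse(pre, fov)
    grad = segment.gradient_magnitude(pre)
    refined = [segment.refine_circle(pre, c, gradient=grad) for c in coarse]
    return fov, refined


def segment_set1(records) -> pd.DataFrame:
    """Segment every Set-1 recording into calibration samples.

    The working distance and the grid spacing of each recording are known
    acquisition parameters and are read from the recording's metadata; the
    circle radii come entirely from the two-stage segmentation.
    """
    per_recording = []
    for rec in records:
        truth = rec["truth"]
        _, refined = segment_circles(rec["image"])
        per_recording.append(
            (
                truth["recording_id"],
                truth["w_mm"],
                truth["spacing_mm"],
                [c.radius_px for c in refined],
            )
        )
    return horizontal.build_calib_samples(per_recording)


def prepare_set2(records, standard_angle_deg: float = 30.0):
    """Detect laser dots in every Set-2 frame; returns (X, w, fovs, dotsets)."""
    dotsets, fovs, ws = [], [], []
    for rec in records:
        pre = segment.preprocess([rec["image"]])
        fov = segment.estimate_fov(pre)
        dotsets.append(segment.detect_laser_dots(pre, fov))
        fovs.append(fov)
        ws.append(rec["truth"]["w_mm"])
    X = wd.dotsets_to_matrix(dotsets, fovs, standard_angle_deg)
    return X, np.asarray(ws), fovs, dotsets


def measure_set4(
    records,
    wd_model: wd.WorkingDistanceEstimator,
    nonuniform: horizontal.NonUniformRadialModel,
    uniform: horizontal.UniformPixelSizeModel | None = None,
) -> pd.DataFrame:
    """Measure every Set-4 segment with working distance decoded from the dots.

    Endpoint pixels are taken from each recording's annotation (standing in
    for the operator's manual endpoint marking); the working distance is
    estimated from the detected laser dots with ``wd_model``.
    """
    rows = []
    for rec in records:
        truth = rec["truth"]
        pre = segment.preprocess([rec["image"]])
        fov = segment.estimate_fov(pre)
        dots = segment.detect_laser_dots(pre, fov)
        w_est, _ = wd.predict_wd(wd_model, dots, fov)
        A = (truth["line"]["ax"], truth["line"]["ay"])
        B = (truth["line"]["bx"], truth["line"]["by"])
        res = measure.measure_general(nonuniform, w_est, A, B, fov=fov,
                                      w_source="wd_model")
        row = {
            "recording_id": truth["recording_id"],
            "w_true": truth["w_mm"],
            "w_est": w_est,
            "len_true_mm": truth["line"]["len_mm"],
            "len_nonuniform_mm": res.length_mm,
            "alpha_deg": res.alpha_deg,
        }
        if uniform is not None:
            row["len_uniform_mm"] = measure.measure_uniform(
                uniform, w_est, A, B, fov=fov, w_source="wd_model"
            ).length_mm
        rows.append(row)
    df = pd.DataFrame(rows)
    df["error_nonuniform_mm"] = df["len_nonuniform_mm"] - df["len_true_mm"]
    if uniform is not None:
        df["error_uniform_mm"] = df["len_uniform_mm"] - df["len_true_mm"]
    return df
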