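"""Calibrated mm length measurement from image-space endpoints.

Radial lengths (one endpoint on the FOV centre) come straight from the
non-uniform model.  A general segment AB is decomposed into the two radial
lengths OA and OB plus the central angle alpha between them -- which the
radially symmetric distortion preserves -- and recombined with the law of
cosines: ``AB^2 = OA^2 + OB^2 - 2 OA OB cos(alpha)``.  The uniform
alternative multiplies the straight pixel distance by gamma(w).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .horizontal import NonUniformRadialModel, UniformPixelSizeModel
from .segment import FOVGeometry

__all__ = [
    "MeasurementResult",
    "central_angle",
    "measure_radial",
    "measure_general",
    "measure_uniform",
    "to_centered",
]

_CENTER_EPS_PX = 1e-9


@dataclass(frozen=True)
class MeasurementResult:
    length_mm: float
    method: str  # nonuniform | uniform
    oa_mm: float | None = None
    ob_mm: float | None = None
    alpha_deg: float | None = None
    w_used: float | None = None
    w_source: str | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)


def to_centered(points, fov: FOVGeometry) -> np.ndarray:
    """Image row/col pixel coordinates -> FOV-centred y-up coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = fov.center_px
    out = np.column_stack([pts[:, 0] - cx, cy - pts[:, 1]])
    return out if np.asarray(points).ndim > 1 else out[0]


def central_angle(A, B) -> float:
    """Central angle (deg, in [0, 180]) between endpoints in centred y-up coords.

    Uses the four-quadrant angles of OA and OB; the absolute difference is
    folded to [0, 180], which leaves the law of cosines unchanged.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.hypot(*A) < _CENTER_EPS_PX or np.hypot(*B) < _CENTER_EPS_PX:
        raise ValueError("central angle undefined for an endpoint at the FOV centre")
    ta = np.degrees(np.arctan2(A[1], A[0]))
    tb = np.degrees(np.arctan2(B[1], B[0]))
    alpha = abs(ta - tb) % 360.0
    return float(min(alpha, 360.0 - alpha))


def measure_radial(model: NonUniformRadialModel, w: float, pixel_length: float) -> float:
    """mm length of a radial segment of ``pixel_length`` px at working distance ``w``."""
    if pixel_length < 0:
        raise ValueError("pixel length must be non-negative")
    if pixel_length == 0:
        return 0.0
    return model.predict_one(w, pixel_length)


def measure_general(
    model: NonUniformRadialModel,
    w: float,
    A,
    B,
    fov: FOVGeometry | None = None,
    w_source: str = "given",
) -> MeasurementResult:
    """Law-of-cosines mm length of the segment AB.

    ``A`` and ``B`` are image pixel coordinates when ``fov`` is given,
    otherwise already FOV-centred y-up coordinates.  If one endpoint
    coincides with the FOV centre the measurement degenerates to the radial
    measurement of the other endpoint.
    """
    if fov is not None:
        A = to_centered(A, fov)
        B = to_centered(B, fov)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    ra, rb = float(np.hypot(*A)), float(np.hypot(*B))
    notes: list[str] = []
    if ra < _CENTER_EPS_PX or rb < _CENTER_EPS_PX:
        other = rb if ra < _CENTER_EPS_PX else ra
        return MeasurementResult(
            length_mm=measure_radial(model, w, other),
            method="nonuniform", oa_mm=0.0,
            ob_mm=measure_radial(model, w, other), alpha_deg=None,
            w_used=w, w_source=w_source,
            warnings=("endpoint at FOV centre; radial measurement used",),
        )
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        oa = measure_radial(model, w, ra)
        ob = measure_radial(model, w, rb)
    notes.extend(str(c.message) for c in caught)
    alpha = central_angle(A, B)
    ab2 = oa**2 + ob**2 - 2.0 * oa * ob * np.cos(np.radians(alpha))
    return MeasurementResult(
        length_mm=float(np.sqrt(max(ab2, 0.0))),
        method="nonuniform", oa_mm=oa, ob_mm=ob, alpha_deg=alpha,
        w_used=w, w_source=w_source, warnings=tuple(notes),
    )


def measure_uniform(
    model: UniformPixelSizeModel,
    w: float,
    A,
    B,
    fov: FOVGeometry | None = None,
    w_source: str = "given",
) -> MeasurementResult:
    """Uniform-model mm length: gamma(w) times the straight pixel distance."""
    if fov is not None:
        A = to_centered(A, fov)
        B = to_centered(B, fov)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        gamma = model.predict_one(w)
    return MeasurementResult(
        length_mm=float(gamma * np.linalg.norm(A - B)),
        method="uniform", w_used=w, w_source=w_source,
        warnings=tuple(str(c.message) for c in caught),
    )
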