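"""Segmentation of calibration targets from endoscopic frames.

Implements the image-side stages of the calibration pipeline: temporal
averaging + Gaussian smoothing, FOV disc and fiducial detection, two-stage
(coarse strip / fine grid-search) concentric-circle segmentation, laser-dot
extraction with 7x7 row-major labelling, Hough-based radial-line detection,
and normalization of detections to a common template frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.transform import hough_line, hough_line_peaks

log = logging.getLogger(__name__)

__all__ = [
    "FOVGeometry",
    "CircleDetection",
    "LaserDot",
    "LaserDotSet",
    "preprocess",
    "estimate_fov",
    "detect_circles_coarse",
    "refine_circle",
    "detect_laser_dots",
    "detect_radial_lines",
    "normalize_to_template",
    "denormalize_from_template",
    "gradient_magnitude",
]

#: Device constant: at this standard angle the 7x7 laser grid is axis-aligned,
#: which is the frame used internally for row/column labelling.
GRID_ALIGNED_STANDARD_ANGLE_DEG = 30.0
DEFAULT_REFERENCE_RADIUS_PX = 135.0


@dataclass(frozen=True)
class FOVGeometry:
    center_px: tuple[float, float]
    radius_px: float
    fiducial_angle_deg: float | None = None

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("FOV radius must be positive")


@dataclass(frozen=True)
class CircleDetection:
    center_px: tuple[float, float]
    radius_px: float
    stage: str = "coarse"  # coarse | refined
    cost: float = float("nan")


@dataclass(frozen=True)
class LaserDot:
    index: int  # 1..49 row-major, top-left first
    position_px: tuple[float, float]
    present: bool


@dataclass(frozen=True)
class LaserDotSet:
    dots: tuple[LaserDot, ...]

    def __post_init__(self):
        idx = [d.index for d in self.dots]
        if sorted(idx) != list(range(1, 50)):
            raise ValueError("LaserDotSet must contain indices 1..49 exactly once")

    def positions(self) -> np.ndarray:
        """(49, 2) array of positions, NaN where absent."""
        out = np.full((49, 2), np.nan)
        for d in self.dots:
            if d.present:
                out[d.index - 1] = d.position_px
        return out


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(frames, sigma: float = 2.0) -> np.ndarray:
    """Temporal mean of the frames followed by Gaussian smoothing.

    ``sigma`` is the Gaussian scale in pixels (kernel truncated at 4 sigma).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("at least one frame is required")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share one shape")
    mean = np.mean(frames, axis=0)
    return ndimage.gaussian_filter(mean, sigma=sigma, truncate=4.0, mode="nearest")


# ---------------------------------------------------------------------------
# FOV geometry
# ---------------------------------------------------------------------------

def estimate_fov(image) -> FOVGeometry:
    """Locate the illuminated FOV disc and the fiducial rim protrusion."""
    image = np.asarray(image, dtype=float)
    thr = threshold_otsu(image)
    bw = image > thr
    if bw.mean() > 0.98 or bw.mean() < 0.02:
        raise ValueError("no FOV rim found (image lacks a bright disc on dark surround)")
    bw = ndimage.binary_fill_holes(bw)
    labels, n = ndimage.label(bw)
    if n == 0:
        raise ValueError("no FOV disc found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    disc = labels == (1 + int(np.argmax(sizes)))
    cy, cx = ndimage.center_of_mass(disc)
    boundary = disc & ~ndimage.binary_erosion(disc)
    ys, xs = np.nonzero(boundary)
    dists = np.hypot(xs - cx, ys - cy)
    radius = float(np.median(dists))
    # fiducial: boundary points protruding beyond the rim circle
    out = dists > radius + 2.0
    fiducial = None
    if np.any(out):
        ang = np.arctan2(cy - ys[out], xs[out] - cx)  # y-up
        fiducial = float(np.degrees(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))) % 360.0)
    return FOVGeometry(center_px=(float(cx), float(cy)), radius_px=radius,
                       fiducial_angle_deg=fiducial)


# ---------------------------------------------------------------------------
# Circle segmentation (coarse stage)
# ---------------------------------------------------------------------------

def _strip_minima(profile, center, prominence_frac):
    """Sub-pixel local minima of a 1-D strip profile (parabolic refinement)."""
    dyn = float(np.ptp(profile))
    if dyn <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(-profile, prominence=prominence_frac * dyn)
    pos = []
    for i in idx:
        if 0 < i < len(profile) - 1:
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            pos.append(i + float(np.clip(delta, -0.5, 0.5)))
        else:
            pos.append(float(i))
    return np.asarray(pos)


def _pair_minima(positions, center, tol):
    """Pair minima on opposite sides of ``center`` by distance from it.

    Returns (centre_estimates, radii); unpaired minima are dropped.
    """
    left = sorted(center - p for p in positions if p < center)
    right = sorted(p - center for p in positions if p > center)
    used = [False] * len(right)
    centres, radii = [], []
    for dl in left:
        best, best_err = None, tol
        for j, dr in enumerate(right):
            if used[j] and best is not None:
                continue
            err = abs(dr - dl)
            if not used[j] and err <= best_err:
                best, best_err = j, err
        if best is not None:
            used[best] = True
            dr = right[best]
            centres.append(center + (dr - dl) / 2.0)
            radii.append((dl + dr) / 2.0)
    return np.asarray(centres), np.asarray(radii)


def detect_circles_coarse(
    image,
    fov: FOVGeometry,
    strip_width: int = 9,
    prominence_frac: float = 0.05,
    pair_tol_px: float = 3.0,
) -> list[CircleDetection]:
    """Coarse concentric-circle detection from two axis-parallel strips.

    A strip of ``strip_width`` px through the FOV centre is averaged across
    its width; paired local minima of the profile give circle centres (pair
    mean) and radii (half pair difference), row-wise for the x-parallel
    strip and column-wise for the y-parallel strip.  The coarse radius is
    the mean of the row- and column-wise estimates.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = fov.center_px
    half = strip_width // 2
    iy, ix = int(round(cy)), int(round(cx))

    row_profile = image[iy - half : iy + half + 1, :].mean(axis=0)
    col_profile = image[:, ix - half : ix + half + 1].mean(axis=1)

    def _inside(p, c):
        return p[np.abs(p - c) <= fov.radius_px]

    x_min = _inside(_strip_minima(row_profile, cx, prominence_frac), cx)
    y_min = _inside(_strip_minima(col_profile, cy, prominence_frac), cy)
    xc, r_row = _pair_minima(x_min, cx, pair_tol_px)
    yc, r_col = _pair_minima(y_min, cy, pair_tol_px)

    # Match row-wise and column-wise circles by radius.
    order_r, order_c = np.argsort(r_row), np.argsort(r_col)
    detections = []
    j = 0
    for i in order_r:
        matched = None
        for k in range(j, len(order_c)):
            if abs(r_col[order_c[k]] - r_row[i]) <= pair_tol_px:
                matched = k
                break
        if matched is None:
            log.warning("dropping unmatched row-wise circle radius %.2f px", r_row[i])
            continue
        k = order_c[matched]
        j = matched + 1
        detections.append(
            CircleDetection(
                center_px=(float(xc[i]), float(yc[k])),
                radius_px=float((r_row[i] + r_col[k]) / 2.0),
                stage="coarse",
            )
        )
    return sorted(detections, key=lambda c: c.radius_px)


# ---------------------------------------------------------------------------
# Circle refinement (fine stage)
# ---------------------------------------------------------------------------

def gradient_magnitude(image) -> np.ndarray:
    """Sobel gradient magnitude used by the ring-mask refinement objective."""
    image = np.asarray(image, dtype=float)
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    gy = ndimage.sobel(image, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def refine_circle(
    image,
    coarse: CircleDetection,
    gradient: np.ndarray | None = None,
    span_px: float = 1.0,
    step_px: float = 0.25,
    mode: str = "ridge",
) -> CircleDetection:
    """Grid-search refinement of one circle on a +-1 px / 0.25 px lattice.

    For each candidate (cx, cy, r) a 1-px-wide ring mask (pixels whose
    centre lies within r +- 0.5 px) is applied to the gradient-magnitude
    image and the masked values are summed.  In ``"ridge"`` mode (default)
    the sum is minimized: the dark circle line is an intensity ridge, so the
    gradient magnitude vanishes on its centreline.  ``"edge"`` maximizes
    instead (useful for single-edged circles).
    """
    if mode not in ("ridge", "edge"):
        raise ValueError("mode must be 'ridge' or 'edge'")
    g = gradient_magnitude(image) if gradient is None else gradient
    cx0, cy0 = coarse.center_px
    r0 = coarse.radius_px
    offs = np.arange(-span_px, span_px + step_px / 2, step_px)

    h, w = g.shape
    pad = span_px + 1.5
    y0 = max(0, int(np.floor(cy0 - r0 - pad)))
    y1 = min(h, int(np.ceil(cy0 + r0 + pad)) + 1)
    x0 = max(0, int(np.floor(cx0 - r0 - pad)))
    x1 = min(w, int(np.ceil(cx0 + r0 + pad)) + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d0 = np.hypot(xs - cx0, ys - cy0)
    band = np.abs(d0 - r0) <= pad
    bx = xs[band].astype(float)
    by = ys[band].astype(float)
    bg = g[y0:y1, x0:x1][band]

    best = None
    for dx in offs:
        for dy in offs:
            d = np.hypot(bx - (cx0 + dx), by - (cy0 + dy))
            for dr in offs:
                ring = np.abs(d - (r0 + dr)) <= 0.5
                cost = float(bg[ring].sum())
                key = cost if mode == "ridge" else -cost
                if best is None or key < best[0]:
                    best = (key, dx, dy, dr, cost)
    _, dx, dy, dr, cost = best
    return CircleDetection(
        center_px=(cx0 + dx, cy0 + dy),
        radius_px=r0 + dr,
        stage="refined",
        cost=cost,
    )


# ---------------------------------------------------------------------------
# Template normalization
# ---------------------------------------------------------------------------

def normalize_to_template(
    points,
    fov: FOVGeometry,
    standard_angle_deg: float = GRID_ALIGNED_STANDARD_ANGLE_DEG,
    reference_radius_px: float = DEFAULT_REFERENCE_RADIUS_PX,
) -> np.ndarray:
    """Map image pixel coordinates into the standard template frame.

    The chain of operations: translate the FOV centre to the origin (and
    flip to y-up), rotate so the fiducial marker lands on
    ``standard_angle_deg``, scale so the FOV radius equals
    ``reference_radius_px``.
    """
    if fov.radius_px <= 0:
        raise ValueError("FOV radius must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = fov.center_px
    u = pts[:, 0] - cx
    v = cy - pts[:, 1]
    fid = fov.fiducial_angle_deg or 0.0
    a = np.radians(standard_angle_deg - fid)
    ru = u * np.cos(a) - v * np.sin(a)
    rv = u * np.sin(a) + v * np.cos(a)
    s = reference_radius_px / fov.radius_px
    out = np.column_stack([ru, rv]) * s
    return out if np.asarray(points).ndim > 1 else out[0]


def denormalize_from_template(
    points,
    fov: FOVGeometry,
    standard_angle_deg: float = GRID_ALIGNED_STANDARD_ANGLE_DEG,
    reference_radius_px: float = DEFAULT_REFERENCE_RADIUS_PX,
) -> np.ndarray:
    """Exact inverse of :func:`normalize_to_template`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) / (
        reference_radius_px / fov.radius_px
    )
    fid = fov.fiducial_angle_deg or 0.0
    a = -np.radians(standard_angle_deg - fid)
    ru = pts[:, 0] * np.cos(a) - pts[:, 1] * np.sin(a)
    rv = pts[:, 0] * np.sin(a) + pts[:, 1] * np.cos(a)
    cx, cy = fov.center_px
    out = np.column_stack([ru + cx, cy - rv])
    return out if np.asarray(points).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# Laser dots
# ---------------------------------------------------------------------------

def detect_laser_dots(
    image,
    fov: FOVGeometry,
    min_area_px: int = 3,
) -> LaserDotSet:
    """Segment the 7x7 laser-dot pattern and label dots row-major 1..49.

    Bright spots inside the FOV are thresholded (Otsu over the upper half of
    the in-FOV intensity distribution, which works on both dark and bright
    backgrounds), reduced to intensity-weighted centroids, and labelled
    after rotating detections into the grid-aligned template frame tracked
    by the fiducial marker.  Missing dots are flagged absent.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = fov.center_px
    ys, xs = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    inside = np.hypot(xs - cx, ys - cy) <= fov.radius_px - 1.0
    vals = image[inside]
    med = float(np.median(vals))
    if float(vals.max()) - med < 0.05 * max(np.ptp(vals), 1e-12) or np.ptp(vals) < 1e-9:
        return _absent_set()
    upper = vals[vals >= med]
    thr = threshold_otsu(upper)
    bw = inside & (image > thr)
    labels, n = ndimage.label(bw)
    comps = []
    weights = np.clip(image - med, 0.0, None)
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        wsum = weights[mask].sum()
        if wsum <= 0:
            continue
        yc = float((ys[mask] * weights[mask]).sum() / wsum)
        xc = float((xs[mask] * weights[mask]).sum() / wsum)
        comps.append((xc, yc))
    if len(comps) > 49:
        raise ValueError(f"{len(comps)} bright components found (>49); suspect noise")
    if not comps:
        return _absent_set()
    pts = np.asarray(comps)
    tmpl = normalize_to_template(pts, fov, GRID_ALIGNED_STANDARD_ANGLE_DEG)
    indices = _label_grid(tmpl)
    dots = {i: None for i in range(1, 50)}
    for (x, y), idx in zip(pts, indices):
        if idx is not None and dots[idx] is None:
            dots[idx] = (float(x), float(y))
    return LaserDotSet(
        dots=tuple(
            LaserDot(index=i, position_px=dots[i] or (np.nan, np.nan),
                     present=dots[i] is not None)
            for i in range(1, 50)
        )
    )


def _absent_set() -> LaserDotSet:
    return LaserDotSet(
        dots=tuple(
            LaserDot(index=i, position_px=(np.nan, np.nan), present=False)
            for i in range(1, 50)
        )
    )


def _label_grid(tmpl_pts: np.ndarray):
    """Row-major 7x7 labels for grid-aligned template points (row 1 on top)."""
    n = len(tmpl_pts)
    ys = tmpl_pts[:, 1]
    if n == 49:
        order = np.argsort(-ys)  # template y-up: top row has largest y
        labels = [None] * n
        for row in range(7):
            chunk = order[row * 7 : (row + 1) * 7]
            chunk = chunk[np.argsort(tmpl_pts[chunk, 0])]
            for col, j in enumerate(chunk):
                labels[j] = row * 7 + col + 1
        return labels
    # partial grids: cluster y into <=7 rows by gap splitting
    order = np.argsort(-ys)
    sy = ys[order]
    gaps = -np.diff(sy)
    rows = [[order[0]]]
    pitch = (sy[0] - sy[-1]) / 6.0 if n > 1 else 1.0
    for g, j in zip(gaps, order[1:]):
        if g > 0.5 * max(pitch, 1e-9):
            rows.append([])
        rows[-1].append(j)
    if len(rows) > 7:
        rows = rows[:7]
    labels = [None] * n
    xspan = tmpl_pts[:, 0]
    lo, hi = xspan.min(), xspan.max()
    col_pos = np.linspace(lo, hi, 7) if hi > lo else np.zeros(7)
    for r, members in enumerate(rows):
        members = sorted(members, key=lambda j: tmpl_pts[j, 0])
        taken = set()
        for j in members:
            col = int(np.argmin(np.abs(col_pos - tmpl_pts[j, 0])))
            while col in taken and col < 6:
                col += 1
            taken.add(col)
            labels[j] = r * 7 + col + 1
    return labels


# ---------------------------------------------------------------------------
# Radial lines (Hough)
# ---------------------------------------------------------------------------

def detect_radial_lines(
    image,
    fov: FOVGeometry,
    expected: int = 12,
    theta_step_deg: float = 0.25,
    center_tol_px: float = 4.0,
    ink_quantile: float = 0.5,
) -> np.ndarray:
    """Angles (deg, y-up, in [0, 180)) of radial lines through the FOV centre.

    Lines are found with the Hough transform on the dark-ink mask, kept if
    they pass within ``center_tol_px`` of the FOV centre, deduplicated (the
    two boundaries of opposite sectors share one line), and refined by a
    second-moment orientation fit of the ink pixels near each line.
    """
    image = np.asarray(image, dtype=float)
    cx, cy = fov.center_px
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    u = xs - cx
    v = cy - ys  # y-up
    d = np.hypot(u, v)
    inside = d <= fov.radius_px - 2.0
    thr = threshold_otsu(image[inside])
    ink = inside & (image < thr) & (d > 6.0)
    # Suppress concentric-ring ink: ring edges have radial gradients while
    # radial-line edges have tangential ones (w.r.t. the FOV centre).
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    gy_down = ndimage.sobel(image, axis=0, mode="nearest")
    gy = -gy_down  # y-up
    gmag = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial_frac = np.abs(gx * u + gy * v) / (gmag * np.maximum(d, 1e-9))
    ink = ink & ((gmag < 0.05 * np.ptp(image)) | (radial_frac < 0.5))

    theta = np.deg2rad(np.arange(0.0, 180.0, theta_step_deg))
    hspace, angles, dists = hough_line(ink.astype(np.uint8), theta=theta)
    _, peak_angles, peak_dists = hough_line_peaks(
        hspace, angles, dists,
        num_peaks=4 * expected,
        min_distance=5,
        min_angle=max(1, int(5.0 / theta_step_deg)),
    )
    found = []
    for ang, dist in zip(peak_angles, peak_dists):
        # rho = x cos(t) + y sin(t) in image coords; distance from centre:
        if abs(cx * np.cos(ang) + cy * np.sin(ang) - dist) > center_tol_px:
            continue
        # normal angle (image y-down) -> line orientation (y-up):
        line_deg = (90.0 - np.degrees(ang)) % 180.0
        found.append(line_deg)
    def _dedupe(angles, tol):
        angles = sorted(angles)
        merged = []
        for a in angles:
            if merged and min(abs(a - merged[-1]), 180 - abs(a - merged[-1])) < tol:
                continue
            if merged and min(abs(a - merged[0]), 180 - abs(a - merged[0])) < tol:
                continue
            merged.append(a)
        return merged

    seeds = _dedupe(found, 6.0)
    refined = _dedupe(
        (_refine_line_angle(ink, xs, ys, cx, cy, a) for a in seeds), 3.0
    )
    if len(refined) < expected:
        warnings.warn(
            f"found {len(refined)} radial lines, expected {expected}", stacklevel=2
        )
    return np.asarray(refined)


def _refine_line_angle(ink, xs, ys, cx, cy, angle_deg, band_px=2.0, n_iter=4):
    """Orientation of the ink line through the centre near ``angle_deg``.

    Iterated second-moment fit about the FOV centre: pixels within a
    perpendicular band of the current line estimate (excluding the
    cluttered centre region) vote for the next orientation, so the band
    tracks the line even when the Hough seed is a degree or two off.
    """
    u = xs - cx
    v = cy - ys  # y-up
    d = np.hypot(u, v)
    far = ink & (d > 20.0)
    ang = float(angle_deg)
    for _ in range(n_iter):
        a = np.radians(ang)
        perp = np.abs(-u * np.sin(a) + v * np.cos(a))
        sel = far & (perp <= band_px)
        if sel.sum() < 10:
            return float(ang % 180.0)
        uu, vv = u[sel], v[sel]
        # second moments about the FOV centre (the line passes through it)
        mu20 = np.mean(uu * uu)
        mu02 = np.mean(vv * vv)
        mu11 = np.mean(uu * vv)
        new = np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02))
        # unwrap to the closest equivalent of the previous estimate
        while new - ang > 90.0:
            new -= 180.0
        while new - ang < -90.0:
            new += 180.0
        if abs(new - ang) < 1e-4:
            ang = new
            break
        ang = new
    return float(ang % 180.0)
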