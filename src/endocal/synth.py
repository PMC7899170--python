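"""Synthetic benchtop scenes rendered through the distorted camera model.

Renders ground-truthed analogs of the four benchtop recording sets used to
calibrate and evaluate the measurement method:

* Set 1 -- concentric circular grids (0.5/1/2 mm spacing) at 65 working
  distances in [2, 32] mm, laser off.
* Set 2 -- 7x7 laser-dot frames at 72 working distances in [2, 35] mm.
* Set 3 -- a 24-sector grid (15 degree central angles) at 4 distances.
* Set 4 -- line segments of 5-20 mm at 15 arbitrary poses per condition,
  laser on (105 images).

Patterns are rasterized at >= 4x supersampling and box-downsampled; every
image comes with a truth record carrying exact projected geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import (
    CameraModel,
    LaserProjector,
    default_camera,
    default_projector,
    dot_positions_mm,
    project_point,
)

__all__ = [
    "SceneSpec",
    "render",
    "generate_dataset",
    "save_record",
    "load_record",
    "SET3_DISTANCES_MM",
    "SET4_CONDITIONS",
]

_KINDS = {"circular_grid", "sector_grid", "line_segment", "laser_frame"}

# Rendering conventions (the source recordings do not document target inks
# or line widths; these values keep strip minima and spot thresholding
# well-posed).
BACKGROUND_LEVEL = 0.85
INK_LEVEL = 0.10
OUTSIDE_LEVEL = 0.02
LASER_BACKGROUND_LEVEL = 0.25
LASER_ON_BACKGROUND_LEVEL = 0.45
LASER_ON_INK_LEVEL = 0.05
SPOT_AMPLITUDE = 0.9
LINE_WIDTH_PX = 2.0
FOV_MARGIN_PX = 6.0
FIDUCIAL_RADIUS_PX = 5.0

SET3_DISTANCES_MM = (6.16, 13.20, 19.54, 26.44)
#: (length_mm, working distance_mm) conditions of the Set-4 analog.
SET4_CONDITIONS = (
    (5.0, 20.18),
    (10.0, 20.18),
    (15.0, 20.18),
    (20.0, 20.18),
    (5.0, 5.12),
    (5.0, 9.98),
    (5.0, 14.98),
)


@dataclass(frozen=True)
class SceneSpec:
    """Description of one synthetic target in front of the endoscope."""

    kind: str
    w_mm: float
    spacing_mm: float | None = None
    n_rings: int = 10
    n_sectors: int = 24
    endpoints_mm: tuple[tuple[float, float], tuple[float, float]] | None = None
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (dx_mm, dy_mm, rot_deg)
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if self.w_mm <= 0:
            raise ValueError("working distance must be positive")
        if self.kind in ("circular_grid", "sector_grid") and not self.spacing_mm:
            raise ValueError(f"{self.kind} requires spacing_mm")
        if self.kind == "line_segment" and self.endpoints_mm is None:
            raise ValueError("line_segment requires endpoints_mm")


def _pose_transform(points_mm: np.ndarray, pose) -> np.ndarray:
    dx, dy, rot = pose
    a = np.radians(rot)
    rotm = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return points_mm @ rotm.T + np.array([dx, dy])


def _supersample_coords(camera: CameraModel, factor: int):
    """Centered y-up coordinates of supersampled pixel centres (px units)."""
    h, w = camera.sensor_height_px, camera.sensor_width_px
    cx, cy = camera.fov_center_px
    xs = (np.arange(w * factor) + 0.5) / factor - 0.5 - cx
    ys = cy - ((np.arange(h * factor) + 0.5) / factor - 0.5)
    return np.meshgrid(xs, ys)


def _project_polyline(camera, pts_mm, w):
    """Project sampled mm polyline points to centred y-up pixel coordinates."""
    r_mm = np.hypot(pts_mm[:, 0], pts_mm[:, 1])
    phi = np.arctan2(pts_mm[:, 1], pts_mm[:, 0])
    r_px = camera.pixel_radius(np.arctan(r_mm / w))
    return np.column_stack([r_px * np.cos(phi), r_px * np.sin(phi)])


def _rasterize_paths(camera, paths_px, factor, shape_ss):
    """Mark projected paths (centred y-up px coords) on the supersampled grid."""
    cx, cy = camera.fov_center_px
    canvas = np.zeros(shape_ss, dtype=bool)
    for path in paths_px:
        col = np.round((path[:, 0] + cx + 0.5) * factor - 0.5).astype(int)
        row = np.round((cy - path[:, 1] + 0.5) * factor - 0.5).astype(int)
        ok = (row >= 0) & (row < shape_ss[0]) & (col >= 0) & (col < shape_ss[1])
        canvas[row[ok], col[ok]] = True
    half = LINE_WIDTH_PX / 2.0
    rad = int(np.ceil(half * factor))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    selem = (xx**2 + yy**2) <= (half * factor) ** 2
    return ndimage.binary_dilation(canvas, structure=selem)


def _downsample(img_ss: np.ndarray, factor: int) -> np.ndarray:
    h, w = img_ss.shape[0] // factor, img_ss.shape[1] // factor
    return img_ss.reshape(h, factor, w, factor).mean(axis=(1, 3))


def _sample_circle(r_mm, n=3000):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r_mm * np.cos(t), r_mm * np.sin(t)])


def _sample_segment(a_mm, b_mm, n=2500):
    t = np.linspace(0.0, 1.0, n)[:, None]
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    return a + t * (b - a)


def render(
    camera: CameraModel,
    spec: SceneSpec,
    projector: LaserProjector | None = None,
    seed: int = 0,
    supersample: int = 4,
):
    """Render one scene; returns ``(image, truth)``.

    ``image`` is a float array in [0, 1] of shape (height, width); ``truth``
    is a JSON-serializable record with the exact projected geometry (circle
    radii in px and mm, dot centres, line endpoints, sector angles).
    """
    if spec.kind == "laser_frame" and projector is None:
        raise ValueError("laser_frame scenes require a projector")
    factor = int(supersample)
    if factor < 4:
        raise ValueError("supersampling factor must be >= 4")
    w = spec.w_mm
    cx, cy = camera.fov_center_px
    X, Y = _supersample_coords(camera, factor)
    d = np.hypot(X, Y)
    shape_ss = d.shape

    fov_mask = d <= camera.fov_radius_px
    fa = np.radians(camera.fiducial_angle_deg)
    fid_c = (
        (camera.fov_radius_px + 2.0) * np.cos(fa),
        (camera.fov_radius_px + 2.0) * np.sin(fa),
    )
    fid_mask = np.hypot(X - fid_c[0], Y - fid_c[1]) <= FIDUCIAL_RADIUS_PX
    bright = fov_mask | fid_mask

    truth: dict = {
        "kind": spec.kind,
        "w_mm": w,
        "fov": {
            "cx": cx,
            "cy": cy,
            "radius_px": camera.fov_radius_px,
            "fiducial_angle_deg": camera.fiducial_angle_deg,
        },
    }
    max_r_px = camera.fov_radius_px - FOV_MARGIN_PX

    centred_pose = spec.pose[0] == 0.0 and spec.pose[1] == 0.0

    if spec.kind in ("circular_grid", "sector_grid"):
        bg = np.where(bright, BACKGROUND_LEVEL, OUTSIDE_LEVEL)
        radii_mm, radii_px = [], []
        for k in range(1, spec.n_rings + 1):
            r_mm = k * spec.spacing_mm
            r_px = float(camera.pixel_radius(np.arctan(r_mm / w)))
            if r_px > max_r_px:
                break
            radii_mm.append(r_mm)
            radii_px.append(r_px)
        if not radii_mm:
            raise ValueError(f"pattern entirely outside FOV for {spec}")
        truth["spacing_mm"] = spec.spacing_mm
        truth["circles"] = [
            {"r_mm": rm, "r_px": rp} for rm, rp in zip(radii_mm, radii_px)
        ]
        if centred_pose:
            ink = np.zeros(shape_ss, dtype=bool)
            for r_px in radii_px:
                ink |= np.abs(d - r_px) <= LINE_WIDTH_PX / 2.0
        else:  # general path: translated grids distort into non-circles
            paths = [
                _project_polyline(camera, _pose_transform(_sample_circle(rm), spec.pose), w)
                for rm in radii_mm
            ]
            ink = _rasterize_paths(camera, paths, factor, shape_ss)
        if spec.kind == "sector_grid":
            outer = radii_mm[-1]
            n_lines = spec.n_sectors // 2
            base = spec.pose[2] % 180.0
            angles = sorted((base + 180.0 * i / n_lines) % 180.0 for i in range(n_lines))
            truth["sector_angles_deg"] = angles
            paths = []
            for ang in angles:
                a = np.radians(ang)
                seg = _sample_segment(
                    (-outer * np.cos(a), -outer * np.sin(a)),
                    (outer * np.cos(a), outer * np.sin(a)),
                )
                if not centred_pose:
                    seg = _pose_transform(seg, (spec.pose[0], spec.pose[1], 0.0))
                paths.append(_project_polyline(camera, seg, w))
            ink |= _rasterize_paths(camera, paths, factor, shape_ss)
        img_ss = np.where(ink & fov_mask, INK_LEVEL, bg)
        img = _downsample(img_ss, factor)

    elif spec.kind == "line_segment":
        # laser-on scenes are exposed for the (much brighter) laser spots,
        # which pushes the illuminated paper to mid-scale
        level = LASER_ON_BACKGROUND_LEVEL if projector is not None else BACKGROUND_LEVEL
        ink_level = LASER_ON_INK_LEVEL if projector is not None else INK_LEVEL
        bg = np.where(bright, level, OUTSIDE_LEVEL)
        a_mm, b_mm = np.asarray(spec.endpoints_mm, dtype=float)
        seg = _pose_transform(np.vstack([a_mm, b_mm]), spec.pose)
        pa = project_point(camera, seg[0], w)
        pb = project_point(camera, seg[1], w)
        if not (pa.in_fov or pb.in_fov):
            raise ValueError(f"pattern entirely outside FOV for {spec}")
        path = _project_polyline(camera, _sample_segment(seg[0], seg[1]), w)
        ink = _rasterize_paths(camera, [path], factor, shape_ss)
        img = _downsample(np.where(ink & fov_mask, ink_level, bg), factor)
        truth["line"] = {
            "ax": pa.x, "ay": pa.y, "bx": pb.x, "by": pb.y,
            "ax_mm": seg[0, 0], "ay_mm": seg[0, 1],
            "bx_mm": seg[1, 0], "by_mm": seg[1, 1],
            "len_mm": float(np.linalg.norm(seg[1] - seg[0])),
        }

    elif spec.kind == "laser_frame":
        img_ss = np.where(bright, LASER_BACKGROUND_LEVEL, OUTSIDE_LEVEL)
        img = _downsample(img_ss, factor)

    if projector is not None and spec.kind in ("laser_frame", "line_segment"):
        pts_mm = dot_positions_mm(projector, w)
        h, wpx = img.shape
        dots = []
        sig = projector.spot_sigma_px
        sig2 = 2.0 * sig**2
        win = int(np.ceil(5.0 * sig))
        for i, p in enumerate(pts_mm, start=1):
            pp = project_point(camera, p, w)
            visible = pp.r_px <= camera.fov_radius_px - 2.0
            dots.append(
                {"index": i, "x": pp.x, "y": pp.y, "in_fov": bool(visible)}
            )
            if visible:
                r0 = max(0, int(pp.y) - win)
                r1 = min(h, int(pp.y) + win + 1)
                c0 = max(0, int(pp.x) - win)
                c1 = min(wpx, int(pp.x) + win + 1)
                xs = np.arange(c0, c1, dtype=float)
                ys = np.arange(r0, r1, dtype=float)
                img[r0:r1, c0:c1] += SPOT_AMPLITUDE * np.exp(
                    -((xs[None, :] - pp.x) ** 2 + (ys[:, None] - pp.y) ** 2) / sig2
                )
        truth["dots"] = dots

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return np.clip(img, 0.0, 1.0), truth


# ---------------------------------------------------------------------------
# Dataset generators
# ---------------------------------------------------------------------------

def _set1_specs(noise_sigma=0.0):
    sweeps = [np.linspace(2.0, 32.0, n) for n in (22, 22, 21)]
    specs = []
    for sweep in sweeps:
        for w in sweep:
            spacing = 0.5 if w < 10 else (1.0 if w < 20 else 2.0)
            specs.append(
                SceneSpec("circular_grid", w_mm=float(w), spacing_mm=spacing,
                          noise_sigma=noise_sigma)
            )
    return specs


def _set2_specs(noise_sigma=0.0):
    return [
        SceneSpec("laser_frame", w_mm=float(w), noise_sigma=noise_sigma)
        for _ in range(4)
        for w in np.linspace(2.0, 35.0, 18)
    ]


def _set3_specs(rng, noise_sigma=0.0):
    return [
        SceneSpec("sector_grid", w_mm=w, spacing_mm=2.0,
                  pose=(0.0, 0.0, float(rng.uniform(0.0, 15.0))),
                  noise_sigma=noise_sigma)
        for w in SET3_DISTANCES_MM
    ]


def _set4_specs(camera, rng, noise_sigma=0.0):
    theta_max = camera.theta_max()
    specs = []
    for length, w in SET4_CONDITIONS:
        r_limit = 0.92 * w * np.tan(theta_max)
        for _ in range(15):
            for _attempt in range(1000):
                rot = rng.uniform(0.0, 360.0)
                c = rng.uniform(-r_limit, r_limit, size=2)
                a = np.radians(rot)
                half = 0.5 * length * np.array([np.cos(a), np.sin(a)])
                pa, pb = c - half, c + half
                if max(np.linalg.norm(pa), np.linalg.norm(pb)) > r_limit:
                    continue
                if min(np.linalg.norm(pa), np.linalg.norm(pb)) < 0.05 * w:
                    continue  # keep endpoints off the FOV centre
                break
            else:
                raise RuntimeError("could not place line segment inside FOV")
            specs.append(
                SceneSpec(
                    "line_segment", w_mm=w,
                    endpoints_mm=(tuple(pa), tuple(pb)),
                    noise_sigma=noise_sigma,
                )
            )
    return specs


def generate_dataset(
    set_id: int,
    camera: CameraModel | None = None,
    projector: LaserProjector | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
    supersample: int = 4,
):
    """Render a full synthetic analog of one benchtop recording set.

    Returns a list of ``{"image", "truth", "spec"}`` records.  Sets 2 and 4
    use the (default) laser projector; sets 1 and 3 are laser-off.
    """
    camera = camera or default_camera()
    rng = np.random.default_rng(seed)
    if set_id == 1:
        specs, use_laser = _set1_specs(noise_sigma), False
    elif set_id == 2:
        specs, use_laser = _set2_specs(noise_sigma), True
    elif set_id == 3:
        specs, use_laser = _set3_specs(rng, noise_sigma), False
    elif set_id == 4:
        specs, use_laser = _set4_specs(camera, rng, noise_sigma), True
    else:
        raise ValueError(f"unknown set_id {set_id!r}")
    if use_laser and projector is None:
        projector = default_projector()
    records = []
    for i, spec in enumerate(specs):
        img, truth = render(
            camera, spec, projector=projector if use_laser else None,
            seed=int(rng.integers(0, 2**31 - 1)), supersample=supersample,
        )
        truth["recording_id"] = i
        records.append({"image": img, "truth": truth, "spec": spec})
    return records


# ---------------------------------------------------------------------------
# Disk IO (16-bit grayscale PNG + JSON truth sidecar)
# ---------------------------------------------------------------------------

def save_record(record, stem):
    """Write ``<stem>.png`` (16-bit grayscale) and ``<stem>.json`` truth."""
    import imageio.v3 as iio

    img16 = np.round(record["image"] * 65535.0).astype(np.uint16)
    iio.imwrite(f"{stem}.png", img16)
    with open(f"{stem}.json", "w") as fh:
        json.dump(record["truth"], fh, indent=1)


def load_record(stem):
    import imageio.v3 as iio

    img = iio.imread(f"{stem}.png").astype(float) / 65535.0
    with open(f"{stem}.json") as fh:
        truth = json.load(fh)
    return {"image": img, "truth": truth, "spec": None}
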