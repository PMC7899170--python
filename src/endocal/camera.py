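"""Forward camera model of a wide-angle fiberoptic endoscope.

The imaging chain is modelled as a radially symmetric fisheye projector: a
scene point on the target plane at working distance ``w`` (mm) subtends an
off-axis angle ``theta = arctan(r_mm / w)`` at the pinhole and lands at a
pixel radius ``r_px = c1*theta + c3*theta**3 + c5*theta**5`` from the centre
of the field of view (FOV).  Azimuth is preserved exactly, so central angles
are undistorted while radial spacing is compressed toward the periphery --
the two signatures of the distortion seen in flexible endoscopy.

The default coefficients are calibrated (least squares on three pixel
anchors) so that for a 0.5 mm circular grid the spacing of the two smallest
circles is 30 px at ``w = 2.87`` mm and 35.5 px at ``w = 2.24`` mm, and the
ring spacing falls to 20 px near the FOV border at ``w = 2.87`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CameraModel",
    "LaserProjector",
    "ProjectedPoint",
    "DEFAULT_DISTORTION_COEFFS",
    "default_camera",
    "default_projector",
    "calibrate_distortion",
    "project_point",
    "pixel_radius",
    "invert_pixel_radius",
    "dot_positions_mm",
]

#: Odd-polynomial fisheye coefficients (c1, c3, c5) of r_px(theta),
#: calibrated against the three pixel-spacing anchors described above.
DEFAULT_DISTORTION_COEFFS = (200.83189997, -97.22066975, 115.40841042)

#: Pixel-spacing anchors used to calibrate the default distortion:
#: (spacing_mm pair (r_a, r_b), working distance mm, target pixel spacing).
DISTORTION_ANCHORS = (
    ((0.5, 1.0), 2.87, 30.0),
    ((0.5, 1.0), 2.24, 35.5),
    ((2.0, 2.5), 2.87, 20.0),
)


@dataclass(frozen=True)
class ProjectedPoint:
    """Image-plane location of a projected scene point.

    ``x``/``y`` are storage pixel coordinates (x rightward, y downward,
    0-based, pixel centres on integers).  ``in_fov`` is False when the
    pixel radius exceeds the FOV radius; coordinates are still returned.
    """

    x: float
    y: float
    r_px: float
    in_fov: bool


@dataclass(frozen=True)
class CameraModel:
    sensor_width_px: int = 288
    sensor_height_px: int = 280
    fov_center_px: tuple[float, float] = (144.0, 140.0)
    fov_radius_px: float = 135.0
    distortion_coeffs: tuple[float, float, float] = DEFAULT_DISTORTION_COEFFS
    fiducial_angle_deg: float = 30.0
    bit_depth: int = 12

    def pixel_radius(self, theta):
        """Pixel radius for off-axis angle(s) ``theta`` (radians)."""
        c1, c3, c5 = self.distortion_coeffs
        theta = np.asarray(theta, dtype=float)
        out = c1 * theta + c3 * theta**3 + c5 * theta**5
        return out if out.ndim else float(out)

    def theta_max(self) -> float:
        """Off-axis angle mapped onto the FOV rim (admissible range bound)."""
        return brentq(
            lambda t: self.pixel_radius(t) - self.fov_radius_px, 1e-9, np.pi / 2 - 1e-9
        )

    def invert_pixel_radius(self, r_px: float) -> float:
        """Off-axis angle whose image lands at pixel radius ``r_px``."""
        if r_px < 0:
            raise ValueError("pixel radius must be non-negative")
        if r_px == 0:
            return 0.0
        hi = self.theta_max()
        # allow slight extrapolation beyond the rim
        while self.pixel_radius(hi) < r_px:
            hi *= 1.1
            if hi > np.pi / 2:
                raise ValueError(f"pixel radius {r_px} outside invertible range")
        return brentq(lambda t: self.pixel_radius(t) - r_px, 0.0, hi)

    def mm_radius(self, r_px: float, w: float) -> float:
        """Exact scene mm radius of a point at pixel radius ``r_px``, plane at ``w``."""
        return w * np.tan(self.invert_pixel_radius(r_px))


def default_camera(**overrides) -> CameraModel:
    return replace(CameraModel(), **overrides) if overrides else CameraModel()


def calibrate_distortion(anchors=DISTORTION_ANCHORS) -> tuple[float, float, float]:
    """Solve (c1, c3, c5) from three pixel-spacing anchors.

    Each anchor fixes the pixel spacing between two concentric circles of
    mm radii (r_a, r_b) imaged at working distance w.  The odd polynomial is
    linear in its coefficients, so three anchors determine them exactly.
    """
    rows, rhs = [], []
    for (r_a, r_b), w, spacing_px in anchors:
        ta, tb = np.arctan(r_a / w), np.arctan(r_b / w)
        rows.append([tb - ta, tb**3 - ta**3, tb**5 - ta**5])
        rhs.append(spacing_px)
    c = np.linalg.solve(np.asarray(rows), np.asarray(rhs))
    return tuple(float(v) for v in c)


def pixel_radius(camera: CameraModel, r_mm, w):
    """Pixel radius of a scene point ``r_mm`` off-axis on the plane at ``w``."""
    if w <= 0:
        raise ValueError("working distance must be positive")
    return camera.pixel_radius(np.arctan(np.asarray(r_mm, dtype=float) / w))


def invert_pixel_radius(camera: CameraModel, r_px, w):
    """Scene mm radius corresponding to image pixel radius ``r_px`` at ``w``."""
    if w <= 0:
        raise ValueError("working distance must be positive")
    return camera.mm_radius(r_px, w)


def project_point(camera: CameraModel, point_mm, w: float) -> ProjectedPoint:
    """Project a scene point (x, y) mm on the plane at working distance ``w``.

    Scene coordinates are y-up with the optical axis at the origin; the
    returned pixel coordinates are y-down storage coordinates.
    """
    if w <= 0:
        raise ValueError("working distance must be positive")
    x_mm, y_mm = float(point_mm[0]), float(point_mm[1])
    r_mm = float(np.hypot(x_mm, y_mm))
    phi = float(np.arctan2(y_mm, x_mm))
    r_px = float(camera.pixel_radius(np.arctan(r_mm / w)))
    cx, cy = camera.fov_center_px
    return ProjectedPoint(
        x=cx + r_px * np.cos(phi),
        y=cy - r_px * np.sin(phi),
        r_px=r_px,
        in_fov=r_px <= camera.fov_radius_px,
    )


# ---------------------------------------------------------------------------
# Laser projector
# ---------------------------------------------------------------------------

#: Row aiming angles (deg, scene y-up; row 1 is the top image row) of the 7x7
#: fan.  The top row is aimed most obliquely -- a simulator convention that
#: geometrically mimics the degraded behaviour of top-row points reported for
#: the physical device.
_ROW_ANGLES_DEG = (24.0, 14.0, 8.4, 2.8, -2.8, -8.4, -14.0)
#: Column aiming angles (deg), left image column first.  The fan is tilted to
#: the same side as the projection-channel offset so that no ray crosses the
#: optical axis anywhere in the simulated working range: every dot's pixel
#: radius is then monotone in the working distance, as in the physical device.
_COL_ANGLES_DEG = (1.0, 4.333, 7.667, 11.0, 14.333, 17.667, 21.0)
#: Offset of the projection channel from the camera pinhole (mm, scene x).
_CHANNEL_OFFSET_MM = (0.5, 0.0, 0.0)


@dataclass(frozen=True)
class LaserProjector:
    """Bundle of 49 diverging laser rays indexed row-major 1..49.

    ``ray_origins_mm`` are offsets of the projection channel from the camera
    pinhole; ``ray_directions`` are unit vectors with positive z toward the
    scene.  Index 1 is the top-left point as seen in the image.
    """

    ray_origins_mm: np.ndarray = field(repr=False, default=None)
    ray_directions: np.ndarray = field(repr=False, default=None)
    spot_sigma_px: float = 1.2

    def __post_init__(self):
        if self.ray_origins_mm is None or self.ray_directions is None:
            raise ValueError("ray origins and directions are required")
        if self.ray_origins_mm.shape != (49, 3) or self.ray_directions.shape != (49, 3):
            raise ValueError("projector must define exactly 49 rays")


def default_projector(spot_sigma_px: float = 1.2) -> LaserProjector:
    origins = np.tile(np.asarray(_CHANNEL_OFFSET_MM, dtype=float), (49, 1))
    dirs = np.empty((49, 3))
    k = 0
    for ay in _ROW_ANGLES_DEG:
        for ax in _COL_ANGLES_DEG:
            d = np.array([np.tan(np.radians(ax)), np.tan(np.radians(ay)), 1.0])
            dirs[k] = d / np.linalg.norm(d)
            k += 1
    return LaserProjector(
        ray_origins_mm=origins, ray_directions=dirs, spot_sigma_px=spot_sigma_px
    )


def dot_positions_mm(projector: LaserProjector, w: float) -> np.ndarray:
    """Scene (x, y) mm of all 49 ray/plane intersections at working distance ``w``.

    The camera pinhole sits at the scene origin and the target plane at
    depth ``w``; each ray ``o + t d`` meets it where ``o_z + t d_z = w``.
    """
    if w <= 0:
        raise ValueError("working distance must be positive")
    o, d = projector.ray_origins_mm, projector.ray_directions
    t = (w - o[:, 2]) / d[:, 2]
    return o[:, :2] + t[:, None] * d[:, :2]
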