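"""Sagittal-camera model: pinhole central projection and planar calibration.

The 2D capture setup is a fixed camera viewing the walkway from the side, its
optical axis normal to the sagittal plane of progression. Metric calibration
uses a one-metre square held in the walkway plane, which fixes a
metres-per-pixel scale *valid only for points on that plane*: a point a
distance ``d`` from the camera (instead of the calibration distance ``D``)
appears scaled by ``D / d`` after the plane-calibrated back-conversion. That
central-projection error is the main systematic difference between planar
video analysis and true 3D reconstruction, so it is modelled explicitly.

Lab frame convention: x = walking direction, y = mediolateral (left
positive), z = vertical. Image convention: origin top-left, u rightward,
v downward, pixel centres at integer coordinates. The plane-calibrated
back-conversion flips v so the returned metric coordinates are y-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = ["CameraModel", "Calibration2D", "project", "calibrate",
           "pixel_resolution", "pixels_to_meters"]


@dataclass
class CameraModel:
    """Pinhole side-view camera.

    Defaults describe a 640x480 machine-vision camera imaging a
    3.36 m x 1.58 m field from 2.5 m. ``side`` selects which side of the
    walkway the camera stands on: ``"right"`` places it at negative y looking
    in +y, ``"left"`` at positive y looking in -y.
    """

    image_width: int = 640
    image_height: int = 480
    field_width: float = 3.36
    field_height: float = 1.58
    distance_to_plane: float = 2.5
    frame_rate: float = 100.0
    side: str = "right"
    center_x: float = 0.0          # lab x of the optical axis
    center_z: float = 0.70         # lab z (height) of the optical axis
    #: distance from the walkway midline (y = 0) to the calibration plane,
    #: toward the camera (m). Calibrating in the near-side marker plane
    #: rather than the body midline minimizes the central-projection scale
    #: error for the markers the 2D analysis actually tracks.
    calibration_plane_offset: float = 0.10
    principal_point: tuple[float, float] | None = None

    def __post_init__(self):
        for name in ("image_width", "image_height", "field_width", "field_height",
                     "distance_to_plane", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"camera {name} must be positive")
        if self.side not in ("left", "right"):
            raise ConfigurationError("camera side must be 'left' or 'right'")
        if self.principal_point is None:
            self.principal_point = (self.image_width / 2.0, self.image_height / 2.0)

    # focal lengths in pixels, implied by field extent at the plane distance
    @property
    def fx(self) -> float:
        return self.distance_to_plane * self.image_width / self.field_width

    @property
    def fy(self) -> float:
        return self.distance_to_plane * self.image_height / self.field_height

    @property
    def position(self) -> np.ndarray:
        sign = -1.0 if self.side == "right" else 1.0
        return np.array([self.center_x,
                         sign * (self.distance_to_plane + self.calibration_plane_offset),
                         self.center_z])

    def plane_scale_x(self) -> float:
        """Metres per pixel, horizontal, on the calibration plane."""
        return pixel_resolution(self.field_width, self.image_width)

    def plane_scale_y(self) -> float:
        """Metres per pixel, vertical, on the calibration plane."""
        return pixel_resolution(self.field_height, self.image_height)


def pixel_resolution(field_extent: float, pixels: int) -> float:
    """Metres per pixel for a field extent imaged onto a pixel count."""
    if field_extent <= 0:
        raise ConfigurationError("field extent must be positive")
    if pixels <= 0:
        raise ConfigurationError("pixel count must be positive")
    return field_extent / pixels


def project(point_3d, camera: CameraModel) -> np.ndarray:
    """Central projection of lab-frame points into pixel coordinates.

    ``point_3d`` is an array of shape (3,) or (N, 3). Points at or behind the
    camera plane are rejected.
    """
    p = np.atleast_2d(np.asarray(point_3d, dtype=float))
    if p.shape[-1] != 3:
        raise DataError("points must have 3 components (x, y, z)")
    cam = camera.position
    # depth along the optical axis (always towards the walkway)
    if camera.side == "right":
        d = p[:, 1] - cam[1]
    else:
        d = cam[1] - p[:, 1]
    if np.any(d <= 0):
        raise DataError("point at or behind the camera plane")
    ppx, ppy = camera.principal_point
    # for a right-side camera looking in +y, lab +x maps to image +u;
    # a left-side camera sees the walk mirrored
    xsign = 1.0 if camera.side == "right" else -1.0
    u = ppx + xsign * camera.fx * (p[:, 0] - cam[0]) / d
    v = ppy - camera.fy * (p[:, 2] - cam[2]) / d
    out = np.column_stack([u, v])
    return out[0] if np.asarray(point_3d).ndim == 1 else out


@dataclass
class Calibration2D:
    """Planar metric calibration from the one-metre calibration square.

    Valid only for points on the calibration plane; off-plane points suffer
    the ``D/d`` central-projection scale error.
    """

    meters_per_pixel_x: float
    meters_per_pixel_y: float
    origin_px: tuple[float, float]
    calibration_plane_distance: float = 2.5
    mirrored: bool = field(default=False)

    def __post_init__(self):
        if self.meters_per_pixel_x <= 0 or self.meters_per_pixel_y <= 0:
            raise ConfigurationError("calibration scales must be positive")


def calibrate(square_corner_pixels, square_side: float,
              plane_distance: float = 2.5, mirrored: bool = False) -> Calibration2D:
    """Metric calibration from the four imaged corners of a square.

    Corners must be ordered (bottom-left, bottom-right, top-right, top-left in
    image terms) and non-degenerate. The horizontal scale comes from the mean
    pixel length of the two horizontal edges, the vertical scale from the two
    vertical edges; the origin is the square centre.
    """
    c = np.asarray(square_corner_pixels, dtype=float)
    if c.shape != (4, 2):
        raise DataError("expected 4 corner points of shape (4, 2)")
    if square_side <= 0:
        raise ConfigurationError("square side must be positive")
    # degenerate quadrilateral: all collinear or repeated points (shoelace)
    x, y = c[:, 0], c[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if area < 1e-9:
        raise DataError("degenerate calibration quadrilateral (collinear corners)")
    horiz = 0.5 * (np.abs(c[1, 0] - c[0, 0]) + np.abs(c[2, 0] - c[3, 0]))
    vert = 0.5 * (np.abs(c[3, 1] - c[0, 1]) + np.abs(c[2, 1] - c[1, 1]))
    if horiz < 1e-9 or vert < 1e-9:
        raise DataError("degenerate calibration quadrilateral (zero edge length)")
    return Calibration2D(
        meters_per_pixel_x=square_side / horiz,
        meters_per_pixel_y=square_side / vert,
        origin_px=tuple(c.mean(axis=0)),
        calibration_plane_distance=plane_distance,
        mirrored=mirrored,
    )


def pixels_to_meters(pixels, calibration: Calibration2D) -> np.ndarray:
    """Convert pixel coordinates to metric sagittal coordinates (y-up).

    Exact for points on the calibration plane; off-plane points carry the
    central-projection scale error by construction.
    """
    p = np.atleast_2d(np.asarray(pixels, dtype=float))
    ox, oy = calibration.origin_px
    xsign = -1.0 if calibration.mirrored else 1.0
    x = xsign * (p[:, 0] - ox) * calibration.meters_per_pixel_x
    zz = -(p[:, 1] - oy) * calibration.meters_per_pixel_y   # image v is down
    out = np.column_stack([x, zz])
    return out[0] if np.asarray(pixels).ndim == 1 else out


def calibration_from_camera(camera: CameraModel, square_side: float = 1.0,
                            square_center=None) -> Calibration2D:
    """Simulate imaging the calibration square and calibrate from it.

    The square is placed in the walkway plane (y = 0), centred on the optical
    axis unless ``square_center=(x, z)`` is given.
    """
    if square_center is None:
        cx, cz = camera.center_x, camera.center_z
    else:
        cx, cz = square_center
    sign = -1.0 if camera.side == "right" else 1.0
    y_plane = sign * camera.calibration_plane_offset
    h = square_side / 2.0
    corners_lab = np.array([
        [cx - h, y_plane, cz - h],
        [cx + h, y_plane, cz - h],
        [cx + h, y_plane, cz + h],
        [cx - h, y_plane, cz + h],
    ])
    px = project(corners_lab, camera)
    if camera.side == "left":
        # ordering convention: make the first edge run left-to-right in image space
        px = px[[1, 0, 3, 2]]
    return calibrate(px, square_side, plane_distance=camera.distance_to_plane,
                     mirrored=(camera.side == "left"))
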