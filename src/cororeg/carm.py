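"""C-arm perspective projection geometry.

Five DICOM attributes define the acquisition: the primary positioner angle
(LAO positive / RAO negative, gantry rotation about the patient y axis), the
secondary positioner angle (CRA positive / CAU negative, about the patient x
axis), the imager pixel spacing, the source-to-detector distance (SID) and
the source-to-patient distance (SOD).  Projection is perspective: a point at
the isocenter is magnified by SID/SOD onto the detector.

Conventions: the isocenter is the origin of the rotated (camera) frame; the
X-ray source sits at z = -SOD on the camera z axis and the detector plane at
z = SID - SOD.  Detector coordinates (u, v) are millimetres with the origin
at the detector centre, +u rightward and +v downward in image space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CArmGeometry", "parse_geometry", "project", "project_depth", "backproject_ray"]

_REQUIRED_TAGS = {
    "PositionerPrimaryAngle": (0x0018, 0x1510),
    "PositionerSecondaryAngle": (0x0018, 0x1511),
    "ImagerPixelSpacing": (0x0018, 0x1164),
    "DistanceSourceToDetector": (0x0018, 0x1110),
    "DistanceSourceToPatient": (0x0018, 0x1111),
}


@dataclass(frozen=True)
class CArmGeometry:
    primary_angle_deg: float
    secondary_angle_deg: float
    pixel_spacing_mm: float
    sid_mm: float
    sod_mm: float
    image_size_px: tuple[int, int] = (512, 512)
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.sid_mm > self.sod_mm > 0):
            raise ValueError("require sid_mm > sod_mm > 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def magnification(self) -> float:
        """Magnification of an object at the isocenter: SID/SOD."""
        return self.sid_mm / self.sod_mm

    def rotation(self) -> np.ndarray:
        """Patient -> camera rotation: secondary (about x) after primary (about y)."""
        a = np.deg2rad(self.primary_angle_deg)
        b = np.deg2rad(self.secondary_angle_deg)
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        ry = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
        rx = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]])
        return rx @ ry

    def with_isocenter(self, iso) -> "CArmGeometry":
        return CArmGeometry(self.primary_angle_deg, self.secondary_angle_deg,
                            self.pixel_spacing_mm, self.sid_mm, self.sod_mm,
                            self.image_size_px, tuple(float(x) for x in iso))

    # -- raster <-> metric detector coordinates -----------------------
    def mm_to_px(self, uv: np.ndarray) -> np.ndarray:
        """Detector mm -> pixel (col, row); pixel (0,0) centre at the image corner."""
        uv = np.atleast_2d(uv)
        rows, cols = self.image_size_px
        centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
        return uv / self.pixel_spacing_mm + centre

    def px_to_mm(self, px: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(px)
        rows, cols = self.image_size_px
        centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
        return (px - centre) * self.pixel_spacing_mm


def parse_geometry(dicom_header, image_size_px: tuple[int, int] | None = None) -> CArmGeometry:
    """Build a :class:`CArmGeometry` from a DICOM header (pydicom Dataset or mapping).

    Raises ``KeyError`` naming the first missing attribute.
    """
    values = {}
    for keyword, tag in _REQUIRED_TAGS.items():
        val = None
        if hasattr(dicom_header, "get"):
            val = dicom_header.get(keyword, None)
        if val is None and hasattr(dicom_header, keyword):
            val = getattr(dicom_header, keyword)
        if val is None:
            raise KeyError(f"missing DICOM attribute {keyword} {tag}")
        values[keyword] = val
    spacing = values["ImagerPixelSpacing"]
    try:
        spacing = float(spacing[0])
    except (TypeError, IndexError):
        spacing = float(spacing)
    if image_size_px is None:
        rows = getattr(dicom_header, "Rows", None) or (
            dicom_header.get("Rows") if hasattr(dicom_header, "get") else None) or 512
        cols = getattr(dicom_header, "Columns", None) or (
            dicom_header.get("Columns") if hasattr(dicom_header, "get") else None) or 512
        image_size_px = (int(rows), int(cols))
    return CArmGeometry(
        primary_angle_deg=float(values["PositionerPrimaryAngle"]),
        secondary_angle_deg=float(values["PositionerSecondaryAngle"]),
        pixel_spacing_mm=spacing,
        sid_mm=float(values["DistanceSourceToDetector"]),
        sod_mm=float(values["DistanceSourceToPatient"]),
        image_size_px=image_size_px,
    )


def _camera_coords(points: np.ndarray, g: CArmGeometry) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - np.asarray(g.isocenter)) @ g.rotation().T


def project(points: np.ndarray, g: CArmGeometry) -> np.ndarray:
    """Perspective projection of 3D patient-space points to detector mm.

    (u, v) = SID / (SOD + z_cam) * (x_cam, y_cam).  Points at or behind the
    source (SOD + z <= eps) raise ``ValueError``.
    """
    cam = _camera_coords(points, g)
    denom = g.sod_mm + cam[:, 2]
    if np.any(denom <= 1e-9):
        raise ValueError("point at or behind the X-ray source")
    scale = g.sid_mm / denom
    return cam[:, :2] * scale[:, None]


def project_depth(points: np.ndarray, g: CArmGeometry) -> np.ndarray:
    """Camera-frame depth z (mm, 0 at isocenter, positive toward the detector)."""
    return _camera_coords(points, g)[:, 2]


def backproject_ray(p2: np.ndarray, g: CArmGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Source ray through a detector point: (origin, unit direction) in patient space.

    Every point on the returned ray projects back onto ``p2``.
    """
    p2 = np.asarray(p2, dtype=float).reshape(2)
    if not np.all(np.isfinite(p2)):
        raise ValueError("non-finite detector point")
    r = g.rotation()
    source_cam = np.array([0.0, 0.0, -g.sod_mm])
    detector_cam = np.array([p2[0], p2[1], g.sid_mm - g.sod_mm])
    origin = r.T @ source_cam + np.asarray(g.isocenter)
    direction = r.T @ (detector_cam - source_cam)
    return origin, direction / np.linalg.norm(direction)


def point_to_ray_distance(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Perpendicular distance from 3D points to a ray (treated as an infinite line)."""
    pts = np.atleast_2d(points)
    w = pts - origin
    t = w @ direction
    perp = w - t[:, None] * direction[None, :]
    return np.linalg.norm(perp, axis=1)
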