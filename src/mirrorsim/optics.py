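"""Planar-mirror virtual-image optics and perspective projection of discs.

The virtual mirror works like the real instrument: a mirror-image camera sits
symmetrically to the viewer's eye across the mirror plane, so what appears on
the mirror surface is the perspective image of each object's *virtual image*
(the object reflected through the mirror plane).  Objects between the mirror
surface and the virtual image are deliberately ignored — the mirror content is
never occluded by intervening geometry, only clipped to the mirror rim (which
happens at the raster stage).

A circular disc seen through a pinhole camera projects to an exact ellipse as
long as the whole disc is in front of the camera.  ``project_disc`` samples the
disc boundary and fits the exact conic; no clipping is supported at this
analytic level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Vec3",
    "ViewerCamera",
    "MirrorPlane",
    "MirrorDisc",
    "LesionDisc",
    "ImageEllipse",
    "reflect_point",
    "reflect_direction",
    "virtual_image_of_disc",
    "project_point",
    "project_disc",
    "mirror_view",
    "point_in_ellipse",
    "disc_boundary",
    "orthonormal_frame",
]

Vec3 = np.ndarray  # shape (3,), float64, scene millimetres


def _vec(v) -> Vec3:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


def _unit(v) -> Vec3:
    a = _vec(v)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return a / n


def orthonormal_frame(normal: Vec3) -> tuple[Vec3, Vec3]:
    """Two unit vectors spanning the plane orthogonal to ``normal``."""
    n = _unit(normal)
    helper = np.array([0.0, 1.0, 0.0]) if abs(n[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


@dataclass(frozen=True)
class ViewerCamera:
    """Pinhole camera standing in for the operator's eye/HMD view.

    ``eye`` is the optical centre in scene mm, ``gaze`` the unit viewing
    direction and ``up`` the approximate up direction (re-orthogonalized
    internally).  Image coordinates are pixels, x right, y down, origin at the
    top-left corner; the principal point sits at the image centre and pixels
    are square.
    """

    eye: Vec3
    gaze: Vec3
    up: Vec3
    vfov_deg: float = 60.0
    width_px: int = 1000
    height_px: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "eye", _vec(self.eye))
        object.__setattr__(self, "gaze", _unit(self.gaze))
        object.__setattr__(self, "up", _unit(self.up))
        if not (0.0 < self.vfov_deg < 180.0):
            raise ValueError("vfov_deg must lie in (0, 180)")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if abs(float(np.dot(self.gaze, self.up))) > 1.0 - 1e-9:
            raise ValueError("gaze and up must not be parallel")

    @property
    def focal_px(self) -> float:
        return (self.height_px / 2.0) / np.tan(np.radians(self.vfov_deg) / 2.0)

    def basis(self) -> tuple[Vec3, Vec3, Vec3]:
        """Right, down, forward unit vectors of the camera frame."""
        fwd = self.gaze
        right = np.cross(fwd, self.up)
        right = right / np.linalg.norm(right)
        down = np.cross(fwd, right)  # y grows downward in image space
        return right, down, fwd


@dataclass(frozen=True)
class MirrorPlane:
    """The reflecting plane of the mirror head (point + unit normal)."""

    point: Vec3
    normal: Vec3

    def __post_init__(self):
        object.__setattr__(self, "point", _vec(self.point))
        object.__setattr__(self, "normal", _unit(self.normal))


@dataclass(frozen=True)
class MirrorDisc:
    """The 20 mm circular mirror face as an oriented disc in scene space."""

    center: Vec3
    normal: Vec3
    diameter_mm: float = 20.0

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        object.__setattr__(self, "normal", _unit(self.normal))
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def plane(self) -> MirrorPlane:
        return MirrorPlane(self.center, self.normal)


TASK_TEETH = (12, 21, 31, 42)


@dataclass(frozen=True)
class LesionDisc:
    """The circular caries target (3 mm by default) on a tooth surface."""

    center: Vec3
    normal: Vec3
    diameter_mm: float = 3.0
    tooth: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        object.__setattr__(self, "normal", _unit(self.normal))
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.tooth is not None and self.tooth not in TASK_TEETH:
            raise ValueError(f"tooth must be one of {TASK_TEETH}, got {self.tooth}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class ImageEllipse:
    """An ellipse in screenshot pixel coordinates.

    ``phi_deg`` is the major-axis orientation in [0, 180) measured from the +x
    image axis (the convention the reference image-analysis tool reports).
    """

    cx_px: float
    cy_px: float
    a_px: float
    b_px: float
    phi_deg: float

    def __post_init__(self):
        if not (self.a_px >= self.b_px > 0):
            raise ValueError("require a_px >= b_px > 0")
        object.__setattr__(self, "phi_deg", float(self.phi_deg) % 180.0)

    @property
    def area_px(self) -> float:
        return np.pi * self.a_px * self.b_px

    @property
    def axis_ratio(self) -> float:
        return self.b_px / self.a_px


def reflect_point(p: Vec3, plane: MirrorPlane) -> Vec3:
    """Mirror image of a point: p - 2((p - q)·n)n."""
    p = _vec(p)
    d = float(np.dot(p - plane.point, plane.normal))
    return p - 2.0 * d * plane.normal


def reflect_direction(v: Vec3, plane: MirrorPlane) -> Vec3:
    """Reflect a direction vector (no translation component)."""
    v = _vec(v)
    return v - 2.0 * float(np.dot(v, plane.normal)) * plane.normal


def virtual_image_of_disc(lesion: LesionDisc, plane: MirrorPlane) -> LesionDisc:
    """Virtual image of a disc behind the mirror plane.

    Reflection is an isometry, so the image is again a circular disc of the
    same diameter, with reflected centre and reflected normal direction.
    """
    return replace(
        lesion,
        center=reflect_point(lesion.center, plane),
        normal=reflect_direction(lesion.normal, plane),
    )


def project_point(p: Vec3, viewer: ViewerCamera) -> tuple[float, float]:
    """Pinhole-project a scene point to pixel coordinates."""
    right, down, fwd = viewer.basis()
    rel = _vec(p) - viewer.eye
    z = float(np.dot(rel, fwd))
    if z <= 1e-9:
        raise ValueError("point is behind the camera")
    f = viewer.focal_px
    x = viewer.width_px / 2.0 + f * float(np.dot(rel, right)) / z
    y = viewer.height_px / 2.0 + f * float(np.dot(rel, down)) / z
    return x, y


def disc_boundary(center: Vec3, normal: Vec3, radius_mm: float, k: int = 256) -> np.ndarray:
    """(k, 3) evenly spaced points on the disc's boundary circle."""
    u, v = orthonormal_frame(normal)
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    return center + radius_mm * (np.outer(np.cos(t), u) + np.outer(np.sin(t), v))


def _project_points(pts: np.ndarray, viewer: ViewerCamera) -> np.ndarray:
    right, down, fwd = viewer.basis()
    rel = pts - viewer.eye
    z = rel @ fwd
    if np.any(z <= 1e-9):
        raise ValueError("disc is partially or fully behind the camera")
    f = viewer.focal_px
    x = viewer.width_px / 2.0 + f * (rel @ right) / z
    y = viewer.height_px / 2.0 + f * (rel @ down) / z
    return np.column_stack([x, y])


def _conic_to_ellipse(coef: np.ndarray) -> ImageEllipse:
    a, b, c, d, e, f = coef
    m = np.array([[a, b / 2.0], [b / 2.0, c]])
    det = np.linalg.det(m)
    if det <= 0:
        raise ValueError("fitted conic is not an ellipse")
    center = np.linalg.solve(2.0 * m, [-d, -e])
    f0 = (
        a * center[0] ** 2
        + b * center[0] * center[1]
        + c * center[1] ** 2
        + d * center[0]
        + e * center[1]
        + f
    )
    evals, evecs = np.linalg.eigh(m)
    with np.errstate(invalid="raise"):
        axes = np.sqrt(-f0 / evals)
    order = np.argsort(axes)[::-1]  # major first
    a_px, b_px = axes[order]
    major_vec = evecs[:, order[0]]
    phi = np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0
    return ImageEllipse(float(center[0]), float(center[1]), float(a_px), float(b_px), float(phi))


def fit_conic(points: np.ndarray) -> ImageEllipse:
    """Exact ellipse through projected boundary points (least-squares conic).

    Points are normalized (centred, scaled) before the SVD solve for
    conditioning; the conic is then de-normalized analytically.
    """
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale < 1e-9:
        raise ValueError("degenerate projected boundary")
    q = (pts - mean) / scale
    x, y = q[:, 0], q[:, 1]
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    a, b, c, d, e, f = vt[-1]
    # de-normalize: substitute x -> (X - mx)/s, y -> (Y - my)/s
    s = scale
    mx, my = mean
    A = a / s**2
    B = b / s**2
    C = c / s**2
    D = (-2 * a * mx - b * my) / s**2 + d / s
    E = (-2 * c * my - b * mx) / s**2 + e / s
    F = (
        (a * mx**2 + b * mx * my + c * my**2) / s**2
        - (d * mx + e * my) / s
        + f
    )
    return _conic_to_ellipse(np.array([A, B, C, D, E, F]))


def project_disc(disc, viewer: ViewerCamera, k: int = 256) -> ImageEllipse:
    """Perspective image of a circular disc as an exact ellipse.

    Samples ``k`` boundary points, projects them through the pinhole model and
    fits the exact conic.  The disc must lie entirely in front of the camera;
    there is no clipping at this analytic level.
    """
    pts = disc_boundary(disc.center, disc.normal, disc.radius_mm, k)
    return fit_conic(_project_points(pts, viewer))


def point_in_ellipse(e: ImageEllipse, x: float, y: float, tol: float = 0.0) -> bool:
    """Whether pixel point (x, y) lies inside (or on) the ellipse."""
    phi = np.radians(e.phi_deg)
    dx, dy = x - e.cx_px, y - e.cy_px
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    return (xr / e.a_px) ** 2 + (yr / e.b_px) ** 2 <= 1.0 + tol


def mirror_view(
    viewer: ViewerCamera,
    mirror: MirrorDisc,
    lesion: LesionDisc,
    k: int = 256,
) -> tuple[ImageEllipse, ImageEllipse, bool]:
    """Analytic screenshot content: mirror rim ellipse and lesion-image ellipse.

    The lesion's virtual image is constructed by reflecting it through the
    mirror plane and projecting it directly — per the symmetric mirror-image
    camera configuration, geometry between the mirror surface and the virtual
    image is ignored, so no occlusion test is applied here.  ``bc_clipped``
    reports whether any part of the lesion image falls outside the mirror rim
    (the raster stage is what actually clips it).
    """
    if float(np.dot(mirror.normal, viewer.eye - mirror.center)) <= 0:
        raise ValueError("mirror faces away from the viewer")
    dm = project_disc(mirror, viewer, k)
    image = virtual_image_of_disc(lesion, mirror.plane)
    bc = project_disc(image, viewer, k)
    boundary = disc_boundary(image.center, image.normal, image.radius_mm, 64)
    px = _project_points(boundary, viewer)
    bc_clipped = not all(point_in_ellipse(dm, x, y, tol=1e-9) for x, y in px)
    return dm, bc, bc_clipped
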