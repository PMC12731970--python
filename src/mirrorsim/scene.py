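"""Virtual intraoral scene and task/criteria model.

The dentition is a parameterized stand-in for the scanned typodont: each tooth
is a capsule on a parabolic arch, the tongue is an ellipsoid lingual to the
mandibular arch, and a "frame" box encloses the dentition (the simulator's
replacement for lip/cheek constraint).  The four task teeth are the anterior
incisors in FDI notation: 12, 21 (maxillary) and 31, 42 (mandibular).

Coordinates are right-handed scene millimetres with y up and the ground plane
at y = 0.  The occlusal plane is the z = 0 plane; its normal (+z) is
horizontal, i.e. the occlusal plane is perpendicular to the ground, matching
the mounted posture of the dentition with the operator seated at the
12 o'clock position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import (
    LesionDisc,
    MirrorDisc,
    TASK_TEETH,
    Vec3,
    ViewerCamera,
    _project_points,
    disc_boundary,
    mirror_view,
    point_in_ellipse,
    project_point,
)

__all__ = [
    "ToothCapsule",
    "Ellipsoid",
    "Box",
    "SceneModel",
    "TaskSpec",
    "ValidityFlags",
    "HandpieceTip",
    "build_default_scene",
    "default_viewer",
    "place_lesion",
    "check_criteria",
    "make_session",
]

MAXILLARY_TEETH = (13, 12, 11, 21, 22, 23)
MANDIBULAR_TEETH = (43, 42, 41, 31, 32, 33)


@dataclass(frozen=True)
class ToothCapsule:
    """A tooth as a capsule (segment + radius) with surface anchor points."""

    fdi: int
    seg_a: Vec3  # incisal end
    seg_b: Vec3  # apical end
    radius_mm: float
    labial_anchor: Vec3
    labial_normal: Vec3
    lingual_anchor: Vec3
    lingual_normal: Vec3

    def distances_to_points(self, pts: np.ndarray) -> np.ndarray:
        """Signed distances from points (N, 3) to the capsule surface (<0 inside)."""
        pts = np.atleast_2d(pts)
        ab = self.seg_b - self.seg_a
        denom = float(np.dot(ab, ab))
        t = np.clip((pts - self.seg_a) @ ab / denom, 0.0, 1.0)
        closest = self.seg_a + np.outer(t, ab)
        return np.linalg.norm(pts - closest, axis=1) - self.radius_mm

    def distance_to_point(self, p: Vec3) -> float:
        """Signed distance from a point to the capsule surface (<0 inside)."""
        return float(self.distances_to_points(np.asarray(p, float))[0])

    def ray_hit(self, origin: Vec3, direction: Vec3, t_max: float) -> bool:
        """Whether the ray origin + t*direction, t in (0, t_max), touches the capsule.

        Conservative: tangency counts as a hit.  Sampled along the ray — the
        capsule radius (several mm) is far larger than the sampling step.
        """
        n = 64
        ts = np.linspace(t_max / n, t_max * (1 - 1e-6), n)
        pts = origin + np.outer(ts, direction)
        return bool(np.any(self.distances_to_points(pts) <= 0.0))


@dataclass(frozen=True)
class Ellipsoid:
    center: Vec3
    axes_mm: np.ndarray  # semi-axes (3,)

    def contains(self, p: Vec3) -> bool:
        q = (np.asarray(p, float) - self.center) / self.axes_mm
        return float(np.dot(q, q)) <= 1.0

    def ray_hit(self, origin: Vec3, direction: Vec3, t_max: float) -> bool:
        o = (origin - self.center) / self.axes_mm
        d = (direction * t_max) / self.axes_mm  # param s in (0,1)
        a = float(np.dot(d, d))
        b = 2.0 * float(np.dot(o, d))
        c = float(np.dot(o, o)) - 1.0
        disc = b * b - 4 * a * c
        if disc < 0:
            return False
        sq = math.sqrt(disc)
        s1 = (-b - sq) / (2 * a)
        s2 = (-b + sq) / (2 * a)
        eps = 1e-9
        return (eps < s1 < 1 - eps) or (eps < s2 < 1 - eps)


@dataclass(frozen=True)
class Box:
    lo: Vec3
    hi: Vec3

    def contains(self, p: Vec3) -> bool:
        p = np.asarray(p, float)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))

    @property
    def center(self) -> Vec3:
        return (self.lo + self.hi) / 2.0


@dataclass(frozen=True)
class HandpieceTip:
    """Working tip of the air-turbine handpiece (Trial 2 only)."""

    tip: Vec3
    axis: Vec3

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, float))
        axis = np.asarray(self.axis, float)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", axis / n)


@dataclass(frozen=True)
class SceneModel:
    teeth: tuple[ToothCapsule, ...]
    tongue: Ellipsoid
    frame_box: Box
    occlusal_plane_normal: Vec3
    mouth_center: Vec3

    def tooth(self, fdi: int) -> ToothCapsule:
        for t in self.teeth:
            if t.fdi == fdi:
                return t
        raise KeyError(f"no tooth with FDI label {fdi}")


@dataclass(frozen=True)
class TaskSpec:
    """One task of a session: tasks 1-4 belong to Trial 1, 5-8 to Trial 2."""

    trial: int
    task_index: int
    tooth: int

    def __post_init__(self):
        if self.trial not in (1, 2):
            raise ValueError("trial must be 1 or 2")
        if not 1 <= self.task_index <= 8:
            raise ValueError("task_index must be in 1..8")
        expected_trial = 1 if self.task_index <= 4 else 2
        if self.trial != expected_trial:
            raise ValueError(
                f"task {self.task_index} belongs to trial {expected_trial}"
            )
        if self.tooth not in TASK_TEETH:
            raise ValueError(f"tooth must be one of {TASK_TEETH}")


@dataclass(frozen=True)
class ValidityFlags:
    """Appropriate-mirror-position criteria.

    Trial 1 applies the first two; Trial 2 adds the handpiece-tip conditions
    (tip inside the frame box and clear of the lesion's mirror image).
    """

    mirror_fully_visible: bool
    no_penetration: bool
    tip_in_box: bool | None = None
    tip_clear_of_bc: bool | None = None

    @property
    def all_ok(self) -> bool:
        flags = [self.mirror_fully_visible, self.no_penetration]
        if self.tip_in_box is not None:
            flags.append(self.tip_in_box)
        if self.tip_clear_of_bc is not None:
            flags.append(self.tip_clear_of_bc)
        return all(flags)


_DEFAULTS = {
    "arch_width_mm": 40.0,
    "arch_depth_mm": 10.0,
    "tooth_radius_mm": 3.5,
    "tooth_height_mm": 10.0,
    "tongue_axes_mm": (24.0, 18.0, 28.0),
    "frame_margin_mm": 8.0,
    "mouth_height_mm": 120.0,
}

# lateral offsets along the arch (mm from the midline); FDI quadrant 1/4 on +x
_TOOTH_X = {
    11: 4.3, 12: 12.0, 13: 19.0, 21: -4.3, 22: -12.0, 23: -19.0,
    41: 3.5, 42: 10.5, 43: 17.0, 31: -3.5, 32: -10.5, 33: -17.0,
}


def build_default_scene(config: dict | None = None) -> SceneModel:
    """Build the parameterized dentition scene.

    ``config`` may override ``arch_width_mm``, ``arch_depth_mm``,
    ``tooth_radius_mm``, ``tooth_height_mm``, ``tongue_axes_mm``,
    ``frame_margin_mm`` and ``mouth_height_mm``; unknown keys are rejected.
    Deterministic: the same config always yields the identical scene.
    """
    cfg = dict(_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
        cfg.update(config)
    for key in ("arch_width_mm", "arch_depth_mm", "tooth_radius_mm",
                "tooth_height_mm", "frame_margin_mm", "mouth_height_mm"):
        if cfg[key] <= 0:
            raise ValueError(f"scene config {key} must be positive")
    axes = np.asarray(cfg["tongue_axes_mm"], float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise ValueError("tongue_axes_mm must be three positive values")

    y0 = cfg["mouth_height_mm"]
    half_w = cfg["arch_width_mm"] / 2.0
    depth = cfg["arch_depth_mm"]
    r = cfg["tooth_radius_mm"]
    h = cfg["tooth_height_mm"]

    teeth = []
    for fdi_set, z_sign in ((MAXILLARY_TEETH, +1.0), (MANDIBULAR_TEETH, -1.0)):
        for fdi in fdi_set:
            x = _TOOTH_X[fdi]
            # parabolic arch in the occlusal (x, y) plane, opening downward
            y = y0 + depth * (1.0 - (x / half_w) ** 2)
            # outward normal of the parabola (labial direction)
            grad = np.array([2.0 * depth * x / half_w**2, 1.0, 0.0])
            out = grad / np.linalg.norm(grad)
            seg_a = np.array([x, y, 0.0])  # incisal end at the occlusal plane
            seg_b = np.array([x, y, z_sign * h])
            mid = (seg_a + seg_b) / 2.0
            teeth.append(
                ToothCapsule(
                    fdi=fdi,
                    seg_a=seg_a,
                    seg_b=seg_b,
                    radius_mm=r,
                    labial_anchor=mid + r * out,
                    labial_normal=out,
                    lingual_anchor=mid - r * out,
                    lingual_normal=-out,
                )
            )

    tongue = Ellipsoid(
        center=np.array([0.0, y0 - axes[1] * 0.4, -axes[2] * 0.9]),
        axes_mm=axes,
    )

    pts = np.array([[t.seg_a, t.seg_b] for t in teeth]).reshape(-1, 3)
    margin = cfg["frame_margin_mm"]
    lo = pts.min(axis=0) - (r + margin)
    hi = pts.max(axis=0) + (r + margin)
    frame_box = Box(lo=lo, hi=hi)
    if not all(frame_box.contains(t.seg_a) and frame_box.contains(t.seg_b) for t in teeth):
        raise AssertionError("frame box must enclose all tooth primitives")

    return SceneModel(
        teeth=tuple(teeth),
        tongue=tongue,
        frame_box=frame_box,
        occlusal_plane_normal=np.array([0.0, 0.0, 1.0]),
        mouth_center=np.array([0.0, y0, 0.0]),
    )


def default_viewer(scene: SceneModel, distance_mm: float = 300.0,
                   vfov_deg: float = 60.0, width_px: int = 1000,
                   height_px: int = 1000) -> ViewerCamera:
    """Operator's eye at the 12 o'clock position, gazing at the mouth centre."""
    target = scene.mouth_center
    eye = target + np.array([0.0, distance_mm * 0.78, distance_mm * 0.62])
    gaze = target - eye
    return ViewerCamera(eye=eye, gaze=gaze, up=np.array([0.0, 1.0, 0.0]),
                        vfov_deg=vfov_deg, width_px=width_px, height_px=height_px)


def place_lesion(scene: SceneModel, tooth: int, diameter_mm: float = 3.0,
                 surface: str | None = None) -> LesionDisc:
    """Anchor the lesion disc on the chosen task tooth.

    By default the lesion sits on the surface that faces the mirror in the
    12 o'clock posture: lingual for the maxillary incisors (12, 21) and labial
    for the mandibular ones (31, 42).  ``surface`` overrides ("labial" or
    "lingual").
    """
    if tooth not in TASK_TEETH:
        raise ValueError(f"tooth {tooth} is not a task tooth {TASK_TEETH}")
    t = scene.tooth(tooth)
    if surface is None:
        surface = "lingual" if tooth in (12, 21) else "labial"
    if surface == "lingual":
        anchor, normal = t.lingual_anchor, t.lingual_normal
    elif surface == "labial":
        anchor, normal = t.labial_anchor, t.labial_normal
    else:
        raise ValueError("surface must be 'labial' or 'lingual'")
    return LesionDisc(center=anchor, normal=normal, diameter_mm=diameter_mm, tooth=tooth)


def _mirror_penetrates(scene: SceneModel, mirror: MirrorDisc, n_boundary: int = 64) -> bool:
    """Whether the mirror disc touches or enters any tooth or the tongue.

    Samples the disc boundary plus interior rings (the disc is thin, so a
    point sample entering a primitive is a penetration; touching counts).
    """
    rings = [1.0, 0.66, 0.33]
    pts = [mirror.center]
    for frac in rings:
        pts.append(disc_boundary(mirror.center, mirror.normal,
                                 mirror.radius_mm * frac, n_boundary))
    samples = np.vstack([np.atleast_2d(p) for p in pts])
    for tooth in scene.teeth:
        if np.any(tooth.distances_to_points(samples) <= 0.0):
            return True
    q = (samples - scene.tongue.center) / scene.tongue.axes_mm
    return bool(np.any(np.einsum("ij,ij->i", q, q) <= 1.0))


def _mirror_visible(scene: SceneModel, viewer: ViewerCamera,
                    mirror: MirrorDisc, n_rays: int = 32) -> bool:
    """Entire mirror inside the viewport and unoccluded from the eye.

    Casts rays from the eye to boundary samples of the mirror; any tooth or
    tongue intersection strictly between eye and mirror (tangency included)
    counts as occlusion.
    """
    boundary = disc_boundary(mirror.center, mirror.normal, mirror.radius_mm, n_rays)
    try:
        px = _project_points(boundary, viewer)
    except ValueError:  # behind the camera
        return False
    if not (np.all(px[:, 0] >= 0.0) and np.all(px[:, 0] < viewer.width_px)
            and np.all(px[:, 1] >= 0.0) and np.all(px[:, 1] < viewer.height_px)):
        return False
    # sample all rays eye -> boundary at 64 interior points and test capsules
    deltas = boundary - viewer.eye  # (n_rays, 3)
    n_samp = 64
    fr = np.linspace(1.0 / n_samp, 1.0 - 1e-6, n_samp)
    pts = (viewer.eye + deltas[:, None, :] * fr[None, :, None]).reshape(-1, 3)
    for tooth in scene.teeth:
        if np.any(tooth.distances_to_points(pts) <= 0.0):
            return False
    for p in boundary:
        direction = p - viewer.eye
        t_max = float(np.linalg.norm(direction))
        if scene.tongue.ray_hit(viewer.eye, direction / t_max, t_max - 1e-6):
            return False
    return True


def check_criteria(
    scene: SceneModel,
    viewer: ViewerCamera,
    mirror: MirrorDisc,
    tip: HandpieceTip | None = None,
    trial: int = 1,
    lesion: LesionDisc | None = None,
) -> ValidityFlags:
    """Evaluate the appropriate-mirror-position criteria for a pose.

    Trial 1: the entire mirror must be visible, and the mirror must not
    penetrate tongue or teeth.  Trial 2 additionally requires the handpiece
    tip inside the frame box and its projection clear of the lesion's mirror
    image (``lesion`` required to evaluate that condition).
    """
    if trial not in (1, 2):
        raise ValueError("trial must be 1 or 2")
    if trial == 2 and tip is None:
        raise ValueError("trial 2 requires the handpiece tip")

    visible = _mirror_visible(scene, viewer, mirror)
    no_pen = not _mirror_penetrates(scene, mirror)

    if trial == 1:
        return ValidityFlags(mirror_fully_visible=visible, no_penetration=no_pen)

    tip_in_box = scene.frame_box.contains(tip.tip)
    tip_clear: bool | None = None
    if lesion is not None:
        try:
            _, bc, _ = mirror_view(viewer, mirror, lesion)
            tx, ty = project_point(tip.tip, viewer)
            tip_clear = not point_in_ellipse(bc, tx, ty)
        except ValueError:
            tip_clear = True  # lesion image not projectable -> nothing to overlap
    return ValidityFlags(
        mirror_fully_visible=visible,
        no_penetration=no_pen,
        tip_in_box=tip_in_box,
        tip_clear_of_bc=tip_clear,
    )


def make_session(rng: np.random.Generator) -> list[TaskSpec]:
    """Eight tasks: each trial targets the four task teeth in random order."""
    tasks: list[TaskSpec] = []
    for trial in (1, 2):
        order = rng.permutation(TASK_TEETH)
        for i, tooth in enumerate(order):
            idx = i + 1 + (4 if trial == 2 else 0)
            tasks.append(TaskSpec(trial=trial, task_index=idx, tooth=int(tooth)))
    return tasks
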