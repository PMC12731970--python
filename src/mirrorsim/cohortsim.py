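"""Synthetic operator cohorts for the mirror-technique evaluation pipeline.

The generator emulates what each experience group *produces on the screen*
rather than simulating hand kinematics: each skill profile parameterizes the
apparent in-mirror-image quantities (radial offset of the lesion image from
the mirror centre, its apparent ellipticity and area ratio, and manipulation
time), because the group-level performance statistics are apparent-image
statistics.  Each sampled pose is constructed so that its *analytic* measured
metrics equal the sampled targets exactly; the render -> segment -> moment-fit
stage then adds only rasterization noise, which is mean-zero, so group means
recovered end-to-end converge to the profile targets.

Distributional forms: Gamma for radial offsets (non-negative and
mean-parameterizable), Beta for ellipticity targets (bounded support),
truncated normal for area-ratio targets, log-normal for manipulation times.
The per-group defaults packaged in ``data/calibrated_cohort.yaml`` encode the
study's printed group means; cohort sizes default to 25/24/17/21 for the
instructor / graduate-student / trainee / student groups.

All randomness flows from a single integer seed; every (group, participant,
task) triple gets its own child stream, so records are reproducible under
reordering and subsetting.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import scene as scene_mod
from .metrics import GROUPS, MetricRecord, make_record
from .optics import (
    LesionDisc,
    MirrorDisc,
    ViewerCamera,
    orthonormal_frame,
    project_disc,
    virtual_image_of_disc,
)
from .raster_measure import measure, render_screenshot
from .scene import HandpieceTip, SceneModel, TaskSpec, ValidityFlags, check_criteria

__all__ = [
    "SkillProfile",
    "CohortSpec",
    "sample_task_geometry",
    "generate_cohort",
    "load_cohort_spec",
    "calibrated_spec",
]

DEFAULT_N_PER_GROUP = {"ID": 25, "GS": 24, "TD": 17, "ST": 21}


def _cell(tooth: int, trial: int) -> str:
    return f"{tooth}/{trial}"


@dataclass
class SkillProfile:
    """Sampling distributions describing one experience group's behaviour.

    Group-level defaults can be refined per tooth x trial cell (keys like
    ``"21/1"``) to encode a full calibration table.  ``time_mean_s`` values
    are arithmetic means in seconds; the log-normal location parameter is
    derived as ``mu = ln(mean) - sigma^2/2`` so the sampled mean matches.
    """

    group: str
    offset_mean_mm: float = 1.4
    offset_shape: float = 4.0
    ellipticity_target_mean: float = 0.87
    ellipticity_sd: float = 0.05
    ratio_target_mean_pct: float = 2.8
    ratio_sd_pct: float = 0.35
    time_mean_s: float = 7.0
    time_sigma_log: float = 0.35
    offset_mean_by_cell: dict = field(default_factory=dict)
    ratio_mean_by_cell: dict = field(default_factory=dict)
    ellipticity_mean_by_trial: dict = field(default_factory=dict)
    time_mean_by_cell: dict = field(default_factory=dict)
    task_time_factors: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.offset_mean_mm < 0:
            raise ValueError("offset_mean_mm must be >= 0")
        if self.offset_shape <= 0:
            raise ValueError("offset_shape must be positive")
        for m in [self.ellipticity_target_mean,
                  *self.ellipticity_mean_by_trial.values()]:
            if not (0.0 < m <= 1.0):
                raise ValueError("ellipticity targets must lie in (0, 1]")
        for m in [self.ratio_target_mean_pct, *self.ratio_mean_by_cell.values()]:
            if not (0.0 < m <= 100.0):
                raise ValueError("ratio targets must lie in (0, 100]")
        if self.time_sigma_log < 0 or self.time_mean_s <= 0:
            raise ValueError("time parameters must be positive")

    @property
    def time_mu_log(self) -> float:
        return float(np.log(self.time_mean_s) - self.time_sigma_log**2 / 2.0)

    def offset_mean(self, tooth: int, trial: int) -> float:
        return float(self.offset_mean_by_cell.get(_cell(tooth, trial), self.offset_mean_mm))

    def ratio_mean(self, tooth: int, trial: int) -> float:
        return float(self.ratio_mean_by_cell.get(_cell(tooth, trial), self.ratio_target_mean_pct))

    def ellipticity_mean(self, trial: int) -> float:
        return float(self.ellipticity_mean_by_trial.get(str(trial),
                     self.ellipticity_mean_by_trial.get(trial, self.ellipticity_target_mean)))

    def time_mean(self, tooth: int, trial: int, task_index: int) -> float:
        mean = float(self.time_mean_by_cell.get(_cell(tooth, trial), self.time_mean_s))
        factor = float(self.task_time_factors.get(str(task_index),
                       self.task_time_factors.get(task_index, 1.0)))
        return mean * factor


@dataclass
class CohortSpec:
    """A full synthetic study: per-group profiles, sizes, tasks and seed."""

    profiles: dict[str, SkillProfile]
    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    trials: tuple[int, ...] = (1, 2)
    seed: int = 0
    scene_config: dict | None = None
    capture_vfov_deg: float = 16.0
    capture_px: int = 800
    viewer_distance_mm: float = 300.0

    def __post_init__(self):
        for g in self.profiles:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        self.n_per_group = {g: int(self.n_per_group.get(g, DEFAULT_N_PER_GROUP[g]))
                            for g in self.profiles}
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("each group needs at least one participant")
        if any(t not in (1, 2) for t in self.trials):
            raise ValueError("trials must be a subset of (1, 2)")


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def _sample_ellipticity(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd <= 0 or mean >= 1.0 - 1e-9:
        return min(mean, 1.0)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:  # sd too large for the support; fall back to the mean
        return mean
    e = rng.beta(mean * nu, (1.0 - mean) * nu)
    return float(np.clip(e, 0.2, 1.0))


def _solve_image_disc(
    camera: ViewerCamera,
    mirror: MirrorDisc,
    direction_rad: float,
    tilt_axis_rad: float,
    depth_mm: float,
    dist_target_mm: float,
    ellipticity_target: float,
    ratio_target_pct: float,
    n_iter: int = 4,
) -> LesionDisc:
    """Place the lesion's virtual-image disc so the analytic measured metrics
    hit the sampled targets.

    Unknowns: the in-plane centre offset (2 coordinates), the tilt about an
    in-plane axis and the diameter.  The centre is driven to a desired
    pixel-space position (mirror-centre pixel plus the target distance along
    the sampled image direction) by Newton steps on a numerically evaluated
    2x2 projection Jacobian; tilt and diameter are rescaled by the
    target/measured ratio.  The couplings are weak, so a handful of
    iterations reach numerical exactness.
    """
    from .optics import _project_points

    u, v = orthonormal_frame(mirror.normal)
    tilt_axis = np.cos(tilt_axis_rad) * u + np.sin(tilt_axis_rad) * v

    dm = project_disc(mirror, camera, k=64)
    mm_per_px = mirror.diameter_mm / (2.0 * dm.a_px)
    desired_px = np.array([dm.cx_px, dm.cy_px]) + (dist_target_mm / mm_per_px) * np.array(
        [np.cos(direction_rad), np.sin(direction_rad)])

    alpha = dist_target_mm * np.cos(direction_rad)
    beta = dist_target_mm * np.sin(direction_rad)
    cos_tau = ellipticity_target
    diameter = mirror.diameter_mm * np.sqrt(
        ratio_target_pct / 100.0 / max(cos_tau, 1e-6)
    )
    for _ in range(n_iter):
        center = mirror.center + alpha * u + beta * v - depth_mm * mirror.normal
        normal = _rotate(mirror.normal, tilt_axis, np.arccos(np.clip(cos_tau, 0.0, 1.0)))
        disc = LesionDisc(center=center, normal=normal, diameter_mm=diameter)
        bc = project_disc(disc, camera, k=64)
        # Newton step on the centre: numerical Jacobian of px w.r.t. (alpha, beta)
        eps = 0.05
        probe = np.vstack([center, center + eps * u, center + eps * v])
        px = _project_points(probe, camera)
        jac = np.column_stack([(px[1] - px[0]) / eps, (px[2] - px[0]) / eps])
        err = desired_px - np.array([bc.cx_px, bc.cy_px])
        step = np.linalg.solve(jac, err)
        alpha += step[0]
        beta += step[1]
        ell = bc.b_px / bc.a_px
        ratio = 100.0 * (bc.a_px * bc.b_px) / (dm.a_px * dm.b_px)
        cos_tau = float(np.clip(cos_tau * ellipticity_target / ell, 1e-6, 1.0))
        diameter *= np.sqrt(ratio_target_pct / ratio)
    center = mirror.center + alpha * u + beta * v - depth_mm * mirror.normal
    normal = _rotate(mirror.normal, tilt_axis, np.arccos(np.clip(cos_tau, 0.0, 1.0)))
    return LesionDisc(center=center, normal=normal, diameter_mm=diameter)


def sample_task_geometry(
    profile: SkillProfile,
    task: TaskSpec,
    rng: np.random.Generator,
    scene: SceneModel,
    camera: ViewerCamera,
    mirror_distance_range: tuple[float, float] = (250.0, 280.0),
) -> tuple[ViewerCamera, MirrorDisc, LesionDisc, float]:
    """Sample one task's pose and manipulation time for a profile.

    The mirror is held on the line of sight to the task tooth, roughly facing
    the viewer with a small random cant and lateral jitter; the lesion is the
    reflection of a virtual-image disc solved so the analytic metrics equal
    the profile's sampled targets (see ``_solve_image_disc``).  Deterministic
    for a given rng state.
    """
    anchor = scene.tooth(task.tooth).labial_anchor
    to_anchor = anchor - camera.eye
    to_anchor = to_anchor / np.linalg.norm(to_anchor)
    d_m = rng.uniform(*mirror_distance_range)
    lateral_u, lateral_v = orthonormal_frame(to_anchor)
    jitter = rng.normal(0.0, 3.0, size=2)
    m_center = camera.eye + d_m * to_anchor + jitter[0] * lateral_u + jitter[1] * lateral_v

    n0 = (camera.eye - m_center) / np.linalg.norm(camera.eye - m_center)
    cant = abs(rng.normal(0.0, np.radians(4.0)))
    axis_ang = rng.uniform(0.0, 2.0 * np.pi)
    u, v = orthonormal_frame(n0)
    cant_axis = np.cos(axis_ang) * u + np.sin(axis_ang) * v
    mirror = MirrorDisc(center=m_center, normal=_rotate(n0, cant_axis, cant))

    offset_mean = profile.offset_mean(task.tooth, task.trial)
    if offset_mean > 0:
        dist_target = rng.gamma(profile.offset_shape, offset_mean / profile.offset_shape)
    else:
        dist_target = 0.0
    ell_target = _sample_ellipticity(profile.ellipticity_mean(task.trial),
                                     profile.ellipticity_sd, rng)
    ratio_target = float(np.clip(
        rng.normal(profile.ratio_mean(task.tooth, task.trial), profile.ratio_sd_pct),
        0.5, 20.0))

    image_disc = _solve_image_disc(
        camera,
        mirror,
        direction_rad=rng.uniform(0.0, 2.0 * np.pi),
        tilt_axis_rad=rng.uniform(0.0, 2.0 * np.pi),
        depth_mm=rng.uniform(1.0, 5.0),
        dist_target_mm=dist_target,
        ellipticity_target=ell_target,
        ratio_target_pct=ratio_target,
    )
    # physical lesion = reflection of the desired virtual image (involution)
    lesion_geom = virtual_image_of_disc(image_disc, mirror.plane)
    lesion = LesionDisc(center=lesion_geom.center, normal=lesion_geom.normal,
                        diameter_mm=lesion_geom.diameter_mm, tooth=task.tooth)

    mean_t = profile.time_mean(task.tooth, task.trial, task.task_index)
    mu = np.log(mean_t) - profile.time_sigma_log**2 / 2.0
    time_s = float(rng.lognormal(mu, profile.time_sigma_log))
    return camera, mirror, lesion, time_s


def _tip_for_trial2(scene: SceneModel, rng: np.random.Generator) -> HandpieceTip:
    """Handpiece tip resting inside the frame box, below the working area."""
    box = scene.frame_box
    span = box.hi - box.lo
    pos = box.center + np.array([0.3, -0.25, -0.2]) * span / 2.0
    pos = pos + rng.normal(0.0, 1.0, size=3)
    pos = np.clip(pos, box.lo + 1.0, box.hi - 1.0)
    return HandpieceTip(tip=pos, axis=np.array([0.0, 1.0, 0.0]))


def generate_cohort(
    spec: CohortSpec,
    check_validity: bool = True,
    screenshot_sink=None,
) -> list[MetricRecord]:
    """Run the full per-participant x per-task pipeline for a cohort spec.

    For every record: sample pose -> analytic mirror view -> rasterize the
    labeled screenshot -> moment-based measurement -> metric record.  When
    ``screenshot_sink`` is given it is called as ``sink(record, screenshot)``
    for the first participant of each group (one capture per task, as in the
    study's screenshot protocol).
    """
    scene = scene_mod.build_default_scene(spec.scene_config)
    camera = scene_mod.default_viewer(
        scene,
        distance_mm=spec.viewer_distance_mm,
        vfov_deg=spec.capture_vfov_deg,
        width_px=spec.capture_px,
        height_px=spec.capture_px,
    )
    records: list[MetricRecord] = []
    for gi, (group, profile) in enumerate(sorted(spec.profiles.items())):
        n = spec.n_per_group[group]
        for pi in range(n):
            order_rng = np.random.default_rng([spec.seed, 1000 + gi, pi])
            session = scene_mod.make_session(order_rng)
            for task in session:
                if task.trial not in spec.trials:
                    continue
                rng = np.random.default_rng([spec.seed, gi, pi, task.task_index])
                try:
                    viewer, mirror, lesion, time_s = sample_task_geometry(
                        profile, task, rng, scene, camera)
                    from .optics import mirror_view  # local to avoid cycle at import

                    dm, bc, _clipped = mirror_view(viewer, mirror, lesion)
                    shot = render_screenshot(dm, bc, camera.width_px, camera.height_px)
                    meas = measure(shot, mirror_diameter_mm=mirror.diameter_mm)
                except (ValueError, ArithmeticError) as exc:
                    raise RuntimeError(
                        f"pipeline failed for group={group} participant={pi} "
                        f"task={task.task_index} (tooth {task.tooth}, trial {task.trial}): {exc}"
                    ) from exc
                tip = _tip_for_trial2(scene, rng) if task.trial == 2 else None
                if check_validity:
                    validity = check_criteria(scene, viewer, mirror, tip=tip,
                                              trial=task.trial, lesion=lesion)
                else:
                    validity = (ValidityFlags(True, True) if task.trial == 1
                                else ValidityFlags(True, True, True, True))
                record = make_record(
                    group=group,
                    participant_id=f"{group}{pi + 1:03d}",
                    task=task,
                    m=meas,
                    time_s=time_s,
                    validity=validity,
                )
                records.append(record)
                if screenshot_sink is not None and pi == 0:
                    screenshot_sink(record, shot)
    return records


def _profile_from_dict(group: str, d: dict) -> SkillProfile:
    known = {f for f in SkillProfile.__dataclass_fields__}
    unknown = set(d) - known - {"n"}
    if unknown:
        raise ValueError(f"unknown profile keys for group {group}: {sorted(unknown)}")
    kwargs = {k: v for k, v in d.items() if k in known and k != "group"}
    return SkillProfile(group=group, **kwargs)


def load_cohort_spec(source) -> CohortSpec:
    """Load a cohort spec from a YAML mapping, path or file object."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    groups = raw.get("groups")
    if not groups:
        raise ValueError("cohort spec must define a 'groups' mapping")
    profiles = {g: _profile_from_dict(g, d or {}) for g, d in groups.items()}
    n_per_group = {g: int((d or {}).get("n", DEFAULT_N_PER_GROUP.get(g, 20)))
                   for g, d in groups.items()}
    kwargs = {}
    for key in ("trials", "seed", "scene_config", "capture_vfov_deg",
                "capture_px", "viewer_distance_mm"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "trials" else raw[key]
    return CohortSpec(profiles=profiles, n_per_group=n_per_group, **kwargs)


def calibrated_spec(**overrides) -> CohortSpec:
    """The packaged study-calibrated cohort spec (printed group means)."""
    ref = importlib.resources.files("mirrorsim.data") / "calibrated_cohort.yaml"
    spec = load_cohort_spec(yaml.safe_load(ref.read_text()))
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec
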