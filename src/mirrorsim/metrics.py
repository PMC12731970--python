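"""The four mirror-technique skill metrics and per-task records.

From each measured screenshot the pipeline scores:

* **distance between centers** (mm) — how close the lesion's mirror image sits
  to the mirror centre; an indicator of visibility.
* **relative ratio** (%) — lesion-image area as a percentage of the mirror
  surface area; an indicator of apparent size.
* **ellipticity** — minor/major axis ratio of the lesion image; 1 means the
  lesion is seen as a perfect circle (no distortion).
* **manipulation time** (s) — how long the operator took to reach the
  appropriate mirror position.

Records failing the appropriate-position criteria are kept and flagged rather
than dropped; downstream statistics use valid records by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics import TASK_TEETH
from .raster_measure import Measurement
from .scene import TaskSpec, ValidityFlags

__all__ = [
    "GROUPS",
    "MetricRecord",
    "distance_between_centers",
    "relative_ratio",
    "ellipticity",
    "make_record",
    "records_to_dataframe",
]

GROUPS = ("ID", "GS", "TD", "ST")


def distance_between_centers(m: Measurement) -> float:
    """Euclidean distance (mm) between the mirror and lesion-image centres."""
    d_px = np.hypot(m.dm.cx_px - m.bc.cx_px, m.dm.cy_px - m.bc.cy_px)
    return float(d_px * m.mm_per_px)


def relative_ratio(m: Measurement) -> float:
    """Lesion-image area as a percentage of the mirror-surface area."""
    return float(100.0 * (m.bc.a_px * m.bc.b_px) / (m.dm.a_px * m.dm.b_px))


def relative_ratio_pixel_count(labels: np.ndarray) -> float:
    """Cross-check variant of the area ratio from raw pixel counts.

    Agrees with the fitted-axes ratio within ~2% on clean rasters; kept as a
    utility, not used by the default pipeline.
    """
    from .raster_measure import BC_LABEL, DM_LABEL

    bc = int(np.count_nonzero(labels == BC_LABEL))
    dm = int(np.count_nonzero(labels == DM_LABEL)) + bc
    if dm == 0:
        raise ValueError("no mirror pixels")
    return 100.0 * bc / dm


def ellipticity(m: Measurement) -> float:
    """Minor/major axis ratio of the lesion image, in (0, 1]."""
    return float(m.bc.b_px / m.bc.a_px)


@dataclass(frozen=True)
class MetricRecord:
    """All outputs of one task for one participant."""

    group: str
    participant_id: str
    trial: int
    task_index: int
    tooth: int
    distance_mm: float
    ratio_pct: float
    ellipticity: float
    theta_deg: float
    time_s: float
    validity: ValidityFlags

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.tooth not in TASK_TEETH:
            raise ValueError(f"tooth must be one of {TASK_TEETH}")
        if self.distance_mm < 0:
            raise ValueError("distance_mm must be non-negative")
        if not (0.0 < self.ellipticity <= 1.0 + 1e-9):
            raise ValueError("ellipticity must lie in (0, 1]")
        if self.time_s <= 0:
            raise ValueError("time_s must be positive")

    @property
    def is_valid(self) -> bool:
        return self.validity.all_ok

    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "participant_id": self.participant_id,
            "trial": self.trial,
            "task_index": self.task_index,
            "tooth": self.tooth,
            "distance_mm": self.distance_mm,
            "ratio_pct": self.ratio_pct,
            "ellipticity": self.ellipticity,
            "theta_deg": self.theta_deg,
            "time_s": self.time_s,
            "mirror_fully_visible": self.validity.mirror_fully_visible,
            "no_penetration": self.validity.no_penetration,
            "tip_in_box": self.validity.tip_in_box,
            "tip_clear_of_bc": self.validity.tip_clear_of_bc,
            "valid": self.is_valid,
        }
        return d


def make_record(
    group: str,
    participant_id: str,
    task: TaskSpec,
    m: Measurement,
    time_s: float,
    validity: ValidityFlags,
) -> MetricRecord:
    """Assemble one task's metric record from a measurement plus timing.

    Records failing the validity criteria are retained with their flags; the
    caller decides whether to filter them downstream.
    """
    if time_s <= 0:
        raise ValueError("manipulation time must be positive")
    return MetricRecord(
        group=group,
        participant_id=participant_id,
        trial=task.trial,
        task_index=task.task_index,
        tooth=task.tooth,
        distance_mm=distance_between_centers(m),
        ratio_pct=relative_ratio(m),
        ellipticity=ellipticity(m),
        theta_deg=m.theta_deg,
        time_s=float(time_s),
        validity=validity,
    )


def records_to_dataframe(records) -> pd.DataFrame:
    """Flatten records (MetricRecord objects or dicts) into a DataFrame."""
    rows = [r.to_dict() if isinstance(r, MetricRecord) else dict(r) for r in records]
    return pd.DataFrame(rows)
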