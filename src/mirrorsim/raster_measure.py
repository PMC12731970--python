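"""Synthetic screenshot rasterization and pixel-level ellipse measurement.

This stage emulates the screenshot-analysis workflow: the HMD view is captured
as a labeled raster (background / mirror surface / lesion image), ellipses are
re-measured from pixels by image moments with the same-area convention of the
reference tool's "Fit Ellipse", and pixel distances are converted to
millimetres using the known 20 mm mirror diameter as the per-image scale
reference (the magnification differs image to image).

Rasterization uses pixel-centre sampling on a half-open viewport
[0, width) x [0, height), y down: a pixel belongs to an ellipse iff its centre
(i + 0.5, j + 0.5) does.  The lesion label is clipped to the mirror region —
the mirror rim bounds its own content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .optics import ImageEllipse

__all__ = [
    "BACKGROUND",
    "DM_LABEL",
    "BC_LABEL",
    "Screenshot",
    "Measurement",
    "MissingLabelError",
    "render_screenshot",
    "fit_ellipse_moments",
    "measure",
]

BACKGROUND = 0
DM_LABEL = 1
BC_LABEL = 2

# RGB preview palette: dark background, silver mirror, black caries
_PALETTE = {BACKGROUND: (40, 40, 48), DM_LABEL: (205, 210, 215), BC_LABEL: (10, 10, 10)}


class MissingLabelError(ValueError):
    """A required label class is absent from the screenshot."""

    def __init__(self, label_name: str):
        self.label_name = label_name
        super().__init__(f"screenshot contains no '{label_name}' pixels")


@dataclass(frozen=True)
class Screenshot:
    """A labeled raster standing in for one HMD screen capture."""

    labels: np.ndarray  # (height, width) uint8 in {0, 1, 2}

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        extra = set(np.unique(lab)) - {BACKGROUND, DM_LABEL, BC_LABEL}
        if extra:
            raise ValueError(f"unexpected label values: {sorted(extra)}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def width_px(self) -> int:
        return self.labels.shape[1]

    @property
    def height_px(self) -> int:
        return self.labels.shape[0]

    def to_png(self, path, preview: bool = False) -> None:
        """Write the label raster (or an RGB preview) as PNG."""
        if preview:
            rgb = np.zeros((*self.labels.shape, 3), dtype=np.uint8)
            for value, color in _PALETTE.items():
                rgb[self.labels == value] = color
            Image.fromarray(rgb, mode="RGB").save(path)
        else:
            Image.fromarray(self.labels, mode="L").save(path)

    @classmethod
    def from_png(cls, path) -> "Screenshot":
        """Read a label raster PNG (grayscale or paletted, values 0/1/2)."""
        img = Image.open(path)
        if img.mode == "P":
            arr = np.asarray(img)
        else:
            arr = np.asarray(img.convert("L"))
        return cls(labels=arr)


@dataclass(frozen=True)
class Measurement:
    """Per-screenshot measurement: fitted ellipses, mirror tilt, pixel scale."""

    dm: ImageEllipse
    bc: ImageEllipse
    theta_deg: float
    mm_per_px: float

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if not (0.0 <= self.theta_deg < 90.0):
            raise ValueError("theta_deg must lie in [0, 90)")


def _ellipse_mask(e: ImageEllipse, width: int, height: int) -> tuple[np.ndarray, tuple]:
    """Boolean mask of pixels whose centres fall inside the ellipse.

    Returns the mask restricted to the ellipse's bounding box together with
    the (row, col) slice placing it in the full raster.
    """
    x0 = max(int(np.floor(e.cx_px - e.a_px - 1)), 0)
    x1 = min(int(np.ceil(e.cx_px + e.a_px + 1)), width)
    y0 = max(int(np.floor(e.cy_px - e.a_px - 1)), 0)
    y1 = min(int(np.ceil(e.cy_px + e.a_px + 1)), height)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((0, 0), dtype=bool), (slice(0, 0), slice(0, 0))
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    phi = np.radians(e.phi_deg)
    dx, dy = gx - e.cx_px, gy - e.cy_px
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    mask = (xr / e.a_px) ** 2 + (yr / e.b_px) ** 2 <= 1.0
    return mask, (slice(y0, y1), slice(x0, x1))


def render_screenshot(
    dm: ImageEllipse,
    bc: ImageEllipse,
    width: int,
    height: int,
    flip_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Screenshot:
    """Rasterize the two analytic ellipses into a labeled screenshot.

    Mirror pixels fill the mirror ellipse; lesion pixels overwrite only inside
    the intersection with the mirror (the rim clips its content).  With
    ``flip_rate`` > 0 a salt-and-pepper label-noise augmentation flips that
    fraction of pixels to a random other class (default off: the synthetic
    pipeline controls segmentation exactly).
    """
    if width <= 0 or height <= 0:
        raise ValueError("screenshot dimensions must be positive")
    labels = np.zeros((height, width), dtype=np.uint8)
    dm_mask, dm_slice = _ellipse_mask(dm, width, height)
    labels[dm_slice][dm_mask] = DM_LABEL
    bc_mask, bc_slice = _ellipse_mask(bc, width, height)
    if bc_mask.size:
        sub = labels[bc_slice]
        sub[bc_mask & (sub == DM_LABEL)] = BC_LABEL
    if flip_rate > 0.0:
        if rng is None:
            raise ValueError("flip_rate > 0 requires an rng")
        flip = rng.random(labels.shape) < flip_rate
        noise = rng.integers(1, 3, size=labels.shape).astype(np.uint8)
        labels[flip] = (labels[flip] + noise[flip]) % 3
    return Screenshot(labels=labels)


def fit_ellipse_moments(pixels: np.ndarray) -> ImageEllipse:
    """Ellipse from a pixel set's centroid and second-order central moments.

    ``pixels`` is either a boolean mask or an (N, 2) array of (x, y)
    pixel-centre coordinates.  Axis directions and ratio come from the
    eigen-decomposition of the central-moment matrix; the axes are then
    scaled so the ellipse area equals the pixel count (the reference tool's
    same-area convention).  Requires >= 16 pixels and a non-degenerate
    spread in both principal directions.
    """
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        ys, xs = np.nonzero(arr)
        pts = np.column_stack([xs + 0.5, ys + 0.5]).astype(float)
    else:
        pts = np.asarray(arr, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("pixel coordinates must be an (N, 2) array")
    n = len(pts)
    if n < 16:
        raise ValueError(f"too few pixels for an ellipse fit ({n} < 16)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9:
        raise ValueError("degenerate pixel set: no spread along the minor axis")
    # uniform ellipse: variance along a principal axis is (semi-axis)^2 / 4
    a_raw, b_raw = 2.0 * np.sqrt(evals[1]), 2.0 * np.sqrt(evals[0])
    scale = np.sqrt(n / (np.pi * a_raw * b_raw))
    major_vec = evecs[:, 1]
    phi = np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0
    return ImageEllipse(
        cx_px=float(centroid[0]),
        cy_px=float(centroid[1]),
        a_px=float(a_raw * scale),
        b_px=float(b_raw * scale),
        phi_deg=float(phi),
    )


def measure(shot: Screenshot, mirror_diameter_mm: float = 20.0) -> Measurement:
    """Measure a screenshot: fit both ellipses, derive tilt and pixel scale.

    The pixel scale is anchored on the mirror's known physical diameter along
    the fitted major axis (a tilted circle keeps its true diameter along the
    tilt axis, making the major axis the tilt-robust reference):
    ``mm_per_px = diameter / (2 a_dm)``.  The mirror inclination is
    ``theta = arccos(b_dm / a_dm)``.
    """
    ys, xs = np.nonzero(shot.labels)
    vals = shot.labels[ys, xs]
    pts = np.column_stack([xs + 0.5, ys + 0.5]).astype(float)
    for value, name in ((DM_LABEL, "DM"), (BC_LABEL, "BC")):
        if not np.any(vals == value):
            raise MissingLabelError(name)
    # the mirror region is everything inside the rim: mirror plus its content
    dm = fit_ellipse_moments(pts)
    bc = fit_ellipse_moments(pts[vals == BC_LABEL])
    ratio = min(dm.axis_ratio, 1.0)
    theta = float(np.degrees(np.arccos(ratio)))
    mm_per_px = mirror_diameter_mm / (2.0 * dm.a_px)
    return Measurement(dm=dm, bc=bc, theta_deg=theta, mm_per_px=mm_per_px)
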