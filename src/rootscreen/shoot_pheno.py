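"""Rosette segmentation in HSV colour space and projected leaf area.

The segmentation is a per-pixel HSV box threshold followed by two
connected-component cleanup passes: small plant clusters are converted to
background, then small background clusters (holes) are converted to plant.
The defaults are the published operating point of the platform's colour
segmentation tool: hue window 21–222°, saturation ≥ 0.11, value ≥ 0.17
(relaxed to 0.08 on the last two imaging days, 19 and 21 DAI, when rosettes
darken), cluster-size limits 95 px (plant) / 24 px (background), raised to
502 / 473 on the late days.  Upper thresholds default to the channel maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv, hsv2rgb
from skimage.filters import sobel
from skimage.measure import label
from skimage.morphology import dilation, disk

from .plate_core import PlateGeometry, PlantId

__all__ = [
    "SegmentationParams",
    "ShootMeasurement",
    "remove_chromatic_aberration",
    "segment_rosette",
    "filter_clusters",
    "projected_leaf_area",
    "measure_shoot_image",
]


@dataclass(frozen=True)
class SegmentationParams:
    """HSV thresholds and cluster-size limits of the rosette segmentation.

    ``strict_exceeding`` switches the cluster filters to the literal reading
    in which components *larger* than the limit are converted (see
    :func:`filter_clusters`); the default keeps the small-cluster-cleanup
    reading, which is the only self-consistent one.
    """

    hue_lo_deg: float = 21.0
    hue_hi_deg: float = 222.0
    sat_lo: float = 0.11
    sat_hi: float = 1.0
    val_lo: float = 0.17
    val_hi: float = 1.0
    val_lo_late: float = 0.08
    plant_cluster_max_px: int = 95
    background_cluster_max_px: int = 24
    plant_cluster_max_px_late: int = 502
    background_cluster_max_px_late: int = 473
    late_days: frozenset = frozenset({19, 21})
    strict_exceeding: bool = False
    aberration_filter: bool = False
    aberration_radius_px: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.hue_lo_deg < self.hue_hi_deg <= 360):
            raise ValueError("need 0 <= hue_lo < hue_hi <= 360")
        if not (0 <= self.sat_lo <= self.sat_hi <= 1):
            raise ValueError("need 0 <= sat_lo <= sat_hi <= 1")
        if not (0 <= self.val_lo <= self.val_hi <= 1):
            raise ValueError("need 0 <= val_lo <= val_hi <= 1")
        for name in ("plant_cluster_max_px", "background_cluster_max_px",
                     "plant_cluster_max_px_late", "background_cluster_max_px_late"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")

    def val_lo_for(self, dai: int | None) -> float:
        return self.val_lo_late if dai in self.late_days else self.val_lo

    def cluster_limits_for(self, dai: int | None) -> tuple[int, int]:
        if dai in self.late_days:
            return self.plant_cluster_max_px_late, self.background_cluster_max_px_late
        return self.plant_cluster_max_px, self.background_cluster_max_px


@dataclass(frozen=True)
class ShootMeasurement:
    """Projected leaf area of one plant at one imaging day."""

    plant: PlantId | None
    dai: int | None
    projected_leaf_area_mm2: float
    n_plant_pixels: int


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected a 3-channel colour image")
    img = image[..., :3]
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(image.dtype).max
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def remove_chromatic_aberration(
    image: np.ndarray,
    radius_px: int = 2,
    edge_threshold: float = 0.25,
    fringe_min_sat: float = 0.4,
) -> np.ndarray:
    """Suppress thin high-chroma fringes along strong luminance edges.

    Chromatic aberration shows up as saturated (often magenta/cyan) pixels in
    a narrow band around dark/bright boundaries.  Pixels within
    ``radius_px`` of a strong value-channel edge whose saturation exceeds
    ``fringe_min_sat`` are desaturated to neutral grey; everything else is
    untouched, so the operation is idempotent.
    """
    rgb = _as_float_rgb(image)
    hsv = rgb2hsv(rgb)
    edges = sobel(hsv[..., 2]) > edge_threshold
    band = dilation(edges, disk(radius_px))
    fringe = band & (hsv[..., 1] >= fringe_min_sat)
    hsv[fringe, 1] = 0.0
    out = hsv2rgb(hsv)
    if np.issubdtype(image.dtype, np.integer):
        return (out * np.iinfo(image.dtype).max).round().astype(image.dtype)
    return out


def segment_rosette(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    dai: int | None = None,
    schedule_days: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Per-pixel HSV box threshold; returns the raw (pre-cleanup) plant mask.

    A pixel is plant iff hue ∈ [hue_lo, hue_hi], sat ∈ [sat_lo, sat_hi] and
    val ∈ [val_lo, val_hi], with the relaxed lower value threshold on the
    late imaging days.
    """
    params = params or SegmentationParams()
    if params.aberration_filter:
        image = remove_chromatic_aberration(image, params.aberration_radius_px)
    rgb = _as_float_rgb(image)
    hsv = rgb2hsv(rgb)
    if schedule_days is not None and dai is not None and dai not in schedule_days:
        warnings.warn(
            f"DAI {dai} is not an imaging day of the schedule; "
            "using non-late segmentation thresholds",
            stacklevel=2,
        )
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    val_lo = params.val_lo_for(dai)
    return (
        (hue >= params.hue_lo_deg) & (hue <= params.hue_hi_deg)
        & (sat >= params.sat_lo) & (sat <= params.sat_hi)
        & (val >= val_lo) & (val <= params.val_hi)
    )


def _convert_small(mask: np.ndarray, limit: int, connectivity: int,
                   strict: bool) -> np.ndarray:
    """Zero out connected True components by size.

    Default reading: components of size <= limit are converted (small-cluster
    cleanup; survival requires size > limit).  ``strict=True`` applies the
    literal "exceeding the limit are converted" reading instead.
    """
    out = mask.copy()
    lab = label(mask, connectivity=connectivity)
    if lab.max() == 0:
        return out
    sizes = np.bincount(lab.ravel())
    kill = (sizes > limit) if strict else (sizes <= limit)
    kill[0] = False
    out[kill[lab]] = False
    return out


def filter_clusters(
    mask: np.ndarray,
    params: SegmentationParams | None = None,
    dai: int | None = None,
) -> np.ndarray:
    """Two-pass cluster cleanup of a raw segmentation mask.

    First pass: plant components (8-connected) at or below the plant size
    limit become background.  Second pass: background components
    (4-connected) at or below the background size limit become plant.  The
    late-day limits apply on the late imaging days.  Idempotent.
    """
    params = params or SegmentationParams()
    plant_max, bg_max = params.cluster_limits_for(dai)
    mask = np.asarray(mask, dtype=bool)
    out = _convert_small(mask, plant_max, connectivity=2,
                         strict=params.strict_exceeding)
    holes = _convert_small(~out, bg_max, connectivity=1,
                           strict=params.strict_exceeding)
    return ~holes


def projected_leaf_area(
    mask: np.ndarray,
    geom: PlateGeometry,
    plant: PlantId | None = None,
    dai: int | None = None,
) -> ShootMeasurement:
    """Projected leaf area in mm²: plant pixel count / px_per_mm²."""
    n = int(np.count_nonzero(mask))
    return ShootMeasurement(plant, dai, n / geom.px_per_mm**2, n)


def measure_shoot_image(
    image: np.ndarray,
    geom: PlateGeometry,
    params: SegmentationParams | None = None,
    dai: int | None = None,
    plant: PlantId | None = None,
) -> tuple[ShootMeasurement, np.ndarray]:
    """Full shoot pipeline: segment, cleanup, measure.  Returns the
    measurement and the final mask."""
    params = params or SegmentationParams()
    raw = segment_rosette(image, params, dai)
    mask = filter_clusters(raw, params, dai)
    return projected_leaf_area(mask, geom, plant, dai), mask
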