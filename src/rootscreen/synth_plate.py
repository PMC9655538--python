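"""Stochastic root-system growth simulator and plate-image renderer.

The study's raw plate images are not deposited, so this module is the
canonical test input: it grows synthetic Arabidopsis-like root systems on a
virtual agar plate and renders backlit root images and top-view rosette
images, returning the exact geometry ("truth") alongside every image so that
downstream measurements can be validated against known values.

The growth model is a discrete-day polyline extension model, not a
mechanistic L-system: each root is a 2-D polyline extended at its tip in
1 mm arc-length steps, with small Normal heading perturbations (tortuosity)
and a deterministic gravitropic bias toward vertical.  First-order laterals
initiate at hard-core-Poisson-spaced points along the primary (a minimum
inter-lateral gap emulates the refractory zone of lateral priming; a pure
Poisson process would place a substantial fraction of laterals closer than
the imaging resolution), second-order laterals initiate the same way along
first-order laterals.  A lateral starts elongating a fixed emergence delay
after the parent tip has passed its initiation point, rounded up to whole
days, so every visible root has grown for at least one full day.

All randomness derives from per-root `numpy` seed sequences keyed by
(seed, plant, root lineage), which makes trajectories bit-reproducible and
— crucially for time-series tests — makes the day-9 snapshot of a plant a
strict extension of its day-7 snapshot.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .plate_core import (
    ImagingSchedule,
    PlantId,
    PlateGeometry,
    TreatmentLabel,
    hole_positions,
)

__all__ = [
    "SimParams",
    "RootPolyline",
    "SimTruth",
    "simulate_root_system",
    "render_root_image",
    "render_rosette_image",
    "simulate_experiment",
    "ExperimentDataset",
    "DEFAULT_SAMPLE_SIZES",
]

ORDER_NAMES = {0: "primary", 1: "lat1", 2: "lat2"}

#: Plants per treatment in the default design.
DEFAULT_SAMPLE_SIZES = {"Amb-Ctl": 12, "Amb-PsJN": 15, "HT-Ctl": 12, "HT-PsJN": 8}

#: Default per-rate treatment multipliers.  Ambient control is the reference;
#: the PsJN factors express bacterial growth stimulation, the high-temperature
#: factors express heat inhibition (strongest on the laterals), and the
#: HT-PsJN cell expresses partial rescue of the heat effect.
DEFAULT_TREATMENT_MULTIPLIERS: dict[str, dict[str, float]] = {
    "Amb-Ctl": {},
    "Amb-PsJN": {
        "primary_elongation_mm_per_day": 1.25,
        "lat1_elongation_mm_per_day": 1.5,
        "lat2_elongation_mm_per_day": 1.5,
        "lat1_initiation_per_cm": 1.3,
        "lat2_initiation_per_cm": 1.3,
    },
    "HT-Ctl": {
        "primary_elongation_mm_per_day": 0.6,
        "lat1_elongation_mm_per_day": 0.35,
        "lat2_elongation_mm_per_day": 0.4,
        "lat1_initiation_per_cm": 0.55,
        "lat2_initiation_per_cm": 0.5,
        "branching_angle_mean_deg": 0.8,
    },
    "HT-PsJN": {
        "primary_elongation_mm_per_day": 0.85,
        "lat1_elongation_mm_per_day": 0.55,
        "lat2_elongation_mm_per_day": 0.6,
        "lat1_initiation_per_cm": 0.75,
        "lat2_initiation_per_cm": 0.7,
        "branching_angle_mean_deg": 0.85,
    },
}

_RATE_FIELDS = (
    "primary_elongation_mm_per_day",
    "lat1_initiation_per_cm",
    "lat1_elongation_mm_per_day",
    "lat2_initiation_per_cm",
    "lat2_elongation_mm_per_day",
    "branching_angle_mean_deg",
)


@dataclass(frozen=True)
class SimParams:
    """Growth-model parameters (rates in mm/day, densities per cm of parent).

    ``treatment_multipliers`` maps a treatment name to multiplicative factors
    on any of the rate fields; unlisted rates keep their base value.
    """

    primary_elongation_mm_per_day: float = 10.0
    lat1_initiation_per_cm: float = 2.0
    lat1_elongation_mm_per_day: float = 3.0
    lat2_initiation_per_cm: float = 1.0
    lat2_elongation_mm_per_day: float = 3.0
    lat1_emergence_day: int = 2
    lat2_emergence_day: int = 3
    branching_angle_mean_deg: float = 55.0
    branching_angle_sd_deg: float = 10.0
    gravitropic_bend_per_mm: float = 0.4
    tortuosity_sd: float = 1.0
    elongation_exclusion_mm: float = 5.0
    min_lateral_gap_mm: float = 2.5
    treatment_multipliers: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_TREATMENT_MULTIPLIERS.items()
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS + (
            "branching_angle_sd_deg",
            "gravitropic_bend_per_mm",
            "tortuosity_sd",
            "elongation_exclusion_mm",
            "min_lateral_gap_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.branching_angle_mean_deg <= 90):
            raise ValueError("branching_angle_mean_deg must be in (0, 90]")
        for t, mults in self.treatment_multipliers.items():
            for k, v in mults.items():
                if v <= 0:
                    raise ValueError(f"multiplier {t}:{k} must be > 0")

    def for_treatment(self, treatment: TreatmentLabel | str | None) -> "SimParams":
        """Return a copy with the treatment's rate multipliers applied."""
        if treatment is None:
            return self
        name = treatment if isinstance(treatment, str) else treatment.name
        mults = self.treatment_multipliers.get(name, {})
        changes = {}
        for k, f in mults.items():
            if k not in _RATE_FIELDS:
                raise KeyError(f"unknown rate field in multipliers: {k}")
            changes[k] = getattr(self, k) * f
        if "branching_angle_mean_deg" in changes:
            changes["branching_angle_mean_deg"] = min(
                90.0, changes["branching_angle_mean_deg"]
            )
        return dataclasses.replace(self, **changes)


@dataclass
class RootPolyline:
    """One root at one time point: an ordered point list in plate mm."""

    root_id: str
    order: int  # 0 primary, 1 first-order lateral, 2 second-order lateral
    parent_id: str | None
    points: np.ndarray  # (N, 2) float, columns (x_mm, depth_mm)
    branch_pos_mm: float  # arc position on the parent where this root starts
    emergence_angle_deg: float | None
    start_day: int

    @property
    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class SimTruth:
    """Exact ground truth for one plant at one imaging day."""

    plant: PlantId
    day: int
    treatment: str | None
    roots: list[RootPolyline]

    def _length_mm(self, order: int) -> float:
        return sum(r.length_mm for r in self.roots if r.order == order)

    @property
    def length_primary_cm(self) -> float:
        return self._length_mm(0) / 10.0

    @property
    def length_lat1_cm(self) -> float:
        return self._length_mm(1) / 10.0

    @property
    def length_lat2_cm(self) -> float:
        return self._length_mm(2) / 10.0

    @property
    def length_total_cm(self) -> float:
        return (self._length_mm(0) + self._length_mm(1) + self._length_mm(2)) / 10.0

    @property
    def n_lat1(self) -> int:
        return sum(1 for r in self.roots if r.order == 1)

    @property
    def n_lat2(self) -> int:
        return sum(1 for r in self.roots if r.order == 2)

    @property
    def emergence_angles_deg(self) -> list[float]:
        return [r.emergence_angle_deg for r in self.roots
                if r.order == 1 and r.emergence_angle_deg is not None]

    @property
    def branching_angle_deg(self) -> float:
        angles = self.emergence_angles_deg
        return float(np.mean(angles)) if angles else float("nan")

    def all_points(self) -> np.ndarray:
        pts = [r.points for r in self.roots if len(r.points)]
        return np.vstack(pts) if pts else np.empty((0, 2))

    @property
    def depth_cm(self) -> float:
        pts = self.all_points()
        return float(pts[:, 1].max()) / 10.0 if len(pts) else 0.0

    @property
    def width_cm(self) -> float:
        pts = self.all_points()
        return float(pts[:, 0].max() - pts[:, 0].min()) / 10.0 if len(pts) else 0.0

    @property
    def convex_hull_area_cm2(self) -> float:
        pts = self.all_points()
        if len(pts) < 3:
            return 0.0
        try:
            return float(ConvexHull(pts).volume) / 100.0  # mm² -> cm²
        except QhullError:  # collinear
            return 0.0

    def traits_row(self) -> dict:
        return {
            "plant_id": str(self.plant),
            "treatment": self.treatment,
            "dai": self.day,
            "length_primary_cm": self.length_primary_cm,
            "length_lat1_cm": self.length_lat1_cm,
            "length_lat2_cm": self.length_lat2_cm,
            "length_total_cm": self.length_total_cm,
            "n_lat1": self.n_lat1,
            "n_lat2": self.n_lat2,
            "system_depth_cm": self.depth_cm,
            "system_width_cm": self.width_cm,
            "convex_hull_area_cm2": self.convex_hull_area_cm2,
            "branching_angle_deg": self.branching_angle_deg,
        }


# ---------------------------------------------------------------------------
# Growth engine

_STEP_MM = 1.0


def _plant_entropy(plant: PlantId) -> int:
    return zlib.crc32(str(plant).encode())


def _root_stream(params: SimParams, plant: PlantId, lineage: tuple[int, ...],
                 tag: int) -> np.random.Generator:
    seq = np.random.SeedSequence(
        [int(params.rng_seed) & 0x7FFFFFFF, _plant_entropy(plant), tag, *lineage]
    )
    return np.random.default_rng(seq)


def _grow_path(start: np.ndarray, heading0: float, length_mm: float,
               geom: PlateGeometry, rng: np.random.Generator,
               tort_sd_deg: float, bend_per_mm: float) -> np.ndarray:
    """Extend a polyline from `start` for `length_mm` of arc, clipping at the
    plate window.  Heading 0 points straight down; positive x is rightward.

    The noise draws are consumed strictly one per step, so the same stream
    re-created on a later day reproduces the earlier prefix exactly.
    """
    n_full = int(np.floor(length_mm / _STEP_MM))
    frac = length_mm - n_full * _STEP_MM
    pts = [start.astype(float)]
    heading = float(heading0)
    w, h = geom.root_window_width_mm, geom.root_window_height_mm
    for i in range(n_full + (1 if frac > 1e-9 else 0)):
        step = _STEP_MM if i < n_full else frac
        heading += np.deg2rad(rng.normal(0.0, tort_sd_deg)) * (step / _STEP_MM)
        # gravitropic relaxation toward vertical (heading 0)
        relax = np.deg2rad(bend_per_mm) * step
        heading -= np.sign(heading) * min(relax, abs(heading))
        nxt = pts[-1] + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0.0 <= nxt[0] <= w and 0.0 <= nxt[1] <= h):
            break  # root reached the plate boundary; growth stops here
        pts.append(nxt)
    return np.asarray(pts)


def _initiation_sites(rng: np.random.Generator, parent_len_mm: float,
                      density_per_cm: float, min_gap_mm: float,
                      angle_mean: float, angle_sd: float):
    """Hard-core point process along a parent root.

    Gaps are min_gap + Exponential(10/density); for each site an emergence
    angle (truncated Normal on (0, 90]) and a side (left/right) are drawn
    from the same stream, so the first k sites are identical whatever length
    the parent later reaches.
    """
    if density_per_cm <= 0 or parent_len_mm <= 0:
        return []
    scale = 10.0 / density_per_cm  # mean exponential gap in mm
    sites = []
    s = 0.0
    while True:
        s += min_gap_mm + rng.exponential(scale)
        angle = rng.normal(angle_mean, angle_sd)
        while not (0.0 < angle <= 90.0):
            angle = rng.normal(angle_mean, angle_sd)
        side = 1.0 if rng.integers(2) else -1.0
        if s > parent_len_mm:
            break
        sites.append((s, angle, side))
    return sites


def _tangent_at(path: np.ndarray, arc_mm: float) -> float:
    """Heading (rad from vertical) of a unit-step path at arc position."""
    i = min(int(round(arc_mm / _STEP_MM)), len(path) - 1)
    i = max(i, 1)
    d = path[i] - path[i - 1]
    return float(np.arctan2(d[0], d[1]))


def _point_at(path: np.ndarray, arc_mm: float) -> np.ndarray:
    i = min(int(np.floor(arc_mm / _STEP_MM)), len(path) - 2)
    i = max(i, 0)
    t = arc_mm / _STEP_MM - i
    return path[i] * (1 - t) + path[i + 1] * min(t, 1.0)


def simulate_root_system(
    params: SimParams,
    plant: PlantId,
    day: int,
    geom: PlateGeometry | None = None,
    treatment: TreatmentLabel | str | None = None,
) -> SimTruth:
    """Grow one plant's root system up to `day` and return its exact truth.

    The primary root emerges at the plant's hole and grows downward at the
    primary elongation rate, capped by the plate window (at most 200 mm
    deep); laterals emerge in whole-day cohorts behind the elongation zone.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    geom = geom or PlateGeometry()
    eff = params.for_treatment(treatment)
    holes = hole_positions(geom)
    if not (0 <= plant.hole_index < geom.n_holes):
        raise ValueError(f"hole_index {plant.hole_index} out of range")
    x0 = holes[plant.hole_index]
    tname = treatment if isinstance(treatment, (str, type(None))) else treatment.name
    roots: list[RootPolyline] = []

    # --- primary root -----------------------------------------------------
    prim_len = eff.primary_elongation_mm_per_day * day
    prim_rng = _root_stream(params, plant, (0,), tag=0)
    prim_path = _grow_path(np.array([x0, 0.0]), 0.0, prim_len, geom, prim_rng,
                           eff.tortuosity_sd, eff.gravitropic_bend_per_mm)
    primary = RootPolyline("P", 0, None, prim_path, 0.0, None, 0)
    roots.append(primary)
    if day == 0 or primary.length_mm <= 0:
        return SimTruth(plant, day, tname, roots if primary.length_mm > 0 else
                        [RootPolyline("P", 0, None, prim_path[:1], 0.0, None, 0)])

    prim_realized = primary.length_mm

    # --- first-order laterals ---------------------------------------------
    init_rng = _root_stream(params, plant, (0,), tag=1)
    sites1 = _initiation_sites(
        init_rng, prim_realized, eff.lat1_initiation_per_cm,
        eff.min_lateral_gap_mm, eff.branching_angle_mean_deg,
        eff.branching_angle_sd_deg,
    )
    for i, (s, angle, side) in enumerate(sites1):
        # the primary tip must have passed s + the elongation-zone exclusion
        t_pass = (s + eff.elongation_exclusion_mm) / eff.primary_elongation_mm_per_day
        t0 = int(np.ceil(t_pass)) + eff.lat1_emergence_day
        age = day - t0
        if age <= 0:
            continue
        if s + eff.elongation_exclusion_mm > prim_realized:
            continue  # tip stopped (window cap) before this site matured
        lat_len = eff.lat1_elongation_mm_per_day * age
        h0 = _tangent_at(prim_path, s) + side * np.deg2rad(angle)
        p0 = _point_at(prim_path, s)
        rng = _root_stream(params, plant, (1, i), tag=0)
        path = _grow_path(p0, h0, lat_len, geom, rng,
                          eff.tortuosity_sd, eff.gravitropic_bend_per_mm)
        lat = RootPolyline(f"L{i}", 1, "P", path, s, angle, t0)
        if lat.length_mm <= 0:
            continue
        roots.append(lat)

        # --- second-order laterals on this first-order lateral -------------
        init2 = _root_stream(params, plant, (1, i), tag=1)
        sites2 = _initiation_sites(
            init2, lat.length_mm, eff.lat2_initiation_per_cm,
            eff.min_lateral_gap_mm, eff.branching_angle_mean_deg,
            eff.branching_angle_sd_deg,
        )
        for j, (s2, angle2, side2) in enumerate(sites2):
            t_pass2 = t0 + (s2 + eff.elongation_exclusion_mm) / eff.lat1_elongation_mm_per_day
            t02 = int(np.ceil(t_pass2)) + eff.lat2_emergence_day
            age2 = day - t02
            if age2 <= 0:
                continue
            if s2 + eff.elongation_exclusion_mm > lat.length_mm:
                continue
            lat2_len = eff.lat2_elongation_mm_per_day * age2
            h02 = _tangent_at(path, s2) + side2 * np.deg2rad(angle2)
            p02 = _point_at(path, s2)
            rng2 = _root_stream(params, plant, (2, i, j), tag=0)
            path2 = _grow_path(p02, h02, lat2_len, geom, rng2,
                               eff.tortuosity_sd, eff.gravitropic_bend_per_mm)
            lat2 = RootPolyline(f"L{i}.{j}", 2, f"L{i}", path2, s2, angle2, t02)
            if lat2.length_mm > 0:
                roots.append(lat2)

    return SimTruth(plant, day, tname, roots)


# ---------------------------------------------------------------------------
# Rendering

def polylines_to_px(truth: SimTruth, geom: PlateGeometry) -> list[np.ndarray]:
    """Truth polylines in image pixel coordinates, rows (row, col)."""
    out = []
    for r in truth.roots:
        if len(r.points) < 2:
            continue
        rows = geom.agar_surface_row_px + r.points[:, 1] * geom.px_per_mm
        cols = r.points[:, 0] * geom.px_per_mm
        out.append(np.column_stack([rows, cols]))
    return out


def rasterize_truth(truth: SimTruth, geom: PlateGeometry,
                    stroke_px: int = 3) -> np.ndarray:
    """Binary mask of the truth polylines at the given stroke width."""
    shape = (geom.agar_surface_row_px + geom.height_px + 1, geom.width_px + 1)
    mask = np.zeros(shape, dtype=bool)
    for poly in polylines_to_px(truth, geom):
        p = np.round(poly).astype(int)
        p[:, 0] = np.clip(p[:, 0], 0, shape[0] - 1)
        p[:, 1] = np.clip(p[:, 1], 0, shape[1] - 1)
        for (r0, c0), (r1, c1) in zip(p[:-1], p[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    if stroke_px > 1:
        mask = dilation(mask, disk(stroke_px // 2))
    return mask


def render_root_image(
    truth: SimTruth,
    geom: PlateGeometry,
    stroke_px: int = 3,
    noise_sd: float = 0.1,
    invert: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Render a backlit-style 16-bit grayscale root image.

    Roots are bright strokes on a dark background (foreground 1.0 vs
    background 0.1 before quantization, i.e. SNR = 0.9 / noise_sd); pass
    ``invert=True`` for dark-roots polarity.  Returns the image together
    with the truth it rendered.
    """
    for r in truth.roots:
        if len(r.points) and (
            r.points[:, 0].min() < -1e-6
            or r.points[:, 0].max() > geom.root_window_width_mm + 1e-6
            or r.points[:, 1].max() > geom.root_window_height_mm + 1e-6
        ):
            raise ValueError(f"polyline {r.root_id} extends outside the plate window")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mask = rasterize_truth(truth, geom, stroke_px)
    img = np.full(mask.shape, 0.1, dtype=np.float64)
    img[mask] = 1.0
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    if invert:
        img = 1.1 - img
    img16 = (np.clip(img, 0.0, 1.2) / 1.2 * 65535).astype(np.uint16)
    return img16, truth


def render_rosette_image(
    n_leaves: int,
    leaf_area_mm2: float,
    geom: PlateGeometry,
    frame_px: int = 360,
    rng: np.random.Generator | int | None = None,
    n_specks: int = 6,
    noise_sd: float = 0.015,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Render a top-view rosette: green elliptical leaves on a dark collar.

    Returns ``(rgb_image, true_area_mm2, plant_mask)`` where the true
    projected area is the exact rendered plant pixel count / px_per_mm².
    Small plant-coloured specks (algal flecks / reflections, below the
    cluster-filter size) and bluish bright specks are added as distractors.
    """
    if leaf_area_mm2 < 0:
        raise ValueError("leaf_area_mm2 must be >= 0")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ppm = geom.px_per_mm
    area_px = leaf_area_mm2 * ppm**2
    if area_px > 0.5 * frame_px**2:
        raise ValueError("requested leaf area does not fit the frame")
    shape = (frame_px, frame_px)
    mask = np.zeros(shape, dtype=bool)
    hsv = np.zeros((*shape, 3), dtype=np.float64)
    hsv[..., 2] = 0.03  # dark collar background

    cy = cx = frame_px / 2.0
    if n_leaves > 0 and area_px > 0:
        per_leaf = area_px / n_leaves
        # ellipse with 2:1 axis ratio and area pi*a*b = per_leaf
        b = np.sqrt(per_leaf / (2 * np.pi))
        a = 2 * b
        # a filled centre (the meristem and youngest leaves) keeps the gaps
        # between leaf bases from becoming enclosed background pockets
        rr, cc = draw_ellipse(cy, cx, 1.2 * b, 1.2 * b, shape=shape)
        mask[rr, cc] = True
        hsv[rr, cc] = (rng.uniform(95, 135) / 360.0, rng.uniform(0.55, 0.9),
                       rng.uniform(0.35, 0.8))
        for _ in range(n_leaves):
            theta = rng.uniform(0, 2 * np.pi)
            # inner end of the leaf near the rosette centre
            d = a * 0.95
            ecy = cy + d * np.sin(theta)
            ecx = cx + d * np.cos(theta)
            rr, cc = draw_ellipse(ecy, ecx, a, b, shape=shape, rotation=-theta)
            mask[rr, cc] = True
            hsv[rr, cc, 0] = rng.uniform(95, 135) / 360.0
            hsv[rr, cc, 1] = rng.uniform(0.55, 0.9)
            hsv[rr, cc, 2] = rng.uniform(0.35, 0.8)
    # distractor specks, kept away from the rosette
    for _ in range(n_specks):
        r0 = rng.uniform(0.05, 0.95) * frame_px
        c0 = rng.uniform(0.05, 0.95) * frame_px
        if np.hypot(r0 - cy, c0 - cx) < 0.35 * frame_px:
            continue
        rad = rng.uniform(1.5, 3.0)  # area <= ~30 px, under the 95-px filter
        rr, cc = draw_ellipse(r0, c0, rad, rad, shape=shape)
        if rng.integers(2):  # plant-coloured fleck (removed by cluster filter)
            hsv[rr, cc] = (rng.uniform(95, 135) / 360.0, 0.7, 0.5)
        else:  # bluish reflection (outside the hue window)
            hsv[rr, cc] = (300 / 360.0, 0.8, 0.7)
    from skimage.color import hsv2rgb

    rgb = hsv2rgb(hsv)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    img = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    true_area_mm2 = float(mask.sum()) / ppm**2
    return img, true_area_mm2, mask


# ---------------------------------------------------------------------------
# Whole-experiment simulation

def _shoot_area_mm2(day: int, treatment: str, rng: np.random.Generator) -> float:
    """Projected leaf area trajectory (mm²): early-exponential growth with a
    treatment-dependent rate and ~8% lognormal plant-to-plant noise."""
    rates = {"Amb-Ctl": 0.33, "Amb-PsJN": 0.35, "HT-Ctl": 0.29, "HT-PsJN": 0.30}
    base = 1.2 * np.exp(rates[treatment] * day)
    return float(base * rng.lognormal(0.0, 0.08))


@dataclass
class ExperimentDataset:
    """In-memory result of :func:`simulate_experiment`."""

    truth: dict[tuple[str, int], SimTruth]          # (plant_id, dai) -> truth
    truth_long: pd.DataFrame                        # one row per root type
    truth_traits: pd.DataFrame                      # one row per plant per day
    shoot_truth: pd.DataFrame                       # projected leaf area truth
    plants: list[tuple[PlantId, str]]
    manifest: pd.DataFrame | None = None


def design_plants(sample_sizes: dict[str, int] | None = None,
                  n_holes: int = 3) -> list[tuple[PlantId, str]]:
    """Assign plants to plates (``n_holes`` per plate) within each treatment."""
    sizes = sample_sizes or DEFAULT_SAMPLE_SIZES
    plants: list[tuple[PlantId, str]] = []
    for tname, n in sizes.items():
        for k in range(n):
            plate = f"{tname}-p{k // n_holes + 1:02d}"
            plants.append((PlantId(plate, k % n_holes), tname))
    return plants


def simulate_experiment(
    params: SimParams | None = None,
    geom: PlateGeometry | None = None,
    schedule: ImagingSchedule | None = None,
    sample_sizes: dict[str, int] | None = None,
    out_dir: str | Path | None = None,
    render_images: bool = False,
    stroke_px: int = 3,
    noise_sd: float = 0.1,
) -> ExperimentDataset:
    """Simulate the full factorial experiment: every plant at every imaging
    day, with treatment multipliers applied.

    With ``out_dir`` set, truth tables (and images, if requested) are written
    to disk along with a manifest mapping files to plant/day metadata.  Image
    rendering pairs one 16-bit root TIFF and one RGB shoot TIFF per plate
    per day (root images carry all plants of a plate, as acquired).
    """
    params = params or SimParams()
    geom = geom or PlateGeometry()
    schedule = schedule or ImagingSchedule()
    plants = design_plants(sample_sizes, geom.n_holes)
    ids = [str(p) for p, _ in plants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate PlantId in design")

    truth: dict[tuple[str, int], SimTruth] = {}
    long_rows, trait_rows, shoot_rows = [], [], []
    for plant, tname in plants:
        shoot_rng = np.random.default_rng(np.random.SeedSequence(
            [int(params.rng_seed) & 0x7FFFFFFF, _plant_entropy(plant), 99]))
        for day in schedule:
            t = simulate_root_system(params, plant, day, geom, tname)
            truth[(str(plant), day)] = t
            trait_rows.append(t.traits_row())
            for order, name in ORDER_NAMES.items():
                long_rows.append({
                    "plant_id": str(plant), "treatment": tname, "dai": day,
                    "root_type": name,
                    "length_cm": t._length_mm(order) / 10.0,
                    "n_lat1": t.n_lat1, "n_lat2": t.n_lat2,
                    "branching_angle_deg": t.branching_angle_deg,
                })
            shoot_rows.append({
                "plant_id": str(plant), "treatment": tname, "dai": day,
                "projected_leaf_area_mm2": _shoot_area_mm2(day, tname, shoot_rng),
            })

    truth_long = pd.DataFrame(long_rows)
    truth_traits = pd.DataFrame(trait_rows)
    shoot_truth = pd.DataFrame(shoot_rows)
    manifest = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth_long.to_csv(out / "truth_long.csv", index=False)
        truth_traits.to_csv(out / "truth_traits.csv", index=False)
        shoot_truth.to_csv(out / "shoot_truth.csv", index=False)
        if render_images:
            import tifffile

            (out / "images").mkdir(exist_ok=True)
            man_rows = []
            plates: dict[str, list[tuple[PlantId, str]]] = {}
            for plant, tname in plants:
                plates.setdefault(plant.plate_id, []).append((plant, tname))
            for plate_id, members in plates.items():
                for day in schedule:
                    merged = SimTruth(
                        members[0][0], day, members[0][1],
                        [r for p, _ in members
                         for r in truth[(str(p), day)].roots],
                    )
                    img_rng = np.random.default_rng(np.random.SeedSequence(
                        [int(params.rng_seed) & 0x7FFFFFFF,
                         zlib.crc32(plate_id.encode()), day, 7]))
                    img, _ = render_root_image(merged, geom, stroke_px,
                                               noise_sd, rng=img_rng)
                    fname = f"images/{plate_id}_d{day:02d}_root.tif"
                    tifffile.imwrite(out / fname, img)
                    man_rows.append({"file": fname, "plate_id": plate_id,
                                     "dai": day, "kind": "root",
                                     "treatment": members[0][1]})
            manifest = pd.DataFrame(man_rows)
            manifest.to_csv(out / "manifest.csv", index=False)

    return ExperimentDataset(truth, truth_long, truth_traits, shoot_truth,
                             plants, manifest)
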