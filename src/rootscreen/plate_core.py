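"""Plate geometry, calibration and experiment metadata.

Every other module works in the coordinate frame defined here: image row 0 at
the top of the root window, depth increasing downward (roots grow down in the
acquired image), the agar surface at ``agar_surface_row_px`` being depth 0.
All exported traits are in cm / cm²; internal geometry is in mm and pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PlateGeometry",
    "Temperature",
    "Inoculation",
    "TreatmentLabel",
    "TREATMENTS",
    "ImagingSchedule",
    "PlantId",
    "pixel_to_depth",
    "depth_to_pixel",
    "hole_positions",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class PlateGeometry:
    """Geometry and calibration of the agar plate's root window.

    The plate offers roots a 200 × 100 mm window; shoots grow through three
    5 mm holes on the short top side, spaced 29 mm apart with the middle hole
    centred.  ``px_per_mm`` is a required calibration input of the cameras
    (it is never auto-detected); ``agar_surface_row_px`` is the pixel row of
    the agar surface, i.e. of depth 0.
    """

    root_window_height_mm: float = 200.0
    root_window_width_mm: float = 100.0
    n_holes: int = 3
    hole_spacing_mm: float = 29.0
    hole_diameter_mm: float = 5.0
    px_per_mm: float = 4.0
    agar_surface_row_px: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        for name in ("root_window_height_mm", "root_window_width_mm",
                     "hole_spacing_mm", "hole_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_holes < 1:
            raise ValueError("n_holes must be >= 1")
        # validate hole positions fall inside the plate width
        hole_positions(self)

    @property
    def width_px(self) -> int:
        return int(round(self.root_window_width_mm * self.px_per_mm))

    @property
    def height_px(self) -> int:
        return int(round(self.root_window_height_mm * self.px_per_mm))

    @property
    def max_depth_cm(self) -> float:
        return self.root_window_height_mm / 10.0


class Temperature(str, enum.Enum):
    ambient = "ambient"
    high = "high"


class Inoculation(str, enum.Enum):
    control = "control"
    psjn = "psjn"


@dataclass(frozen=True)
class TreatmentLabel:
    """One cell of the 2 × 2 microbe × temperature design."""

    temperature: Temperature
    inoculation: Inoculation

    _NAMES = {
        (Temperature.ambient, Inoculation.control): "Amb-Ctl",
        (Temperature.ambient, Inoculation.psjn): "Amb-PsJN",
        (Temperature.high, Inoculation.control): "HT-Ctl",
        (Temperature.high, Inoculation.psjn): "HT-PsJN",
    }

    @property
    def name(self) -> str:
        return self._NAMES[(self.temperature, self.inoculation)]

    @classmethod
    def from_name(cls, name: str) -> "TreatmentLabel":
        for (t, i), n in cls._NAMES.items():
            if n == name:
                return cls(t, i)
        raise ValueError(f"unknown treatment name: {name!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The four treatment combinations, in the conventional reporting order.
TREATMENTS: tuple[TreatmentLabel, ...] = (
    TreatmentLabel(Temperature.ambient, Inoculation.control),
    TreatmentLabel(Temperature.ambient, Inoculation.psjn),
    TreatmentLabel(Temperature.high, Inoculation.control),
    TreatmentLabel(Temperature.high, Inoculation.psjn),
)


@dataclass(frozen=True)
class ImagingSchedule:
    """Imaging days after inoculation (DAI); strictly increasing."""

    days_after_inoculation: tuple[int, ...] = (5, 7, 9, 12, 14, 16, 19, 21)

    def __post_init__(self) -> None:
        days = self.days_after_inoculation
        if any(d < 0 for d in days):
            raise ValueError("DAI must be >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("DAI must be strictly increasing")

    def __iter__(self):
        return iter(self.days_after_inoculation)

    def __len__(self) -> int:
        return len(self.days_after_inoculation)


@dataclass(frozen=True, order=True)
class PlantId:
    """A single plant: one hole on one plate."""

    plate_id: str
    hole_index: int

    def __str__(self) -> str:
        return f"{self.plate_id}:h{self.hole_index}"

    @classmethod
    def parse(cls, s: str) -> "PlantId":
        plate, _, hole = s.rpartition(":h")
        return cls(plate, int(hole))


class OutOfWindowError(ValueError):
    """A coordinate lies outside the plate's root window."""


def pixel_to_depth(row_px: float, geom: PlateGeometry) -> float:
    """Depth in cm of an image row; depth 0 at the agar surface, increasing
    downward.

    Raises :class:`OutOfWindowError` for rows above the agar surface.
    """
    if row_px < geom.agar_surface_row_px:
        raise OutOfWindowError(
            f"row {row_px} is above the agar surface row {geom.agar_surface_row_px}"
        )
    return (row_px - geom.agar_surface_row_px) / geom.px_per_mm / 10.0


def depth_to_pixel(depth_cm: float, geom: PlateGeometry) -> float:
    """Inverse of :func:`pixel_to_depth` (continuous row coordinate)."""
    if depth_cm < 0:
        raise OutOfWindowError("depth must be >= 0")
    return geom.agar_surface_row_px + depth_cm * 10.0 * geom.px_per_mm


def hole_positions(geom: PlateGeometry) -> np.ndarray:
    """x coordinates (mm) of the shoot holes along the plate's top edge.

    The holes form a centred arithmetic sequence: middle hole exactly at
    half the plate width, neighbours at ± the hole spacing.
    """
    center = geom.root_window_width_mm / 2.0
    offsets = (np.arange(geom.n_holes) - (geom.n_holes - 1) / 2.0)
    xs = center + offsets * geom.hole_spacing_mm
    if xs.min() < 0 or xs.max() > geom.root_window_width_mm:
        raise ValueError(
            f"hole positions {xs} fall outside the plate width "
            f"[0, {geom.root_window_width_mm}] mm"
        )
    return xs


# ---------------------------------------------------------------------------
# Config file I/O

@dataclass
class Config:
    """Bundle of every tunable the pipeline reads, loadable from YAML/JSON."""

    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    schedule: ImagingSchedule = field(default_factory=ImagingSchedule)
    segmentation: dict = field(default_factory=dict)
    simulator: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)


def load_config(path: str | Path) -> Config:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geom = PlateGeometry(**raw.get("geometry", {}))
    sched_raw = raw.get("schedule", {})
    days = sched_raw.get("days_after_inoculation")
    sched = ImagingSchedule(tuple(days)) if days else ImagingSchedule()
    return Config(
        geometry=geom,
        schedule=sched,
        segmentation=raw.get("segmentation", {}),
        simulator=raw.get("simulator", {}),
        analysis=raw.get("analysis", {}),
    )


def save_config(cfg: Config, path: str | Path) -> None:
    raw = {
        "geometry": asdict(cfg.geometry),
        "schedule": {"days_after_inoculation": list(cfg.schedule)},
        "segmentation": cfg.segmentation,
        "simulator": cfg.simulator,
        "analysis": cfg.analysis,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
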