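"""Linking root structures across imaging days and growth-rate computation.

Roots only extend between imaging days, so a previously analyzed structure
must be contained (up to a pixel tolerance) in the next day's skeleton.
``append_timepoint`` exploits that asymmetry: the earlier graph's pixels are
matched into the later skeleton, matched roots inherit their earlier
identities and order labels, and only the newly grown parts are classified
de novo.  Growth rates are per-interval finite differences, reported at the
interval's end day, so rate curves have points at 7, 9, …, 21 DAI under the
default imaging schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .plate_core import PlateGeometry
from .root_pheno import (
    DepthProfile,
    GraphParams,
    RootSystemGraph,
    RootTraits,
    build_root_graphs,
    classify_root_orders,
)

__all__ = [
    "GrowthSeries",
    "TrackingError",
    "append_timepoint",
    "growth_rates",
    "relative_effect",
    "LENGTH_TRAITS",
]

#: Trait columns for which finite-difference growth rates are computed.
LENGTH_TRAITS = (
    "length_total_cm",
    "length_primary_cm",
    "length_lat1_cm",
    "length_lat2_cm",
)


class TrackingError(RuntimeError):
    """The previous day's structure could not be found in the next image."""

    def __init__(self, overlap: float, threshold: float):
        self.overlap = overlap
        super().__init__(
            f"previous structure not contained in next skeleton "
            f"(overlap {overlap:.3f} < threshold {threshold:.2f}); "
            "check plate identity/orientation")


def _edge_points(graph: RootSystemGraph) -> np.ndarray:
    return np.vstack([e.polyline for e in graph.edges.values()])


def _root_points(graph: RootSystemGraph, root_id: str) -> np.ndarray:
    return np.vstack([e.polyline for e in graph.edges.values()
                      if e.root_id == root_id])


def append_timepoint(
    prev: RootSystemGraph,
    next_mask: np.ndarray,
    geom: PlateGeometry | None = None,
    params: GraphParams | None = None,
    match_tol_px: float = 3.0,
    overlap_threshold: float = 0.8,
) -> RootSystemGraph:
    """Carry root identities from ``prev`` into the next day's image.

    The next mask is analyzed de novo, then each previous root's pixels are
    tested for containment within ``match_tol_px`` of the new skeleton.  If
    the overall containment falls below ``overlap_threshold`` a
    :class:`TrackingError` is raised (wrong plate, flipped image, …).
    Otherwise each previous lateral is matched to the new lateral that best
    contains it and keeps its identity; laterals with no predecessor are new
    growth and keep their de-novo labels under fresh identities.
    """
    geom = geom or prev.geom
    params = params or GraphParams()
    if not prev.labeled:
        raise ValueError("prev graph must be order-labeled")
    graphs = build_root_graphs(next_mask, geom, params)
    if prev.hole_index not in graphs:
        raise TrackingError(0.0, overlap_threshold)
    nxt = graphs[prev.hole_index]
    nxt.plant = prev.plant
    classify_root_orders(nxt, params)

    prev_pts = _edge_points(prev)
    tree = cKDTree(_edge_points(nxt))
    d, _ = tree.query(prev_pts, k=1)
    overlap = float(np.mean(d <= match_tol_px))
    if overlap < overlap_threshold:
        raise TrackingError(overlap, overlap_threshold)

    # match previous roots to next roots of the same order by containment
    prev_roots = sorted({(e.order, e.root_id) for e in prev.edges.values()
                         if e.root_id is not None and e.order in (1, 2)})
    next_roots: dict[str, np.ndarray] = {}
    next_order: dict[str, int] = {}
    for e in nxt.edges.values():
        if e.root_id is not None and e.order in (1, 2):
            next_order[e.root_id] = e.order
            next_roots.setdefault(e.root_id, None)
    trees = {rid: cKDTree(_root_points(nxt, rid)) for rid in next_roots}

    mapping: dict[str, str] = {}
    taken: set[str] = set()
    for order, prid in prev_roots:
        pts = _root_points(prev, prid)
        best, best_frac = None, 0.0
        for rid, t in trees.items():
            if rid in taken or next_order[rid] != order:
                continue
            dd, _ = t.query(pts, k=1)
            frac = float(np.mean(dd <= match_tol_px))
            if frac > best_frac:
                best, best_frac = rid, frac
        if best is not None and best_frac >= 0.5:
            mapping[best] = prid
            taken.add(best)

    # rename: matched roots inherit previous ids; new roots get fresh ids
    def fresh(order: int, existing: set[str]) -> str:
        i = 0
        while True:
            cand = f"L{i}" if order == 1 else f"Lx.{i}"
            if cand not in existing:
                return cand
            i += 1

    final: dict[str, str] = {}
    used_ids = set(mapping.values())
    for rid in sorted(next_roots):
        if rid in mapping:
            final[rid] = mapping[rid]
        else:
            parent_new = rid.rsplit(".", 1)[0] if "." in rid else None
            if parent_new and parent_new in final:
                base = final[parent_new]
                j = 0
                while f"{base}.{j}" in used_ids:
                    j += 1
                final[rid] = f"{base}.{j}"
            else:
                final[rid] = fresh(next_order[rid], used_ids)
            used_ids.add(final[rid])
    for e in nxt.edges.values():
        if e.root_id in final:
            e.root_id = final[e.root_id]
    return nxt


@dataclass
class GrowthSeries:
    """One plant's trajectory: traits (and optionally profiles and shoot
    measurements) at each imaging day, with per-interval growth rates."""

    plant: str
    treatment: str | None
    days: list[int] = field(default_factory=list)
    traits: list[RootTraits] = field(default_factory=list)
    profiles: list[DepthProfile | None] = field(default_factory=list)
    shoot_area_mm2: list[float | None] = field(default_factory=list)

    def add(self, dai: int, traits: RootTraits,
            profile: DepthProfile | None = None,
            shoot_area_mm2: float | None = None) -> None:
        if self.days and dai <= self.days[-1]:
            raise ValueError("DAIs must be added in strictly increasing order")
        self.days.append(dai)
        self.traits.append(traits)
        self.profiles.append(profile)
        self.shoot_area_mm2.append(shoot_area_mm2)

    def traits_frame(self) -> pd.DataFrame:
        rows = []
        for d, t in zip(self.days, self.traits):
            r = t.as_dict()
            r["dai"], r["plant_id"], r["treatment"] = d, self.plant, self.treatment
            rows.append(r)
        return pd.DataFrame(rows)

    def rates(self, shrink_tol: float = 0.05) -> pd.DataFrame:
        return growth_rates(self.traits_frame(), shrink_tol=shrink_tol)


def growth_rates(
    traits: pd.DataFrame,
    trait_cols: tuple[str, ...] = LENGTH_TRAITS,
    shrink_tol: float = 0.05,
) -> pd.DataFrame:
    """Finite-difference growth rates (cm/day) per trait per interval.

    Expects a tidy table with ``plant_id``, ``dai`` and trait columns; rates
    are assigned to the interval's end DAI.  Lengths cannot shrink, so
    negative rates beyond ``shrink_tol`` cm/day are flagged in the
    ``suspect`` column (measurement noise).  Plants with a single timepoint
    yield no rows.
    """
    cols = [c for c in trait_cols if c in traits.columns]
    rows = []
    for pid, sub in traits.groupby("plant_id", sort=True):
        sub = sub.sort_values("dai")
        if len(sub) < 2:
            continue
        days = sub["dai"].to_numpy()
        treatment = sub["treatment"].iloc[0] if "treatment" in sub else None
        for trait in cols:
            vals = sub[trait].to_numpy(dtype=float)
            dv = np.diff(vals)
            dt = np.diff(days).astype(float)
            for i in range(len(dv)):
                rate = dv[i] / dt[i]
                rows.append({
                    "plant_id": pid, "treatment": treatment,
                    "dai": int(days[i + 1]), "trait": trait,
                    "value": vals[i + 1], "rate": rate,
                    "suspect": bool(rate < -shrink_tol),
                })
    return pd.DataFrame(
        rows, columns=["plant_id", "treatment", "dai", "trait",
                       "value", "rate", "suspect"])


def relative_effect(mean_treated: float, mean_control: float) -> float:
    """Percent difference of a treated mean vs its control mean.

    ``100 × (treated − control) / control``; undefined (NaN) when the
    control mean is not positive.
    """
    if not np.isfinite(mean_control) or mean_control <= 0:
        return float("nan")
    return 100.0 * (mean_treated - mean_control) / mean_control
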