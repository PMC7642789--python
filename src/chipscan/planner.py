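"""Shot planning and crystal-economy metrics.

Each accepted crystal receives one primary shot at the deepest interior
point of its polygon eroded by half the X-ray beam FWHM, plus subsequent
shots on a hexagonal grid of pitch one FWHM inside the eroded polygon —
every exposure then probes a fresh crystal volume and adjacent shots
never overlap.  In pump–probe mode, crystals close enough to a retained
shot to receive collateral laser illumination are excluded outright,
evaluated greedily in rank order so higher-ranked crystals win.

All planner coordinates are in µm (scale pixel-space candidates with the
``pixel_scale`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely import affinity
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import polylabel

from .finder import CrystalCandidate

__all__ = [
    "BeamParams",
    "Shot",
    "ShotPlan",
    "OutcomeTable",
    "plan_shots",
    "economy_metrics",
]


@dataclass(frozen=True)
class BeamParams:
    """X-ray and pump-laser beam sizes (µm).

    ``exclusion_radius`` defaults to the laser FWHM (500 µm focal spot):
    any crystal inside that disc around a shot sees collateral laser
    light.
    """

    xray_fwhm: float = 50.0
    laser_fwhm: float = 500.0
    exclusion_radius: float | None = None

    def __post_init__(self) -> None:
        if self.xray_fwhm <= 0 or self.laser_fwhm <= 0:
            raise ValueError("beam sizes must be positive")
        if self.exclusion_radius is not None and self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be positive")

    @property
    def exclusion(self) -> float:
        return (
            self.laser_fwhm if self.exclusion_radius is None else self.exclusion_radius
        )


@dataclass(frozen=True)
class Shot:
    """One planned X-ray exposure position."""

    id: int
    center: tuple[float, float]  # µm
    kind: str  # "primary" | "subsequent"
    crystal_id: int


@dataclass
class ShotPlan:
    """Ordered shots, per-crystal exclusions, and the parameters used."""

    shots: list[Shot]
    excluded: list[tuple[int, str]]  # (crystal_id, reason)
    params: BeamParams
    pump_probe: bool = False
    crystal_rank: dict[int, int] = field(default_factory=dict)  # id -> rank


def _largest_polygon(geom) -> Polygon | None:
    if isinstance(geom, Polygon):
        return geom if geom.area > 0 else None
    if isinstance(geom, MultiPolygon):
        parts = [g for g in geom.geoms if g.area > 0]
        return max(parts, key=lambda g: g.area) if parts else None
    return None


def _hex_grid(poly: Polygon, pitch: float) -> list[tuple[float, float]]:
    """Hexagonal lattice points of the given pitch inside ``poly``."""
    minx, miny, maxx, maxy = poly.bounds
    dy = pitch * math.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = miny
    while y <= maxy:
        x = minx + (pitch / 2.0 if row % 2 else 0.0)
        while x <= maxx:
            if poly.contains(Point(x, y)):
                pts.append((x, y))
            x += pitch
        y += dy
        row += 1
    return pts


def plan_shots(
    ranked: Sequence[CrystalCandidate],
    params: BeamParams,
    pump_probe: bool = False,
    max_count: int | None = None,
    min_score: float | None = None,
    pixel_scale: float = 1.0,
) -> ShotPlan:
    """Plan X-ray shots over a ranked candidate list.

    Steps, in rank order: apply the count/score cutoff; skip candidates
    flagged cluster or irregular; erode each accepted polygon by half the
    X-ray FWHM (too-small crystals are excluded); place the primary shot
    at the eroded polygon's pole of inaccessibility and subsequent shots
    on a FWHM-pitch hexagonal grid inside it; drop any shot within one
    FWHM of an already retained shot; in pump–probe mode exclude every
    lower-ranked crystal whose polygon comes within the laser exclusion
    radius of a retained shot.

    An empty candidate list yields an empty plan.
    """
    fwhm = params.xray_fwhm
    shots: list[Shot] = []
    excluded: list[tuple[int, str]] = []
    laser_excluded: set[int] = set()
    rank_of: dict[int, int] = {}
    retained = np.empty((0, 2))
    n_planned = 0
    for rank, cand in enumerate(ranked):
        rank_of[cand.id] = rank
        if max_count is not None and n_planned >= max_count:
            excluded.append((cand.id, "below_cutoff"))
            continue
        if min_score is not None and cand.score < min_score:
            excluded.append((cand.id, "below_cutoff"))
            continue
        if cand.id in laser_excluded:
            excluded.append((cand.id, "laser_proximity"))
            continue
        if "cluster" in cand.flags:
            excluded.append((cand.id, "cluster"))
            continue
        if "irregular" in cand.flags:
            excluded.append((cand.id, "irregular"))
            continue
        poly = cand.polygon
        if pixel_scale != 1.0:
            poly = affinity.scale(
                poly, xfact=pixel_scale, yfact=pixel_scale, origin=(0, 0)
            )
        eroded = _largest_polygon(poly.buffer(-fwhm / 2.0))
        if eroded is None:
            excluded.append((cand.id, "too_small"))
            continue
        primary = polylabel(eroded, tolerance=fwhm / 100.0)
        sites = [(primary.x, primary.y, "primary")]
        for x, y in _hex_grid(eroded, fwhm):
            if math.hypot(x - primary.x, y - primary.y) >= fwhm * (1 - 1e-9):
                sites.append((x, y, "subsequent"))
        kept_here: list[Shot] = []
        for x, y, kind in sites:
            if retained.size:
                dmin = float(np.min(np.hypot(retained[:, 0] - x, retained[:, 1] - y)))
                if dmin < fwhm * (1 - 1e-9):
                    if kind == "primary":
                        kept_here = []
                        break  # crystal unshootable without overlapping a shot
                    continue
            if kept_here:
                d_own = min(
                    math.hypot(s.center[0] - x, s.center[1] - y) for s in kept_here
                )
                if d_own < fwhm * (1 - 1e-9):
                    continue
            kept_here.append(Shot(len(shots) + len(kept_here), (x, y), kind, cand.id))
        if not kept_here:
            excluded.append((cand.id, "shot_conflict"))
            continue
        shots.extend(kept_here)
        retained = np.array([s.center for s in shots])
        n_planned += 1
        if pump_probe:
            radius = params.exclusion
            for other in ranked[rank + 1 :]:
                if other.id in laser_excluded:
                    continue
                opoly = other.polygon
                if pixel_scale != 1.0:
                    opoly = affinity.scale(
                        opoly, xfact=pixel_scale, yfact=pixel_scale, origin=(0, 0)
                    )
                for s in kept_here:
                    if opoly.distance(Point(*s.center)) < radius:
                        laser_excluded.add(other.id)
                        break
    return ShotPlan(
        shots=shots,
        excluded=excluded,
        params=params,
        pump_probe=pump_probe,
        crystal_rank=rank_of,
    )


@dataclass
class OutcomeTable:
    """Per-image hit/indexing outcomes plus crystal-preparation totals."""

    hit: np.ndarray  # bool per image
    indexed_merged: np.ndarray  # bool per image
    crystals_prepared: int
    images_taken: int | None = None  # defaults to len(hit)

    def __post_init__(self) -> None:
        self.hit = np.asarray(self.hit, dtype=bool)
        self.indexed_merged = np.asarray(self.indexed_merged, dtype=bool)
        if self.hit.shape != self.indexed_merged.shape:
            raise ValueError("hit and indexed_merged must align")
        if np.any(self.indexed_merged & ~self.hit):
            raise ValueError("an indexed/merged image must also be a hit")
        if self.images_taken is None:
            self.images_taken = int(self.hit.size)
        if self.images_taken < self.hit.size:
            raise ValueError("images_taken below the number of recorded images")
        if self.crystals_prepared < int(self.hit.sum()):
            raise ValueError("crystals_prepared below the observed hit count")


def economy_metrics(outcomes: OutcomeTable) -> dict[str, float]:
    """Hit rate, diffraction yield, and their effective forms.

    hit_rate = hits / images taken; diffraction_yield = hits / crystals
    prepared; the effective variants count only images successfully
    indexed and merged.  The yield metrics replace the image count in the
    denominator by the number of prepared crystals, measuring the economy
    of crystal use rather than of beam time.
    """
    if not outcomes.images_taken or outcomes.images_taken <= 0:
        raise ValueError("images_taken must be positive")
    if outcomes.crystals_prepared <= 0:
        raise ValueError("crystals_prepared must be positive")
    hits = int(outcomes.hit.sum())
    good = int(outcomes.indexed_merged.sum())
    return {
        "hit_rate": hits / outcomes.images_taken,
        "effective_hit_rate": good / outcomes.images_taken,
        "diffraction_yield": hits / outcomes.crystals_prepared,
        "effective_yield": good / outcomes.crystals_prepared,
    }
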