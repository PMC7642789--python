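"""Crystal recognition on the chip montage.

Well-faceted protein crystals appear in transmission micrographs as
convex shapes bounded by sharp, nearly parallel edges.  The recognizer
therefore works on line segments: detect segments from intensity
gradients, filter them by length, pair them by parallelism / gap /
longitudinal overlap, validate that the strip between a paired couple of
edges is actually darker than the background (crystals attenuate the
transmitted light), group pairs that share segments into connected
components, and take each component's convex hull as a crystal candidate.
Candidates are flagged when they look like clusters or irregular debris,
and ranked by a projected-volume proxy (area × minimum caliper width) or
a user-supplied scorer.

The segment-detection backend is pluggable: any callable returning
:class:`Segment` objects deterministically for a fixed input satisfies
the contract.  The bundled backend is Canny edge detection followed by a
probabilistic Hough transform with a fixed random stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon, box
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

__all__ = [
    "FinderParams",
    "Segment",
    "SegmentPair",
    "CrystalCandidate",
    "detect_segments",
    "filter_segments",
    "pair_segments",
    "form_candidates",
    "rank_candidates",
    "find_crystals",
    "match_candidates",
]


@dataclass
class FinderParams:
    """Tunable recognition parameters (all lengths in pixels).

    ``curved`` mode relaxes the parallelism tolerance to 25° so crystals
    with gently curved edges (polygonal approximations of arcs) still
    pair up.
    """

    canny_sigma: float = 1.5
    hough_threshold: int = 10
    hough_line_length: int = 8
    hough_line_gap: int = 3
    min_length: float = 12.0
    parallel_tol: float = 10.0
    gap_bounds: tuple[float, float] = (6.0, 300.0)
    min_overlap: float = 0.3
    area_bounds: tuple[float, float] = (400.0, 1.0e6)
    max_aspect: float = 8.0
    intensity_margin: float = 0.04  # darker-than-background test for pairs
    merge_overlap: float = 0.5  # component hulls overlapping this much merge
    curved: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curved:
            self.parallel_tol = max(self.parallel_tol, 25.0)


@dataclass(frozen=True)
class Segment:
    """A detected straight edge segment."""

    p0: tuple[float, float]  # (x, y) pixels
    p1: tuple[float, float]
    strength: float = 0.0

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def angle(self) -> float:
        """Orientation in degrees, normalized to [0, 180)."""
        a = math.degrees(
            math.atan2(self.p1[1] - self.p0[1], self.p1[0] - self.p0[0])
        )
        return a % 180.0

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            0.5 * (self.p0[0] + self.p1[0]),
            0.5 * (self.p0[1] + self.p1[1]),
        )


@dataclass(frozen=True)
class SegmentPair:
    """Two nearly parallel segments hypothesized to bound one crystal."""

    i: int
    j: int
    parallelism_deviation: float  # degrees
    gap: float  # perpendicular distance, pixels
    longitudinal_overlap: float  # fraction of the shorter projection


@dataclass
class CrystalCandidate:
    """A crystal hypothesis: convex hull of a component of paired segments."""

    id: int
    polygon: Polygon  # pixel coordinates of the analyzed image
    score: float = 0.0
    flags: set[str] = field(default_factory=set)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def min_caliper_width(self) -> float:
        """Smallest distance between parallel supporting lines of the hull."""
        coords = np.asarray(self.polygon.convex_hull.exterior.coords)[:-1]
        n = len(coords)
        if n < 3:
            return 0.0
        best = math.inf
        for a in range(n):
            e = coords[(a + 1) % n] - coords[a]
            norm = np.hypot(*e)
            if norm < 1e-12:
                continue
            nvec = np.array([-e[1], e[0]]) / norm
            d = (coords - coords[a]) @ nvec
            best = min(best, float(d.max() - d.min()))
        return 0.0 if math.isinf(best) else best


def detect_segments(
    image: np.ndarray, params: FinderParams | None = None
) -> list[Segment]:
    """Detect straight edge segments from intensity gradients.

    Canny edges followed by a probabilistic Hough transform; the Hough
    sampling stream is seeded from ``params.seed`` so the result is
    deterministic for a fixed image and parameter set.
    """
    if params is None:
        params = FinderParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a grayscale image")
    edges = canny(img, sigma=params.canny_sigma)
    lines = probabilistic_hough_line(
        edges,
        threshold=params.hough_threshold,
        line_length=params.hough_line_length,
        line_gap=params.hough_line_gap,
        rng=np.random.default_rng(params.seed),
    )
    segments = [
        Segment(p0=(float(a[0]), float(a[1])), p1=(float(b[0]), float(b[1])))
        for a, b in lines
    ]
    return [replace(s, strength=s.length) for s in segments]


def filter_segments(
    segments: Sequence[Segment], min_length: float
) -> list[Segment]:
    """Keep segments at least ``min_length`` long, preserving order."""
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    return [s for s in segments if s.length >= min_length]


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def pair_segments(
    segments: Sequence[Segment],
    parallel_tol: float = 10.0,
    gap_bounds: tuple[float, float] = (10.0, 300.0),
    min_overlap: float = 0.3,
) -> list[SegmentPair]:
    """Pair segments by parallelism, perpendicular gap and overlap.

    A pair (i < j) is reported when the angular deviation is within
    ``parallel_tol`` degrees, the perpendicular distance between the two
    segments (measured along the pair's mean normal) lies inside
    ``gap_bounds``, and the projections onto the pair's mean direction
    overlap by at least ``min_overlap`` of the shorter projection.
    """
    if parallel_tol <= 0 or min_overlap < 0:
        raise ValueError("tolerances must be positive")
    n = len(segments)
    if n < 2:
        return []
    angles = np.array([s.angle for s in segments])
    p0 = np.array([s.p0 for s in segments])
    p1 = np.array([s.p1 for s in segments])
    pairs: list[SegmentPair] = []
    for i in range(n - 1):
        d = np.abs(angles[i + 1 :] - angles[i]) % 180.0
        dev = np.minimum(d, 180.0 - d)
        for jj in np.nonzero(dev <= parallel_tol)[0]:
            j = i + 1 + int(jj)
            # mean direction, respecting the 180-degree wrap
            delta = (angles[j] - angles[i] + 90.0) % 180.0 - 90.0
            mean_deg = math.radians(angles[i] + 0.5 * delta)
            u = np.array([math.cos(mean_deg), math.sin(mean_deg)])
            nvec = np.array([-u[1], u[0]])
            pi = np.vstack([p0[i], p1[i]])
            pj = np.vstack([p0[j], p1[j]])
            gap = abs(float((pj.mean(axis=0) - pi.mean(axis=0)) @ nvec))
            if not (gap_bounds[0] <= gap <= gap_bounds[1]):
                continue
            ti = pi @ u
            tj = pj @ u
            lo = max(ti.min(), tj.min())
            hi = min(ti.max(), tj.max())
            shorter = min(ti.max() - ti.min(), tj.max() - tj.min())
            if shorter <= 0:
                continue
            frac = max(0.0, hi - lo) / shorter
            if frac < min_overlap:
                continue
            pairs.append(SegmentPair(i, j, float(dev[jj]), gap, frac))
    return pairs


def _pair_is_dark(
    seg_a: Segment,
    seg_b: Segment,
    image: np.ndarray,
    background: float,
    margin: float,
    n_samples: int = 11,
) -> bool:
    """True when the strip between two paired edges is darker than background.

    Samples the midline between the two segments over their common
    longitudinal extent; a crystal interior attenuates the transmitted
    light, while an accidental pairing of edges from two distinct objects
    spans bright background.
    """
    ca = np.array([seg_a.p0, seg_a.p1]).mean(axis=0)
    cb = np.array([seg_b.p0, seg_b.p1]).mean(axis=0)
    # direction of the pair: use the longer segment's direction
    longer = seg_a if seg_a.length >= seg_b.length else seg_b
    u = np.array(
        [longer.p1[0] - longer.p0[0], longer.p1[1] - longer.p0[1]]
    )
    u /= np.hypot(*u) + 1e-12
    half = 0.4 * min(seg_a.length, seg_b.length)
    ts = np.linspace(-half, half, n_samples)
    # sample several lines spanning the region between the two edges; a
    # genuine crystal interior is dark throughout, while an accidental
    # cross-object pairing spans bright background somewhere in between
    fracs = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
    anchors = ca[None, :] + fracs[:, None] * (cb - ca)[None, :]
    pts = anchors[:, None, :] + ts[None, :, None] * u[None, None, :]
    pts = pts.reshape(-1, 2)
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, image.shape[1] - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, image.shape[0] - 1)
    dark = image[rows, cols] < background - margin
    return float(dark.mean()) >= 0.85


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def form_candidates(
    pairs: Sequence[SegmentPair],
    segments: Sequence[Segment],
    image: np.ndarray,
    params: FinderParams | None = None,
) -> list[CrystalCandidate]:
    """Group validated pairs into crystal candidates.

    Pairs whose inter-segment strip is not darker than the image median
    are discarded; surviving pairs sharing segments form connected
    components, each component's convex hull of segment endpoints becomes
    a candidate polygon (clipped to the image).  Components whose hulls
    largely coincide (two edge pairs of the same crystal) are merged;
    remaining partially-overlapping hulls are flagged ``cluster``, and
    hulls with out-of-bounds area or aspect ratio are flagged
    ``irregular``.
    """
    if params is None:
        params = FinderParams()
    img = np.asarray(image, dtype=float)
    background = float(np.median(img))
    good = [
        p
        for p in pairs
        if _pair_is_dark(
            segments[p.i], segments[p.j], img, background, params.intensity_margin
        )
    ]
    if not good:
        return []
    uf = _UnionFind(len(segments))
    for p in good:
        uf.union(p.i, p.j)
    members: dict[int, set[int]] = {}
    for p in good:
        members.setdefault(uf.find(p.i), set()).update((p.i, p.j))

    frame = box(0.0, 0.0, float(img.shape[1] - 1), float(img.shape[0] - 1))

    def hull_of(seg_ids: set[int]) -> Polygon | None:
        pts = []
        for sid in seg_ids:
            pts.extend([segments[sid].p0, segments[sid].p1])
        hull = MultiPoint(pts).convex_hull
        if not isinstance(hull, Polygon):
            return None
        hull = hull.intersection(frame)
        return hull if isinstance(hull, Polygon) and hull.area > 0 else None

    comps = []
    for seg_ids in members.values():
        hull = hull_of(seg_ids)
        if hull is not None:
            comps.append((seg_ids, hull))
    comps.sort(key=lambda c: min(c[0]))

    # merge components that are two views of the same crystal
    merged = True
    while merged and len(comps) > 1:
        merged = False
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                pa, pb = comps[a][1], comps[b][1]
                inter = pa.intersection(pb).area
                if inter > params.merge_overlap * min(pa.area, pb.area):
                    ids = comps[a][0] | comps[b][0]
                    hull = hull_of(ids)
                    if hull is None:
                        continue
                    comps[a] = (ids, hull)
                    del comps[b]
                    merged = True
                    break
            if merged:
                break

    candidates = [
        CrystalCandidate(id=idx, polygon=hull) for idx, (_, hull) in enumerate(comps)
    ]
    for a in range(len(candidates)):
        for b in range(a + 1, len(candidates)):
            if candidates[a].polygon.intersection(candidates[b].polygon).area > 0:
                candidates[a].flags.add("cluster")
                candidates[b].flags.add("cluster")
    lo_area, hi_area = params.area_bounds
    for c in candidates:
        width = c.min_caliper_width
        aspect = math.inf if width <= 0 else (c.area / width) / width
        if not (lo_area <= c.area <= hi_area) or aspect > params.max_aspect:
            c.flags.add("irregular")
    return candidates


def rank_candidates(
    candidates: Sequence[CrystalCandidate],
    scorer: Callable[[CrystalCandidate], float] | None = None,
) -> list[CrystalCandidate]:
    """Rank candidates by descending score.

    The default score is area × minimum caliper width — a volume proxy
    from the 2D projection.  Ties break deterministically by (score,
    area, id), so permuting the input never changes the ranked sequence.
    """
    if scorer is None:
        scorer = lambda c: c.area * c.min_caliper_width  # noqa: E731
    ranked = []
    for c in candidates:
        c.score = float(scorer(c))
        if c.score < 0:
            raise ValueError("scores must be non-negative")
        ranked.append(c)
    return sorted(ranked, key=lambda c: (-c.score, -c.area, c.id))


def find_crystals(
    image: np.ndarray, params: FinderParams | None = None
) -> list[CrystalCandidate]:
    """Full recognition pipeline: detect, filter, pair, form, rank."""
    if params is None:
        params = FinderParams()
    segments = detect_segments(image, params)
    segments = filter_segments(segments, params.min_length)
    pairs = pair_segments(
        segments, params.parallel_tol, params.gap_bounds, params.min_overlap
    )
    candidates = form_candidates(pairs, segments, image, params)
    return rank_candidates(candidates)


def match_candidates(
    candidates: Sequence[CrystalCandidate],
    truth_polygons: Sequence[np.ndarray],
    iou_min: float = 0.3,
) -> dict[str, float]:
    """Score candidates against ground-truth polygons.

    A candidate matches a truth crystal when its centroid lies inside the
    truth polygon and their intersection-over-union is at least
    ``iou_min``.  Recall counts truth crystals matched by any candidate;
    precision counts matched candidates among those not flagged
    cluster/irregular (the set actually proposed for targeting).
    """
    truths = [Polygon(p) for p in truth_polygons]
    matched_truth = set()
    accepted = [c for c in candidates if not c.flags]
    matched_accepted = 0
    for c in candidates:
        cen = Point(*c.centroid)
        hit = False
        for ti, t in enumerate(truths):
            if not t.contains(cen):
                continue
            inter = c.polygon.intersection(t).area
            union = c.polygon.union(t).area
            if union > 0 and inter / union >= iou_min:
                matched_truth.add(ti)
                hit = True
        if hit and not c.flags:
            matched_accepted += 1
    recall = len(matched_truth) / len(truths) if truths else 1.0
    precision = matched_accepted / len(accepted) if accepted else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(truths),
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
    }
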