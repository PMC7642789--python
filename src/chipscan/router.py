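"""Shot visiting order: by crystal rank, or a near-shortest route.

The ranked order visits crystals in descending rank (primary shot first
within a crystal); the traveling-salesman option builds an open path by
nearest-neighbour construction from the shot closest to the chip origin
and improves it with 2-opt to a local optimum, which greatly reduces the
total stage motion on chips with many targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .planner import ShotPlan

__all__ = ["Route", "ranked_route", "tsp_route", "route_length_mm"]


@dataclass
class Route:
    """A visiting order over a plan's shots."""

    order: list[int]  # shot ids, a permutation
    total_length_mm: float
    strategy: str  # "ranked" | "tsp"
    converged: bool = True  # 2-opt reached a local optimum


def _coords(plan: ShotPlan) -> np.ndarray:
    return np.array([s.center for s in plan.shots], dtype=float)


def route_length_mm(plan: ShotPlan, order: list[int]) -> float:
    """Total Euclidean path length (mm) of visiting shots in ``order``."""
    pos = {s.id: s.center for s in plan.shots}
    pts = np.array([pos[i] for i in order], dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T)))) / 1000.0


def ranked_route(plan: ShotPlan) -> Route:
    """Visit shots in descending crystal rank, primary before subsequent."""
    if not plan.shots:
        raise ValueError("plan has no shots")
    order = [
        s.id
        for s in sorted(
            plan.shots,
            key=lambda s: (
                plan.crystal_rank.get(s.crystal_id, 0),
                s.kind != "primary",
                s.id,
            ),
        )
    ]
    return Route(order, route_length_mm(plan, order), "ranked")


def _two_opt(pts: np.ndarray, order: np.ndarray, max_passes: int = 50):
    """Best-improvement 2-opt on an open path; never increases length."""
    n = len(order)
    converged = False
    for _ in range(max_passes):
        improved = False
        path = pts[order]
        # d[i] = distance between consecutive path points i, i+1
        seg = np.diff(path, axis=0)
        d = np.hypot(seg[:, 0], seg[:, 1])
        for i in range(n - 2):
            # reversing order[i+1 .. j] replaces edges (i, i+1) and (j, j+1)
            j = np.arange(i + 1, n - 1)
            cur = d[i] + d[j]
            new = np.hypot(*(path[j] - path[i]).T) + np.hypot(
                *(path[j + 1] - path[i + 1]).T
            )
            gains = cur - new
            best = int(np.argmax(gains))
            if gains[best] > 1e-9:
                jj = i + 1 + best
                order[i + 1 : jj + 1] = order[i + 1 : jj + 1][::-1]
                path = pts[order]
                seg = np.diff(path, axis=0)
                d = np.hypot(seg[:, 0], seg[:, 1])
                improved = True
        # the final edge into the last point: handled because j runs to n-2
        if not improved:
            converged = True
            break
    return order, converged


def tsp_route(plan: ShotPlan, seed: int = 0) -> Route:
    """Open near-shortest path over all shots (nearest neighbour + 2-opt).

    The construction starts from the shot nearest the chip origin and is
    fully deterministic; ``seed`` is accepted for interface stability and
    reserved for randomized restarts.
    """
    if not plan.shots:
        raise ValueError("plan has no shots")
    del seed  # deterministic construction; no randomness needed
    pts = _coords(plan)
    n = len(pts)
    ids = np.array([s.id for s in plan.shots])
    if n == 1:
        return Route([int(ids[0])], 0.0, "tsp")
    start = int(np.argmin(np.hypot(pts[:, 0], pts[:, 1])))
    unvisited = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=int)
    order[0] = start
    unvisited[start] = False
    cur = start
    for i in range(1, n):
        dist = np.hypot(pts[:, 0] - pts[cur, 0], pts[:, 1] - pts[cur, 1])
        dist[~unvisited] = np.inf
        cur = int(np.argmin(dist))
        order[i] = cur
        unvisited[cur] = False
    order, converged = _two_opt(pts, order)
    id_order = [int(ids[i]) for i in order]
    return Route(id_order, route_length_mm(plan, id_order), "tsp", converged)
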