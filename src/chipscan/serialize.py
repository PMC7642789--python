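"""JSON/CSV interchange for candidates, plans and routes (CLI plumbing)."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from shapely.geometry import Polygon

from .finder import CrystalCandidate
from .planner import BeamParams, Shot, ShotPlan
from .router import Route

__all__ = [
    "candidates_to_json",
    "candidates_from_json",
    "plan_to_json",
    "plan_from_json",
    "plan_to_csv",
    "route_to_json",
    "route_from_json",
]


def candidates_to_json(
    candidates: list[CrystalCandidate], path: str | Path, pixel_scale: float = 1.0
) -> None:
    data = {
        "pixel_scale_um": pixel_scale,
        "candidates": [
            {
                "id": c.id,
                "score": c.score,
                "flags": sorted(c.flags),
                "polygon_px": [[float(x), float(y)] for x, y in c.polygon.exterior.coords[:-1]],
            }
            for c in candidates
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def candidates_from_json(path: str | Path) -> tuple[list[CrystalCandidate], float]:
    data = json.loads(Path(path).read_text())
    cands = [
        CrystalCandidate(
            id=c["id"],
            polygon=Polygon(c["polygon_px"]),
            score=c.get("score", 0.0),
            flags=set(c.get("flags", [])),
        )
        for c in data["candidates"]
    ]
    return cands, float(data.get("pixel_scale_um", 1.0))


def plan_to_json(plan: ShotPlan, path: str | Path, route: Route | None = None) -> None:
    data = {
        "params": {
            "xray_fwhm": plan.params.xray_fwhm,
            "laser_fwhm": plan.params.laser_fwhm,
            "exclusion_radius": plan.params.exclusion,
        },
        "pump_probe": plan.pump_probe,
        "crystal_rank": {str(k): v for k, v in plan.crystal_rank.items()},
        "shots": [
            {
                "id": s.id,
                "crystal_id": s.crystal_id,
                "kind": s.kind,
                "x_um": s.center[0],
                "y_um": s.center[1],
            }
            for s in plan.shots
        ],
        "excluded": [[cid, reason] for cid, reason in plan.excluded],
    }
    if route is not None:
        data["route"] = {
            "order": route.order,
            "total_length_mm": route.total_length_mm,
            "strategy": route.strategy,
        }
    Path(path).write_text(json.dumps(data, indent=1))


def plan_from_json(path: str | Path) -> tuple[ShotPlan, Route | None]:
    data = json.loads(Path(path).read_text())
    p = data["params"]
    plan = ShotPlan(
        shots=[
            Shot(s["id"], (s["x_um"], s["y_um"]), s["kind"], s["crystal_id"])
            for s in data["shots"]
        ],
        excluded=[(c, r) for c, r in data["excluded"]],
        params=BeamParams(
            xray_fwhm=p["xray_fwhm"],
            laser_fwhm=p["laser_fwhm"],
            exclusion_radius=p.get("exclusion_radius"),
        ),
        pump_probe=data["pump_probe"],
        crystal_rank={int(k): v for k, v in data.get("crystal_rank", {}).items()},
    )
    route = None
    if "route" in data:
        r = data["route"]
        route = Route(r["order"], r["total_length_mm"], r["strategy"])
    return plan, route


def plan_to_csv(plan: ShotPlan, path: str | Path, route: Route | None = None) -> None:
    visit = {}
    if route is not None:
        visit = {sid: i for i, sid in enumerate(route.order)}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["shot_id", "crystal_id", "kind", "x_um", "y_um"]
        if visit:
            header.append("visit_order")
        writer.writerow(header)
        for s in plan.shots:
            row = [s.id, s.crystal_id, s.kind, f"{s.center[0]:.3f}", f"{s.center[1]:.3f}"]
            if visit:
                row.append(visit.get(s.id, ""))
            writer.writerow(row)


def route_to_json(route: Route, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "order": route.order,
                "total_length_mm": route.total_length_mm,
                "strategy": route.strategy,
                "converged": route.converged,
            },
            indent=1,
        )
    )


def route_from_json(path: str | Path) -> Route:
    d = json.loads(Path(path).read_text())
    return Route(d["order"], d["total_length_mm"], d["strategy"], d.get("converged", True))
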