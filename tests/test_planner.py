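"""Shot planning and crystal-economy metrics."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from chipscan.finder import CrystalCandidate, rank_candidates
from chipscan.fixtures import ChipSpec, sample_crystals
from chipscan.planner import (
    BeamParams,
    OutcomeTable,
    economy_metrics,
    plan_shots,
)


def rect_candidate(cid, x0, y0, w, h):
    return CrystalCandidate(
        id=cid, polygon=Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)])
    )


def test_small_crystal_gets_single_primary_shot():
    cand = rect_candidate(0, 0, 0, 80.0, 70.0)  # < 2 x FWHM in both axes
    plan = plan_shots(rank_candidates([cand]), BeamParams(xray_fwhm=50.0))
    kinds = [s.kind for s in plan.shots]
    assert kinds == ["primary"]


def test_large_crystal_gets_subsequent_shots():
    cand = rect_candidate(0, 0, 0, 300.0, 100.0)
    fwhm = 50.0
    plan = plan_shots(rank_candidates([cand]), BeamParams(xray_fwhm=fwhm))
    kinds = [s.kind for s in plan.shots]
    assert kinds.count("primary") == 1
    assert kinds.count("subsequent") >= 2
    pts = np.array([s.center for s in plan.shots])
    eroded = cand.polygon.buffer(-fwhm / 2.0)
    for p in pts:
        assert eroded.distance(Point(*p)) <= 1e-6
    d = np.hypot(
        pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
    )
    np.fill_diagonal(d, np.inf)
    assert d.min() >= fwhm - 1e-6


def test_pump_probe_excludes_nearby_crystal():
    big = rect_candidate(0, 0, 0, 200.0, 150.0)
    small = rect_candidate(1, 300.0, 0.0, 60.0, 60.0)  # ~200 µm from big's shots
    plan = plan_shots(
        rank_candidates([big, small]),
        BeamParams(xray_fwhm=50.0, laser_fwhm=500.0),
        pump_probe=True,
    )
    assert (1, "laser_proximity") in plan.excluded
    assert all(s.crystal_id != 1 for s in plan.shots)


def test_no_pump_probe_keeps_both_crystals():
    big = rect_candidate(0, 0, 0, 200.0, 150.0)
    small = rect_candidate(1, 300.0, 0.0, 80.0, 80.0)
    plan = plan_shots(rank_candidates([big, small]), BeamParams(xray_fwhm=50.0))
    assert {s.crystal_id for s in plan.shots} == {0, 1}


def test_flagged_candidates_are_skipped():
    good = rect_candidate(0, 0, 0, 100.0, 100.0)
    clustered = rect_candidate(1, 500.0, 0, 100.0, 100.0)
    clustered.flags.add("cluster")
    debris = rect_candidate(2, 1000.0, 0, 100.0, 100.0)
    debris.flags.add("irregular")
    plan = plan_shots(rank_candidates([good, clustered, debris]), BeamParams(50.0))
    assert {s.crystal_id for s in plan.shots} == {0}
    assert (1, "cluster") in plan.excluded
    assert (2, "irregular") in plan.excluded


def test_rank_cutoff_never_adds_shots():
    rng = np.random.default_rng(4)
    cands = [
        rect_candidate(i, *rng.uniform(0, 4000, 2), *rng.uniform(80, 200, 2))
        for i in range(12)
    ]
    ranked = rank_candidates(cands)
    full = plan_shots(ranked, BeamParams(50.0))
    for cutoff in (8, 4, 1):
        limited = plan_shots(ranked, BeamParams(50.0), max_count=cutoff)
        assert len(limited.shots) <= len(full.shots)
        assert len({s.crystal_id for s in limited.shots}) <= cutoff


def test_score_cutoff():
    big = rect_candidate(0, 0, 0, 200.0, 200.0)
    small = rect_candidate(1, 1000.0, 0, 90.0, 90.0)
    ranked = rank_candidates([big, small])
    plan = plan_shots(ranked, BeamParams(50.0), min_score=1e6)
    assert {s.crystal_id for s in plan.shots} == {0}
    assert (1, "below_cutoff") in plan.excluded


def test_empty_candidate_list_gives_empty_plan():
    plan = plan_shots([], BeamParams(50.0))
    assert plan.shots == [] and plan.excluded == []


def test_planning_invariants_on_random_chips():
    fwhm = 50.0
    for seed in range(10):
        spec = ChipSpec(window_mm=(5.0, 5.0), n_crystals=40, seed=seed)
        cands = [
            CrystalCandidate(id=c.id, polygon=Polygon(c.polygon_um))
            for c in sample_crystals(spec)
        ]
        plan = plan_shots(
            rank_candidates(cands),
            BeamParams(xray_fwhm=fwhm),
            pump_probe=seed % 2 == 0,
        )
        pts = np.array([s.center for s in plan.shots])
        if len(pts) > 1:
            d = np.hypot(
                pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
            )
            np.fill_diagonal(d, np.inf)
            assert d.min() >= fwhm - 1e-6
        shot_ids = {s.crystal_id for s in plan.shots}
        assert shot_ids.isdisjoint({cid for cid, _ in plan.excluded})


class TestEconomyMetrics:
    def test_textbook_rates(self):
        hit = np.zeros(200, dtype=bool)
        hit[:40] = True
        outcomes = OutcomeTable(hit, np.zeros(200, bool), crystals_prepared=1000)
        m = economy_metrics(outcomes)
        assert m["hit_rate"] == pytest.approx(0.20)
        assert m["diffraction_yield"] == pytest.approx(0.04)
        assert m["effective_hit_rate"] == 0.0

    def test_perfect_run(self):
        hit = np.ones(50, dtype=bool)
        outcomes = OutcomeTable(hit, hit.copy(), crystals_prepared=50)
        assert all(v == 1.0 for v in economy_metrics(outcomes).values())

    def test_effective_never_exceeds_raw(self):
        rng = np.random.default_rng(0)
        hit = rng.random(300) < 0.3
        idx = hit & (rng.random(300) < 0.6)
        m = economy_metrics(OutcomeTable(hit, idx, crystals_prepared=900))
        assert m["effective_hit_rate"] <= m["hit_rate"]
        assert m["effective_yield"] <= m["diffraction_yield"]

    def test_indexed_without_hit_rejected(self):
        with pytest.raises(ValueError):
            OutcomeTable(
                np.array([False]), np.array([True]), crystals_prepared=10
            )

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            economy_metrics(
                OutcomeTable(np.array([], bool), np.array([], bool), 1)
            )
        with pytest.raises(ValueError):
            OutcomeTable(np.array([True]), np.array([True]), crystals_prepared=0)
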