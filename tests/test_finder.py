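"""Segment detection, pairing, candidate formation and ranking."""

import numpy as np
import pytest

from chipscan.finder import (
    CrystalCandidate,
    Segment,
    detect_segments,
    filter_segments,
    find_crystals,
    match_candidates,
    pair_segments,
    rank_candidates,
)
from shapely.geometry import Polygon

from conftest import rect_image


def test_blank_image_yields_no_segments():
    assert detect_segments(np.full((200, 200), 0.8)) == []


def test_rectangle_edges_detected():
    img = rect_image()
    segments = filter_segments(detect_segments(img), 12.0)
    assert len(segments) >= 4
    for s in segments:
        angle = min(s.angle % 90.0, 90.0 - (s.angle % 90.0))
        assert angle <= 3.0  # axis-aligned rectangle edges
    # every segment hugs the rectangle boundary
    rect = Polygon([(100, 130), (200, 130), (200, 170), (100, 170)]).buffer(4)
    from shapely.geometry import Point

    for s in segments:
        assert rect.contains(Point(*s.midpoint))


@pytest.mark.parametrize(
    "min_length,expected",
    [(0.0, 3), (10.0, 2), (100.0, 0)],
)
def test_filter_segments_by_length(min_length, expected):
    segs = [
        Segment((0, 0), (5, 0)),
        Segment((0, 0), (20, 0)),
        Segment((0, 0), (40, 0)),
    ]
    assert len(filter_segments(segs, min_length)) == expected


def test_filter_preserves_order():
    segs = [Segment((0, 0), (30, 0)), Segment((0, 5), (20, 5))]
    assert filter_segments(segs, 10.0) == segs


class TestPairing:
    def test_parallel_pair_in_bounds(self):
        segs = [Segment((0, 0), (50, 0)), Segment((0, 20), (50, 20))]
        pairs = pair_segments(segs, 10.0, (6.0, 300.0), 0.3)
        assert len(pairs) == 1
        assert pairs[0].gap == pytest.approx(20.0)
        assert pairs[0].longitudinal_overlap == pytest.approx(1.0)

    def test_perpendicular_segments_never_pair(self):
        segs = [Segment((0, 0), (50, 0)), Segment((25, -25), (25, 25))]
        assert pair_segments(segs, 10.0, (6.0, 300.0), 0.3) == []

    def test_gap_bounds_respected(self):
        near = [Segment((0, 0), (50, 0)), Segment((0, 2), (50, 2))]
        far = [Segment((0, 0), (50, 0)), Segment((0, 500), (50, 500))]
        assert pair_segments(near, 10.0, (6.0, 300.0), 0.3) == []
        assert pair_segments(far, 10.0, (6.0, 300.0), 0.3) == []

    def test_pair_count_monotone_in_tolerance(self):
        rng = np.random.default_rng(42)
        segs = []
        for _ in range(60):
            p = rng.uniform(0, 500, 2)
            ang = rng.uniform(0, np.pi)
            ln = rng.uniform(15, 60)
            q = p + ln * np.array([np.cos(ang), np.sin(ang)])
            segs.append(Segment(tuple(p), tuple(q)))
        counts = [
            len(pair_segments(segs, tol, (6.0, 300.0), 0.3))
            for tol in (2.0, 5.0, 10.0, 20.0, 40.0)
        ]
        assert counts == sorted(counts)


class TestCandidates:
    def test_single_rectangle_candidate_area(self):
        img = rect_image(size=(100.0, 40.0))
        cands = find_crystals(img)
        assert len(cands) == 1
        assert cands[0].area == pytest.approx(4000.0, rel=0.10)
        assert cands[0].min_caliper_width == pytest.approx(40.0, rel=0.15)

    def test_two_separated_rectangles(self):
        img = rect_image(shape=(300, 520), origin=(60.0, 130.0))
        img2 = rect_image(shape=(300, 520), origin=(340.0, 130.0), background=0.0)
        img = np.minimum(img, img2 + 0.8)  # second rectangle carved in
        cands = find_crystals(img)
        assert len(cands) == 2
        assert all("cluster" not in c.flags for c in cands)

    def test_overlapping_rectangles_flagged_as_cluster(self):
        img = np.full((300, 300), 0.8)
        for origin in ((90.0, 120.0), (150.0, 150.0)):
            sub = rect_image(shape=(300, 300), origin=origin, background=0.0)
            img = np.minimum(img, sub + 0.8)
        cands = find_crystals(img)
        assert len(cands) >= 1
        # overlapping objects either merge into one hypothesis or carry flags
        if len(cands) > 1:
            assert any("cluster" in c.flags for c in cands)

    def test_candidates_stay_inside_image(self, medium_chip_image):
        spec, img, truth = medium_chip_image
        cands = find_crystals(img)
        h, w = img.shape
        for c in cands:
            minx, miny, maxx, maxy = c.polygon.bounds
            assert minx >= 0 and miny >= 0
            assert maxx <= w - 1 and maxy <= h - 1

    def test_recognition_on_synthetic_chip(self, medium_chip_image):
        spec, img, truth = medium_chip_image
        cands = find_crystals(img)
        scores = match_candidates(
            cands, [c.polygon_px(spec.pixel_scale) for c in truth.crystals]
        )
        assert scores["recall"] >= 0.8
        assert scores["precision"] >= 0.8


class TestRanking:
    def _square(self, cid, side):
        return CrystalCandidate(
            id=cid, polygon=Polygon([(0, 0), (side, 0), (side, side), (0, side)])
        )

    def test_larger_crystal_ranks_first(self):
        small, big = self._square(0, 10.0), self._square(1, 30.0)
        ranked = rank_candidates([small, big])
        assert [c.id for c in ranked] == [1, 0]
        assert ranked[0].score == pytest.approx(30.0**3)

    def test_ties_break_by_id(self):
        a, b = self._square(0, 10.0), self._square(1, 10.0)
        assert [c.id for c in rank_candidates([b, a])] == [0, 1]

    def test_constant_scorer_falls_back_to_id_order(self):
        # identical geometry and constant scores: the (score, area, id)
        # tie-break leaves a stable id order whatever the input order
        cands = [self._square(i, 10.0) for i in range(4)]
        ranked = rank_candidates(list(reversed(cands)), scorer=lambda c: 1.0)
        assert [c.id for c in ranked] == [0, 1, 2, 3]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        cands = [self._square(i, float(rng.integers(5, 40))) for i in range(10)]
        base = [c.id for c in rank_candidates(cands)]
        for _ in range(3):
            perm = list(cands)
            rng.shuffle(perm)
            assert [c.id for c in rank_candidates(perm)] == base

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([self._square(0, 10.0)], scorer=lambda c: -1.0)
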