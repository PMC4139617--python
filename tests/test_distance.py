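"""Chessboard distance fields, critical points, pairing and corridors."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clumpsplit.concavity import SplittingTriangle, decompose_st, splitting_triangles
from clumpsplit.distance import (
    SplitPoint,
    arc_split_points,
    chebyshev_field,
    contour_fallback,
    critical_point,
    pair_points,
    set_distance,
    shortest_path_region,
)
from clumpsplit.preprocess import label_components
from clumpsplit.synthetic import make_two_disc_clump

from conftest import rasterise_disc


def brute_force_field(seeds, shape):
    """O(h*w*|S|) oracle: min over seeds of max(|dr|, |dc|)."""
    out = np.empty(shape, dtype=int)
    for r in range(shape[0]):
        for c in range(shape[1]):
            out[r, c] = min(max(abs(r - sr), abs(c - sc)) for sr, sc in seeds)
    return out


class TestChebyshevField:
    def test_single_corner_seed_closed_form(self):
        field = chebyshev_field(np.array([[0, 0]]), (3, 3))
        np.testing.assert_array_equal(field, [[0, 1, 2], [1, 1, 2], [2, 2, 2]])

    def test_two_seed_min_of_fields(self):
        seeds = np.array([[0, 0], [2, 2]])
        field = chebyshev_field(seeds, (3, 3))
        np.testing.assert_array_equal(field, brute_force_field(seeds, (3, 3)))

    def test_random_seed_sets_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(1, 8)
            seeds = rng.integers(0, 20, size=(n, 2))
            field = chebyshev_field(seeds, (20, 20))
            np.testing.assert_array_equal(field, brute_force_field(seeds, (20, 20)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 11), st.integers(0, 11)),
            min_size=1,
            max_size=5,
            unique=True,
        )
    )
    def test_lipschitz_under_chebyshev(self, seeds):
        field = chebyshev_field(np.array(seeds), (12, 12))
        # 1-Lipschitz: neighbouring pixels differ by at most 1
        assert np.abs(np.diff(field, axis=0)).max() <= 1
        assert np.abs(np.diff(field, axis=1)).max() <= 1
        diag = np.abs(field[1:, 1:] - field[:-1, :-1]).max()
        assert diag <= 1

    def test_empty_and_out_of_bounds_seeds(self):
        with pytest.raises(ValueError):
            chebyshev_field(np.empty((0, 2), int), (5, 5))
        with pytest.raises(ValueError):
            chebyshev_field(np.array([[6, 1]]), (5, 5))


def semicircle_st(radius=12):
    """Synthetic ST: semicircular arc over a straight chord."""
    cx = radius + 2
    chord = np.array([[2, c] for c in range(2, 2 * radius + 3)])
    theta = np.linspace(0, np.pi, 10 * radius)
    arc = np.unique(
        np.column_stack(
            [
                np.round(2 + radius * np.sin(theta)).astype(int),
                np.round(cx + radius * np.cos(theta)).astype(int),
            ]
        ),
        axis=0,
    )
    st_ = SplittingTriangle(cell_id=1, index=1, region=np.vstack([arc, chord]))
    st_.edge = np.vstack([arc, chord])
    st_.chord = chord
    st_.arc = arc
    return st_, (2 + radius, cx)


class TestCriticalPoint:
    def test_semicircle_peak_at_midpoint(self):
        st_, apex = semicircle_st()
        point = critical_point(st_, (40, 40))
        # oracle: per-arc-pixel brute-force chessboard distance to chord
        chord = st_.chord
        best = -1
        for px in st_.arc:
            d = min(max(abs(px[0] - q[0]), abs(px[1] - q[1])) for q in chord)
            best = max(best, d)
        for px in point.pixels:
            d = min(max(abs(px[0] - q[0]), abs(px[1] - q[1])) for q in chord)
            assert d == best
        # the apex is in (or adjacent to) the returned tie plateau
        assert any(
            max(abs(px[0] - apex[0]), abs(px[1] - apex[1])) <= 1
            for px in point.pixels
        )

    def test_parallel_arc_returns_tie_set(self):
        chord = np.array([[0, c] for c in range(8)])
        arc = np.array([[4, c] for c in range(8)])
        st_ = SplittingTriangle(cell_id=1, index=1, region=np.vstack([arc, chord]))
        st_.edge, st_.chord, st_.arc = np.vstack([arc, chord]), chord, arc
        point = critical_point(st_, (10, 10))
        assert len(point.pixels) == len(arc)

    @pytest.mark.parametrize("r,f", [(10, 1.4), (14, 1.6), (12, 1.2)])
    def test_two_disc_pinch_location(self, r, f):
        mask, pinch = make_two_disc_clump(r, f)
        obj = label_components(mask)[0]
        for st_ in splitting_triangles(obj, min_area=4):
            st_ = decompose_st(st_, obj)
            point = critical_point(st_, mask.shape)
            err = np.maximum(
                np.abs(point.pixels[:, None, 0] - pinch[None, :, 0]),
                np.abs(point.pixels[:, None, 1] - pinch[None, :, 1]),
            ).min()
            assert err <= 2.0

    def test_translation_and_rotation_invariance(self):
        st_, _ = semicircle_st()
        base = critical_point(st_, (60, 60)).pixels
        shifted = SplittingTriangle(cell_id=1, index=1, region=st_.region + 7)
        shifted.edge, shifted.chord, shifted.arc = (
            st_.edge + 7,
            st_.chord + 7,
            st_.arc + 7,
        )
        np.testing.assert_array_equal(
            critical_point(shifted, (60, 60)).pixels, base + 7
        )
        # 90-degree rotation: (r, c) -> (c, 59 - r)
        def rot(px):
            return np.column_stack([px[:, 1], 59 - px[:, 0]])

        rotated = SplittingTriangle(cell_id=1, index=1, region=rot(st_.region))
        rotated.edge, rotated.chord, rotated.arc = (
            rot(st_.edge),
            rot(st_.chord),
            rot(st_.arc),
        )
        got = {tuple(p) for p in critical_point(rotated, (60, 60)).pixels}
        assert got == {tuple(p) for p in rot(base)}


def exhaustive_matching(points):
    """Min-total-cost perfect matching oracle on the set distances."""
    n = len(points)
    best, best_cost = None, np.inf
    idx = list(range(n))
    for perm in itertools.permutations(idx):
        if any(perm[i] > perm[i + 1] for i in range(0, n - 1, 2)):
            continue
        if any(perm[i] > perm[i + 2] for i in range(0, n - 3, 2)):
            continue
        cost = sum(
            set_distance(points[perm[i]].pixels, points[perm[i + 1]].pixels)
            for i in range(0, n - 1, 2)
        )
        if cost < best_cost:
            best_cost = cost
            best = {(min(perm[i], perm[i + 1]), max(perm[i], perm[i + 1])) for i in range(0, n - 1, 2)}
    return best


class TestPairing:
    def point(self, r, c, st_index=None):
        return SplitPoint(1, np.array([[r, c]]), st_index=st_index)

    def test_three_points_leave_far_one_out(self):
        pts = [self.point(0, 0), self.point(0, 4), self.point(10, 10)]
        pairs, leftovers = pair_points(pts)
        assert len(pairs) == 1
        got = {pairs[0][0].anchor, pairs[0][1].anchor}
        assert got == {(0, 0), (0, 4)}
        assert [p.anchor for p in leftovers] == [(10, 10)]

    def test_two_points_single_pair(self):
        pairs, leftovers = pair_points([self.point(3, 3), self.point(9, 9)])
        assert len(pairs) == 1 and not leftovers

    def test_four_point_chain_pairs_across_pinches(self):
        # straight-chain geometry: across-pinch gaps are the short ones
        pts = [
            self.point(5, 15, 1),
            self.point(20, 15, 2),
            self.point(5, 32, 3),
            self.point(20, 32, 4),
        ]
        pairs, leftovers = pair_points(pts)
        assert not leftovers
        got = {frozenset((p.anchor, v.anchor)) for p, v in pairs}
        oracle = exhaustive_matching(pts)
        oracle_pairs = {
            frozenset((pts[i].anchor, pts[j].anchor)) for i, j in oracle
        }
        assert got == oracle_pairs == {
            frozenset({(5, 15), (20, 15)}),
            frozenset({(5, 32), (20, 32)}),
        }

    def test_order_invariance(self):
        pts = [self.point(0, 0), self.point(0, 5), self.point(8, 0), self.point(8, 5)]
        ref = pair_points(pts)[0]
        ref_set = {frozenset((p.anchor, v.anchor)) for p, v in ref}
        for perm in itertools.permutations(pts):
            got = pair_points(list(perm))[0]
            assert {frozenset((p.anchor, v.anchor)) for p, v in got} == ref_set

    def test_same_region_points_never_pair(self):
        pts = [self.point(0, 0, st_index=1), self.point(0, 3, st_index=1)]
        pairs, leftovers = pair_points(pts)
        assert not pairs and len(leftovers) == 2

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            pair_points([self.point(0, 0)])


class TestContourFallback:
    def crescent(self):
        disc = rasterise_disc((40, 40), (20, 20), 12).astype(bool)
        bite = rasterise_disc((40, 40), (20, 28), 9).astype(bool)
        return (disc & ~bite).astype(np.uint8)

    def test_crescent_partner_across_waist(self):
        mask = self.crescent()
        obj = label_components(mask)[0]
        sts = [
            decompose_st(st, obj)
            for st in splitting_triangles(obj, min_area=10)
        ]
        sts = [s for s in sts if s is not None]
        assert len(sts) == 1
        p = critical_point(sts[0], mask.shape)
        pair = contour_fallback(obj, p, sts, mask.shape)
        assert pair is not None
        _, partner = pair
        # partner must not touch the concave mouth
        arc = {tuple(a) for st in sts for a in st.arc}
        for px in partner.pixels:
            assert all(
                max(abs(px[0] - a[0]), abs(px[1] - a[1])) > 1 for a in arc
            )

    def test_partner_is_nearest_allowed_boundary(self):
        mask = self.crescent()
        obj = label_components(mask)[0]
        sts = [
            decompose_st(st, obj)
            for st in splitting_triangles(obj, min_area=10)
        ]
        p = critical_point(sts[0], mask.shape)
        _, partner = contour_fallback(obj, p, sts, mask.shape)
        # brute force over all boundary pixels
        from clumpsplit.distance import fallback_candidates

        cands = fallback_candidates(obj, p, sts, mask.shape)
        best = set_distance(cands[0].pixels, p.pixels)
        assert set_distance(partner.pixels, p.pixels) == best


class TestCorridor:
    def test_collinear_straight_segment(self):
        p = SplitPoint(1, np.array([[0, 0]]))
        v = SplitPoint(1, np.array([[0, 4]]))
        m = shortest_path_region(p, v, (8, 8))
        assert m[0, :5].all()

    def test_matches_brute_force_interval(self):
        p = SplitPoint(1, np.array([[0, 0]]))
        v = SplitPoint(1, np.array([[3, 1]]))
        m = shortest_path_region(p, v, (10, 10))
        d = 3
        for r in range(10):
            for c in range(10):
                expect = max(abs(r), abs(c)) + max(abs(r - 3), abs(c - 1)) == d
                assert m[r, c] == expect

    def test_adjacent_pair_two_pixels(self):
        p = SplitPoint(1, np.array([[4, 4]]))
        v = SplitPoint(1, np.array([[4, 5]]))
        m = shortest_path_region(p, v, (10, 10))
        assert m.sum() == 2 and m[4, 4] and m[4, 5]

    def test_min_equals_set_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.integers(0, 15, size=(2, 2))
            b = rng.integers(0, 15, size=(3, 2))
            p, v = SplitPoint(1, a), SplitPoint(1, b)
            from clumpsplit.distance import chebyshev_field as cf

            dp = cf(p.pixels, (15, 15))
            dv = cf(v.pixels, (15, 15))
            assert (dp + dv).min() == set_distance(p.pixels, v.pixels)


class TestArcSplitPoints:
    def test_single_pinch_matches_critical_point(self, two_disc_mask):
        mask, _ = two_disc_mask
        obj = label_components(mask)[0]
        for st_ in splitting_triangles(obj, min_area=10):
            st_ = decompose_st(st_, obj)
            pts = arc_split_points(st_, mask.shape)
            cp = critical_point(st_, mask.shape)
            # the deepest point is always among the candidates
            anchors = {p.anchor for p in pts}
            assert cp.anchor in anchors or any(
                set_distance(p.pixels, cp.pixels) <= 1 for p in pts
            )
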