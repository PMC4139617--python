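"""Chessboard-distance seed growing, critical points and geodesic corridors.

All distances in the splitting stage are chessboard (Chebyshev)
distances, ``max(|dr|, |dc|)``: for morphological work on binary masks
the chessboard metric behaves like the Euclidean one at a fraction of
the cost.  A *distance field* is grown from a seed pixel set: seeds sit
at 0 and every other pixel holds the distance to its nearest seed.

Built on these fields are

* :func:`critical_point` — the arc pixels of a splitting triangle at
  maximal distance from its chord (the initial splitting points),
* :func:`pair_points` — nearest-first pairing of the initial splitting
  points of one clump (the multi-pinch scenario),
* :func:`contour_fallback` — the partner point on the far contour when a
  clump has a single concave region (the one-pinch scenario),
* :func:`shortest_path_region` — the corridor of pixels lying on some
  chessboard geodesic between a paired pair of points.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .concavity import SplittingTriangle
from .preprocess import EIGHT_CONNECTED, CellObject

__all__ = [
    "SplitPoint",
    "chebyshev_field",
    "critical_point",
    "set_distance",
    "pair_points",
    "contour_fallback",
    "shortest_path_region",
]


class SplitPoint:
    """Initial splitting point of one pinch: 1+ pixels on the source arc.

    More than one arc pixel can sit at the maximal distance from the
    chord, so a splitting point is a pixel set, not a single pixel.
    """

    def __init__(self, cell_id: int, pixels: np.ndarray, st_index: int | None = None):
        pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
        if len(pixels) == 0:
            raise ValueError("a SplitPoint needs at least one pixel")
        # canonical order makes downstream tie-breaks order-independent
        order = np.lexsort((pixels[:, 1], pixels[:, 0]))
        self.cell_id = int(cell_id)
        self.pixels = pixels[order]
        #: index of the splitting triangle this point came from (if any);
        #: two points of the same concave region are never paired together
        self.st_index = st_index

    @property
    def anchor(self) -> tuple[int, int]:
        """Lexicographically smallest member pixel."""
        return tuple(self.pixels[0])

    def __repr__(self):
        return f"SplitPoint(cell={self.cell_id}, n={len(self.pixels)}, at={self.anchor})"


def chebyshev_field(seeds: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Exact nearest-seed chessboard distance at every pixel of the grid.

    ``seeds`` is an ``(n, 2)`` array of (row, col) coordinates.  The
    field is grown with the chamfer chessboard distance transform, which
    is exact for this metric on a rectangular grid.
    """
    seeds = np.asarray(seeds, dtype=int).reshape(-1, 2)
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    if (
        seeds[:, 0].min() < 0
        or seeds[:, 1].min() < 0
        or seeds[:, 0].max() >= shape[0]
        or seeds[:, 1].max() >= shape[1]
    ):
        raise ValueError("seeds must lie inside the grid")
    grid = np.ones(shape, dtype=np.uint8)
    grid[seeds[:, 0], seeds[:, 1]] = 0
    return ndimage.distance_transform_cdt(grid, metric="chessboard").astype(np.int32)


def _window_for(pixels: np.ndarray, pad: int, shape: tuple[int, int]):
    r0 = max(int(pixels[:, 0].min()) - pad, 0)
    c0 = max(int(pixels[:, 1].min()) - pad, 0)
    r1 = min(int(pixels[:, 0].max()) + pad + 1, shape[0])
    c1 = min(int(pixels[:, 1].max()) + pad + 1, shape[1])
    return (r0, c0), (r1 - r0, c1 - c0)


def critical_point(st: SplittingTriangle, shape: tuple[int, int]) -> SplitPoint:
    """Arc pixels of one splitting triangle farthest from its chord.

    Two fields are grown over a window covering the triangle — DA from
    the arc seeds and DC from the chord seeds — and summed into DM.
    On the arc DA is zero, so the maximisers of DM over the arc are the
    arc pixels at maximal chessboard distance from the chord: the
    initial splitting points of this pinch.
    """
    if len(st.arc) == 0 or len(st.chord) == 0:
        raise ValueError("splitting triangle must be decomposed first")
    both = np.vstack([st.arc, st.chord])
    (r0, c0), win_shape = _window_for(both, pad=1, shape=shape)
    da = chebyshev_field(st.arc - [r0, c0], win_shape)
    dc = chebyshev_field(st.chord - [r0, c0], win_shape)
    dm = da + dc
    arc_local = st.arc - [r0, c0]
    vals = dm[arc_local[:, 0], arc_local[:, 1]]
    best = st.arc[vals == vals.max()]
    return SplitPoint(st.cell_id, best, st_index=st.index)


def _order_curve(pixels: np.ndarray) -> list[np.ndarray]:
    """Order the pixels of an 8-connected open curve end to end.

    Handles multi-component curves (one ordering per component) and
    tolerates small corner spurs by tracing the longest end-to-end path;
    spur pixels are dropped from the ordering.
    """
    from collections import deque

    pixel_set = {tuple(px) for px in pixels}

    def neighbours(px):
        r, c = px
        return [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr or dc) and (r + dr, c + dc) in pixel_set
        ]

    def bfs_far(start, members):
        seen = {start: None}
        queue = deque([start])
        last = start
        while queue:
            px = queue.popleft()
            last = px
            for q in neighbours(px):
                if q in members and q not in seen:
                    seen[q] = px
                    queue.append(q)
        return last, seen

    remaining = set(pixel_set)
    paths = []
    while remaining:
        start = min(remaining)
        # component members
        comp = set()
        queue = deque([start])
        while queue:
            px = queue.popleft()
            if px in comp:
                continue
            comp.add(px)
            queue.extend(q for q in neighbours(px) if q in remaining)
        remaining -= comp
        # two-sweep BFS: farthest pixel from an arbitrary one, then trace back
        end_a, _ = bfs_far(start, comp)
        end_b, parents = bfs_far(end_a, comp)
        path = []
        cur = end_b
        while cur is not None:
            path.append(cur)
            cur = parents[cur]
        paths.append(np.array(path))
    return paths


def arc_split_points(
    st: SplittingTriangle,
    shape: tuple[int, int],
    prominence: float = 1.0,
) -> list[SplitPoint]:
    """All candidate splitting points of one concave region.

    A concave region usually holds a single pinch and a single deepest
    arc point, but when two pinches of a chain clump share one deficit
    component (the hull bridges both on the same side) its arc has one
    depth maximum per pinch, and the shallower one can sit only a pixel
    above its saddle.  The chord-distance profile is therefore read
    along the ordered arc and every local peak plateau becomes a
    candidate initial splitting point; the global maximum is always
    included.  Spurious rasterisation peaks are cheap to carry: a cut
    routed from one is rejected by downstream route validation.
    """
    from scipy.signal import find_peaks

    if len(st.arc) == 0 or len(st.chord) == 0:
        raise ValueError("splitting triangle must be decomposed first")
    both = np.vstack([st.arc, st.chord])
    (r0, c0), win_shape = _window_for(both, pad=1, shape=shape)
    dc = chebyshev_field(st.chord - [r0, c0], win_shape)

    points: list[SplitPoint] = []
    global_best = -1
    for path in _order_curve(st.arc):
        profile = dc[path[:, 0] - r0, path[:, 1] - c0].astype(float)
        global_best = max(global_best, int(profile.max()))
        peaks, _ = find_peaks(
            np.pad(profile, 1, constant_values=-1), prominence=prominence
        )
        for peak in peaks:
            # expand to the plateau of equal-height pixels around the peak
            height = profile[peak - 1]
            lo = hi = peak - 1
            while lo > 0 and profile[lo - 1] == height:
                lo -= 1
            while hi < len(profile) - 1 and profile[hi + 1] == height:
                hi += 1
            points.append(
                SplitPoint(st.cell_id, path[lo : hi + 1], st_index=st.index)
            )
    # dedupe identical plateaus and make sure the deepest point is present
    seen = set()
    unique = []
    for p in points:
        key = tuple(map(tuple, p.pixels))
        if key not in seen:
            seen.add(key)
            unique.append(p)
    if not unique:
        return [critical_point(st, shape)]
    # merge peaks closer than a few pixels: they mark the same pinch
    merged: list[SplitPoint] = []
    for p in unique:
        for i, q in enumerate(merged):
            if set_distance(p.pixels, q.pixels) <= 3:
                merged[i] = SplitPoint(
                    st.cell_id,
                    np.vstack([q.pixels, p.pixels]),
                    st_index=st.index,
                )
                break
        else:
            merged.append(p)
    return merged


def set_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Chessboard distance between two pixel sets (min over member pairs)."""
    a = np.asarray(a).reshape(-1, 2)
    b = np.asarray(b).reshape(-1, 2)
    dr = np.abs(a[:, None, 0] - b[None, :, 0])
    dc = np.abs(a[:, None, 1] - b[None, :, 1])
    return int(np.maximum(dr, dc).min())


def set_distance_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two pixel sets (min over member pairs).

    Used for ranking candidate point pairs: the chessboard metric
    under-measures diagonal separations by up to a factor sqrt(2),
    which can make a diagonal pair across the cell body rank ahead of
    the true across-pinch pair.  Route geometry stays chessboard.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def closest_pair(a: np.ndarray, b: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    """One (pixel_a, pixel_b) pair attaining the set distance, lex tie-break."""
    a = np.asarray(a).reshape(-1, 2)
    b = np.asarray(b).reshape(-1, 2)
    dr = np.abs(a[:, None, 0] - b[None, :, 0])
    dc = np.abs(a[:, None, 1] - b[None, :, 1])
    d = np.maximum(dr, dc)
    ia, ib = np.nonzero(d == d.min())
    # inputs are lexsorted, so the first hit is the lexicographic choice
    return tuple(a[ia[0]]), tuple(b[ib[0]])


def pair_points(
    points: list[SplitPoint],
) -> tuple[list[tuple[SplitPoint, SplitPoint]], list[SplitPoint]]:
    """Pair the initial splitting points of one clump, nearest first.

    Each point's partner is the point at minimal chessboard set distance
    (the minimum of the summed border-distance fields of the two point
    objects).  Pairs are formed greedily by ascending distance, each
    point used at most once; ties break on the points' anchor pixels so
    the result is independent of input order.  A splitting cut joins one
    concave region to a counterpart region, so two points carrying the
    same ``st_index`` are never paired with each other.  Points left
    unpaired (odd count, or only same-region partners available) are
    returned for contour fallback routing.
    """
    if len(points) < 2:
        raise ValueError("pairing needs at least two splitting points")
    pts = sorted(points, key=lambda p: p.anchor)
    n = len(pts)
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            if (
                pts[i].st_index is not None
                and pts[i].st_index == pts[j].st_index
            ):
                continue
            d = set_distance(pts[i].pixels, pts[j].pixels)
            cand.append((d, pts[i].anchor, pts[j].anchor, i, j))
    cand.sort()
    used = [False] * n
    pairs: list[tuple[SplitPoint, SplitPoint]] = []
    for _, _, _, i, j in cand:
        if not used[i] and not used[j]:
            used[i] = used[j] = True
            pairs.append((pts[i], pts[j]))
    leftovers = [pts[i] for i in range(n) if not used[i]]
    return pairs, leftovers


def fallback_candidates(
    obj: CellObject,
    p: SplitPoint,
    sts: list[SplittingTriangle],
    shape: tuple[int, int],
) -> list[SplitPoint]:
    """Ranked partner candidates on the contour for a lone splitting point.

    Candidate targets are the clump's boundary pixels excluding anything
    within one chessboard pixel of any splitting-triangle arc, so a cut
    cannot end inside a concave region.  Candidates are clustered into
    connected runs of equal distance from ``p`` and returned as virtual
    splitting points by ascending distance (lexicographic tie-break).
    Empty when no contour pixels remain.
    """
    win, (r0, c0) = obj.window_mask(pad=1, shape=shape)
    eroded = ndimage.binary_erosion(win, structure=EIGHT_CONNECTED, border_value=0)
    boundary = win & ~eroded

    excl = np.zeros_like(win)
    for st in sts:
        arc = st.arc
        if len(arc) == 0:
            continue
        keep = (
            (arc[:, 0] >= r0)
            & (arc[:, 0] < r0 + win.shape[0])
            & (arc[:, 1] >= c0)
            & (arc[:, 1] < c0 + win.shape[1])
        )
        a = arc[keep]
        excl[a[:, 0] - r0, a[:, 1] - c0] = True
    excl = ndimage.binary_dilation(excl, structure=EIGHT_CONNECTED)
    candidates = boundary & ~excl
    if not candidates.any():
        return []

    cand_px = np.column_stack(np.nonzero(candidates)) + [r0, c0]
    dr = np.abs(cand_px[:, None, 0] - p.pixels[None, :, 0])
    dc = np.abs(cand_px[:, None, 1] - p.pixels[None, :, 1])
    d = np.maximum(dr, dc).min(axis=1)

    out: list[SplitPoint] = []
    for dist in np.unique(d):
        tier = cand_px[d == dist]
        tier_set = {tuple(px) for px in tier}
        seen: set[tuple[int, int]] = set()
        clusters = []
        for px in sorted(tier_set):
            if px in seen:
                continue
            stack, comp = [px], set()
            while stack:
                q = stack.pop()
                if q in comp:
                    continue
                comp.add(q)
                for dr_ in (-1, 0, 1):
                    for dc_ in (-1, 0, 1):
                        nb = (q[0] + dr_, q[1] + dc_)
                        if nb in tier_set and nb not in comp:
                            stack.append(nb)
            seen |= comp
            clusters.append(comp)
        for comp in clusters:
            out.append(SplitPoint(obj.id, np.array(sorted(comp))))
    return out


def contour_fallback(
    obj: CellObject,
    p: SplitPoint,
    sts: list[SplittingTriangle],
    shape: tuple[int, int],
) -> tuple[SplitPoint, SplitPoint] | None:
    """Partner a lone splitting point with the nearest far-contour pixels.

    The partner is the nearest candidate cluster from
    :func:`fallback_candidates`; ``None`` flags the cell unsplittable.
    """
    cands = fallback_candidates(obj, p, sts, shape)
    if not cands:
        return None
    return p, cands[0]


def shortest_path_region(
    p: SplitPoint, v: SplitPoint, shape: tuple[int, int]
) -> np.ndarray:
    """Chessboard geodesic corridor between two splitting points.

    Growing border-distance fields from each point and summing them, the
    pixels where the sum attains its global minimum are exactly the
    pixels lying on some shortest chessboard path between the two point
    sets.  Returned as a boolean image-shaped mask.
    """
    both = np.vstack([p.pixels, v.pixels])
    pad = set_distance(p.pixels, v.pixels) + 1
    (r0, c0), win_shape = _window_for(both, pad=pad, shape=shape)
    dp = chebyshev_field(p.pixels - [r0, c0], win_shape)
    dv = chebyshev_field(v.pixels - [r0, c0], win_shape)
    b = dp + dv
    out = np.zeros(shape, dtype=bool)
    out[r0 : r0 + win_shape[0], c0 : c0 + win_shape[1]] = b == b.min()
    return out
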