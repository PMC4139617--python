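"""Cut-path thinning, mask cutting, cell counting and count evaluation.

A geodesic corridor between two paired splitting points is shrunk to a
single-pixel splitting route by two-subiteration parallel thinning
(Guo–Hall).  Thinning erodes the width of the corridor but never its
length, and the two splitting points are anchored, so the route runs
from one splitting point to the other.  Zeroing the route pixels in the
mask severs the clump; the split fragments are counted as cells without
any morphological restoration of their shapes — the goal is the count,
not the contours.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import EIGHT_CONNECTED

__all__ = [
    "CutPath",
    "CountReport",
    "guo_hall_thin",
    "thin_to_path",
    "apply_cuts",
    "count_cells",
    "evaluate",
]

#: 4-connectivity structure, the dual of the 8-connected cut paths: an
#: 8-connected curve separates its complement under 4-connectivity.
FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)


class RoutingError(RuntimeError):
    """Raised when a corridor cannot be reduced to a single cut path."""


@dataclass
class CutPath:
    """Ordered single-pixel splitting route between two paired points."""

    cell_id: int
    pixels: np.ndarray  # (n, 2) ordered from one anchor to the other

    def __len__(self):
        return len(self.pixels)


# Guo-Hall neighbour order: x1 = east, counterclockwise.
_NEIGHBOUR_SHIFTS = [
    (0, 1),  # x1 E
    (-1, 1),  # x2 NE
    (-1, 0),  # x3 N
    (-1, -1),  # x4 NW
    (0, -1),  # x5 W
    (1, -1),  # x6 SW
    (1, 0),  # x7 S
    (1, 1),  # x8 SE
]


def _neighbours(img: np.ndarray) -> list[np.ndarray]:
    """The eight shifted copies x1..x8 of a padded binary image."""
    out = []
    padded = np.pad(img, 1)
    h, w = img.shape
    for dr, dc in _NEIGHBOUR_SHIFTS:
        out.append(padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w])
    return out


def guo_hall_thin(
    image: np.ndarray, protected: np.ndarray | None = None
) -> np.ndarray:
    """Two-subiteration parallel thinning to a one-pixel-wide skeleton.

    Each pass deletes border pixels satisfying the connectivity-
    preserving conditions of the two-subiteration scheme; subiteration 1
    peels from one diagonal direction, subiteration 2 from the other.
    Pixels of ``protected`` (the splitting-point anchors) are never
    deleted.  Iterates to a fixed point.
    """
    img = np.asarray(image, dtype=bool).copy()
    keep = (
        np.zeros_like(img)
        if protected is None
        else np.asarray(protected, dtype=bool)
    )
    while True:
        changed = False
        for sub in (0, 1):
            x = _neighbours(img)
            x.append(x[0])  # x9 = x1, closes the ring
            c = sum(
                (~x[2 * k] & (x[2 * k + 1] | x[2 * k + 2])).astype(np.uint8)
                for k in range(4)
            )
            n1 = sum((x[2 * k] | x[2 * k + 1]).astype(np.uint8) for k in range(4))
            n2 = sum((x[2 * k + 1] | x[2 * k + 2]).astype(np.uint8) for k in range(4))
            n = np.minimum(n1, n2)
            if sub == 0:
                edge = (x[1] | x[2] | ~x[7]) & x[0]
            else:
                edge = (x[5] | x[6] | ~x[3]) & x[4]
            remove = img & (c == 1) & (n >= 2) & (n <= 3) & ~edge & ~keep
            if remove.any():
                img &= ~remove
                changed = True
        if not changed:
            return img


def _bfs_path(
    skeleton: np.ndarray, start: tuple[int, int], goal: tuple[int, int]
) -> np.ndarray | None:
    """Shortest 8-connected path between two skeleton pixels, or None."""
    if not (skeleton[start] and skeleton[goal]):
        return None
    prev: dict[tuple[int, int], tuple[int, int] | None] = {start: None}
    queue = deque([start])
    h, w = skeleton.shape
    while queue:
        px = queue.popleft()
        if px == goal:
            path = []
            cur: tuple[int, int] | None = px
            while cur is not None:
                path.append(cur)
                cur = prev[cur]
            return np.array(path[::-1])
        r, c = px
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (r + dr, c + dc)
                if (
                    0 <= q[0] < h
                    and 0 <= q[1] < w
                    and skeleton[q]
                    and q not in prev
                ):
                    prev[q] = px
                    queue.append(q)
    return None


def thin_to_path(corridor: np.ndarray, p, v) -> CutPath:
    """Reduce a geodesic corridor to a single-pixel cut path.

    The corridor is thinned (Guo–Hall) with the closest anchor pixel of
    each splitting point protected, then the route is read off as the
    shortest 8-connected path between the anchors on the skeleton — this
    prunes any residual skeleton spur, guaranteeing a simple path whose
    interior pixels have exactly two path neighbours.
    """
    from .distance import closest_pair

    corridor = np.asarray(corridor, dtype=bool)
    anchor_p, anchor_v = closest_pair(p.pixels, v.pixels)
    work = corridor.copy()
    work[anchor_p] = True
    work[anchor_v] = True
    protected = np.zeros_like(work)
    protected[anchor_p] = True
    protected[anchor_v] = True

    skeleton = guo_hall_thin(work, protected=protected)
    path = _bfs_path(skeleton, anchor_p, anchor_v)
    if path is None:
        raise RoutingError(
            f"corridor between {anchor_p} and {anchor_v} of cell "
            f"{p.cell_id} is disconnected"
        )
    return CutPath(cell_id=p.cell_id, pixels=path)


def apply_cuts(mask: np.ndarray, paths: list[CutPath]) -> np.ndarray:
    """Zero the cut-path pixels in the mask; nothing else changes.

    Path pixels outside the foreground (the route's endpoints sit in the
    concave deficit just off the cell contour) are clipped silently.
    Split fragments are left as they fall — no restoration.
    """
    out = np.asarray(mask).astype(np.uint8).copy()
    for path in paths:
        px = path.pixels
        inside = (
            (px[:, 0] >= 0)
            & (px[:, 0] < out.shape[0])
            & (px[:, 1] >= 0)
            & (px[:, 1] < out.shape[1])
        )
        px = px[inside]
        out[px[:, 0], px[:, 1]] = 0
    return out


def count_fragments(region_mask: np.ndarray) -> int:
    """Number of 4-connected pieces of a (possibly cut) clump region."""
    _, n = ndimage.label(np.asarray(region_mask, dtype=bool), structure=FOUR_CONNECTED)
    return int(n)


def count_cells(objects, post_split_mask: np.ndarray) -> int:
    """Total cell count: non-OC objects plus post-cut clump fragments.

    Every object not labelled OC counts as one cell (including residual
    PO objects).  Each OC clump contributes its number of 4-connected
    fragments in the post-cut mask; an unsplittable clump therefore
    still counts as one.
    """
    total = 0
    arr = np.asarray(post_split_mask, dtype=bool)
    for obj in objects:
        if obj.stage1_label != "OC":
            total += 1
        else:
            region = np.zeros_like(arr)
            region[obj.rows, obj.cols] = True
            total += max(count_fragments(region & arr), 1)
    return total


@dataclass(frozen=True)
class CountReport:
    """Detection-style evaluation of predicted cells against ground truth."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def evaluate(
    predicted: list[np.ndarray],
    truth: list[np.ndarray],
    iou_threshold: float = 0.5,
) -> CountReport:
    """Match predicted cell regions to ground-truth cells one-to-one.

    Regions are ``(n, 2)`` pixel-coordinate arrays.  Candidate matches
    are ranked by descending pixel overlap and accepted greedily if the
    intersection-over-union reaches ``iou_threshold`` or the predicted
    centroid falls inside the truth cell.  Matched pairs are true
    positives; leftover predictions are false positives (over-
    segmentation) and leftover truth cells false negatives (under-
    segmentation).  Empty-vs-empty scores as a perfect 100 %.
    """
    pred_sets = [set(map(tuple, np.asarray(p).reshape(-1, 2))) for p in predicted]
    true_sets = [set(map(tuple, np.asarray(t).reshape(-1, 2))) for t in truth]

    candidates = []
    for i, ps in enumerate(pred_sets):
        if not ps:
            continue
        centroid = tuple(np.round(np.mean(np.array(list(ps)), axis=0)).astype(int))
        for j, ts in enumerate(true_sets):
            inter = len(ps & ts)
            if inter == 0:
                continue
            iou = inter / len(ps | ts)
            if iou >= iou_threshold or centroid in ts:
                candidates.append((inter, iou, i, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    used_pred: set[int] = set()
    used_true: set[int] = set()
    tp = 0
    for _, _, i, j in candidates:
        if i in used_pred or j in used_true:
            continue
        used_pred.add(i)
        used_true.add(j)
        tp += 1
    return CountReport(
        tp=tp,
        fp=len(pred_sets) - tp,
        fn=len(true_sets) - tp,
    )
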