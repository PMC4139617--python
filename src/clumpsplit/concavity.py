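"""Splitting-triangle extraction and decomposition for overlapping cells.

The convex-hull deficit of a clump — hull region minus cell region —
breaks into connected components wherever neighbouring cells pinch the
contour.  Each sufficiently large component is a *splitting triangle*
(ST): the marker of one concave pinch.  Its boundary decomposes into

* the **chord**: the part tangent to the convex-hull contour (the
  straight "bridge" the hull draws across the pinch), and
* the **arc**: the remainder, lying along the cell contour and reaching
  the deepest point of the pinch.

The arc pixel farthest from the chord is where a splitting cut starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import EIGHT_CONNECTED, CellObject
from .stage1 import object_hull

__all__ = [
    "SplittingTriangle",
    "splitting_triangles",
    "decompose_st",
    "build_label_matrices",
]

#: Minimum ST area (pixels) for a concave region to count as dominant.
#: Smaller deficit slivers are contour rasterisation noise, not pinches:
#: on 512x512 masks of 8-14 px cells, noise components are 1-2 px while
#: genuine pinch deficits of even shallow overlaps are 6 px and up.
DEFAULT_MIN_ST_AREA = 5


@dataclass
class SplittingTriangle:
    """One dominant concave region of an overlapping cell.

    Pixel sets are ``(n, 2)`` arrays of global (row, col) coordinates.
    ``edge = chord ∪ arc`` with ``chord ∩ arc = ∅`` after decomposition.
    """

    cell_id: int
    index: int
    region: np.ndarray
    edge: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    chord: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    arc: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    @property
    def area(self) -> int:
        return int(len(self.region))


def _inner_boundary(region: np.ndarray) -> np.ndarray:
    """Pixels of a boolean window with an 8-neighbour (or frame) outside."""
    eroded = ndimage.binary_erosion(
        region, structure=EIGHT_CONNECTED, border_value=0
    )
    return region & ~eroded


def splitting_triangles(
    obj: CellObject,
    min_area: int = DEFAULT_MIN_ST_AREA,
) -> list[SplittingTriangle]:
    """Extract the dominant concave regions of one clump.

    Connected components (8-connectivity) of hull-minus-cell with area at
    least ``min_area`` are returned, indexed 1..C in scan order.  A convex
    object yields an empty list.  The hull deficit is conserved exactly:
    hull area = cell area + kept ST areas + discarded sliver areas.
    """
    hull, (r0, c0) = object_hull(obj)
    win = np.zeros_like(hull)
    win[obj.rows - r0, obj.cols - c0] = True
    deficit = hull & ~win
    labels, n = ndimage.label(deficit, structure=EIGHT_CONNECTED)
    sts: list[SplittingTriangle] = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(labels == i)
        if rr.size < min_area:
            continue
        region = np.column_stack([rr + r0, cc + c0])
        sts.append(
            SplittingTriangle(cell_id=obj.id, index=len(sts) + 1, region=region)
        )
    return sts


def decompose_st(
    st: SplittingTriangle, obj: CellObject
) -> SplittingTriangle | None:
    """Fill the edge / chord / arc pixel sets of one splitting triangle.

    The edge is the 8-connected inner boundary of the ST region (on a
    binary region this is exactly the contour a gradient edge detector
    would trace, but deterministic and threshold-free).  The chord is
    the intersection of the edge with the hull contour — the only part
    of the triangle tangent to the convex hull; the remaining edge
    pixels form the arc.  Degenerate slivers whose arc or chord comes
    out empty are discarded with a warning and ``None`` is returned.
    """
    if st.area == 0:
        return None
    hull, (r0, c0) = object_hull(obj)
    region = np.zeros_like(hull)
    region[st.region[:, 0] - r0, st.region[:, 1] - c0] = True

    edge = _inner_boundary(region)
    hull_boundary = _inner_boundary(hull)
    chord = edge & hull_boundary
    arc = edge & ~chord

    if not arc.any() or not chord.any():
        warnings.warn(
            f"ST {st.index} of cell {st.cell_id} is a degenerate sliver "
            "(empty arc or chord); discarded",
            stacklevel=2,
        )
        return None

    offset = np.array([r0, c0])
    st.edge = np.column_stack(np.nonzero(edge)) + offset
    st.chord = np.column_stack(np.nonzero(chord)) + offset
    st.arc = np.column_stack(np.nonzero(arc)) + offset
    return st


def st_overlay(obj: CellObject, sts: list[SplittingTriangle], shape) -> np.ndarray:
    """Debug RGB rendering of one clump's concave-region decomposition.

    Cell grey, ST regions dark blue, chords red, arcs yellow — useful
    for eyeballing why a clump did or did not split.
    """
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    rgb[obj.rows, obj.cols] = (190, 190, 190)
    for st in sts:
        rgb[st.region[:, 0], st.region[:, 1]] = (70, 90, 160)
        if len(st.chord):
            rgb[st.chord[:, 0], st.chord[:, 1]] = (220, 50, 50)
        if len(st.arc):
            rgb[st.arc[:, 0], st.arc[:, 1]] = (235, 210, 60)
    return rgb


def build_label_matrices(
    sts: list[SplittingTriangle], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Paint arc (EA) and chord (EC) pixels with their cell id.

    Both matrices are image-sized integer arrays, zero outside arcs and
    chords — the global layout the seed-growing step reads its seeds
    from.
    """
    ea = np.zeros(shape, dtype=np.int32)
    ec = np.zeros(shape, dtype=np.int32)
    for st in sts:
        if len(st.arc):
            ea[st.arc[:, 0], st.arc[:, 1]] = st.cell_id
        if len(st.chord):
            ec[st.chord[:, 0], st.chord[:, 1]] = st.cell_id
    return ea, ec
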