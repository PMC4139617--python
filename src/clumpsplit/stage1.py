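"""Stage 1: discriminate overlapping cell clumps from single cells.

Each foreground object is scored with three purely morphological features
and labelled by a chain of three rules:

* area ``A_i`` — clumps of overlapped cells are larger than singles, so
  objects above the image mean area are Potentially Overlapping (PO),
  the rest Potentially Single (PS);
* diameter equality ``DE_i`` — the ratio of the minor to the major
  diameter; single tumour cells are nearly round so PO objects with
  ``DE_i`` above a threshold gamma are relabelled Single Cell (SC);
* concavity ``CX_i`` — the normalised convex-hull deficit
  ``(A_hull - A) / A_hull``; remaining PO objects more concave than the
  image average are relabelled Overlapping Cell (OC).

Objects whose final label is OC form the overlapping set that stage 2
splits.  A residual PO (large, elongated, but not unusually concave) is
counted as a single cell downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.morphology import convex_hull_image

from .preprocess import CellObject

__all__ = [
    "Stage1Params",
    "ImageStats",
    "diameter_equality",
    "concavity",
    "compute_features",
    "assign_labels",
    "overlapping_mask",
    "stage1_report",
]

#: Diameter-equality threshold above which a large object counts as round.
DEFAULT_GAMMA = 0.9


@dataclass(frozen=True)
class Stage1Params:
    """Tunable thresholds of the stage-1 label chain."""

    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")


@dataclass(frozen=True)
class ImageStats:
    """Per-image feature means used by the label rules."""

    mean_area: float
    mean_concavity: float


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a point cloud; falls back to the cloud
    itself for degenerate (collinear) inputs."""
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:
        return points


def feret_diameters(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Maximum Feret diameter and minimum caliper width of a pixel set.

    Distances are between pixel centres.  The maximum diameter is the
    largest pairwise distance (attained on hull vertices); the minimum
    width is the smallest extent of the hull projected perpendicular to
    each hull edge (rotating calipers).
    """
    pts = np.column_stack([rows, cols]).astype(float)
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return 0.0, 0.0
    verts = _hull_vertices(pts)
    major = float(pdist(verts).max())

    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 0
    if not good.any():  # all points coincide after dedup — cannot happen
        return major, 0.0
    normals = np.column_stack([-edges[good, 1], edges[good, 0]]) / lengths[good, None]
    proj = normals @ verts.T  # (n_edges, n_verts)
    widths = proj.max(axis=1) - proj.min(axis=1)
    minor = float(widths.min())
    return major, minor


def diameter_equality(obj: CellObject) -> float:
    """Minor-to-major diameter ratio ``DE_i`` in [0, 1].

    Near 1 for round cells, low for elongated clumps.  A single-pixel
    object has no measurable diameters and is defined as DE = 1 (round)
    with a warning.
    """
    if obj.area < 2:
        warnings.warn(
            f"object {obj.id} has a single pixel; DE defined as 1.0",
            stacklevel=2,
        )
        return 1.0
    major, minor = feret_diameters(obj.rows, obj.cols)
    if major == 0.0:
        return 1.0
    return min(minor / major, 1.0)


def object_hull(obj: CellObject) -> tuple[np.ndarray, tuple[int, int]]:
    """Filled convex hull of the object as a boolean window plus origin.

    The hull is rasterised with :func:`skimage.morphology.convex_hull_image`
    over the object's bounding box and cached on the object.
    """
    if obj._hull_window is None:
        win, origin = obj.window_mask()
        # pixel-centre polygon: corner-offset rasterisation would inflate
        # the hull of small convex cells and fake a concavity signal
        obj._hull_window = (
            convex_hull_image(win, offset_coordinates=False) if win.any() else win
        )
        obj._hull_origin = origin
    return obj._hull_window, obj._hull_origin


def concavity(obj: CellObject) -> float:
    """Normalised convex-hull deficit ``CX_i = (A_hull - A_i) / A_hull``.

    Zero (up to hull rasterisation) for convex objects, increasing as
    concave pinches cut deeper into the object.
    """
    if obj.area == 0:
        raise ValueError("cannot compute concavity of an empty object")
    hull, _ = object_hull(obj)
    hull_area = int(hull.sum())
    obj.hull_area = hull_area
    return (hull_area - obj.area) / hull_area


def compute_features(objects: list[CellObject]) -> None:
    """Populate ``de``, ``cx`` and ``hull_area`` on every object in place."""
    for obj in objects:
        obj.de = diameter_equality(obj)
        obj.cx = concavity(obj)


def image_stats(objects: list[CellObject]) -> ImageStats:
    areas = [o.area for o in objects]
    cxs = [o.cx for o in objects]
    return ImageStats(
        mean_area=float(np.mean(areas)),
        mean_concavity=float(np.mean(cxs)),
    )


def assign_labels(
    objects: list[CellObject],
    params: Stage1Params | None = None,
) -> list[CellObject]:
    """Run the three sequential label rules over all objects of one image.

    Rule 1: ``A_i > mean(A)`` -> PO, else PS.
    Rule 2: among PO, ``DE_i > gamma`` -> SC.
    Rule 3: among remaining PO, ``CX_i > mean(CX)`` -> OC.

    All comparisons are strict, so ties fall to the non-overlapping side
    (under-splitting is the safer failure mode than over-segmentation).
    Features are computed on demand if missing.  Returns the same list.
    """
    if not objects:
        return objects
    params = params or Stage1Params()
    if any(np.isnan(o.de) or np.isnan(o.cx) for o in objects):
        compute_features(objects)
    stats = image_stats(objects)
    for obj in objects:
        obj.stage1_label = "PO" if obj.area > stats.mean_area else "PS"
    for obj in objects:
        if obj.stage1_label == "PO" and obj.de > params.gamma:
            obj.stage1_label = "SC"
    for obj in objects:
        if obj.stage1_label == "PO" and obj.cx > stats.mean_concavity:
            obj.stage1_label = "OC"
    return objects


def overlapping_mask(objects: list[CellObject], shape: tuple[int, int]) -> np.ndarray:
    """Binary mask whose foreground is the union of OC-labelled objects."""
    out = np.zeros(shape, dtype=np.uint8)
    for obj in objects:
        if obj.stage1_label == "OC":
            out[obj.rows, obj.cols] = 1
    return out


def stage1_report(objects: list[CellObject]) -> pd.DataFrame:
    """Per-object feature table (id, area, DE, CX, label)."""
    return pd.DataFrame(
        {
            "object_id": [o.id for o in objects],
            "area": [o.area for o in objects],
            "diameter_equality": [o.de for o in objects],
            "concavity": [o.cx for o in objects],
            "label": [o.stage1_label for o in objects],
        }
    )
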