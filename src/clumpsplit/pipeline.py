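"""End-to-end orchestration: preprocess -> stage 1 -> stage 2 -> count.

:func:`process_mask` runs the full two-stage analysis on one binary
mask and returns everything downstream consumers need (labelled
objects, cut paths, the post-cut mask, predicted cell regions and the
count).  :func:`run_count` batches it over images, evaluates against
ground truth when available, and writes the CSV/overlay artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage

from . import concavity as cg
from . import distance as de
from . import splitting as sp
from . import stage1 as s1
from .preprocess import CellObject, clean_mask, label_components
from .synthetic import GroundTruth

logger = logging.getLogger("clumpsplit")

__all__ = ["RunConfig", "PipelineResult", "process_mask", "run_count", "overlay_image"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of the pipeline, with their defaults.

    ``gamma`` is the diameter-equality threshold for calling a large
    object round (hence single); the structuring-element radii drive the
    morphological cleaning; ``min_st_area`` separates dominant concave
    regions from contour noise.
    """

    gamma: float = s1.DEFAULT_GAMMA
    opening_radius: int = 2
    closing_radius: int = 2
    min_st_area: int = cg.DEFAULT_MIN_ST_AREA
    min_fragment_frac: float = 0.1
    iou_threshold: float = 0.5
    no_split: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0 or self.opening_radius <= 0 or self.closing_radius <= 0:
            raise ValueError("thresholds and radii must be positive")
        if self.min_st_area <= 0:
            raise ValueError("min_st_area must be positive")

    def to_text(self) -> str:
        return "".join(
            f"{f.name} = {getattr(self, f.name)}\n" for f in fields(self)
        )

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"unknown config key: {key}")
            if key == "no_split":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("gamma", "iou_threshold", "min_fragment_frac"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything produced by one run of the pipeline on one mask."""

    cleaned_mask: np.ndarray
    objects: list[CellObject]
    cut_paths: list[sp.CutPath]
    final_mask: np.ndarray
    predicted_regions: list[np.ndarray]
    count: int
    n_unsplittable: int = 0

    @property
    def n_single(self) -> int:
        return sum(o.stage1_label != "OC" for o in self.objects)

    @property
    def n_clumps(self) -> int:
        return sum(o.stage1_label == "OC" for o in self.objects)


def _route(p, v, shape):
    corridor = de.shortest_path_region(p, v, shape)
    return sp.thin_to_path(corridor, p, v)


def _valid_cut(
    path: sp.CutPath, state: np.ndarray, n_before: int, min_frag: float
) -> np.ndarray | None:
    """Accept a splitting route only if it severs one more cell off.

    Applied to the current (already cut) clump region, an accepted
    route must raise the fragment count by exactly one and leave every
    fragment at a plausible cell size.  This rejects degenerate corner
    nicks (no new fragment), shoulder slices between same-side pinches
    (a tiny fragment) and redundant or crossing routes (more than one
    new fragment) — the over-segmentation modes of pure nearest-point
    pairing.  Returns the new region state, or ``None`` if rejected.
    """
    cut = state.copy()
    px = path.pixels
    inside = (
        (px[:, 0] >= 0)
        & (px[:, 0] < cut.shape[0])
        & (px[:, 1] >= 0)
        & (px[:, 1] < cut.shape[1])
    )
    px = px[inside]
    cut[px[:, 0], px[:, 1]] = False
    labels, n = ndimage.label(cut, structure=sp.FOUR_CONNECTED)
    if n != n_before + 1:
        return None
    sizes = ndimage.sum_labels(cut, labels, index=range(1, n + 1))
    if sizes.min() < min_frag:
        return None
    return cut


def split_object(
    obj: CellObject, shape: tuple[int, int], config: RunConfig
) -> tuple[list[sp.CutPath], bool]:
    """Stage 2 for one OC clump: STs -> points -> pairs -> cut paths.

    Candidate point pairs are tried nearest first and each route is
    validated on the clump region before acceptance; points whose pair
    candidates are all rejected fall back to contour partners, also
    validated nearest first.  Returns the accepted cut paths and a flag
    set when the clump had concave regions but no valid route was found.
    """
    sts = [
        st
        for st in (
            cg.decompose_st(st, obj)
            for st in cg.splitting_triangles(obj, min_area=config.min_st_area)
        )
        if st is not None
    ]
    if not sts:
        return [], True

    state = np.zeros(shape, dtype=bool)
    state[obj.rows, obj.cols] = True
    n_frags = 1
    min_frag = config.min_fragment_frac * obj.area

    points = [p for st in sts for p in de.arc_split_points(st, shape)]
    points.sort(key=lambda p: p.anchor)
    cand = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if points[i].st_index == points[j].st_index:
                continue
            d = de.set_distance_euclidean(points[i].pixels, points[j].pixels)
            cand.append((d, points[i].anchor, points[j].anchor, i, j))
    cand.sort()

    paths: list[sp.CutPath] = []
    used = [False] * len(points)
    for _, _, _, i, j in cand:
        if used[i] or used[j]:
            continue
        try:
            path = _route(points[i], points[j], shape)
        except sp.RoutingError as exc:
            logger.warning("routing failed for cell %d: %s", obj.id, exc)
            continue
        new_state = _valid_cut(path, state, n_frags, min_frag)
        if new_state is not None:
            used[i] = used[j] = True
            paths.append(path)
            state, n_frags = new_state, n_frags + 1

    # contour fallback, only for concave regions not yet served by a cut:
    # a region already joined to a counterpart marks no further pinch,
    # and extra peaks on its arc are rasterisation artifacts
    served = {points[i].st_index for i in range(len(points)) if used[i]}
    for i, p in enumerate(points):
        if used[i] or p.st_index in served:
            continue
        for partner in de.fallback_candidates(obj, p, sts, shape)[:40]:
            try:
                path = _route(p, partner, shape)
            except sp.RoutingError:
                continue
            new_state = _valid_cut(path, state, n_frags, min_frag)
            if new_state is not None:
                used[i] = True
                served.add(p.st_index)
                paths.append(path)
                state, n_frags = new_state, n_frags + 1
                break

    return paths, not paths


def process_mask(mask: np.ndarray, config: RunConfig | None = None) -> PipelineResult:
    """Run preprocess, stage 1, stage 2 and counting on one binary mask."""
    config = config or RunConfig()
    cleaned = clean_mask(
        mask, opening_radius=config.opening_radius, closing_radius=config.closing_radius
    )
    objects = label_components(cleaned)
    s1.assign_labels(objects, s1.Stage1Params(gamma=config.gamma))

    shape = cleaned.shape
    cut_paths: list[sp.CutPath] = []
    n_unsplittable = 0
    if not config.no_split:
        for obj in objects:
            if obj.stage1_label != "OC":
                continue
            paths, unsplittable = split_object(obj, shape, config)
            cut_paths.extend(paths)
            n_unsplittable += bool(unsplittable and not paths)

    final = sp.apply_cuts(cleaned, cut_paths)

    predicted: list[np.ndarray] = []
    arr = final.astype(bool)
    for obj in objects:
        if obj.stage1_label != "OC" or config.no_split:
            predicted.append(np.column_stack([obj.rows, obj.cols]))
            continue
        region = np.zeros(shape, dtype=bool)
        region[obj.rows, obj.cols] = True
        labels, n = ndimage.label(region & arr, structure=sp.FOUR_CONNECTED)
        if n == 0:
            predicted.append(np.column_stack([obj.rows, obj.cols]))
            continue
        for i in range(1, n + 1):
            rr, cc = np.nonzero(labels == i)
            predicted.append(np.column_stack([rr, cc]))

    return PipelineResult(
        cleaned_mask=cleaned,
        objects=objects,
        cut_paths=cut_paths,
        final_mask=final,
        predicted_regions=predicted,
        count=len(predicted),
        n_unsplittable=n_unsplittable,
    )


def run_count(
    masks: dict[str, np.ndarray],
    config: RunConfig | None = None,
    truths: dict[str, GroundTruth] | None = None,
) -> tuple[pd.DataFrame, dict[str, PipelineResult]]:
    """Batch the pipeline over named masks; returns the per-image table.

    When ground truth is supplied for an image, predicted regions are
    matched against true cells and TP/FP/FN with precision, recall and
    F-measure (percent) are reported alongside the counts.  Per-image
    failures are logged and skipped.
    """
    config = config or RunConfig()
    rows = []
    results: dict[str, PipelineResult] = {}
    for name, mask in masks.items():
        try:
            res = process_mask(mask, config)
        except Exception:
            logger.exception("failed to process image %s", name)
            continue
        results[name] = res
        row = {
            "image": name,
            "n_single": res.n_single,
            "n_clumps": res.n_clumps,
            "n_cuts": len(res.cut_paths),
            "count_pred": res.count,
        }
        if truths and name in truths:
            truth = truths[name]
            report = sp.evaluate(
                res.predicted_regions, truth.cells, iou_threshold=config.iou_threshold
            )
            row.update(
                count_true=truth.count,
                TP=report.tp,
                FP=report.fp,
                FN=report.fn,
                precision=round(report.precision, 2),
                recall=round(report.recall, 2),
                f_measure=round(report.f_measure, 2),
            )
        rows.append(row)
    return pd.DataFrame(rows), results


def overlay_image(result: PipelineResult) -> np.ndarray:
    """RGB rendering of one result: mask grey, OC clumps tinted, cuts red."""
    h, w = result.cleaned_mask.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    fg = result.cleaned_mask.astype(bool)
    rgb[fg] = (200, 200, 200)
    for obj in result.objects:
        if obj.stage1_label == "OC":
            rgb[obj.rows, obj.cols] = (150, 180, 230)
    for path in result.cut_paths:
        px = path.pixels
        inside = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
        px = px[inside]
        rgb[px[:, 0], px[:, 1]] = (220, 40, 40)
    return rgb
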