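"""Spatial segmentation of MSI sections and ROI construction.

Sections are partitioned into molecularly similar segments by bisecting
k-means under the Manhattan (L1) metric: the segment with the largest
within-segment L1 cost is repeatedly split in two by alternating
nearest-center assignment and component-wise *median* center updates (the
median minimizes L1 cost, so every iteration is a descent step).  Anatomical
ROIs — gray matter (GM), white matter (WM), hippocampus (HC), outer cortex
(OC) and corpus callosum (CC) — are then assembled from segments, either by
explicit label sets, by ranking segments on a marker lipid's mean abundance,
by the outer-cortex pixel-count layering rule, or from a hand-drawn polygon.
Segments touching the grid border are treated as embedding background and
excluded from tissue ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

__all__ = [
    "SegmentationResult",
    "ROIMask",
    "bisecting_kmeans",
    "border_labels",
    "rank_segments_by_marker",
    "segments_to_roi",
    "accumulate_layers",
    "outer_cortex_selection",
    "manual_polygon_roi",
    "roi_mean_abundance",
]

ROI_NAMES = ("GM", "WM", "HC", "OC", "CC")


@dataclass
class SegmentationResult:
    """Per-pixel segment labels plus the split history (dendrogram)."""

    labels: np.ndarray
    n_segments: int
    counts: np.ndarray
    splits: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        assert self.counts.sum() == self.labels.size


@dataclass
class ROIMask:
    """Named boolean pixel mask on the section grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def write_png(self, path: str | Path) -> Path:
        from PIL import Image

        path = Path(path)
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(path)
        return path

    def to_coords(self) -> np.ndarray:
        """(n, 2) array of 1-based (x, y) pixel coordinates inside the mask."""
        r, c = np.nonzero(self.mask)
        return np.column_stack([c + 1, r + 1])

    @classmethod
    def read_png(cls, path: str | Path, name: str | None = None) -> "ROIMask":
        from PIL import Image

        path = Path(path)
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(name or path.stem, arr > 127)

    @classmethod
    def from_coords(
        cls, coords: np.ndarray, shape: tuple[int, int], name: str
    ) -> "ROIMask":
        """Build a mask from 1-based (x, y) coordinate pairs."""
        mask = np.zeros(shape, dtype=bool)
        coords = np.asarray(coords, dtype=int)
        mask[coords[:, 1] - 1, coords[:, 0] - 1] = True
        return cls(name, mask)


def _l1_cost(pts: np.ndarray) -> tuple[float, np.ndarray]:
    center = np.median(pts, axis=0)
    return float(np.abs(pts - center).sum()), center


def _canonical_order(pts: np.ndarray) -> np.ndarray:
    """Row order independent of input permutation (lexicographic by value)."""
    return np.lexsort(pts.T[::-1])


def _two_medians(
    pts: np.ndarray, init: tuple[np.ndarray, np.ndarray], max_iter: int
) -> tuple[np.ndarray, float]:
    c = np.stack(init)
    assign = None
    for _ in range(max_iter):
        d = cdist(pts, c, metric="cityblock")
        new_assign = np.argmin(d, axis=1)
        # guard against an empty side: give it the farthest point
        for k in (0, 1):
            if not np.any(new_assign == k):
                far = np.argmax(d[:, 1 - k])
                new_assign[far] = k
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        c = np.stack([np.median(pts[assign == k], axis=0) for k in (0, 1)])
    d = cdist(pts, c, metric="cityblock")
    cost = float(d[np.arange(len(pts)), assign].sum())
    return assign, cost


def bisecting_kmeans(
    X: np.ndarray,
    n_segments: int,
    seed: int = 0,
    max_iter: int = 50,
    subsample: int = 256,
) -> SegmentationResult:
    """Bisecting k-means under the Manhattan metric with median updates.

    At each step the segment with the largest within-segment L1 cost is split
    into two.  The 2-means split tries two deterministic initializations —
    the maximally L1-distant pair within a (canonically ordered, seeded)
    subsample, and (parent median, farthest point from it) — and keeps the
    cheaper result; the second initialization guarantees the total cost never
    increases at a split.  Segments whose points are all identical cannot be
    split; if no splittable segment remains the result has fewer segments
    than requested.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > n:
        raise ValueError(f"n_segments={n_segments} exceeds pixel count {n}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    cost0, _ = _l1_cost(X)
    seg_cost = {0: cost0}
    splits: list[dict] = []
    next_label = 1
    while len(seg_cost) < n_segments:
        candidates = [
            (c, lab)
            for lab, c in seg_cost.items()
            if c > 0 and np.sum(labels == lab) > 1
        ]
        if not candidates:
            break
        _, lab = max(candidates, key=lambda t: (t[0], -t[1]))
        rows = np.flatnonzero(labels == lab)
        pts = X[rows]
        order = _canonical_order(pts)
        pts_c = pts[order]
        # init 1: maximally distant pair within a canonical subsample
        if len(pts_c) > subsample:
            pick = rng.choice(len(pts_c), size=subsample, replace=False)
            pick.sort()
            sub = pts_c[pick]
        else:
            sub = pts_c
        d = cdist(sub, sub, metric="cityblock")
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assign1, cost1 = _two_medians(pts_c, (sub[i], sub[j]), max_iter)
        # init 2: parent median + farthest point (guarantees descent)
        parent_cost = seg_cost[lab]
        med = np.median(pts_c, axis=0)
        far = pts_c[np.argmax(np.abs(pts_c - med).sum(axis=1))]
        assign2, cost2 = _two_medians(pts_c, (med, far), max_iter)
        assign, cost = (assign1, cost1) if cost1 <= cost2 else (assign2, cost2)
        # map back from canonical order to original rows
        full_assign = np.empty(len(rows), dtype=int)
        full_assign[order] = assign
        new_rows = rows[full_assign == 1]
        labels[new_rows] = next_label
        c_a, _ = _l1_cost(X[rows[full_assign == 0]])
        c_b, _ = _l1_cost(X[new_rows])
        splits.append(
            {
                "parent": lab,
                "children": (lab, next_label),
                "cost_before": parent_cost,
                "cost_after": c_a + c_b,
            }
        )
        seg_cost[lab] = c_a
        seg_cost[next_label] = c_b
        next_label += 1
    k = next_label
    counts = np.bincount(labels, minlength=k)
    return SegmentationResult(labels=labels, n_segments=k, counts=counts, splits=splits)


def labels_image(seg: SegmentationResult, grid_index: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Segment labels rendered on the section grid (-1 = no pixel)."""
    img = np.full(shape, -1, dtype=int)
    img[grid_index[:, 0], grid_index[:, 1]] = seg.labels
    return img


def border_labels(
    seg: SegmentationResult, grid_index: np.ndarray, shape: tuple[int, int]
) -> set[int]:
    """Labels of segments touching the grid border (embedding background)."""
    img = labels_image(seg, grid_index, shape)
    edge = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    return set(int(v) for v in np.unique(edge) if v >= 0)


def rank_segments_by_marker(
    seg: SegmentationResult,
    marker_values: np.ndarray,
    exclude: set[int] | None = None,
) -> list[tuple[int, float]]:
    """Segments ordered by decreasing mean abundance of a marker feature."""
    exclude = exclude or set()
    out = []
    for lab in range(seg.n_segments):
        if lab in exclude:
            continue
        sel = seg.labels == lab
        if np.any(sel):
            out.append((lab, float(np.mean(marker_values[sel]))))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def segments_to_roi(
    seg: SegmentationResult,
    grid_index: np.ndarray,
    shape: tuple[int, int],
    name: str,
    labels: Sequence[int] | None = None,
    marker_values: np.ndarray | None = None,
    threshold_frac: float = 0.5,
    top_n: int | None = None,
    exclude: set[int] | None = None,
) -> ROIMask:
    """Union of selected segments as one named mask.

    Selection is either an explicit ``labels`` set, or marker-ranked: with
    ``top_n`` the n segments of highest mean marker abundance, otherwise all
    segments whose mean marker abundance is at least ``threshold_frac`` of
    the top segment's.  ``exclude`` (e.g. border/embedding segments) is
    honored in marker ranking.
    """
    if labels is None:
        if marker_values is None:
            raise ValueError("provide either labels or marker_values")
        ranked = rank_segments_by_marker(seg, marker_values, exclude)
        if not ranked:
            raise ValueError(f"no candidate segments for ROI {name!r}")
        if top_n is not None:
            labels = [lab for lab, _ in ranked[:top_n]]
        else:
            top = ranked[0][1]
            labels = [lab for lab, v in ranked if v >= threshold_frac * top]
    labels = set(int(v) for v in labels)
    sel = np.isin(seg.labels, sorted(labels))
    if not np.any(sel):
        raise ValueError(f"ROI {name!r}: empty segment selection")
    mask = np.zeros(shape, dtype=bool)
    gi = grid_index[sel]
    mask[gi[:, 0], gi[:, 1]] = True
    return ROIMask(name, mask)


def _range_distance(v: int, lo: int, hi: int) -> int:
    return 0 if lo <= v <= hi else max(lo - v, v - hi)


def accumulate_layers(counts: Sequence[int], target_range: tuple[int, int]) -> int:
    """How many outermost-first layers to take for a target pixel count.

    Takes the first layer unconditionally, then adds layers while below the
    lower bound; when the next layer would overshoot the upper bound, the
    nearer of undershoot/overshoot to the range wins.  Returns the number of
    layers selected.
    """
    if not counts:
        raise ValueError("no layers to select")
    lo, hi = target_range
    n_sel, total = 1, counts[0]
    for n in counts[1:]:
        if total >= lo:
            break
        if total + n > hi:
            if _range_distance(total + n, lo, hi) < _range_distance(total, lo, hi):
                n_sel += 1
                total += n
            break
        n_sel += 1
        total += n
    return n_sel


def outer_cortex_selection(
    seg: SegmentationResult,
    grid_index: np.ndarray,
    shape: tuple[int, int],
    tissue_mask: np.ndarray,
    target_range: tuple[int, int] = (2500, 3500),
    name: str = "OC",
    exclude: set[int] | None = None,
) -> ROIMask:
    """Outer cortical layers accumulated to a target pixel-count range.

    Segments (of a segmentation restricted to the cortical sub-region) are
    ordered outermost-first by mean distance to the tissue boundary; layers
    are added inward until the pixel count reaches the target range.  When
    adding the next layer would overshoot, whichever of under/overshoot lies
    closer to the range wins.  If the whole sub-region is smaller than the
    lower bound, everything is returned with a warning.
    """
    lo, hi = target_range
    exclude = exclude or set()
    # pad with background so a tissue mask reaching the grid edge still has
    # a boundary there
    dist = ndimage.distance_transform_edt(
        np.pad(tissue_mask, 1, constant_values=False)
    )[1:-1, 1:-1]
    pix_dist = dist[grid_index[:, 0], grid_index[:, 1]]
    order = []
    for lab in range(seg.n_segments):
        if lab in exclude:
            continue
        sel = seg.labels == lab
        if np.any(sel):
            order.append((float(np.mean(pix_dist[sel])), lab, int(sel.sum())))
    order.sort()
    if not order:
        raise ValueError("no candidate segments for outer cortex")
    n_sel = accumulate_layers([n for _, _, n in order], (lo, hi))
    chosen = [lab for _, lab, _ in order[:n_sel]]
    count = sum(n for _, _, n in order[:n_sel])
    if count < lo:
        warnings.warn(
            f"outer cortex: only {count} pixels available, below target {lo}"
        )
    return segments_to_roi(seg, grid_index, shape, name, labels=chosen)


def manual_polygon_roi(
    vertices: Sequence[tuple[float, float]],
    shape: tuple[int, int],
    name: str = "manual",
) -> ROIMask:
    """Mask of pixels whose centers fall strictly inside a simple polygon.

    Vertices are in 1-based pixel coordinates (x, y); self-intersecting or
    degenerate polygons are rejected.
    """
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon must be simple (non-self-intersecting, nonzero area)")
    nrow, ncol = shape
    xs, ys = np.meshgrid(np.arange(1, ncol + 1), np.arange(1, nrow + 1))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(shape)
    return ROIMask(name, inside)


def roi_mean_abundance(
    pixel_table: np.ndarray,
    mask: ROIMask,
    grid_index: np.ndarray,
) -> np.ndarray:
    """Per-feature arithmetic mean over the masked pixels of one section."""
    sel = mask.mask[grid_index[:, 0], grid_index[:, 1]]
    if not np.any(sel):
        raise ValueError(f"ROI {mask.name!r} covers no pixels of this section")
    return np.asarray(pixel_table)[sel].mean(axis=0)
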