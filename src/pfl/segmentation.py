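"""Pore-free island recognition by K-means with an automatic cluster-number rule.

The pan-NPC channel is summarized by three per-pixel moment features
(:mod:`pfl.features`), clustered with K-means for every k in a range
(default 2..20).  For each k, the cluster whose pixels have the lowest mean
channel intensity is taken as the class containing the pore-free islands,
and the within-class variation (WCV) of the three features over that class
is recorded.  After min-max normalizing each feature's WCV sequence across
k, their unweighted mean gives a total-WCV curve; the selected k is the
first strict local minimum of that curve — the point where the difference
between subsequent k, Diff_WCV(k) = WCV(k+1) - WCV(k), changes sign from
minus to plus.  The island-class pixels at the selected k are cleaned by
morphological closing and hole filling, and connected components that are
large enough and do not touch the ROI rim become the island masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .features import FeatureStack, local_moment_features, standardize_features

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class KSelectionTrace:
    """Per-k record of the cluster-number decision rule."""

    k_values: list[int]
    wcv_per_feature: np.ndarray  # (n_k, 3) raw WCVs of the island class
    wcv_normalized: np.ndarray  # (n_k, 3) after min-max across k
    wcv_total: np.ndarray  # (n_k,)
    diffs: np.ndarray  # (n_k - 1,)
    selected_k: int | None = None
    fallback: bool = False


@dataclass
class SegmentationResult:
    """Final segmentation of one sample's pan-NPC channel."""

    label_map: np.ndarray  # int cluster id per valid pixel, -1 outside
    island_class_id: int
    island_masks: list[np.ndarray] = field(default_factory=list)
    boundaries: list[np.ndarray] = field(default_factory=list)
    trace: KSelectionTrace | None = None
    n_islands_pre_filter: int = 0


def cluster_pixels(
    features: np.ndarray,
    valid_mask: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 2,
) -> np.ndarray:
    """K-means (k-means++ init, best of `restarts`) over valid pixels.

    Returns an integer label map, -1 outside ``valid_mask``.  Deterministic
    given ``seed``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    x = features[valid_mask]
    if len(x) < k:
        raise ValueError(f"k={k} exceeds the {len(x)} valid pixels")
    with warnings.catch_warnings():
        # identical feature vectors legitimately collapse clusters
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
        labels = km.fit_predict(x)
    out = np.full(valid_mask.shape, -1, dtype=np.int32)
    out[valid_mask] = labels
    return out


def select_island_class(label_map: np.ndarray, channel_a: np.ndarray) -> int:
    """Cluster id whose pixels have the lowest mean channel-A intensity.

    Ties are broken toward the smaller label id (logged).
    """
    img = np.asarray(channel_a, dtype=np.float64)
    labels = np.unique(label_map[label_map >= 0])
    if labels.size == 0:
        raise ValueError("label map has no valid pixels")
    means = np.array([img[label_map == lab].mean() for lab in labels])
    best = means.min()
    winners = labels[means == best]
    if winners.size > 1:
        logger.info("island-class tie between labels %s; taking %d", winners, winners[0])
    return int(winners[0])


def wcv_trace(
    features: np.ndarray,
    label_maps: dict[int, np.ndarray],
    channel_a: np.ndarray,
    k_values: list[int] | None = None,
) -> KSelectionTrace:
    """Build the WCV trace (without the selected k) from per-k clusterings.

    Per k and feature, WCV is the population variance of that (standardized)
    feature over the island-class pixels; each feature's sequence is min-max
    normalized across k to [0, 1], and the total WCV is their unweighted
    mean.  Diff_WCV(k) = WCV_total(k+1) - WCV_total(k).
    """
    if k_values is None:
        k_values = sorted(label_maps)
    raw = np.empty((len(k_values), 3))
    for i, k in enumerate(k_values):
        lm = label_maps[k]
        cls = select_island_class(lm, channel_a)
        px = features[lm == cls]
        raw[i] = px.var(axis=0)
    span = raw.max(axis=0) - raw.min(axis=0)
    norm = np.zeros_like(raw)
    nz = span > 0
    norm[:, nz] = (raw[:, nz] - raw.min(axis=0)[nz]) / span[nz]
    total = norm.mean(axis=1)
    diffs = np.diff(total)
    return KSelectionTrace(list(k_values), raw, norm, total, diffs)


def select_k(trace: KSelectionTrace) -> int:
    """Apply the sign-change rule to a WCV trace.

    Returns the smallest k at a strict local minimum of WCV_total: the k
    right after the last negative Diff before the first positive Diff,
    zero diffs continuing the preceding sign (a plateau minimum selects the
    plateau's smallest k).  A monotone trace (no minus-to-plus change)
    falls back to the argmin of WCV_total with a FALLBACK flag logged.
    """
    k = trace.k_values
    d = trace.diffs
    if len(k) < 3:
        raise ValueError("need at least 3 usable k values to select k")
    last_neg = None
    for i, di in enumerate(d):
        if di < 0:
            last_neg = i
        elif di > 0:
            if last_neg is not None:
                sel = k[last_neg + 1]
                trace.selected_k = sel
                return sel
            last_neg = None  # rising from the start: no minimum yet passed
    sel = k[int(np.argmin(trace.wcv_total))]
    trace.selected_k = sel
    trace.fallback = True
    logger.warning("no minus-to-plus Diff_WCV sign change; FALLBACK to argmin k=%d", sel)
    return sel


def extract_islands(
    label_map: np.ndarray,
    island_class_id: int,
    nucleus_mask: np.ndarray,
    min_island_area_px: float = 0.0,
    drop_border: bool = True,
) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Clean the island-class pixels into per-island masks and boundaries.

    Pipeline: binary mask -> 3x3 morphological closing -> hole filling ->
    3x3 opening (cuts the thin bridges that closing can build between
    islands, label-map speckle chains and the ROI rim) -> 8-connected
    components -> drop components below ``min_island_area_px`` or
    (optionally) touching the valid-region rim.  Boundary pixels are
    island pixels 4-adjacent to a non-island pixel.

    Returns (island_masks, boundaries, n_components_pre_filter).
    """
    raw = (label_map == island_class_id) & (label_map >= 0)
    if not raw.any():
        return [], [], 0
    closed = ndimage.binary_closing(raw, structure=_STRUCT8)
    filled = ndimage.binary_fill_holes(closed)
    filled = ndimage.binary_opening(filled, structure=_STRUCT8)
    filled &= np.asarray(nucleus_mask, dtype=bool)
    lab, n_comp = ndimage.label(filled, structure=_STRUCT8)
    if n_comp == 0:
        return [], [], 0

    outside = label_map < 0  # beyond the valid clustering region
    near_outside = ndimage.binary_dilation(outside, structure=_STRUCT8, border_value=1)
    rim_ids = set(np.unique(lab[near_outside & (lab > 0)]))

    masks: list[np.ndarray] = []
    bounds: list[np.ndarray] = []
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_comp + 1))
    for cid in range(1, n_comp + 1):
        if areas[cid - 1] < min_island_area_px:
            continue
        if drop_border and cid in rim_ids:
            continue
        m = lab == cid
        masks.append(m)
        bounds.append(m & ~ndimage.binary_erosion(m, structure=_STRUCT4, border_value=0))
    return masks, bounds, int(n_comp)


class IslandSegmenter(BaseEstimator):
    """Recognize pore-free islands on a pan-NPC channel image.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive K-means cluster-number search interval.
    seed : int
        K-means random seed (k-means++ restarts).
    restarts : int
        Restarts per k; best by within-cluster sum of squares.
    window : int
        Odd moment-feature window side (px).
    min_island_area_px : float
        Components below this area (px) are discarded.
    drop_border : bool
        Discard components touching the ROI rim (islands must be surrounded
        by pore-rich region).

    Attributes (after :meth:`fit`)
    ------------------------------
    features_ : FeatureStack
    standardized_ : (H, W, 3) ndarray
    label_map_ : ndarray, cluster labels at the selected k (-1 outside ROI)
    island_class_ : int
    k_ : int, selected cluster number
    trace_ : KSelectionTrace
    island_masks_, boundaries_ : lists of boolean masks
    n_islands_pre_filter_ : int
    result_ : SegmentationResult
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 20),
        seed: int = 0,
        restarts: int = 2,
        window: int = 3,
        min_island_area_px: float = 0.0,
        drop_border: bool = True,
    ):
        self.k_range = k_range
        self.seed = seed
        self.restarts = restarts
        self.window = window
        self.min_island_area_px = min_island_area_px
        self.drop_border = drop_border

    def fit(self, X: np.ndarray, nucleus_mask: np.ndarray | None = None):
        """Segment one image; X is the 2-D pan-NPC intensity grid."""
        lo, hi = self.k_range
        if lo < 2:
            raise ValueError("k_range lower bound must be >= 2")
        img = np.asarray(X, dtype=np.float64)
        self.features_ = local_moment_features(img, self.window, nucleus_mask)
        self.standardized_ = standardize_features(self.features_)
        valid = self.features_.valid_mask
        n_valid = int(valid.sum())
        k_values = [k for k in range(lo, hi + 1) if k <= n_valid]
        label_maps = {
            k: cluster_pixels(self.standardized_, valid, k, self.seed, self.restarts)
            for k in k_values
        }
        trace = wcv_trace(self.standardized_, label_maps, img, k_values)
        k_sel = select_k(trace)
        lm = label_maps[k_sel]
        cls = select_island_class(lm, img)
        roi = nucleus_mask if nucleus_mask is not None else np.ones(img.shape, bool)
        masks, bounds, n_pre = extract_islands(
            lm, cls, roi, self.min_island_area_px, self.drop_border
        )
        self.label_map_ = lm
        self.island_class_ = cls
        self.k_ = k_sel
        self.trace_ = trace
        self.island_masks_ = masks
        self.boundaries_ = bounds
        self.n_islands_pre_filter_ = n_pre
        self.result_ = SegmentationResult(lm, cls, masks, bounds, trace, n_pre)
        return self


def segment_islands(
    channel_a: np.ndarray, nucleus_mask: np.ndarray | None = None, **params
) -> SegmentationResult:
    """Functional wrapper over :class:`IslandSegmenter`."""
    return IslandSegmenter(**params).fit(channel_a, nucleus_mask).result_
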