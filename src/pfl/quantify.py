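"""Island size, focus appearance frequency, and boundary-distance profiles.

Sizes are reported in px and um^2 (area_um2 = area_px * pixel_size^2) and
the appearance frequency is the focus count per um^2 of island.  For the
spatial analysis, each island gets an exact Euclidean distance field
measured from the pore-free/pore-rich boundary inward (rim pixels are at
distance 1); focus counts per unit-distance bin are divided by the number
of island pixels in that bin, per-island frequencies are averaged across
islands of a condition, and the aggregate is normalized to sum 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class IslandRecord:
    sample_id: str
    island_id: int
    area_px: int
    area_um2: float
    n_foci: int
    frequency: float  # foci / um^2


@dataclass
class DistanceProfile:
    """Per-distance-bin focus statistics for one island or a condition.

    Bins are half-open ``(lo, hi]`` of width ``distance_bin`` px starting
    at 0; ``bin_edges`` has length ``n_bins + 1``.  ``normalized_frequency``
    is None for single-island (unnormalized) profiles and for aggregates
    with no foci at all.
    """

    bin_edges: np.ndarray
    focus_counts: np.ndarray  # float: observed counts or simulated means
    pixel_counts: np.ndarray
    raw_frequency: np.ndarray
    normalized_frequency: np.ndarray | None = None
    n_islands_aggregated: int = 1
    kind: str = "observed"

    @property
    def n_bins(self) -> int:
        return len(self.focus_counts)


def island_metrics(
    island_mask: np.ndarray,
    n_foci: int,
    pixel_size: float,
    sample_id: str = "",
    island_id: int = 0,
) -> IslandRecord:
    """Size and appearance frequency of one island."""
    area_px = int(np.asarray(island_mask, bool).sum())
    if area_px == 0:
        raise ValueError("island mask is empty")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    area_um2 = area_px * pixel_size * pixel_size
    return IslandRecord(sample_id, island_id, area_px, area_um2, n_foci, n_foci / area_um2)


def distance_field(island_mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each island pixel to the exterior.

    Boundary pixels (4-adjacent to a non-island pixel) get 1; pixels
    outside the island get 0.
    """
    mask = np.asarray(island_mask, dtype=bool)
    if not mask.any():
        raise ValueError("island mask is empty")
    return ndimage.distance_transform_edt(mask)


def _bin_index(d: float, distance_bin: float) -> int:
    """Index of the half-open bin (lo, hi] containing distance d > 0."""
    return int(math.ceil(d / distance_bin)) - 1


def bin_pixel_counts(field: np.ndarray, distance_bin: float = 1.0) -> np.ndarray:
    """Island pixel counts per distance bin."""
    d = field[field > 0]
    n_bins = _bin_index(float(d.max()), distance_bin) + 1
    idx = np.ceil(d / distance_bin).astype(int) - 1
    return np.bincount(idx, minlength=n_bins)


def distance_profile(
    foci_coords: list[tuple[float, float]],
    field: np.ndarray,
    distance_bin: float = 1.0,
) -> DistanceProfile:
    """Single-island (unnormalized) boundary-distance profile.

    Each focus is assigned the field value at its centroid's containing
    pixel; a focus landing outside the island is an assignment bug and
    raises.
    """
    pixels = bin_pixel_counts(field, distance_bin)
    n_bins = len(pixels)
    counts = np.zeros(n_bins, dtype=np.float64)
    for r, c in foci_coords:
        pr, pc = int(math.floor(r + 0.5)), int(math.floor(c + 0.5))
        d = field[pr, pc]
        if d <= 0:
            raise ValueError(f"focus at ({r:.2f}, {c:.2f}) lies outside the island")
        counts[_bin_index(float(d), distance_bin)] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(pixels > 0, counts / np.maximum(pixels, 1), 0.0)
    edges = np.arange(n_bins + 1, dtype=np.float64) * distance_bin
    return DistanceProfile(edges, counts, pixels, raw)


def aggregate_profiles(
    profiles: list[DistanceProfile], kind: str | None = None
) -> DistanceProfile:
    """Condition-level profile: average per-island raw frequencies, then
    normalize to sum 1.0.

    An island contributes to a bin only if its own field reaches it, so
    bin b is averaged over the islands possessing bin b.  All-empty
    profiles leave ``normalized_frequency`` as None.
    """
    if not profiles:
        raise ValueError("need at least one profile to aggregate")
    db = profiles[0].bin_edges[1] - profiles[0].bin_edges[0]
    for p in profiles:
        if abs((p.bin_edges[1] - p.bin_edges[0]) - db) > 1e-12:
            raise ValueError("profiles have differing bin widths")
    n_bins = max(p.n_bins for p in profiles)
    counts = np.zeros(n_bins)
    pixels = np.zeros(n_bins, dtype=np.int64)
    freq_sum = np.zeros(n_bins)
    n_having = np.zeros(n_bins, dtype=np.int64)
    for p in profiles:
        nb = p.n_bins
        counts[:nb] += p.focus_counts
        pixels[:nb] += p.pixel_counts
        freq_sum[:nb] += p.raw_frequency
        n_having[:nb] += 1
    mean_freq = freq_sum / n_having  # n_having >= 1 for every bin by construction
    total = mean_freq.sum()
    normalized = mean_freq / total if total > 0 else None
    edges = np.arange(n_bins + 1, dtype=np.float64) * db
    return DistanceProfile(
        edges,
        counts,
        pixels,
        mean_freq,
        normalized,
        n_islands_aggregated=len(profiles),
        kind=kind or profiles[0].kind,
    )


def split_proximal_distal(
    profile: DistanceProfile, proximal_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Partition bin indices into proximal and distal regions.

    The proximal region holds the bins whose upper edge is within
    ``proximal_fraction`` of the maximum distance present, i.e. the first
    ``floor(fraction * n_bins)`` bins (at least one); the distal region is
    the rest (empty for a single-bin profile, which is flagged upstream).
    """
    if not 0 < proximal_fraction < 1:
        raise ValueError("proximal_fraction must be in (0, 1)")
    n = profile.n_bins
    if n == 0:
        raise ValueError("profile has no bins")
    n_prox = max(1, int(math.floor(proximal_fraction * n)))
    idx = np.arange(n)
    return idx[:n_prox], idx[n_prox:]
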