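"""Sample loading, run configuration, and automated QC.

Inputs are single-plane grayscale TIFFs (8/16-bit) per channel plus an
optional binary nucleus-ROI mask TIFF; a samplesheet CSV maps images to
experimental conditions.  QC replaces the manual accept/reject step with
three automated flags — intensity saturation, nucleus edge blurring, and
minute/absent islands — plus overlay images for optional human review.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class Condition:
    inhibitor: str = ""
    treatment_hours: float = 0.0
    antibody: str = ""


@dataclass
class RawSample:
    """One cell's two channel images, nucleus mask and condition labels."""

    sample_id: str
    condition: Condition
    channel_a: np.ndarray  # pan-NPC stain
    channel_b: np.ndarray  # single-Nup counterstain
    nucleus_mask: np.ndarray
    pixel_size: float  # um / px, isotropic

    def __post_init__(self):
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channel shapes differ")
        if self.nucleus_mask.shape != self.channel_a.shape:
            raise ValueError("nucleus mask shape differs from channels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.nucleus_mask.any():
            raise ValueError("nucleus mask has no foreground pixel")


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline (TOML-mappable)."""

    k_range: tuple[int, int] = (2, 20)
    kmeans_seed: int = 0
    kmeans_restarts: int = 2
    feature_window: int = 3  # odd, px
    curvature_sigma: float = 0.8  # px
    min_island_area: float = 2.0  # um^2
    min_focus_area: int = 2  # px
    max_focus_area: int = 100  # px
    saturation_fraction_limit: float = 1e-3
    blur_metric_limit: float = 0.0  # 0 disables the EDGE_BLUR flag
    sim_reps: int = 33029
    sim_seed: int = 0
    distance_bin: float = 1.0  # px
    proximal_fraction: float = 0.5
    alpha: float = 0.05

    def __post_init__(self):
        if self.k_range[0] < 2:
            raise ValueError("k_range lower bound must be >= 2")
        if self.sim_reps < 1:
            raise ValueError("sim_reps must be >= 1")
        if not 0 < self.proximal_fraction < 1:
            raise ValueError("proximal_fraction must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCReport:
    sample_id: str
    saturation_fraction: float = 0.0
    blur_metric: float = 0.0
    n_islands_pre_filter: int = 0
    n_islands_post_filter: int = 0
    flags: set[str] = field(default_factory=set)
    error: str = ""

    @property
    def accepted(self) -> bool:
        return not self.flags


def _read_plane(path: str | Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-plane grayscale image, got shape {img.shape}"
        )
    return img


def load_sample(
    channel_a_path: str | Path,
    channel_b_path: str | Path,
    mask_path: str | Path | None,
    condition: Condition,
    pixel_size: float,
    sample_id: str | None = None,
) -> RawSample:
    """Load one sample's TIFFs into a validated :class:`RawSample`.

    A missing/empty mask path degrades to a whole-image ROI with a logged
    warning; shape mismatches and multi-plane/RGB inputs are hard errors
    naming the offending files.
    """
    a = _read_plane(channel_a_path)
    b = _read_plane(channel_b_path)
    if a.shape != b.shape:
        raise ValueError(
            f"shape mismatch: {channel_a_path} {a.shape} vs {channel_b_path} {b.shape}"
        )
    if mask_path:
        m = _read_plane(mask_path)
        if m.shape != a.shape:
            raise ValueError(
                f"shape mismatch: {channel_a_path} {a.shape} vs mask {mask_path} {m.shape}"
            )
        mask = m > 0
    else:
        logger.warning(
            "no nucleus mask for %s; using the whole image as ROI", channel_a_path
        )
        mask = np.ones(a.shape, dtype=bool)
    sid = sample_id or Path(channel_a_path).stem
    return RawSample(sid, condition, a, b, mask, pixel_size)


def blur_metric(channel_a: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """Normalized gradient energy at the nucleus edge.

    RMS Sobel gradient magnitude over a thin band at the mask boundary,
    divided by the mean in-mask intensity; low values indicate a blurred
    nucleus edge.  Needs per-dataset calibration to act as a reject
    threshold, so it is reported for every sample but only flagged when a
    positive ``blur_metric_limit`` is configured.
    """
    img = np.asarray(channel_a, dtype=np.float64)
    mask = np.asarray(nucleus_mask, bool)
    band = mask & ~ndimage.binary_erosion(mask, iterations=2, border_value=0)
    if not band.any():
        return 0.0
    gy = ndimage.sobel(img, axis=0)
    gx = ndimage.sobel(img, axis=1)
    energy = np.sqrt(np.mean(gy[band] ** 2 + gx[band] ** 2))
    denom = img[mask].mean()
    return float(energy / denom) if denom > 0 else 0.0


def compute_qc(
    sample: RawSample,
    n_islands_pre_filter: int,
    n_islands_post_filter: int,
    cfg: RunConfig,
) -> QCReport:
    """Automated accept/reject flags for one segmented sample.

    * SATURATED — fraction of in-mask pixels at the dtype maximum exceeds
      ``saturation_fraction_limit`` (integer images only).
    * EDGE_BLUR — blur metric below a positive ``blur_metric_limit``.
    * MINUTE_ISLANDS — islands were found but all fell below
      ``min_island_area``.
    * NO_ISLANDS — the island class produced no component at all.
    """
    mask = sample.nucleus_mask
    a = sample.channel_a
    if np.issubdtype(a.dtype, np.integer):
        sat = float(np.mean(a[mask] == np.iinfo(a.dtype).max))
    else:
        sat = 0.0
    blur = blur_metric(a, mask)
    report = QCReport(
        sample.sample_id,
        saturation_fraction=sat,
        blur_metric=blur,
        n_islands_pre_filter=n_islands_pre_filter,
        n_islands_post_filter=n_islands_post_filter,
    )
    if sat > cfg.saturation_fraction_limit:
        report.flags.add("SATURATED")
    if cfg.blur_metric_limit > 0 and blur < cfg.blur_metric_limit:
        report.flags.add("EDGE_BLUR")
    if n_islands_pre_filter == 0:
        report.flags.add("NO_ISLANDS")
    elif n_islands_post_filter == 0:
        report.flags.add("MINUTE_ISLANDS")
    return report
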