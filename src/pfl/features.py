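"""Per-pixel image-moment texture features for pore-free island recognition.

Three local statistics are computed over a small square window around each
pixel of the pan-NPC (mAb414-like) channel: the window mean (brightness), the
population variance (contrast), and the intensity-normalized second-order
central spatial moment around the intensity-weighted centroid (intensity
spread, in px^2).  A pore-rich region is a dense carpet of bright puncta,
so all three statistics differ systematically from the flat, dim interior
of a pore-free island; K-means on this 3-vector field separates the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class FeatureStack:
    """Per-pixel moment features.

    Attributes
    ----------
    mean_map : ndarray
        Window mean intensity.
    variance_map : ndarray
        Window population variance (intensity^2).
    spread_map : ndarray
        Trace of the intensity-normalized second central spatial moment
        matrix over the window (px^2); 0 where the window holds no signal.
    window : int
        Odd window side length.
    valid_mask : ndarray of bool
        Pixels whose full window lies inside the ROI (and the image).
    """

    mean_map: np.ndarray
    variance_map: np.ndarray
    spread_map: np.ndarray
    window: int
    valid_mask: np.ndarray


def local_moment_features(
    image: np.ndarray, window: int = 3, roi: np.ndarray | None = None
) -> FeatureStack:
    """Compute the three per-pixel moment features over a sliding window.

    For a pixel p with window W(p) of side `window`:

    * ``mean = sum(I) / |W|``
    * ``variance = sum(I^2)/|W| - mean^2``  (population variance)
    * ``spread = mu'20 + mu'02`` where ``mu'pq = sum I(x,y)(x-xc)^p(y-yc)^q
      / sum I`` with (xc, yc) the intensity-weighted centroid of W; defined
      as 0 when the window's total intensity is 0.

    Windows that overlap the ROI edge or the image border are excluded via
    ``valid_mask`` rather than padded.

    Parameters
    ----------
    image : 2-D array, non-negative intensities.
    window : odd int >= 3.
    roi : 2-D bool array or None
        Region of interest (nucleus mask); None means the whole image.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("roi shape does not match image shape")

    n = window * window
    box = np.ones((window, window))
    offs = np.arange(window, dtype=np.float64) - window // 2
    ky = np.repeat(offs[:, None], window, axis=1)  # row offsets
    kx = ky.T  # column offsets

    s0 = ndimage.correlate(img, box, mode="constant")
    mean = s0 / n
    meansq = ndimage.correlate(img * img, box, mode="constant") / n
    variance = np.maximum(meansq - mean * mean, 0.0)

    sy = ndimage.correlate(img, ky, mode="constant")
    sx = ndimage.correlate(img, kx, mode="constant")
    syy = ndimage.correlate(img, ky * ky, mode="constant")
    sxx = ndimage.correlate(img, kx * kx, mode="constant")

    with np.errstate(divide="ignore", invalid="ignore"):
        cy = np.where(s0 > 0, sy / s0, 0.0)
        cx = np.where(s0 > 0, sx / s0, 0.0)
        spread = np.where(s0 > 0, (sxx + syy) / np.where(s0 > 0, s0, 1.0), 0.0)
    spread = np.maximum(spread - (cx * cx + cy * cy), 0.0)

    valid = ndimage.binary_erosion(
        roi, structure=np.ones((window, window), dtype=bool), border_value=0
    )
    if not valid.any():
        raise ValueError("ROI admits no pixel with a full feature window")

    for m in (mean, variance, spread):
        m[~valid] = 0.0
    return FeatureStack(mean, variance, spread, window, valid)


def standardize_features(stack: FeatureStack) -> np.ndarray:
    """Z-score each feature over the valid pixels.

    Returns an (H, W, 3) array ordered (mean, variance, spread), each plane
    having mean 0 and SD 1 over ``stack.valid_mask``; a zero-variance feature
    maps to all zeros with a warning.  Invalid pixels are 0.
    """
    valid = stack.valid_mask
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid pixels to standardize")
    out = np.zeros(stack.mean_map.shape + (3,), dtype=np.float64)
    names = ("mean", "variance", "spread")
    for i, (name, m) in enumerate(
        zip(names, (stack.mean_map, stack.variance_map, stack.spread_map))
    ):
        vals = m[valid]
        mu = vals.mean()
        sd = vals.std()
        if sd == 0:
            warnings.warn(f"feature '{name}' is constant; standardized to zeros")
            continue
        out[valid, i] = (vals - mu) / sd
    return out
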