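"""Dark-field threshold segmentation of lung tissue.

Scattering lung parenchyma suppresses the stepping-curve modulation, so
lung pixels sit at *low* relative visibility while the water/formalin
background clusters near V = 1.  The segmentation threshold is placed
at the valley between the background mode and the lung signal peak of
the dark-field histogram; the resulting mask indexes all three channels
so per-pixel statistics are computed over identical lung areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .retrieval import ProjectionTriplet

__all__ = ["SegmentationMask", "darkfield_threshold", "segment_lung"]


class SegmentationError(ValueError):
    """Raised when no usable lung mask can be derived."""


@dataclass
class SegmentationMask:
    mask: np.ndarray
    threshold: float
    method: Literal["valley", "otsu", "manual"]
    pixel_count: int


def darkfield_threshold(
    V_map: np.ndarray,
    valid_mask: np.ndarray,
    method: Literal["valley", "otsu"] = "valley",
    bins: int = 256,
    smooth_bins: int = 5,
    otsu_fallback: bool = True,
) -> float:
    """Locate the border between background noise and the lung peak.

    The default ``valley`` method histograms V over valid pixels,
    smooths the counts with a moving average and returns the location
    of the minimum between the dominant background mode (the highest
    peak, near V = 1 after water normalization) and the nearest
    distinct mode below it -- the lung signal peak.  Anchoring the
    valley at the background mode keeps the threshold at the border of
    the background noise even when strongly scattering lung regions
    pile up near V = 0 and rival the mid-V lung peak in height.  If no
    second mode is found the threshold falls back to Otsu's criterion
    (with a warning), unless ``otsu_fallback`` is disabled, in which
    case a unimodal histogram is an error.
    """
    values = np.asarray(V_map)[np.asarray(valid_mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise SegmentationError(
            f"need at least 100 valid pixels to estimate a threshold, "
            f"got {values.size}"
        )
    if values.max() == values.min():
        raise SegmentationError(
            "dark-field histogram is degenerate (all values equal)"
        )
    if method == "otsu":
        return float(threshold_otsu(values, nbins=bins))
    if method != "valley":
        raise ValueError(f"unknown threshold method {method!r}")

    counts, edges = np.histogram(values, bins=bins)
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(counts, kernel, mode="same")
    # a minimum peak separation keeps detected maxima in distinct modes
    # instead of adjacent noise bins of one mode
    min_distance = max(2, bins // 16)
    peaks, _ = find_peaks(smoothed, height=0, distance=min_distance)
    background = peaks[np.argmax(smoothed[peaks])] if len(peaks) else None
    left = peaks[peaks < background] if len(peaks) else np.empty(0, int)
    if len(left):
        lo = left[-1]
        valley = lo + int(np.argmin(smoothed[lo : background + 1]))
        # a genuine inter-mode valley dips far below the background
        # spike; bumps inside a single mode do not
        if smoothed[valley] < 0.25 * smoothed[background]:
            centers = 0.5 * (edges[:-1] + edges[1:])
            return float(centers[valley])
    if otsu_fallback:
        warnings.warn(
            "dark-field histogram shows fewer than two modes; falling "
            "back to Otsu's threshold",
            stacklevel=2,
        )
        return float(threshold_otsu(values, nbins=bins))
    raise SegmentationError(
        "dark-field histogram shows fewer than two modes and the Otsu "
        "fallback is disabled"
    )


def segment_lung(
    triplet: ProjectionTriplet,
    threshold: float,
    method: Literal["valley", "otsu", "manual"] = "valley",
    min_component_size: int = 20,
) -> SegmentationMask:
    """Mask lung tissue: valid pixels with V below the threshold.

    Connected components smaller than ``min_component_size`` pixels are
    dropped, which removes isolated noise pixels and most of the
    trachea/main-bronchi remnants.  The same mask is applied to T, V
    and S downstream.
    """
    with np.errstate(invalid="ignore"):
        mask = triplet.valid_mask & (triplet.V_map < threshold)
    if min_component_size > 1:
        labelled, n_components = ndimage.label(mask)
        if n_components:
            sizes = np.bincount(labelled.ravel())
            keep = sizes >= min_component_size
            keep[0] = False
            mask = keep[labelled]
    count = int(mask.sum())
    if count == 0:
        raise SegmentationError(
            f"segmentation at threshold {threshold:.4g} selects no pixels; "
            f"review the threshold against the dark-field histogram"
        )
    return SegmentationMask(
        mask=mask, threshold=float(threshold), method=method, pixel_count=count
    )
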