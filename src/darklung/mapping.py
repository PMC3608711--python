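"""Parametric emphysema-distribution maps.

For a chosen channel and cutoff, each lung pixel's deviation *toward
the emphysematous signal direction* is normalized against the
interquartile range of that channel over the control-group pixel pool
and clipped to [0, 1] (so the color scale reads "0 to 1 control IQRs of
deviation").  Deviations toward the healthy direction are mapped to 0.
The map is rendered as a color overlay (yellow to red by default) on
the min-max-windowed grayscale transmission image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import matplotlib

matplotlib.use("Agg")
import numpy as np
from matplotlib import colormaps

from .roc import Orientation

__all__ = [
    "DeviationMap",
    "deviation_map",
    "render_overlay",
    "REFERENCE_CONTROL_IQRS",
]

#: control-group per-pixel IQR presets for ex-vivo murine lungs
REFERENCE_CONTROL_IQRS: Dict[str, float] = {
    "transmission": 0.06,
    "dark_field": 0.37,
    "normalized_scatter": 7.2,
}


class MappingError(ValueError):
    pass


@dataclass
class DeviationMap:
    """Per-pixel disease-direction deviation in control-IQR units."""

    values: np.ndarray
    parameter: str
    cutoff: float
    orientation: Orientation
    control_iqr: float


def deviation_map(
    param_map: np.ndarray,
    mask: np.ndarray,
    cutoff: float,
    orientation: Orientation,
    control_iqr: float,
    parameter: str = "",
) -> DeviationMap:
    """Signed deviation toward disease, in control-IQR units, clipped.

    ``(param - cutoff)`` for ``greater_is_diseased`` channels,
    ``(cutoff - param)`` for ``less_is_diseased``; divided by the
    control-group IQR and clipped to [0, 1].  Pixels outside the mask
    (and pixels deviating in the healthy direction) are exactly 0.
    """
    if not (control_iqr > 0):
        raise MappingError(
            f"control IQR must be positive, got {control_iqr}"
        )
    mask = np.asarray(mask, dtype=bool)
    param_map = np.asarray(param_map, dtype=float)
    if orientation == "greater_is_diseased":
        dev = param_map - cutoff
    elif orientation == "less_is_diseased":
        dev = cutoff - param_map
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    values = np.zeros(param_map.shape)
    values[mask] = np.clip(np.nan_to_num(dev[mask]) / control_iqr, 0.0, 1.0)
    return DeviationMap(
        values=values,
        parameter=parameter,
        cutoff=float(cutoff),
        orientation=orientation,
        control_iqr=float(control_iqr),
    )


def render_overlay(
    T_map: np.ndarray,
    deviation: DeviationMap,
    colormap_name: str = "autumn_r",
    alpha_floor: float = 0.35,
    window_percentiles: tuple = (1.0, 99.0),
) -> np.ndarray:
    """Blend the deviation map over the grayscale transmission image.

    Returns a uint8 RGB array.  The background is the transmission map
    windowed to its given percentile range; pixels with positive
    deviation are blended with the colormap, the blend weight rising
    linearly from ``alpha_floor`` (so even mild disease stays visible)
    to 1 at a full-IQR deviation.  Output bytes are deterministic for
    fixed inputs.
    """
    if T_map.shape != deviation.values.shape:
        raise MappingError("transmission map and deviation map shapes differ")
    finite = np.isfinite(T_map)
    lo, hi = np.percentile(T_map[finite], window_percentiles)
    if hi <= lo:
        hi = lo + 1.0
    gray = np.clip((np.nan_to_num(T_map, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=2)

    dev = deviation.values
    colored = dev > 0
    cmap = colormaps[colormap_name]
    overlay = cmap(dev)[..., :3]
    alpha = np.where(colored, alpha_floor + (1.0 - alpha_floor) * dev, 0.0)
    out = (1.0 - alpha[..., None]) * rgb + alpha[..., None] * overlay
    return np.round(np.clip(out, 0.0, 1.0) * 255.0).astype(np.uint8)
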