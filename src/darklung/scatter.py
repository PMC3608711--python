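"""The normalized-scatter statistic and group comparisons.

Both log-signals of a projection grow linearly with the traversed
tissue thickness, so their ratio

    S = -ln(V) / (ln(T) - c)

is thickness-independent: it measures scatter per unit of (log)
transmission excess over the specimen background.  The correction
factor ``c`` accounts for the formalin-filled container, whose
transmission is slightly above the surrounding water bath; it is
estimated per specimen as the log-ratio of the mean transmission in a
formalin ROI to that in a water ROI.

Emphysematous tissue has fewer alveolar interfaces per unit thickness,
so its normalized scatter is *lower* than in healthy lung, while the
raw dark-field median is essentially unchanged and transmission rises
only moderately -- which is what makes S the discriminating statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ScatterResult",
    "GroupSummary",
    "estimate_correction",
    "normalized_scatter",
    "summarize_groups",
    "PARAMETERS",
]

#: canonical channel names used across summaries, ROC and maps
PARAMETERS = ("transmission", "dark_field", "normalized_scatter")


class ScatterError(ValueError):
    pass


@dataclass
class ScatterResult:
    """Per-projection normalized-scatter map plus analysis vectors."""

    S_map: np.ndarray
    c_used: float
    defined_mask: np.ndarray
    T_values: np.ndarray
    V_values: np.ndarray
    S_values: np.ndarray
    n_undefined: int
    specimen_id: str = ""
    projection_index: int = -1
    group_label: str = ""


@dataclass
class GroupSummary:
    """Median/quartile table and Mann-Whitney p-values per parameter."""

    table: pd.DataFrame
    p_values: Dict[str, float]
    level: Literal["per_pixel", "per_individual"]
    n_per_group: Dict[str, int]


def estimate_correction(
    T_map: np.ndarray,
    formalin_roi: np.ndarray,
    water_roi: np.ndarray,
) -> float:
    """Background correction ``c = ln(mean T formalin / mean T water)``.

    ROI means are arithmetic means of transmission over finite pixels.
    For a multi-projection specimen, average the per-projection values
    of ``c`` into one per-specimen correction.
    """
    formalin_roi = np.asarray(formalin_roi, dtype=bool)
    water_roi = np.asarray(water_roi, dtype=bool)
    if not formalin_roi.any() or not water_roi.any():
        raise ScatterError("formalin and water ROIs must be non-empty")
    t_f = np.nanmean(np.where(formalin_roi, T_map, np.nan))
    t_w = np.nanmean(np.where(water_roi, T_map, np.nan))
    if not (t_f > 0 and t_w > 0):
        raise ScatterError(
            f"non-positive ROI mean transmission (formalin {t_f}, water {t_w})"
        )
    return float(np.log(t_f / t_w))


def normalized_scatter(
    T_map: np.ndarray,
    V_map: np.ndarray,
    c: float,
    mask: np.ndarray,
    eps: float = 1e-4,
    specimen_id: str = "",
    projection_index: int = -1,
    group_label: str = "",
) -> ScatterResult:
    """Compute ``S = -ln(V) / (ln(T) - c)`` over the analysis mask.

    Pixels whose denominator ``ln(T) - c`` does not exceed ``eps`` are
    flagged undefined: their S would be unstable or negative-infinite,
    so they are excluded from the statistics and counted instead.
    """
    if not np.isfinite(c):
        raise ScatterError(f"correction factor must be finite, got {c}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ScatterError("analysis mask is empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.log(T_map) - c
        numer = -np.log(V_map)
    defined = mask & np.isfinite(denom) & np.isfinite(numer) & (denom > eps)
    S_map = np.zeros_like(np.asarray(T_map, dtype=float))
    S_map[defined] = numer[defined] / denom[defined]
    return ScatterResult(
        S_map=S_map,
        c_used=float(c),
        defined_mask=defined,
        T_values=np.asarray(T_map)[mask],
        V_values=np.asarray(V_map)[mask],
        S_values=S_map[defined],
        n_undefined=int(mask.sum() - defined.sum()),
        specimen_id=specimen_id,
        projection_index=projection_index,
        group_label=group_label,
    )


def _pooled_vectors(
    results: Sequence[ScatterResult],
) -> Dict[str, Dict[str, np.ndarray]]:
    """{group: {parameter: pooled pixel values}} over all projections."""
    pools: Dict[str, Dict[str, List[np.ndarray]]] = {}
    for r in results:
        g = pools.setdefault(r.group_label, {p: [] for p in PARAMETERS})
        g["transmission"].append(r.T_values)
        g["dark_field"].append(r.V_values)
        g["normalized_scatter"].append(r.S_values)
    return {
        g: {p: np.concatenate(v) if v else np.empty(0) for p, v in d.items()}
        for g, d in pools.items()
    }


def _per_individual_vectors(
    results: Sequence[ScatterResult],
) -> Dict[str, Dict[str, np.ndarray]]:
    """Reduce each specimen to the median of its pooled pixels."""
    by_specimen: Dict[str, List[ScatterResult]] = {}
    group_of: Dict[str, str] = {}
    for r in results:
        by_specimen.setdefault(r.specimen_id, []).append(r)
        group_of[r.specimen_id] = r.group_label
    out: Dict[str, Dict[str, List[float]]] = {}
    for sid, rs in by_specimen.items():
        pooled = _pooled_vectors(rs)[group_of[sid]]
        g = out.setdefault(group_of[sid], {p: [] for p in PARAMETERS})
        for p in PARAMETERS:
            if pooled[p].size == 0:
                raise ScatterError(
                    f"specimen {sid!r} has no defined pixels for {p}"
                )
            g[p].append(float(np.median(pooled[p])))
    return {g: {p: np.asarray(v) for p, v in d.items()} for g, d in out.items()}


def summarize_groups(
    results: Sequence[ScatterResult],
    level: Literal["per_pixel", "per_individual"] = "per_pixel",
) -> GroupSummary:
    """Group medians, quartiles and two-sided Mann-Whitney comparisons.

    ``per_pixel`` pools every defined pixel of every projection of every
    specimen in a group (pixels treated as independent observations, an
    assumption the run report flags); ``per_individual`` first reduces
    each specimen to its median.  Quartiles use linear interpolation.
    """
    if level == "per_pixel":
        vectors = _pooled_vectors(results)
    elif level == "per_individual":
        vectors = _per_individual_vectors(results)
    else:
        raise ValueError(f"unknown analysis level {level!r}")
    groups = sorted(vectors)
    if len(groups) != 2:
        raise ScatterError(
            f"expected exactly two groups, got {groups!r}"
        )
    for g in groups:
        for p in PARAMETERS:
            if vectors[g][p].size == 0:
                raise ScatterError(f"group {g!r} has no defined pixels for {p}")

    rows = []
    p_values: Dict[str, float] = {}
    for p in PARAMETERS:
        a, b = (vectors[g][p] for g in groups)
        if np.array_equal(a, b) or (np.all(a == a[0]) and np.all(b == a[0])):
            p_values[p] = 1.0
        else:
            p_values[p] = float(
                mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        for g in groups:
            v = vectors[g][p]
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                dict(group=g, parameter=p, median=med, q1=q1, q3=q3,
                     n=v.size, p_value=p_values[p])
            )
    table = pd.DataFrame(rows)
    return GroupSummary(
        table=table,
        p_values=p_values,
        level=level,
        n_per_group={g: int(vectors[g][PARAMETERS[0]].size) for g in groups},
    )
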