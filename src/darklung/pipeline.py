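"""End-to-end orchestration: simulate, retrieve, analyze, map.

Two execution paths share the same stage logic:

* :func:`analyze_cohort` runs the whole chain in memory and returns a
  structured :class:`CohortAnalysis`; this is the library entry point.
* The ``stage_*`` functions read and write artifact directories; the
  command-line subcommands (``simulate``, ``retrieve``, ``analyze``,
  ``map``, ``all``) are thin wrappers over them, and ``all`` simply
  runs the four stages in sequence, so stepwise and single-shot runs
  produce identical outputs.

All randomness flows from the single seed in the configuration through
per-(specimen, projection, stage) substreams, so identical config and
seed give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .mapping import (
    REFERENCE_CONTROL_IQRS,
    DeviationMap,
    deviation_map,
    render_overlay,
)
from .phantom import (
    GROUP_EMPHYSEMA,
    PhantomParams,
    PhantomTruth,
    generate_cohort,
)
from .retrieval import ProjectionTriplet, normalize_to_water, retrieve_signals
from .roc import (
    DEFAULT_ORIENTATIONS,
    REFERENCE_CUTOFFS,
    DelongResult,
    RocCurve,
    delong_compare,
    optimal_cutoff,
    roc_curve,
    sensitivity_at_specificity,
)
from .scatter import (
    PARAMETERS,
    GroupSummary,
    ScatterResult,
    estimate_correction,
    normalized_scatter,
    summarize_groups,
)
from .segmentation import darkfield_threshold, segment_lung

logger = logging.getLogger("darklung")

__all__ = [
    "RunConfig",
    "RunReport",
    "CohortAnalysis",
    "analyze_cohort",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Pipeline configuration; block names mirror the YAML layout."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    validity_floor: float = 0.01
    segmentation_method: str = "valley"
    global_threshold: bool = False
    min_component_size: int = 20
    histogram_bins: int = 256
    histogram_smooth_bins: int = 5
    eps: float = 1e-4
    orientations: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATIONS)
    )
    cutoff_criterion: str = "youden"
    specificity_level: float = 0.75
    cutoff_source: str = "from_roc"  # or "reference"
    iqr_source: str = "from_run"  # or "reference"
    colormap: str = "autumn_r"
    alpha_floor: float = 0.35
    display_projection: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cutoff_source not in ("from_roc", "reference"):
            raise ValueError(f"unknown cutoff_source {self.cutoff_source!r}")
        if self.iqr_source not in ("from_run", "reference"):
            raise ValueError(f"unknown iqr_source {self.iqr_source!r}")
        for p in PARAMETERS:
            if p not in self.orientations:
                raise ValueError(f"orientations missing channel {p!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        phantom_block = dict(data.pop("phantom", {}))
        if "image_shape" in phantom_block:
            phantom_block["image_shape"] = tuple(phantom_block["image_shape"])
        for key in ("group_T_quantiles", "group_S_quantiles"):
            if key in phantom_block:
                phantom_block[key] = {
                    g: tuple(q) for g, q in phantom_block[key].items()
                }
        kwargs: Dict = {"phantom": PhantomParams(**phantom_block)}
        block_fields = {
            "retrieval": ("validity_floor",),
            "segmentation": (
                "segmentation_method",
                "global_threshold",
                "min_component_size",
                "histogram_bins",
                "histogram_smooth_bins",
            ),
            "statistic": ("eps",),
            "roc": ("orientations", "cutoff_criterion", "specificity_level"),
            "mapping": (
                "cutoff_source",
                "iqr_source",
                "colormap",
                "alpha_floor",
                "display_projection",
            ),
        }
        for block, names in block_fields.items():
            blk = data.pop(block, {}) or {}
            unknown = set(blk) - {n.removeprefix("segmentation_") for n in names} - set(names)
            if unknown:
                raise ValueError(f"unknown keys in block {block!r}: {unknown}")
            for name in names:
                short = name.removeprefix("segmentation_")
                if name in blk:
                    kwargs[name] = blk[name]
                elif short in blk:
                    kwargs[name] = blk[short]
        for name in ("log_level", "seed"):
            if name in data:
                if name == "seed":
                    kwargs["phantom"] = dataclasses.replace(
                        kwargs["phantom"], seed=int(data.pop(name))
                    )
                else:
                    kwargs[name] = data.pop(name)
        if data:
            raise ValueError(f"unknown top-level config keys: {set(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict:
        out = dataclasses.asdict(self)
        phantom = out.pop("phantom")
        phantom["image_shape"] = list(phantom["image_shape"])
        phantom["group_T_quantiles"] = {
            g: list(q) for g, q in phantom["group_T_quantiles"].items()
        }
        phantom["group_S_quantiles"] = {
            g: list(q) for g, q in phantom["group_S_quantiles"].items()
        }
        out["phantom"] = phantom
        return out


# ---------------------------------------------------------------------------
# in-memory analysis


@dataclass
class ProjectionRecord:
    truth: PhantomTruth
    triplet: ProjectionTriplet
    scatter: Optional[ScatterResult] = None
    seg_threshold: Optional[float] = None
    seg_mask: Optional[np.ndarray] = None


@dataclass
class CohortAnalysis:
    """Everything the downstream statistics and maps need."""

    config: RunConfig
    records: List[ProjectionRecord]
    correction_per_specimen: Dict[str, float]
    correction_mean: float
    summary_per_pixel: GroupSummary
    summary_per_individual: GroupSummary
    pixel_scores: Dict[str, np.ndarray]
    pixel_labels: np.ndarray
    roc_per_pixel: Dict[str, RocCurve]
    roc_per_individual: Optional[Dict[str, RocCurve]]
    delong: Dict[str, DelongResult]
    cutoffs: Dict[str, float]
    control_iqrs: Dict[str, float]
    n_undefined: int


def _segment_record(rec: ProjectionRecord, config: RunConfig,
                    threshold: Optional[float] = None) -> None:
    if threshold is None:
        threshold = darkfield_threshold(
            rec.triplet.V_map,
            rec.triplet.valid_mask,
            method=config.segmentation_method
            if config.segmentation_method != "manual"
            else "valley",
            bins=config.histogram_bins,
            smooth_bins=config.histogram_smooth_bins,
        )
    seg = segment_lung(
        rec.triplet,
        threshold,
        method=config.segmentation_method,
        min_component_size=config.min_component_size,
    )
    rec.seg_threshold = seg.threshold
    rec.seg_mask = seg.mask


def _paired_pixel_scores(
    records: Sequence[ProjectionRecord],
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Pooled per-pixel score triples over all defined pixels.

    The analysis unit of the per-pixel ROC/DeLong comparison is a
    segmented, defined pixel carrying its (T, V, S) triple, so all
    three channels are extracted at identical positions.
    """
    scores = {p: [] for p in PARAMETERS}
    labels = []
    for rec in records:
        d = rec.scatter.defined_mask
        scores["transmission"].append(rec.triplet.T_map[d])
        scores["dark_field"].append(rec.triplet.V_map[d])
        scores["normalized_scatter"].append(rec.scatter.S_map[d])
        labels.append(
            np.full(int(d.sum()), rec.truth.group_label == GROUP_EMPHYSEMA)
        )
    return (
        {p: np.concatenate(v) for p, v in scores.items()},
        np.concatenate(labels),
    )


def _per_individual_scores(
    records: Sequence[ProjectionRecord],
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """One median triple per specimen."""
    by_specimen: Dict[str, List[ProjectionRecord]] = {}
    for rec in records:
        by_specimen.setdefault(rec.truth.specimen_id, []).append(rec)
    scores = {p: [] for p in PARAMETERS}
    labels = []
    for sid in sorted(by_specimen):
        recs = by_specimen[sid]
        pooled, _ = _paired_pixel_scores(recs)
        for p in PARAMETERS:
            scores[p].append(float(np.median(pooled[p])))
        labels.append(recs[0].truth.group_label == GROUP_EMPHYSEMA)
    return (
        {p: np.asarray(v) for p, v in scores.items()},
        np.asarray(labels),
    )


def analyze_cohort(
    config: RunConfig | None = None,
    records: Optional[List[ProjectionRecord]] = None,
) -> CohortAnalysis:
    """Run simulate -> retrieve -> segment -> statistic -> ROC in memory.

    ``records`` may be supplied pre-built (e.g. truths with rescaled
    thickness pushed through :func:`darklung.phantom.forward_project`)
    to reuse the downstream stages; otherwise the cohort is generated
    from ``config.phantom``.
    """
    if config is None:
        config = RunConfig()
    params = config.phantom

    if records is None:
        records = []
        for truth, sample, reference in generate_cohort(params):
            triplet = retrieve_signals(
                sample, reference, validity_floor=config.validity_floor
            )
            triplet = normalize_to_water(triplet, truth.water_roi)
            records.append(ProjectionRecord(truth=truth, triplet=triplet))
            logger.debug(
                "retrieved %s projection %d",
                truth.specimen_id,
                truth.projection_index,
            )

    # segmentation: per projection by default, one pooled threshold if asked
    if config.global_threshold:
        pooled_v = np.concatenate(
            [r.triplet.V_map[r.triplet.valid_mask] for r in records]
        )
        thr = darkfield_threshold(
            pooled_v,
            np.ones(pooled_v.shape, dtype=bool),
            method="valley" if config.segmentation_method == "manual"
            else config.segmentation_method,
            bins=config.histogram_bins,
            smooth_bins=config.histogram_smooth_bins,
        )
        for rec in records:
            _segment_record(rec, config, threshold=thr)
    else:
        for rec in records:
            _segment_record(rec, config)

    # background correction, one value per specimen
    c_values: Dict[str, List[float]] = {}
    for rec in records:
        c = estimate_correction(
            rec.triplet.T_map, rec.truth.formalin_roi, rec.truth.water_roi
        )
        c_values.setdefault(rec.truth.specimen_id, []).append(c)
    c_per_specimen = {sid: float(np.mean(v)) for sid, v in c_values.items()}
    c_mean = float(np.mean(list(c_per_specimen.values())))

    # normalized scatter per projection with the specimen's correction
    for rec in records:
        rec.scatter = normalized_scatter(
            rec.triplet.T_map,
            rec.triplet.V_map,
            c_per_specimen[rec.truth.specimen_id],
            rec.seg_mask,
            eps=config.eps,
            specimen_id=rec.truth.specimen_id,
            projection_index=rec.truth.projection_index,
            group_label=rec.truth.group_label,
        )
    scatter_results = [rec.scatter for rec in records]
    summary_px = summarize_groups(scatter_results, level="per_pixel")
    summary_ind = summarize_groups(scatter_results, level="per_individual")

    # ROC and paired AUC comparisons on the pooled pixel triples
    pixel_scores, pixel_labels = _paired_pixel_scores(records)
    roc_px = {
        p: roc_curve(pixel_scores[p], pixel_labels, config.orientations[p])
        for p in PARAMETERS
    }
    delong: Dict[str, DelongResult] = {}
    for a, b in (
        ("normalized_scatter", "transmission"),
        ("normalized_scatter", "dark_field"),
        ("transmission", "dark_field"),
    ):
        delong[f"{a}_vs_{b}"] = delong_compare(
            pixel_scores[a],
            pixel_scores[b],
            pixel_labels,
            orientation_a=config.orientations[a],
            orientation_b=config.orientations[b],
        )

    roc_ind: Optional[Dict[str, RocCurve]] = None
    if params.n_per_group >= 2:
        ind_scores, ind_labels = _per_individual_scores(records)
        roc_ind = {
            p: roc_curve(ind_scores[p], ind_labels, config.orientations[p])
            for p in PARAMETERS
        }
    else:
        warnings.warn(
            "per-individual ROC skipped: needs at least 2 specimens per "
            "group",
            stacklevel=2,
        )

    if config.cutoff_source == "reference":
        cutoffs = dict(REFERENCE_CUTOFFS)
    else:
        cutoffs = {
            p: optimal_cutoff(roc_px[p], criterion=config.cutoff_criterion)
            for p in PARAMETERS
        }

    if config.iqr_source == "reference":
        control_iqrs = dict(REFERENCE_CONTROL_IQRS)
    else:
        control = ~pixel_labels
        control_iqrs = {}
        for p in PARAMETERS:
            q1, q3 = np.percentile(pixel_scores[p][control], [25, 75])
            control_iqrs[p] = float(q3 - q1)

    return CohortAnalysis(
        config=config,
        records=records,
        correction_per_specimen=c_per_specimen,
        correction_mean=c_mean,
        summary_per_pixel=summary_px,
        summary_per_individual=summary_ind,
        pixel_scores=pixel_scores,
        pixel_labels=pixel_labels,
        roc_per_pixel=roc_px,
        roc_per_individual=roc_ind,
        delong=delong,
        cutoffs=cutoffs,
        control_iqrs=control_iqrs,
        n_undefined=int(sum(r.scatter.n_undefined for r in records)),
    )


def build_deviation_maps(
    analysis: CohortAnalysis, record: ProjectionRecord
) -> Dict[str, DeviationMap]:
    """The three parametric maps for one projection."""
    config = analysis.config
    maps = {}
    channel_maps = {
        "transmission": record.triplet.T_map,
        "dark_field": record.triplet.V_map,
        "normalized_scatter": record.scatter.S_map,
    }
    for p in PARAMETERS:
        mask = record.scatter.defined_mask if p == "normalized_scatter" \
            else record.seg_mask
        maps[p] = deviation_map(
            channel_maps[p],
            mask,
            cutoff=analysis.cutoffs[p],
            orientation=config.orientations[p],
            control_iqr=analysis.control_iqrs[p],
            parameter=p,
        )
    return maps


# ---------------------------------------------------------------------------
# report and disk stages


@dataclass
class RunReport:
    data: Dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(data=json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summary_records(summary: GroupSummary) -> List[Dict]:
    return json.loads(summary.table.to_json(orient="records"))


def _roc_block(curves: Dict[str, RocCurve], config: RunConfig) -> Dict:
    out = {}
    for p, c in curves.items():
        out[p] = {
            "auc": c.auc,
            "n_pos": c.n_pos,
            "n_neg": c.n_neg,
            "orientation": c.orientation,
            "sensitivity_at_specificity": {
                str(config.specificity_level): sensitivity_at_specificity(
                    c, config.specificity_level
                )
            },
        }
    return out


def report_from_analysis(analysis: CohortAnalysis) -> RunReport:
    config = analysis.config
    params = config.phantom
    data = {
        "config": config.to_dict(),
        "cohort": {
            "n_specimens": 2 * params.n_per_group,
            "n_projections": 2 * params.n_per_group * params.n_projections,
            "specimen_ids": list(params.specimen_ids()),
        },
        "correction": {
            "per_specimen": analysis.correction_per_specimen,
            "mean": analysis.correction_mean,
        },
        "group_summary": {
            "per_pixel": _summary_records(analysis.summary_per_pixel),
            "per_individual": _summary_records(analysis.summary_per_individual),
        },
        "mann_whitney_p": {
            "per_pixel": analysis.summary_per_pixel.p_values,
            "per_individual": analysis.summary_per_individual.p_values,
        },
        "pixel_independence_note": (
            "per-pixel Mann-Whitney and ROC treat segmented pixels as "
            "independent observations"
        ),
        "roc": {
            "per_pixel": _roc_block(analysis.roc_per_pixel, config),
            "per_individual": (
                _roc_block(analysis.roc_per_individual, config)
                if analysis.roc_per_individual is not None
                else None
            ),
        },
        "delong": {
            name: {
                "auc_a": r.auc_a,
                "auc_b": r.auc_b,
                "z": r.z,
                "p": r.p,
                "covariance": r.covariance.tolist(),
            }
            for name, r in analysis.delong.items()
        },
        "cutoffs": analysis.cutoffs,
        "control_iqrs": analysis.control_iqrs,
        "segmentation": {
            "thresholds": {
                f"{r.truth.specimen_id}_p{r.truth.projection_index:02d}":
                    r.seg_threshold
                for r in analysis.records
            },
            "method": config.segmentation_method,
        },
        "undefined_pixels": analysis.n_undefined,
        "manifest": {},
    }
    if analysis.roc_per_individual is not None:
        n = config.phantom.n_per_group
        data["roc"]["per_individual_granularity_note"] = (
            f"with {n} vs {n} specimens the per-individual AUC lives on a "
            f"grid of spacing 1/{n * n}"
        )
    return RunReport(data=data)


def _proj_stem(specimen_id: str, projection_index: int) -> str:
    return f"{specimen_id}_p{projection_index:02d}"


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    """Generate the cohort and write raw scans and truth maps."""
    run_dir = Path(run_dir)
    for truth, sample, reference in generate_cohort(config.phantom):
        stem = _proj_stem(truth.specimen_id, truth.projection_index)
        dio.write_stepscan(run_dir / "raw" / f"{stem}_sample.tif", sample)
        dio.write_stepscan(run_dir / "raw" / f"{stem}_reference.tif", reference)
        tdir = run_dir / "truth"
        dio.write_map(tdir / f"{stem}_u.tif", truth.u_map)
        dio.write_map(tdir / f"{stem}_s.tif", truth.s_map)
        dio.write_mask(tdir / f"{stem}_lung.tif", truth.lung_mask)
        dio.write_mask(tdir / f"{stem}_formalin.tif", truth.formalin_roi)
        dio.write_mask(tdir / f"{stem}_water.tif", truth.water_roi)
        dio.write_mask(tdir / f"{stem}_container.tif", truth.container_mask)
        meta = {
            "specimen_id": truth.specimen_id,
            "projection_index": truth.projection_index,
            "group_label": truth.group_label,
        }
        (tdir / f"{stem}_truth.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )
    logger.info("simulate: wrote raw scans under %s", run_dir / "raw")


def _load_truths(config: RunConfig, run_dir: Path) -> List[PhantomTruth]:
    params = config.phantom
    truths = []
    tdir = Path(run_dir) / "truth"
    for sid in params.specimen_ids():
        for pj in range(params.n_projections):
            stem = _proj_stem(sid, pj)
            meta = json.loads((tdir / f"{stem}_truth.json").read_text())
            truths.append(
                PhantomTruth(
                    u_map=dio.read_map(tdir / f"{stem}_u.tif"),
                    s_map=dio.read_map(tdir / f"{stem}_s.tif"),
                    lung_mask=dio.read_mask(tdir / f"{stem}_lung.tif"),
                    formalin_roi=dio.read_mask(tdir / f"{stem}_formalin.tif"),
                    water_roi=dio.read_mask(tdir / f"{stem}_water.tif"),
                    container_mask=dio.read_mask(
                        tdir / f"{stem}_container.tif"
                    ),
                    group_label=meta["group_label"],
                    specimen_id=meta["specimen_id"],
                    projection_index=meta["projection_index"],
                )
            )
    return truths


def stage_retrieve(config: RunConfig, run_dir: Path) -> None:
    """Fourier retrieval + water normalization for every projection."""
    run_dir = Path(run_dir)
    for truth in _load_truths(config, run_dir):
        stem = _proj_stem(truth.specimen_id, truth.projection_index)
        sample = dio.read_stepscan(run_dir / "raw" / f"{stem}_sample.tif")
        reference = dio.read_stepscan(
            run_dir / "raw" / f"{stem}_reference.tif"
        )
        triplet = retrieve_signals(
            sample, reference, validity_floor=config.validity_floor
        )
        triplet = normalize_to_water(triplet, truth.water_roi)
        rdir = run_dir / "retrieved"
        dio.write_map(rdir / f"{stem}_T.tif", triplet.T_map)
        dio.write_map(rdir / f"{stem}_V.tif", triplet.V_map)
        dio.write_map(rdir / f"{stem}_dphi.tif", triplet.dphi_map)
        dio.write_mask(rdir / f"{stem}_valid.tif", triplet.valid_mask)
    logger.info("retrieve: wrote maps under %s", run_dir / "retrieved")


def _load_records(config: RunConfig, run_dir: Path) -> List[ProjectionRecord]:
    records = []
    rdir = Path(run_dir) / "retrieved"
    for truth in _load_truths(config, run_dir):
        stem = _proj_stem(truth.specimen_id, truth.projection_index)
        triplet = ProjectionTriplet(
            T_map=dio.read_map(rdir / f"{stem}_T.tif"),
            dphi_map=dio.read_map(rdir / f"{stem}_dphi.tif"),
            V_map=dio.read_map(rdir / f"{stem}_V.tif"),
            valid_mask=dio.read_mask(rdir / f"{stem}_valid.tif"),
            metadata={
                "specimen_id": truth.specimen_id,
                "projection_index": truth.projection_index,
            },
        )
        records.append(ProjectionRecord(truth=truth, triplet=triplet))
    return records


def _write_analysis_outputs(
    analysis: CohortAnalysis, run_dir: Path
) -> None:
    run_dir = Path(run_dir)
    adir = run_dir / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    for rec in analysis.records:
        stem = _proj_stem(rec.truth.specimen_id, rec.truth.projection_index)
        dio.write_map(adir / f"{stem}_S.tif", rec.scatter.S_map)
        dio.write_mask(adir / f"{stem}_lungmask.tif", rec.seg_mask)
        dio.write_mask(adir / f"{stem}_defined.tif", rec.scatter.defined_mask)
    tables = []
    for level, summary in (
        ("per_pixel", analysis.summary_per_pixel),
        ("per_individual", analysis.summary_per_individual),
    ):
        t = summary.table.copy()
        t.insert(0, "level", level)
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(
        adir / "group_summary.csv", index=False
    )
    auc_rows = []
    for level, curves in (
        ("per_pixel", analysis.roc_per_pixel),
        ("per_individual", analysis.roc_per_individual or {}),
    ):
        for p, c in curves.items():
            auc_rows.append(
                dict(level=level, parameter=p, auc=c.auc,
                     n_pos=c.n_pos, n_neg=c.n_neg)
            )
    pd.DataFrame(auc_rows).to_csv(adir / "auc_table.csv", index=False)
    for p, c in analysis.roc_per_pixel.items():
        pd.DataFrame(
            {
                "threshold": c.thresholds,
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
            }
        ).to_csv(adir / f"roc_points_{p}.csv", index=False)


def stage_analyze(config: RunConfig, run_dir: Path) -> CohortAnalysis:
    """Segmentation, statistic, group summaries and ROC from disk."""
    records = _load_records(config, run_dir)
    analysis = analyze_cohort(config, records=records)
    _write_analysis_outputs(analysis, Path(run_dir))
    report = report_from_analysis(analysis)
    (Path(run_dir) / "analysis" / "analysis.json").write_text(
        report.to_json()
    )
    logger.info("analyze: wrote tables under %s", Path(run_dir) / "analysis")
    return analysis


def stage_map(
    config: RunConfig, run_dir: Path, analysis: Optional[CohortAnalysis] = None
) -> RunReport:
    """Parametric maps + overlays; assembles the final report."""
    run_dir = Path(run_dir)
    if analysis is None:
        records = _load_records(config, run_dir)
        analysis = analyze_cohort(config, records=records)
    params = config.phantom
    display = (
        config.display_projection
        if config.display_projection is not None
        else params.n_projections // 2
    )
    mdir = run_dir / "maps"
    map_provenance = {}
    for rec in analysis.records:
        if rec.truth.projection_index != display:
            continue
        stem = _proj_stem(rec.truth.specimen_id, rec.truth.projection_index)
        for p, dev in build_deviation_maps(analysis, rec).items():
            dio.write_map(mdir / f"{stem}_{p}_deviation.tif", dev.values)
            rgb = render_overlay(
                rec.triplet.T_map,
                dev,
                colormap_name=config.colormap,
                alpha_floor=config.alpha_floor,
            )
            dio.write_png(mdir / f"{stem}_{p}_overlay.png", rgb)
            map_provenance[f"{stem}_{p}"] = {
                "cutoff": dev.cutoff,
                "control_iqr": dev.control_iqr,
                "orientation": dev.orientation,
            }
    report = report_from_analysis(analysis)
    report.data["maps"] = map_provenance
    report.data["n_parametric_maps"] = len(map_provenance)
    manifest = {}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name != "report.json":
            manifest[str(f.relative_to(run_dir))] = _sha256(f)
    report.data["manifest"] = manifest
    (run_dir / "report.json").write_text(report.to_json())
    logger.info("map: wrote report %s", run_dir / "report.json")
    return report


def run_pipeline(config: RunConfig, run_dir: str | Path) -> RunReport:
    """Execute all stages in order against one artifact directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    stage_simulate(config, run_dir)
    stage_retrieve(config, run_dir)
    analysis = stage_analyze(config, run_dir)
    return stage_map(config, run_dir, analysis=analysis)
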