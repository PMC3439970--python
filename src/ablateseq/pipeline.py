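"""End-to-end orchestration: load → normalize → filter → scores → report.

:func:`analyze` performs the whole in-memory analysis; :func:`run_pipeline`
wraps it with file IO and a reproducible run manifest.  Stage order:

1. low-expression filter on control counts (defines the universe)
2. RPKM + replicate averaging
3. relative expression vs matched controls
4. downregulation calls and the progeny-peak filter
5. Venn accounting of the two downregulated sets (with overlap P)
6. ΔFC filter → final high-confidence list
7. insensitivity scores and per-condition density summaries
8. RNAi dynamics classes
9. term enrichment of the final list (when annotations are given)
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._utils import round_half_up, sha256_file
from .dynamics import classify_dynamics
from .enrichment import overlap_significance, term_enrichment
from .filters import VennSummary, compute_calls, venn
from .insensitivity import density_summary, insensitivity_scores
from .io import (
    AnnotationTable,
    CountMatrix,
    StudyDesign,
    load_annotations,
    load_dataset,
    write_results,
)
from .normalization import (
    FilterThresholds,
    RelativeProfiles,
    average_replicates,
    compute_rpkm,
    filter_low_expression,
    relative_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_pipeline", "summarize_run"]


@dataclass
class RunConfig:
    """Inputs, thresholds, and output location of one pipeline run."""

    counts_path: str | Path
    design_path: str | Path
    out_dir: str | Path
    library_sizes_path: str | Path | None = None
    annotations_path: str | Path | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    adjust: str = "none"
    dynamics_slack: float = 0.02
    write_intermediates: bool = True


@dataclass
class AnalysisResult:
    """All tables produced by one analysis."""

    universe: pd.Index
    profiles: RelativeProfiles
    calls: pd.DataFrame
    venn: VennSummary
    final_ids: set[str]
    scores: pd.DataFrame
    dynamics: pd.Series
    densities: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame | None
    manifest: dict


def _stage(name: str):
    logger.info("stage: %s", name)


def analyze(
    cm: CountMatrix,
    design: StudyDesign,
    thresholds: FilterThresholds = FilterThresholds(),
    annotations: AnnotationTable | None = None,
    adjust: str = "none",
    dynamics_slack: float = 0.02,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    _stage("low-expression filter")
    universe = filter_low_expression(cm, design, thresholds)
    if len(universe) == 0:
        raise ValueError("low-expression filter removed every transcript")
    sub = cm.subset(universe)

    _stage("normalization")
    rpkm = compute_rpkm(sub)
    cond = average_replicates(rpkm, design)
    profiles = relative_expression(cond, design)

    _stage("downregulation calls")
    calls = compute_calls(profiles, thresholds)
    summary = venn(calls)
    overlap_ids = calls.index[calls["irr_down"] & calls["rnai_down"]]
    overlap_p = overlap_significance(
        set(calls.index[calls["irr_down"]]),
        set(calls.index[calls["rnai_down"]]),
        set(calls.index),
    )
    final_ids = set(calls.index[calls["final"]])

    _stage("insensitivity scores")
    scores = insensitivity_scores(profiles)

    _stage("dynamics classification")
    dyn = classify_dynamics(profiles, thresholds, slack=dynamics_slack)

    _stage("density summaries")
    densities = {}
    for arm, prof in profiles.arms.items():
        for day in prof.columns:
            densities[f"density_{arm}_d{day:g}"] = density_summary(profiles, arm, day)

    enr = None
    if annotations is not None:
        _stage("term enrichment")
        ann_u = annotations.restrict(universe)
        if final_ids:
            enr = term_enrichment(final_ids, ann_u, set(universe), adjust=adjust)
        else:
            logger.warning("final list empty; skipping enrichment")

    n_removed = len(overlap_ids) - len(final_ids)
    manifest = {
        "ablateseq_version": __version__,
        "thresholds": {
            "min_reads": thresholds.min_reads,
            "theta_down": thresholds.theta_down,
            "theta_peak": thresholds.theta_peak,
            "theta_dfc": thresholds.theta_dfc,
            "dynamics_slack": dynamics_slack,
        },
        "stage_counts": {
            "n_input_transcripts": int(len(cm.transcript_ids)),
            "n_universe": int(len(universe)),
            "n_irr_down": summary.n_irr_down,
            "n_rnai_down": summary.n_rnai_down,
            "n_overlap": summary.n_overlap,
            "n_dfc_removed": int(n_removed),
            "n_final": int(len(final_ids)),
        },
        "venn_pct": {
            "pct_irr_of_universe": summary.pct_irr_of_universe,
            "pct_overlap_of_rnai": summary.pct_overlap_of_rnai,
            "pct_overlap_of_universe": summary.pct_overlap_of_universe,
            "pct_irr_only_of_universe": summary.pct_irr_only_of_universe,
            "pct_irr_only_of_irr": summary.pct_irr_only_of_irr,
        },
        "overlap_log10_p": float(overlap_p.log10_p),
    }
    if enr is not None and len(enr):
        manifest["top_terms"] = [
            {"term_id": str(t.term_id), "p_raw": float(t.p_raw)}
            for t in enr.head(5).itertuples()
        ]
    return AnalysisResult(
        universe=universe,
        profiles=profiles,
        calls=calls,
        venn=summary,
        final_ids=final_ids,
        scores=scores,
        dynamics=dyn,
        densities=densities,
        enrichment=enr,
        manifest=manifest,
    )


def run_pipeline(config: RunConfig) -> tuple[AnalysisResult, dict[str, Path]]:
    """Load inputs, analyze, and persist result tables plus a run manifest."""
    cm, design = load_dataset(
        config.counts_path, config.design_path, config.library_sizes_path
    )
    annotations = None
    if config.annotations_path is not None:
        annotations = load_annotations(config.annotations_path, cm.transcript_ids)
    result = analyze(
        cm,
        design,
        thresholds=config.thresholds,
        annotations=annotations,
        adjust=config.adjust,
        dynamics_slack=config.dynamics_slack,
    )
    result.manifest["inputs"] = {
        str(Path(p).name): sha256_file(p)
        for p in [
            config.counts_path,
            config.design_path,
            config.library_sizes_path,
            config.annotations_path,
        ]
        if p is not None
    }

    final_table = result.scores.loc[sorted(result.final_ids)].round(6)
    tables: dict[str, pd.DataFrame] = {
        "final_list": final_table,
        "venn": result.venn.to_frame(),
        "calls": result.calls,
        "is_scores": result.scores.round(6),
        "dynamics": result.dynamics.to_frame(),
    }
    if config.write_intermediates:
        for arm, prof in result.profiles.arms.items():
            t = prof.copy().round(6)
            t.columns = [f"{arm}_d{d:g}" for d in t.columns]
            t.index.name = "transcript_id"
            tables[f"relative_expression_{arm}"] = t
        tables.update(result.densities)
    if result.enrichment is not None:
        tables["enrichment"] = result.enrichment
    paths = write_results(tables, config.out_dir, manifest=result.manifest)
    logger.info("wrote %d tables to %s", len(paths), config.out_dir)
    return result, paths


def summarize_run(manifest: dict) -> str:
    """Human-readable report of a completed run's manifest."""
    for key in ("stage_counts", "venn_pct", "thresholds"):
        if key not in manifest:
            raise ValueError(f"manifest is missing {key!r}")
    sc = manifest["stage_counts"]
    vp = manifest["venn_pct"]
    lines = [
        "ablation transcript-selection run",
        f"  universe (low-expression filtered): {sc['n_universe']}",
        f"  downregulated by irradiation:       {sc['n_irr_down']}"
        f" ({vp['pct_irr_of_universe']}% of universe)",
        f"  downregulated by RNAi:              {sc['n_rnai_down']}",
        f"  overlap:                            {sc['n_overlap']}"
        f" ({vp['pct_overlap_of_rnai']}% of RNAi-down,"
        f" {vp['pct_overlap_of_universe']}% of universe)",
        f"  irradiation-only:                   {sc['n_irr_down'] - sc['n_overlap']}"
        f" ({vp['pct_irr_only_of_universe']}% of universe,"
        f" {vp['pct_irr_only_of_irr']}% of irradiation-down)",
        f"  removed by the dFC filter:          {sc['n_dfc_removed']}",
        f"  final high-confidence list:         {sc['n_final']}",
    ]
    if "top_terms" in manifest and manifest["top_terms"]:
        lines.append("  top enriched terms:")
        for t in manifest["top_terms"]:
            lines.append(f"    {t['term_id']}: P = {t['p_raw']:.3g}")
    return "\n".join(lines)
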