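"""Synthetic compartment-ablation transcriptome generator.

Each transcript's expression is a mixture over cellular compartments
(stem cells, early and late stem-cell progeny, central nervous system,
other differentiated tissue).  A treatment arm ablates compartments
along a per-day abundance trajectory expressed as a multiplier of the
control abundance (control = 1):

* irradiation kills every stem cell within the first two days, and its
  progeny drain soon after;
* RNAi ablation is slower and specific — stem cells fall to a 10%
  day-5 residual while progeny first overshoot (the doomed stem cells
  differentiate) before declining;
* CNS and differentiated tissue are untouched by either treatment.

An optional *stress artifact* emulates the transcriptome-wide side
effect of whole-organism irradiation: a per-transcript multiplicative
factor ``severity`` in (0, 1) applied to the non-stem part of expression
in irradiated samples only, which drags irradiation insensitivity below
RNAi insensitivity for transcripts shared with unablated compartments.

Expected RPKM of transcript g in condition c is

    baseline_g * sum_comp weight[g, comp] * trajectory(comp, c) * artifact_g(c)

and counts are drawn around the implied expected count (negative
binomial by default, Poisson, or noise off = rounded expectation).  All
randomness flows from the single configured seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AnnotationTable, CountMatrix, StudyDesign, write_dataset
from .normalization import FilterThresholds

__all__ = [
    "COMPARTMENTS",
    "TRUTH_CLASSES",
    "CompartmentModel",
    "SimulationConfig",
    "build_truth",
    "simulate_counts",
    "emit_annotations",
    "simulate_dataset",
    "expected_relative_expression",
    "expected_final_set",
    "write_simulation",
]

COMPARTMENTS = ("stem", "early_progeny", "late_progeny", "cns", "differentiated")
TRUTH_CLASSES = ("pure_stem", "cns_shared", "progeny", "artifact", "unaffected")

# Default per-compartment abundance trajectories (multiplier vs control).
# Stem: eliminated by irradiation within 48 h; RNAi ablation leaves a ~10%
# day-5 residual.  Early progeny: transient ~130% overshoot at RNAi day 1
# then decline to ~20%; late progeny overshoot less and only fall to ~50%.
# Progeny drain after irradiation with a short lag.  CNS and differentiated
# tissue are unaffected by both treatments.
DEFAULT_TRAJECTORIES: dict[str, dict[str, dict[float, float]]] = {
    "stem": {
        "irradiation": {2: 0.0, 4: 0.0, 7: 0.0},
        "rnai": {1: 1.0, 2: 0.5, 5: 0.1},
    },
    "early_progeny": {
        "irradiation": {2: 0.5, 4: 0.1, 7: 0.0},
        "rnai": {1: 1.3, 2: 0.6, 5: 0.2},
    },
    "late_progeny": {
        "irradiation": {2: 0.8, 4: 0.4, 7: 0.1},
        "rnai": {1: 1.2, 2: 0.8, 5: 0.5},
    },
    "cns": {
        "irradiation": {2: 1.0, 4: 1.0, 7: 1.0},
        "rnai": {1: 1.0, 2: 1.0, 5: 1.0},
    },
    "differentiated": {
        "irradiation": {2: 1.0, 4: 1.0, 7: 1.0},
        "rnai": {1: 1.0, 2: 1.0, 5: 1.0},
    },
}


@dataclass(frozen=True)
class CompartmentModel:
    """Per-compartment, per-arm, per-day abundance multipliers."""

    trajectories: Mapping[str, Mapping[str, Mapping[float, float]]] = field(
        default_factory=lambda: DEFAULT_TRAJECTORIES
    )

    def __post_init__(self):
        for comp, arms in self.trajectories.items():
            for arm, days in arms.items():
                for day, mult in days.items():
                    if mult < 0:
                        raise ValueError(
                            f"negative multiplier for {comp}/{arm}/day {day}"
                        )

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.trajectories)

    def days(self, arm: str) -> list[float]:
        any_comp = next(iter(self.trajectories.values()))
        return sorted(float(d) for d in any_comp[arm])

    def multiplier(self, compartment: str, arm: str, day: float) -> float:
        """Abundance multiplier; the control condition is identically 1."""
        table = self.trajectories[compartment][arm]
        for d, mult in table.items():
            if float(d) == float(day):
                return float(mult)
        raise KeyError(f"no trajectory for {compartment}/{arm}/day {day}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Class sizes emulate the real design's proportions at reduced scale:
    irradiation artifacts plus unaffected transcripts dominate the
    universe while genuinely stem-cell-expressed transcripts are a
    small minority.  Libraries default to duplicates of 10^7 mapped
    reads; count noise is negative binomial with a shared dispersion
    alpha (var = mu + alpha * mu^2).
    """

    n_pure_stem: int = 150
    n_cns_shared: int = 100
    n_progeny: int = 120
    n_artifact: int = 400
    n_unaffected: int = 600
    cns_weight_range: tuple[float, float] = (0.3, 0.7)
    artifact_severity_range: tuple[float, float] = (0.3, 0.7)
    artifact_on_shared: bool = True
    baseline_log_mean: float = 3.0   # natural-log scale; median ~20 RPKM
    baseline_log_sd: float = 1.0
    length_log_mean: float = 7.3     # median ~1480 nt
    length_log_sd: float = 0.45
    noise: str = "nb"                # "nb", "poisson", or "off"
    dispersion: float = 0.1
    n_replicates: int = 2
    library_size: int = 10_000_000
    stem_term_fraction: float = 0.9
    annotation_background_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("nb", "poisson", "off"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "nb" and self.dispersion <= 0:
            raise ValueError("nb noise needs a positive dispersion")
        if self.n_replicates < 1 or self.library_size < 1:
            raise ValueError("need at least one replicate and a positive library size")
        lo, hi = self.cns_weight_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("cns_weight_range must be within [0, 1]")
        lo, hi = self.artifact_severity_range
        if not 0 < lo <= hi < 1:
            raise ValueError("artifact_severity_range must be within (0, 1)")

    @property
    def class_sizes(self) -> dict[str, int]:
        return {
            "pure_stem": self.n_pure_stem,
            "cns_shared": self.n_cns_shared,
            "progeny": self.n_progeny,
            "artifact": self.n_artifact,
            "unaffected": self.n_unaffected,
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(16)[stream])


def build_truth(
    config: SimulationConfig, model: CompartmentModel | None = None
) -> pd.DataFrame:
    """Ground-truth table: class, mixture weights, artifact flag, baseline, length.

    Deterministic given the config seed.  Progeny transcripts alternate
    between the early and late progeny compartments; unaffected
    transcripts alternate between CNS and other differentiated tissue.
    """
    sizes = config.class_sizes
    if sum(sizes.values()) == 0:
        raise ValueError("all class counts are zero")
    rng = _rng(config, 0)
    rows = []
    i = 0
    for cls in TRUTH_CLASSES:
        for j in range(sizes[cls]):
            weights = dict.fromkeys(COMPARTMENTS, 0.0)
            artifact = False
            severity = np.nan
            if cls == "pure_stem":
                weights["stem"] = 1.0
            elif cls == "cns_shared":
                w = rng.uniform(*config.cns_weight_range)
                weights["cns"] = w
                weights["stem"] = 1.0 - w
                if config.artifact_on_shared:
                    artifact = True
                    severity = rng.uniform(*config.artifact_severity_range)
            elif cls == "progeny":
                weights["early_progeny" if j % 2 == 0 else "late_progeny"] = 1.0
            elif cls == "artifact":
                weights["differentiated"] = 1.0
                artifact = True
                severity = rng.uniform(*config.artifact_severity_range)
            else:  # unaffected
                weights["cns" if j % 2 == 0 else "differentiated"] = 1.0
            rows.append(
                {
                    "transcript_id": f"T{i:05d}",
                    "truth_class": cls,
                    **{f"w_{c}": weights[c] for c in COMPARTMENTS},
                    "stress_artifact": artifact,
                    "artifact_severity": severity,
                }
            )
            i += 1
    truth = pd.DataFrame(rows).set_index("transcript_id")
    n = len(truth)
    truth["baseline_rpkm"] = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )
    truth["length_nt"] = (
        np.exp(rng.normal(config.length_log_mean, config.length_log_sd, size=n))
        .round()
        .clip(200, 20000)
        .astype(int)
    )
    return truth


def _artifact_factor(truth: pd.DataFrame) -> np.ndarray:
    return np.where(
        truth["stress_artifact"].to_numpy(),
        truth["artifact_severity"].fillna(1.0).to_numpy(),
        1.0,
    )


def expected_relative_expression(
    truth: pd.DataFrame, model: CompartmentModel | None = None
) -> dict[str, pd.DataFrame]:
    """Closed-form relative expression per arm and day from the truth table.

    r(g, arm, day) = sum_comp w[g, comp] * trajectory(comp, arm, day) *
    artifact_g(arm), with the artifact factor applied to non-stem
    compartments in the irradiation arm only.  Independent of baseline
    expression and library composition, so it serves as an oracle for
    the count-level pipeline.
    """
    model = model or CompartmentModel()
    out = {}
    af = _artifact_factor(truth)
    for arm in ("irradiation", "rnai"):
        days = model.days(arm)
        cols = {}
        for day in days:
            r = np.zeros(len(truth))
            for comp in model.compartments:
                w = truth[f"w_{comp}"].to_numpy()
                mult = model.multiplier(comp, arm, day)
                factor = af if (arm == "irradiation" and comp != "stem") else 1.0
                r = r + w * mult * factor
            cols[day] = r
        prof = pd.DataFrame(cols, index=truth.index)
        prof.columns.name = "day"
        out[arm] = prof
    return out


def expected_final_set(
    truth: pd.DataFrame,
    model: CompartmentModel | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    universe: pd.Index | None = None,
) -> set[str]:
    """Truth-derived expectation of the high-confidence list.

    Applies the selection rules to the closed-form mixture relative
    expressions (no counts, normalization, or averaging involved), so a
    noise-free pipeline run must recover exactly this set.  Pass the
    pipeline's retained ``universe`` to account for transcripts dropped
    by the low-expression filter.
    """
    profiles = expected_relative_expression(truth, model)
    irr, rnai = profiles["irradiation"], profiles["rnai"]
    irr_down = (irr <= thresholds.theta_down).all(axis=1)
    peaked = (rnai > thresholds.theta_peak).any(axis=1)
    final_day = sorted(rnai.columns)[-1]
    rnai_down = (rnai[final_day] <= thresholds.theta_down) & ~peaked
    d_irr = irr.sort_index(axis=1).diff(axis=1).iloc[:, 1:]
    d_rnai = rnai.sort_index(axis=1).diff(axis=1).iloc[:, 1:]
    dfc_ok = (d_irr.abs() <= thresholds.theta_dfc).all(axis=1) & (
        d_rnai <= thresholds.theta_dfc
    ).all(axis=1)
    keep = irr_down & rnai_down & dfc_ok
    ids = set(truth.index[keep])
    if universe is not None:
        ids &= set(universe)
    return ids


def _design(config: SimulationConfig, model: CompartmentModel) -> StudyDesign:
    rows = []
    for arm, tag in (("irradiation", "irr"), ("rnai", "rnai")):
        days = model.days(arm)
        ctrl_day = 0.0 if arm == "irradiation" else max(days)
        for rep in range(1, config.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{tag}_ctrl_r{rep}",
                    "arm": arm,
                    "condition": "control",
                    "day": ctrl_day,
                    "replicate": rep,
                }
            )
        for day in days:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tag}_d{day:g}_r{rep}",
                        "arm": arm,
                        "condition": "treated",
                        "day": day,
                        "replicate": rep,
                    }
                )
    return StudyDesign(pd.DataFrame(rows))


def simulate_counts(
    truth: pd.DataFrame,
    model: CompartmentModel | None = None,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[CountMatrix, StudyDesign]:
    """Draw a count matrix and its design around the truth table's expectations.

    Expected counts follow from expected RPKM, transcript length, and
    library size; the configured noise model supplies the draw
    (``"off"`` rounds the expectation to the nearest integer).
    """
    model = model or CompartmentModel()
    design = _design(config, model)
    rng = _rng(config, 1)
    rel = expected_relative_expression(truth, model)
    baseline = truth["baseline_rpkm"].to_numpy()
    lengths = truth["length_nt"].to_numpy()
    scale = lengths * config.library_size / 1e9  # RPKM -> expected count

    cols = {}
    for arm, condition, day, samples in design.groups():
        if condition == "control":
            exp_rpkm = baseline
        else:
            exp_rpkm = baseline * rel[arm][day].to_numpy()
        mu = exp_rpkm * scale
        for s in samples:
            if config.noise == "off":
                draw = np.rint(mu)
            elif config.noise == "poisson":
                draw = rng.poisson(mu)
            else:
                size = 1.0 / config.dispersion
                draw = np.where(
                    mu > 0,
                    rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12))),
                    0,
                )
            cols[s] = draw.astype(np.int64)
    counts = pd.DataFrame(cols, index=truth.index)
    counts = counts.loc[:, design.sample_ids]
    library_sizes = pd.Series(
        np.maximum(config.library_size, counts.sum(axis=0)),
        index=counts.columns,
        name="library_size",
    )
    cm = CountMatrix(
        counts=counts,
        lengths_nt=truth["length_nt"].copy(),
        library_sizes=library_sizes,
    )
    return cm, design


def emit_annotations(
    truth: pd.DataFrame, config: SimulationConfig = SimulationConfig()
) -> AnnotationTable:
    """Annotation table with a known positive-control term.

    ``stem_term`` annotates ``stem_term_fraction`` of pure-stem
    transcripts plus a background rate elsewhere, so term enrichment on
    the recovered list has a predictable strong hit; ``broad_term``
    annotates a uniform random tenth of the universe as a null term.
    """
    rng = _rng(config, 2)
    mapping: dict[str, set[str]] = {}
    is_stem = truth["truth_class"] == "pure_stem"
    for tid, stem in zip(truth.index, is_stem):
        rate = config.stem_term_fraction if stem else config.annotation_background_rate
        if rng.random() < rate:
            mapping.setdefault(tid, set()).add("stem_term")
        if rng.random() < 0.1:
            mapping.setdefault(tid, set()).add("broad_term")
    return AnnotationTable(mapping=mapping, universe=set(truth.index))


def simulate_dataset(
    config: SimulationConfig = SimulationConfig(),
    model: CompartmentModel | None = None,
) -> tuple[CountMatrix, StudyDesign, AnnotationTable, pd.DataFrame]:
    """Convenience wrapper: truth, counts, design, and annotations in one call."""
    model = model or CompartmentModel()
    truth = build_truth(config, model)
    cm, design = simulate_counts(truth, model, config)
    ann = emit_annotations(truth, config)
    return cm, design, ann, truth


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig = SimulationConfig(),
    model: CompartmentModel | None = None,
) -> dict[str, Path]:
    """Write the synthetic dataset in the pipeline's input formats plus truth.tsv."""
    out_dir = Path(out_dir)
    cm, design, ann, truth = simulate_dataset(config, model)
    paths = write_dataset(cm, design, out_dir)
    truth_path = out_dir / "truth.tsv"
    truth.sort_index().to_csv(truth_path, sep="\t", lineterminator="\n")
    ann_path = out_dir / "annotations.tsv"
    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write("transcript_id\tterm_id\n")
        for tid in sorted(ann.mapping):
            for term in sorted(ann.mapping[tid]):
                fh.write(f"{tid}\t{term}\n")
    paths["truth"] = truth_path
    paths["annotations"] = ann_path
    return paths
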