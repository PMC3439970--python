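"""RPKM normalization, the low-expression filter, and relative-expression profiles.

The pipeline's expression unit is RPKM (reads per kilobase of transcript
per million mapped reads):

    rpkm[g, s] = counts[g, s] * 1e9 / (library_size[s] * length_nt[g])

Downstream calls operate on *relative expression* r: the ratio of a
treated condition's replicate-averaged RPKM to the matched control's.
Transcripts expressed at fewer than ``min_reads`` summed control reads in
either arm are excluded up front, which guarantees nonzero denominators
for every retained transcript, so r needs no pseudocount: zero treated
counts yield r = 0 exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ARMS, CountMatrix, StudyDesign

__all__ = [
    "FilterThresholds",
    "RelativeProfiles",
    "compute_rpkm",
    "filter_low_expression",
    "average_replicates",
    "relative_expression",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the transcript-selection pipeline.

    min_reads
        minimum summed control read count per arm for a transcript to
        enter the analysis universe (default 10; "fewer than 10 mapped
        reads" is filtered, so exactly 10 is retained).
    theta_down
        a transcript counts as downregulated when its relative
        expression is at or below this fraction of control (default
        0.75, i.e. reduced to 75% or less; boundary inclusive).
    theta_peak
        relative expression strictly above this fraction at any RNAi
        time point marks a progeny-like peak (default 1.10).
    theta_dfc
        bound on consecutive-time-point changes in relative expression
        (default 0.2, i.e. 20 percentage points of control expression);
        exceeded strictly.
    """

    min_reads: int = 10
    theta_down: float = 0.75
    theta_peak: float = 1.10
    theta_dfc: float = 0.2

    def __post_init__(self):
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")
        if not 0 < self.theta_down <= 1:
            raise ValueError("theta_down must be in (0, 1]")
        if self.theta_peak <= 1:
            raise ValueError("theta_peak must exceed 1")
        if self.theta_dfc <= 0:
            raise ValueError("theta_dfc must be positive")


@dataclass
class RelativeProfiles:
    """Per-arm relative-expression time courses.

    ``arms`` maps an arm name to a transcripts-by-days DataFrame of r
    values (columns are the arm's treated days, ascending).
    ``control_rpkm`` holds the replicate-averaged control RPKM each
    profile was divided by, one column per arm.
    """

    arms: dict[str, pd.DataFrame]
    control_rpkm: pd.DataFrame

    @property
    def irradiation(self) -> pd.DataFrame:
        return self.arms["irradiation"]

    @property
    def rnai(self) -> pd.DataFrame:
        return self.arms["rnai"]

    @property
    def universe(self) -> pd.Index:
        return next(iter(self.arms.values())).index

    def arm(self, name: str) -> pd.DataFrame:
        if name not in self.arms:
            raise KeyError(f"no profile for arm {name!r}")
        return self.arms[name]


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """RPKM per transcript per sample."""
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    lengths = cm.lengths_nt.to_numpy(dtype=float)
    vals = cm.counts.to_numpy(dtype=float) * 1e9 / (lib[None, :] * lengths[:, None])
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def filter_low_expression(
    cm: CountMatrix,
    design: StudyDesign,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.Index:
    """Transcripts with at least ``min_reads`` summed control reads in each arm.

    Both arms' controls must pass because the downstream ratios need a
    nonzero denominator in both arms.  The retained set is the analysis
    universe.
    """
    keep = pd.Series(True, index=cm.transcript_ids)
    for arm in ARMS:
        ctrl = design.control_samples(arm)
        if not ctrl:
            raise ValueError(f"no control samples for arm {arm!r}")
        keep &= cm.counts[ctrl].sum(axis=1) >= thresholds.min_reads
    return cm.transcript_ids[keep]


def average_replicates(rpkm: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Arithmetic mean of replicate RPKM per (arm, condition, day) group.

    Averaging happens on the RPKM scale, not the count scale, because
    replicate libraries differ in size.
    """
    cols: dict[tuple, pd.Series] = {}
    for arm, condition, day, samples in design.groups():
        missing = [s for s in samples if s not in rpkm.columns]
        if missing:
            raise ValueError(f"samples {missing} absent from expression matrix")
        cols[(arm, condition, day)] = rpkm[samples].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["arm", "condition", "day"])
    return out


def relative_expression(
    condition_rpkm: pd.DataFrame, design: StudyDesign
) -> RelativeProfiles:
    """Relative expression r = treated RPKM / control RPKM, per arm and day.

    Values are unclipped: r > 1 is preserved for peak detection.  A zero
    control RPKM for any transcript is a hard error — apply
    :func:`filter_low_expression` first.
    """
    arms: dict[str, pd.DataFrame] = {}
    ctrl_cols: dict[str, pd.Series] = {}
    for arm in ARMS:
        ctrl_day = design.control_day(arm)
        ctrl = condition_rpkm[(arm, "control", ctrl_day)]
        if (ctrl == 0).any():
            bad = list(ctrl.index[ctrl == 0])[:5]
            raise ValueError(
                f"zero control RPKM in arm {arm!r} for retained transcript(s) {bad}; "
                "the low-expression filter must run first"
            )
        days = design.treated_days(arm)
        prof = pd.DataFrame(
            {day: condition_rpkm[(arm, "treated", day)] / ctrl for day in days}
        )
        prof.columns.name = "day"
        arms[arm] = prof
        ctrl_cols[arm] = ctrl
    return RelativeProfiles(arms=arms, control_rpkm=pd.DataFrame(ctrl_cols))
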