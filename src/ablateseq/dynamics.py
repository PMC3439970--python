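"""Classification of RNAi time-course behaviors.

After genetic ablation of the stem-cell compartment, transcript classes
separate by their RNAi time-course shape: stem-cell transcripts fall
progressively, progeny transcripts first overshoot (the doomed stem
cells differentiate into a transient surplus of progeny) and then fall,
and transcripts expressed only in differentiated tissue stay flat.
The classifier encodes these shapes with the same thresholds that drive
the selection filters:

progressive_down
    non-increasing within a slack ``eps`` (sampling noise makes strict
    decrease too brittle), never strictly above ``theta_peak``, final
    point at or below ``theta_down``.
peak_then_down
    some point strictly above ``theta_peak`` and a final point below
    the peak value.
unchanged
    every point within ``[theta_down, theta_peak]``.
other
    anything else.

Labels are assigned in that order, making them mutually exclusive and
exhaustive (a boundary profile such as (1.0, 0.8, 0.75) meets both the
progressive_down and unchanged definitions and takes the first).
"""
from __future__ import annotations

from typing import Mapping, Set

import numpy as np
import pandas as pd

from .normalization import FilterThresholds, RelativeProfiles

__all__ = ["LABELS", "classify_dynamics", "class_counts"]

LABELS = ("progressive_down", "peak_then_down", "unchanged", "other")


def classify_dynamics(
    profiles: RelativeProfiles,
    thresholds: FilterThresholds = FilterThresholds(),
    slack: float = 0.02,
) -> pd.Series:
    """Label each transcript's RNAi profile with one behavior class."""
    if slack < 0:
        raise ValueError("slack must be non-negative")
    prof = profiles.rnai.sort_index(axis=1)
    if prof.isna().any().any():
        raise ValueError("rnai profile has missing time points")
    r = prof.to_numpy()
    final = r[:, -1]
    nonincreasing = (np.diff(r, axis=1) <= slack).all(axis=1)
    peaked = (r > thresholds.theta_peak).any(axis=1)
    peak_val = np.where(peaked, np.max(np.where(r > thresholds.theta_peak, r, -np.inf), axis=1), np.nan)

    progressive = nonincreasing & ~peaked & (final <= thresholds.theta_down)
    peak_then_down = peaked & (final < peak_val)
    unchanged = ((r >= thresholds.theta_down) & (r <= thresholds.theta_peak)).all(axis=1)

    labels = np.full(len(prof), "other", dtype=object)
    labels[unchanged] = "unchanged"
    labels[peak_then_down] = "peak_then_down"
    labels[progressive] = "progressive_down"
    return pd.Series(labels, index=prof.index, name="dynamics_class")


def class_counts(
    classes: pd.Series, reference_sets: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """Contingency table: one row per reference set, one column per label."""
    rows = {}
    known = set(classes.index)
    for name, ids in reference_sets.items():
        unknown = set(ids) - known
        if unknown:
            raise ValueError(
                f"reference set {name!r} contains unknown id(s): {sorted(unknown)[:5]}"
            )
        sub = classes.loc[sorted(ids)]
        rows[name] = {label: int((sub == label).sum()) for label in LABELS}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(LABELS))
    out.index.name = "reference_set"
    return out
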