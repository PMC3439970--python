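"""Ablation-insensitivity scores and relative-expression density summaries.

The insensitivity (IS) of a transcript approximates the fraction of its
expression that survives stem-cell ablation, i.e. the fraction located
outside the stem-cell compartment:

* irradiation IS — the unweighted mean of the relative expressions at
  the three irradiation time points (the residual is stable across
  them);
* RNAi IS — the relative expression at the final RNAi time point (day
  5), by which the stem-cell compartment is depleted.

RNAi IS is the preferred proxy: whole-organism irradiation also
depresses expression in cells it does not ablate, dragging irradiation
IS below the true non-ablated fraction.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalization import RelativeProfiles

__all__ = [
    "insensitivity_scores",
    "set_median_is",
    "density_summary",
    "DEFAULT_DENSITY_EDGES",
]

#: Bin edges on the percent-of-control scale: [0,10), ..., [140,150), [150, inf)
DEFAULT_DENSITY_EDGES: tuple[float, ...] = tuple(float(x) for x in range(0, 151, 10))


def insensitivity_scores(profiles: RelativeProfiles) -> pd.DataFrame:
    """Per-transcript ``irr_is`` and ``rnai_is`` columns.

    Values are reported unclipped (tables render them at 2 decimals).
    """
    for arm in ("irradiation", "rnai"):
        if arm not in profiles.arms:
            raise ValueError(f"profiles are missing arm {arm!r}")
    irr = profiles.irradiation.sort_index(axis=1)
    rnai = profiles.rnai.sort_index(axis=1)
    scores = pd.DataFrame(
        {"irr_is": irr.mean(axis=1), "rnai_is": rnai[rnai.columns[-1]]}
    )
    scores.index.name = "transcript_id"
    return scores


def set_median_is(scores: pd.DataFrame, ids: Iterable[str]) -> float:
    """Median RNAi IS over a transcript set (mean of the middle pair for even n)."""
    ids = pd.Index(sorted(set(ids)))
    if len(ids) == 0:
        raise ValueError("empty transcript set")
    missing = ids.difference(scores.index)
    if len(missing):
        raise ValueError(f"ids without scores: {list(missing)[:5]}")
    return float(scores.loc[ids, "rnai_is"].median())


def density_summary(
    profiles: RelativeProfiles,
    arm: str,
    day: float,
    edges: Sequence[float] = DEFAULT_DENSITY_EDGES,
) -> pd.DataFrame:
    """Proportion of the universe per bin of relative expression (percent scale).

    Bins are half-open ``[lo, hi)`` over ``100 * r``; the final listed
    edge opens an unbounded top bin closed at +inf, so proportions
    always sum to 1.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    prof = profiles.arm(arm)
    if day not in prof.columns:
        raise ValueError(f"arm {arm!r} has no day {day!r}")
    pct = 100.0 * prof[day].to_numpy()
    full = np.asarray(edges + [np.inf])
    counts, _ = np.histogram(pct, bins=full)
    out = pd.DataFrame(
        {
            "bin_lo": full[:-1],
            "bin_hi": full[1:],
            "proportion": counts / counts.sum(),
        }
    )
    return out
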