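"""Downregulation calls, the progeny-peak filter, Venn accounting, and the
consecutive-time-point (ΔFC) filter.

The selection logic triangulates two ablation methods:

* irradiation downregulation — relative expression at or below
  ``theta_down`` at *every* irradiation time point;
* RNAi downregulation — relative expression at or below ``theta_down``
  at the final RNAi time point, *and* never strictly above
  ``theta_peak`` at any RNAi time point (transcripts expressed in
  stem-cell progeny transiently rise as the stem cells differentiate,
  so a peak disqualifies);
* ΔFC filter — transcripts in the overlap whose relative expression
  jumps between consecutive time points (absolute changes above
  ``theta_dfc`` in the irradiation arm, or increases above
  ``theta_dfc`` in the RNAi arm) are discarded from the final list.
  Removal by either arm's criterion removes the transcript outright.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._utils import round_half_up
from .normalization import FilterThresholds, RelativeProfiles

__all__ = [
    "call_irradiation_down",
    "call_rnai_down",
    "compute_calls",
    "VennSummary",
    "venn",
    "delta_fc",
    "dfc_filter",
]


def _require_profile(profile: pd.DataFrame, arm: str) -> pd.DataFrame:
    if profile.shape[1] < 1:
        raise ValueError(f"{arm} profile has no time points")
    if profile.isna().any().any():
        raise ValueError(f"{arm} profile has missing time points")
    return profile.sort_index(axis=1)


def call_irradiation_down(
    profiles: RelativeProfiles, thresholds: FilterThresholds = FilterThresholds()
) -> pd.Series:
    """True where r <= theta_down at every irradiation time point (boundary inclusive)."""
    prof = _require_profile(profiles.irradiation, "irradiation")
    return (prof <= thresholds.theta_down).all(axis=1).rename("irr_down")


def call_rnai_down(
    profiles: RelativeProfiles, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[pd.Series, pd.Series]:
    """RNAi downregulation call plus the progeny-peak exclusion flag.

    Returns ``(rnai_down, peaked)``: ``peaked`` is true where any RNAi
    time point is strictly above ``theta_peak``; ``rnai_down`` requires
    the final time point at or below ``theta_down`` and no peak.  Only
    the final day enters the downregulation condition — intermediate
    days matter solely through the peak flag.
    """
    prof = _require_profile(profiles.rnai, "rnai")
    final_day = prof.columns[-1]
    peaked = (prof > thresholds.theta_peak).any(axis=1).rename("peaked")
    down = ((prof[final_day] <= thresholds.theta_down) & ~peaked).rename("rnai_down")
    return down, peaked


def delta_fc(profiles: RelativeProfiles) -> dict[str, pd.DataFrame]:
    """Consecutive-time-point differences of relative expression, per arm.

    Column ``d2_to_d4`` holds r(day 4) − r(day 2) on the
    fraction-of-control scale.
    """
    out: dict[str, pd.DataFrame] = {}
    for arm, prof in profiles.arms.items():
        prof = _require_profile(prof, arm)
        if prof.shape[1] < 2:
            raise ValueError(f"{arm} profile needs at least two time points")
        days = list(prof.columns)
        cols = {
            f"d{days[i]:g}_to_d{days[i + 1]:g}": prof[days[i + 1]] - prof[days[i]]
            for i in range(len(days) - 1)
        }
        out[arm] = pd.DataFrame(cols)
    return out


def dfc_filter(
    overlap_ids: Iterable[str],
    profiles: RelativeProfiles,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[set[str], set[str], set[str]]:
    """Remove overlap transcripts with erratic consecutive-time-point changes.

    Returns ``(final_ids, dfc_out_irr, dfc_out_rnai)``.  A transcript is
    removed when any irradiation |Δ| is strictly above ``theta_dfc`` or
    any RNAi Δ is strictly above ``+theta_dfc`` (RNAi decreases of any
    size are the expected behavior and never trigger removal).  Removal
    by either criterion is final, so
    ``final_ids = overlap − (dfc_out_irr ∪ dfc_out_rnai)``.
    """
    overlap = set(overlap_ids)
    missing = overlap - set(profiles.universe)
    if missing:
        raise ValueError(f"overlap ids outside the profile universe: {sorted(missing)[:5]}")
    deltas = delta_fc(profiles)
    idx = pd.Index(sorted(overlap))
    irr_bad = (deltas["irradiation"].loc[idx].abs() > thresholds.theta_dfc).any(axis=1)
    rnai_bad = (deltas["rnai"].loc[idx] > thresholds.theta_dfc).any(axis=1)
    out_irr = set(idx[irr_bad])
    out_rnai = set(idx[rnai_bad])
    final = overlap - out_irr - out_rnai
    return final, out_irr, out_rnai


def compute_calls(
    profiles: RelativeProfiles, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Full per-transcript boolean call table.

    Columns: ``irr_down, rnai_down, peaked, dfc_out_irr, dfc_out_rnai,
    final``.  ΔFC flags are computed only for transcripts in the
    overlap of the two downregulated sets (elsewhere they are False);
    ``final`` marks the high-confidence list.
    """
    irr_down = call_irradiation_down(profiles, thresholds)
    rnai_down, peaked = call_rnai_down(profiles, thresholds)
    calls = pd.DataFrame(
        {"irr_down": irr_down, "rnai_down": rnai_down, "peaked": peaked}
    )
    overlap = calls.index[calls["irr_down"] & calls["rnai_down"]]
    final, out_irr, out_rnai = dfc_filter(overlap, profiles, thresholds)
    calls["dfc_out_irr"] = calls.index.isin(out_irr)
    calls["dfc_out_rnai"] = calls.index.isin(out_rnai)
    calls["final"] = calls.index.isin(final)
    calls.index.name = "transcript_id"
    return calls


@dataclass(frozen=True)
class VennSummary:
    """Counts and printed-style percentages of the two downregulated sets.

    Percentages are rendered at one decimal with round-half-up.
    """

    n_universe: int
    n_irr_down: int
    n_rnai_down: int
    n_overlap: int

    def __post_init__(self):
        if self.n_universe <= 0:
            raise ValueError("empty universe")
        if self.n_overlap > min(self.n_irr_down, self.n_rnai_down):
            raise ValueError("overlap exceeds a downregulated set")
        if max(self.n_irr_down, self.n_rnai_down) > self.n_universe:
            raise ValueError("downregulated set exceeds the universe")

    @property
    def n_irr_only(self) -> int:
        return self.n_irr_down - self.n_overlap

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return round_half_up(100.0 * num / den, 1) if den else float("nan")

    @property
    def pct_irr_of_universe(self) -> float:
        return self._pct(self.n_irr_down, self.n_universe)

    @property
    def pct_overlap_of_rnai(self) -> float:
        return self._pct(self.n_overlap, self.n_rnai_down)

    @property
    def pct_overlap_of_universe(self) -> float:
        return self._pct(self.n_overlap, self.n_universe)

    @property
    def pct_irr_only_of_universe(self) -> float:
        return self._pct(self.n_irr_only, self.n_universe)

    @property
    def pct_irr_only_of_irr(self) -> float:
        return self._pct(self.n_irr_only, self.n_irr_down)

    def as_dict(self) -> dict[str, float]:
        return {
            "n_universe": self.n_universe,
            "n_irr_down": self.n_irr_down,
            "n_rnai_down": self.n_rnai_down,
            "n_overlap": self.n_overlap,
            "n_irr_only": self.n_irr_only,
            "pct_irr_of_universe": self.pct_irr_of_universe,
            "pct_overlap_of_rnai": self.pct_overlap_of_rnai,
            "pct_overlap_of_universe": self.pct_overlap_of_universe,
            "pct_irr_only_of_universe": self.pct_irr_only_of_universe,
            "pct_irr_only_of_irr": self.pct_irr_only_of_irr,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.as_dict()])

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "VennSummary":
        return cls(
            n_universe=len(calls),
            n_irr_down=int(calls["irr_down"].sum()),
            n_rnai_down=int(calls["rnai_down"].sum()),
            n_overlap=int((calls["irr_down"] & calls["rnai_down"]).sum()),
        )


def venn(calls: pd.DataFrame) -> VennSummary:
    """Venn accounting of the irradiation- and RNAi-downregulated sets."""
    return VennSummary.from_calls(calls)
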