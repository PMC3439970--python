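"""Downregulation calls, peak filter, Venn accounting, and the ΔFC filter."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ablateseq import (
    FilterThresholds,
    VennSummary,
    call_irradiation_down,
    call_rnai_down,
    compute_calls,
    delta_fc,
    dfc_filter,
    venn,
)

THR = FilterThresholds()


def _profiles(irr: dict, rnai: dict):
    """Module-level twin of the make_profiles fixture for hypothesis tests."""
    from ablateseq import RelativeProfiles

    irr_df = pd.DataFrame.from_dict(irr, orient="index", columns=[2.0, 4.0, 7.0])
    rnai_df = pd.DataFrame.from_dict(rnai, orient="index", columns=[1.0, 2.0, 5.0])
    ctrl = pd.DataFrame({"irradiation": 10.0, "rnai": 10.0}, index=irr_df.index)
    return RelativeProfiles(
        arms={"irradiation": irr_df, "rnai": rnai_df}, control_rpkm=ctrl
    )


@pytest.mark.parametrize(
    "r, expected",
    [
        ((0.50, 0.60, 0.70), True),
        ((0.50, 0.80, 0.30), False),  # one point above theta_down
        ((0.75, 0.75, 0.75), True),  # boundary inclusive
    ],
)
def test_irradiation_call(make_profiles, r, expected):
    profiles = make_profiles(irr={"t": r}, rnai={"t": (1.0, 1.0, 1.0)})
    assert bool(call_irradiation_down(profiles, THR)["t"]) is expected


@pytest.mark.parametrize(
    "r, down, peaked",
    [
        ((0.90, 0.50, 0.20), True, False),
        ((1.20, 0.60, 0.30), False, True),  # progeny-like peak excluded
        ((1.05, 0.90, 0.80), False, False),  # final day above theta_down
        ((1.10, 0.50, 0.20), True, False),  # exactly 110% is not a peak
    ],
)
def test_rnai_call(make_profiles, r, down, peaked):
    profiles = make_profiles(irr={"t": (0.5, 0.5, 0.5)}, rnai={"t": r})
    d, p = call_rnai_down(profiles, THR)
    assert bool(d["t"]) is down
    assert bool(p["t"]) is peaked


def test_delta_fc_values(make_profiles):
    profiles = make_profiles(
        irr={"flat": (0.1, 0.1, 0.1), "move": (0.2, 0.5, 0.3)},
        rnai={"flat": (0.9, 0.5, 0.1), "move": (0.9, 0.5, 0.1)},
    )
    d = delta_fc(profiles)
    np.testing.assert_allclose(d["irradiation"].loc["flat"], [0.0, 0.0])
    np.testing.assert_allclose(d["irradiation"].loc["move"], [0.3, -0.2])
    np.testing.assert_allclose(d["rnai"].loc["flat"], [-0.4, -0.4])
    assert list(d["irradiation"].columns) == ["d2_to_d4", "d4_to_d7"]


def test_dfc_filter_rules(make_profiles):
    profiles = make_profiles(
        irr={
            "jumpy": (0.10, 0.35, 0.35),  # |delta| 0.25 -> removed
            "steady": (0.30, 0.30, 0.30),
            "drop": (0.30, 0.30, 0.30),
        },
        rnai={
            "jumpy": (0.9, 0.5, 0.1),
            "steady": (0.9, 0.5, 0.1),
            "drop": (0.9, 0.4, 0.1),  # decreases never trigger the rnai rule
        },
    )
    final, out_irr, out_rnai = dfc_filter({"jumpy", "steady", "drop"}, profiles, THR)
    assert out_irr == {"jumpy"}
    assert out_rnai == set()
    assert final == {"steady", "drop"}


def test_dfc_rnai_increase_removed(make_profiles):
    profiles = make_profiles(
        irr={"up": (0.3, 0.3, 0.3)},
        rnai={"up": (0.3, 0.6, 0.1)},  # +0.3 increase between rnai days
    )
    final, out_irr, out_rnai = dfc_filter({"up"}, profiles, THR)
    assert out_rnai == {"up"} and final == set()


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.tuples(*[st.floats(0, 2, allow_nan=False) for _ in range(6)]),
        min_size=1,
        max_size=12,
    )
)
def test_dfc_conservation_property(data):
    """|final| + |out_irr ∪ out_rnai| = |overlap| for arbitrary profiles."""
    irr = {f"t{i}": row[:3] for i, row in enumerate(data)}
    rnai = {f"t{i}": row[3:] for i, row in enumerate(data)}
    profiles = _profiles(irr, rnai)
    overlap = set(irr)
    final, out_irr, out_rnai = dfc_filter(overlap, profiles, THR)
    assert len(final) + len(out_irr | out_rnai) == len(overlap)
    assert final <= overlap


def _random_profiles(make_profiles, seed, n=40):
    rng = np.random.default_rng(seed)
    irr = {f"t{i}": tuple(rng.uniform(0, 1.6, 3)) for i in range(n)}
    rnai = {f"t{i}": tuple(rng.uniform(0, 1.6, 3)) for i in range(n)}
    return make_profiles(irr=irr, rnai=rnai)


def test_threshold_monotonicity(make_profiles):
    """Lowering theta_down never grows the calls; raising theta_peak never shrinks them."""
    profiles = _random_profiles(make_profiles, seed=1)
    loose = FilterThresholds(theta_down=0.75, theta_peak=1.10)
    tight_down = FilterThresholds(theta_down=0.50, theta_peak=1.10)
    high_peak = FilterThresholds(theta_down=0.75, theta_peak=1.60)
    assert not (
        call_irradiation_down(profiles, tight_down)
        & ~call_irradiation_down(profiles, loose)
    ).any()
    down_loose, _ = call_rnai_down(profiles, loose)
    down_high_peak, _ = call_rnai_down(profiles, high_peak)
    assert not (down_loose & ~down_high_peak).any()


def test_final_list_nests_in_overlap(make_profiles):
    profiles = _random_profiles(make_profiles, seed=2)
    calls = compute_calls(profiles, THR)
    overlap = calls["irr_down"] & calls["rnai_down"]
    assert not (calls["final"] & ~overlap).any()
    assert not (calls["rnai_down"] & calls["peaked"]).any()
    # conservation: overlap splits into final and dFC-removed
    removed = calls["dfc_out_irr"] | calls["dfc_out_rnai"]
    assert (overlap.sum()) == (calls["final"].sum() + removed.sum())


def test_venn_summary_counts_and_validation(make_profiles):
    profiles = make_profiles(
        irr={"a": (0.1, 0.1, 0.1), "b": (0.2, 0.2, 0.2), "c": (1.0, 1.0, 1.0)},
        rnai={"a": (0.9, 0.5, 0.1), "b": (1.0, 1.0, 1.0), "c": (0.9, 0.5, 0.1)},
    )
    vs = venn(compute_calls(profiles, THR))
    assert (vs.n_universe, vs.n_irr_down, vs.n_rnai_down, vs.n_overlap) == (3, 2, 2, 1)
    assert vs.n_irr_only == 1
    with pytest.raises(ValueError, match="empty universe"):
        VennSummary(0, 0, 0, 0)
    with pytest.raises(ValueError, match="overlap"):
        VennSummary(10, 2, 2, 3)


def test_percentages_round_half_up():
    vs = VennSummary(n_universe=1000, n_irr_down=125, n_rnai_down=400, n_overlap=101)
    assert vs.pct_irr_of_universe == 12.5
    assert vs.pct_overlap_of_rnai == 25.3  # 25.25 rounds up, not to even


# -- behavior on simulated ground truth ------------------------------------


def test_noise_free_truth_classes(sim_noise_off):
    """Pure-stem in the final list, peaked progeny out, artifacts irradiation-only."""
    truth, result = sim_noise_off["truth"], sim_noise_off["result"]
    calls = result.calls

    def in_universe(cls):  # the low-expression filter may drop faint transcripts
        ids = truth.index[truth["truth_class"] == cls]
        return ids.intersection(calls.index)

    stem = in_universe("pure_stem")
    assert len(stem) > 100
    assert calls.loc[stem, "final"].all()
    progeny = in_universe("progeny")
    assert calls.loc[progeny, "peaked"].all()
    assert not calls.loc[progeny, "rnai_down"].any()
    artifact = in_universe("artifact")
    assert calls.loc[artifact, "irr_down"].all()
    assert not calls.loc[artifact, "rnai_down"].any()
    unaffected = in_universe("unaffected")
    assert not calls.loc[unaffected, "irr_down"].any()
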