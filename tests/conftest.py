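"""Shared fixtures: a hand-sized on-disk dataset and cached simulations."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ablateseq import (
    RelativeProfiles,
    SimulationConfig,
    StudyDesign,
    analyze,
    simulate_dataset,
)

TOY_SAMPLES = [
    # sample_id, arm, condition, day, replicate
    ("irr_ctrl", "irradiation", "control", 0, 1),
    ("irr_d2", "irradiation", "treated", 2, 1),
    ("irr_d4", "irradiation", "treated", 4, 1),
    ("irr_d7", "irradiation", "treated", 7, 1),
    ("rnai_ctrl", "rnai", "control", 5, 1),
    ("rnai_d1", "rnai", "treated", 1, 1),
    ("rnai_d2", "rnai", "treated", 2, 1),
    ("rnai_d5", "rnai", "treated", 5, 1),
]


@pytest.fixture()
def toy_design() -> StudyDesign:
    return StudyDesign(
        pd.DataFrame(
            TOY_SAMPLES, columns=["sample_id", "arm", "condition", "day", "replicate"]
        )
    )


@pytest.fixture()
def toy_counts_frame() -> pd.DataFrame:
    """Three transcripts, eight samples, one replicate per condition."""
    samples = [s[0] for s in TOY_SAMPLES]
    data = {
        #          ctrl d2  d4  d7  ctrl d1  d2  d5   (irr then rnai)
        "tA": [100, 10, 10, 10, 100, 100, 50, 10],
        "tB": [200, 200, 200, 200, 200, 200, 200, 200],
        "tC": [50, 40, 30, 20, 50, 65, 30, 10],
    }
    frame = pd.DataFrame(data, index=samples).T
    frame.index.name = "transcript_id"
    return frame


@pytest.fixture()
def toy_files(tmp_path, toy_counts_frame):
    """The toy dataset written in the package's on-disk formats."""
    counts = toy_counts_frame.copy()
    counts.insert(0, "length_nt", [1000, 2000, 500])
    counts_path = tmp_path / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    design_path = tmp_path / "design.tsv"
    pd.DataFrame(
        TOY_SAMPLES, columns=["sample_id", "arm", "condition", "day", "replicate"]
    ).to_csv(design_path, sep="\t", index=False)
    lib_path = tmp_path / "library_sizes.tsv"
    samples = [s[0] for s in TOY_SAMPLES]
    with open(lib_path, "w") as fh:
        fh.write("\t".join(samples) + "\n")
        fh.write("\t".join(["1000000"] * len(samples)) + "\n")
    return {"counts": counts_path, "design": design_path, "library_sizes": lib_path}


@pytest.fixture()
def make_profiles():
    """Factory for RelativeProfiles from literal per-transcript vectors.

    Usage: make_profiles(irr={"t1": (0.5, 0.5, 0.5)}, rnai={"t1": (1.0, 0.5, 0.1)}).
    """

    def _make(irr: dict, rnai: dict) -> RelativeProfiles:
        irr_df = pd.DataFrame.from_dict(irr, orient="index", columns=[2.0, 4.0, 7.0])
        rnai_df = pd.DataFrame.from_dict(rnai, orient="index", columns=[1.0, 2.0, 5.0])
        ctrl = pd.DataFrame(
            {"irradiation": 10.0, "rnai": 10.0}, index=irr_df.index
        )
        return RelativeProfiles(
            arms={"irradiation": irr_df, "rnai": rnai_df}, control_rpkm=ctrl
        )

    return _make


@pytest.fixture(scope="session")
def sim_noise_off():
    """Deterministic noise-free simulation plus its full analysis."""
    config = dataclasses.replace(SimulationConfig(), noise="off", seed=11)
    cm, design, ann, truth = simulate_dataset(config)
    result = analyze(cm, design, annotations=ann)
    return {
        "config": config,
        "cm": cm,
        "design": design,
        "annotations": ann,
        "truth": truth,
        "result": result,
    }


@pytest.fixture(scope="session")
def sim_noisy():
    """One default negative-binomial simulation plus analysis."""
    config = SimulationConfig(seed=7)
    cm, design, ann, truth = simulate_dataset(config)
    result = analyze(cm, design)
    return {"config": config, "truth": truth, "result": result}
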