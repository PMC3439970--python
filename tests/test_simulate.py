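"""The synthetic compartment-ablation generator and its closed-form oracles."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ablateseq import (
    CompartmentModel,
    SimulationConfig,
    build_truth,
    emit_annotations,
    expected_final_set,
    expected_relative_expression,
    hypergeom_upper_tail,
    simulate_counts,
    simulate_dataset,
    write_simulation,
    load_dataset,
)


def test_truth_class_counts_and_weights():
    config = SimulationConfig(seed=4)
    truth = build_truth(config)
    counts = truth["truth_class"].value_counts().to_dict()
    assert counts == {
        "unaffected": 600,
        "artifact": 400,
        "pure_stem": 150,
        "progeny": 120,
        "cns_shared": 100,
    }
    w_cols = [c for c in truth.columns if c.startswith("w_")]
    np.testing.assert_allclose(truth[w_cols].sum(axis=1), 1.0)
    stem = truth[truth["truth_class"] == "pure_stem"]
    assert (stem["w_stem"] == 1.0).all()
    shared = truth[truth["truth_class"] == "cns_shared"]
    assert shared["w_cns"].between(0.3, 0.7).all()
    art = truth[truth["truth_class"] == "artifact"]
    assert art["stress_artifact"].all()
    assert art["artifact_severity"].between(0.3, 0.7).all()


def test_same_seed_is_byte_identical(tmp_path):
    p1 = write_simulation(tmp_path / "a", SimulationConfig(seed=9))
    p2 = write_simulation(tmp_path / "b", SimulationConfig(seed=9))
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()
    p3 = write_simulation(tmp_path / "c", SimulationConfig(seed=10))
    assert p3["counts"].read_bytes() != p1["counts"].read_bytes()


def test_expected_relative_expression_closed_forms():
    config = SimulationConfig(seed=0)
    truth = build_truth(config)
    rel = expected_relative_expression(truth)
    # 30% CNS / 70% stem at RNAi day 5: 0.3*1.0 + 0.7*0.1 = 0.37
    synthetic = truth.iloc[[0]].copy()
    for c in ("stem", "early_progeny", "late_progeny", "cns", "differentiated"):
        synthetic[f"w_{c}"] = 0.0
    synthetic["w_cns"], synthetic["w_stem"] = 0.3, 0.7
    synthetic["stress_artifact"], synthetic["artifact_severity"] = False, np.nan
    r = expected_relative_expression(synthetic)
    assert r["rnai"].iloc[0][5.0] == pytest.approx(0.37)
    # artifact transcript (differentiated, s = 0.5): irr 0.5 everywhere, rnai 1.0
    synthetic["w_cns"], synthetic["w_stem"] = 0.0, 0.0
    synthetic["w_differentiated"] = 1.0
    synthetic["stress_artifact"], synthetic["artifact_severity"] = True, 0.5
    r = expected_relative_expression(synthetic)
    np.testing.assert_allclose(r["irradiation"].iloc[0], [0.5, 0.5, 0.5])
    np.testing.assert_allclose(r["rnai"].iloc[0], [1.0, 1.0, 1.0])
    # pure stem: irradiation trajectory identically zero
    stem_ids = truth.index[truth["truth_class"] == "pure_stem"]
    assert (rel["irradiation"].loc[stem_ids] == 0).all().all()


def test_noise_off_counts_match_expectation():
    config = dataclasses.replace(SimulationConfig(), noise="off", seed=2)
    truth = build_truth(config)
    cm, design = simulate_counts(truth, config=config)
    # pure stem transcript, irradiation day 2 -> count exactly 0
    stem_ids = truth.index[truth["truth_class"] == "pure_stem"]
    d2 = design.samples("irradiation", "treated", 2.0)
    assert (cm.counts.loc[stem_ids, d2] == 0).all().all()
    # unaffected transcript: identical expected counts in every condition
    un = truth.index[truth["truth_class"] == "unaffected"][0]
    assert cm.counts.loc[un].nunique() == 1
    # expected count arithmetic for a control sample
    ctrl = design.control_samples("rnai")[0]
    expected = np.rint(
        truth["baseline_rpkm"] * truth["length_nt"] * config.library_size / 1e9
    ).astype(int)
    assert (cm.counts[ctrl] == expected).all()


def test_noise_models_reproducible_and_distinct():
    base = SimulationConfig(seed=5)
    truth = build_truth(base)
    cm_nb, _ = simulate_counts(truth, config=base)
    cm_nb2, _ = simulate_counts(truth, config=base)
    pd.testing.assert_frame_equal(cm_nb.counts, cm_nb2.counts)
    cm_pois, _ = simulate_counts(
        truth, config=dataclasses.replace(base, noise="poisson")
    )
    assert not cm_nb.counts.equals(cm_pois.counts)
    # negative binomial with alpha=0.1 is visibly overdispersed vs poisson
    ctrl_cols = cm_nb.counts.columns[:2]
    mu = cm_nb.counts[ctrl_cols].mean(axis=1)
    big = mu > 200
    nb_cv = (cm_nb.counts[ctrl_cols].std(axis=1) / mu)[big].median()
    pois_cv = (
        cm_pois.counts[ctrl_cols].std(axis=1) / cm_pois.counts[ctrl_cols].mean(axis=1)
    )[big].median()
    assert nb_cv > pois_cv


def test_expected_final_set_is_the_truth_classes():
    config = dataclasses.replace(SimulationConfig(), noise="off", seed=6)
    truth = build_truth(config)
    expected = expected_final_set(truth)
    by_class = set(
        truth.index[truth["truth_class"].isin(["pure_stem", "cns_shared"])]
    )
    assert expected == by_class


def test_annotations_positive_control():
    config = SimulationConfig(seed=8)
    truth = build_truth(config)
    ann = emit_annotations(truth, config)
    members = ann.term_members()["stem_term"]
    stem = set(truth.index[truth["truth_class"] == "pure_stem"])
    k = len(members & stem)
    assert k >= 0.75 * len(stem)  # ~90% annotation fraction
    p = hypergeom_upper_tail(len(truth), len(members), len(stem), k)
    assert p < 1e-20
    ann2 = emit_annotations(truth, config)
    assert ann.mapping == ann2.mapping


def test_written_simulation_loads_back(tmp_path):
    config = dataclasses.replace(SimulationConfig(), noise="off", seed=3)
    paths = write_simulation(tmp_path, config)
    cm, design = load_dataset(paths["counts"], paths["design"], paths["library_sizes"])
    cm0, design0, _, truth = simulate_dataset(config)
    pd.testing.assert_frame_equal(cm.counts, cm0.counts)
    assert design == design0
    truth_back = pd.read_csv(paths["truth"], sep="\t", index_col="transcript_id")
    assert list(truth_back.index) == sorted(truth.index)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(noise="gauss")
    with pytest.raises(ValueError):
        SimulationConfig(noise="nb", dispersion=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(artifact_severity_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        build_truth(
            SimulationConfig(
                n_pure_stem=0,
                n_cns_shared=0,
                n_progeny=0,
                n_artifact=0,
                n_unaffected=0,
            )
        )
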