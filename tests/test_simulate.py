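"""Synthetic-data generator: structure, determinism, truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from quinoaphs.errors import ConfigError, SimulationError
from quinoaphs.phenotypes import derive_phenotypes
from quinoaphs.scoring import SCORE_LEVELS, daily_genotype_means
from quinoaphs.simulate import (SimConfig, plant_qtns, read_dataset,
                                simulate_dataset, simulate_genotypes,
                                simulate_trajectories, write_dataset)


def hudson_fst(calls, clusters):
    """Independent Hudson-estimator oracle (ratio of averages)."""
    num = den = 0.0
    for j in range(calls.shape[1]):
        col = calls[:, j]
        g1 = col[(clusters == 0) & ~np.isnan(col)]
        g2 = col[(clusters == 1) & ~np.isnan(col)]
        n1, n2 = 2 * len(g1), 2 * len(g2)
        if n1 < 4 or n2 < 4:
            continue
        p1, p2 = g1.sum() / n1, g2.sum() / n2
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(seed=None).validate()
    with pytest.raises(ConfigError):
        SimConfig(fst=0.0, seed=1).validate()
    with pytest.raises(ConfigError):
        SimConfig(maf_range=(0.4, 0.1), seed=1).validate()
    with pytest.raises(ConfigError):
        SimConfig(qtn_targets=("d",), seed=1).validate()


def test_genotypes_alphabet_and_no_missing_when_rate_zero():
    cfg = SimConfig(n_accessions=4, n_markers=3, marker_missing_rate=0.0,
                    n_qtn=0, seed=2)
    G = simulate_genotypes(cfg)
    assert G.calls.shape == (4, 3)
    assert np.all(np.isin(G.calls, (0.0, 1.0, 2.0)))


def test_genotypes_missing_rate_close_to_nominal():
    cfg = SimConfig(n_accessions=100, n_markers=500, marker_missing_rate=0.1,
                    n_qtn=0, seed=3)
    G = simulate_genotypes(cfg)
    assert abs(np.isnan(G.calls).mean() - 0.1) < 0.01


def test_fst_matches_target_with_independent_oracle():
    cfg = SimConfig(n_accessions=500, n_markers=2000, fst=0.2,
                    marker_missing_rate=0.0, n_qtn=0, seed=1)
    G = simulate_genotypes(cfg)
    clusters = G.markers.attrs["cluster_labels"]
    assert abs(hudson_fst(G.calls, clusters) - 0.2) < 0.05


def test_determinism_identical_seed_identical_output(tmp_path):
    cfg = SimConfig(n_accessions=30, n_markers=60, n_qtn=2, seed=9)
    G1, truth1, t1 = simulate_dataset(cfg)
    G2, truth2, t2 = simulate_dataset(SimConfig(n_accessions=30, n_markers=60,
                                                n_qtn=2, seed=9))
    assert np.array_equal(G1.calls, G2.calls, equal_nan=True)
    assert truth1.qtn_ids == truth2.qtn_ids
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(truth1.params, truth2.params)


def test_qtn_placement_and_null_model():
    cfg = SimConfig(n_accessions=50, n_markers=100, n_qtn=0, seed=4)
    G = simulate_genotypes(cfg)
    truth = plant_qtns(G, cfg)
    assert truth.qtn_ids == []
    for col in ("a", "b", "c"):
        assert truth.params.groupby("planting_date")[col].std().max() == 0

    cfg_a = SimConfig(n_accessions=50, n_markers=100, n_qtn=1,
                      qtn_targets=("a",), seed=4)
    truth_a = plant_qtns(G, cfg_a)
    assert truth_a.params["b"].std() == 0  # untargeted parameter untouched
    assert truth_a.params["a"].std() > 0
    assert set(truth_a.qtn_ids) <= set(G.markers["id"])
    maf = dict(zip(G.markers["id"], G.maf()))
    assert all(maf[q] >= 0.1 for q in truth_a.qtn_ids)


def test_qtn_truth_bounds_and_pd_shift(small_panel):
    _, G, truth, _ = small_panel
    wide = truth.params.pivot(index="genotype_id", columns="planting_date")
    assert (truth.params["a"] <= 9).all() and (truth.params["a"] >= 0).all()
    assert (truth.params["b"] > 0).all()
    dc = wide[("c", "PD2")] - wide[("c", "PD1")]
    assert np.allclose(dc, -0.5)


def test_too_few_eligible_markers_raises():
    cfg = SimConfig(n_accessions=10, n_markers=5, n_qtn=5,
                    maf_range=(0.01, 0.02), seed=8)
    G = simulate_genotypes(cfg)
    with pytest.raises(SimulationError):
        plant_qtns(G, cfg)


def test_trajectories_no_sprouting_and_saturation():
    cfg = SimConfig(n_accessions=6, n_markers=10, n_qtn=0, n_reps=2,
                    score_noise_sd=0.0, batch_sd=0.0, baseline_a=0.0, seed=5)
    G = simulate_genotypes(cfg)
    table = simulate_trajectories(plant_qtns(G, cfg), cfg)
    assert (table["score"] == 0).all()

    cfg9 = SimConfig(n_accessions=6, n_markers=10, n_qtn=0, n_reps=2,
                     score_noise_sd=0.0, batch_sd=0.0, baseline_a=9.0,
                     baseline_b=3.0, baseline_c=2.0, pd_effect_on_c=0.0, seed=5)
    table9 = simulate_trajectories(plant_qtns(G, cfg9), cfg9)
    assert (table9.loc[table9["day"] == 7, "score"] == 9).all()


def test_trajectory_row_counts_and_levels(small_panel):
    cfg, _, _, table = small_panel
    per_day = cfg.n_accessions * 2 * cfg.n_reps
    assert len(table) == per_day * 7
    assert table["score"].isin(SCORE_LEVELS).all()
    assert set(table["planting_date"]) == {"PD1", "PD2"}


def test_controls_present_in_every_batch(small_panel):
    cfg, _, truth, table = small_panel
    for pdate in ("PD1", "PD2"):
        batches = set(table.loc[table["planting_date"] == pdate, "batch"])
        for cid in truth.control_ids:
            covered = set(table.loc[(table["genotype_id"] == cid)
                                    & (table["planting_date"] == pdate), "batch"])
            assert covered == batches


def test_dataset_round_trip(tmp_path, small_panel):
    cfg, G, truth, table = small_panel
    write_dataset(G, table, truth, tmp_path, cfg=cfg)
    G2, table2, truth2 = read_dataset(tmp_path)
    assert np.array_equal(G.calls, G2.calls, equal_nan=True)
    assert G2.markers["id"].tolist() == G.markers["id"].tolist()
    assert truth2.qtn_ids == truth.qtn_ids
    assert truth2.control_ids == truth.control_ids
    pd.testing.assert_frame_equal(
        table2[["genotype_id", "day", "score"]],
        table[["genotype_id", "day", "score"]])


def test_true_sprouting_extent_tracks_si():
    """SI and the true asymptote both measure sprouting extent."""
    cfg = SimConfig(n_accessions=200, n_markers=500, n_qtn=2,
                    qtn_targets=("a",), qtn_effect_sd=1.5, baseline_a=5.0,
                    seed=5)
    _, truth, table = simulate_dataset(cfg)
    pooled = daily_genotype_means(table, by_planting_date=False)
    pheno = derive_phenotypes(pooled).set_index("genotype_id")
    true_a = truth.params.groupby("genotype_id")["a"].mean()
    rho = spearmanr(true_a.loc[pheno.index], pheno["SI"]).statistic
    assert rho > 0.9
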