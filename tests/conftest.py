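import numpy as np
import pandas as pd
import pytest

from quinoaphs.genotype import GenotypeMatrix, marker_ids
from quinoaphs.simulate import SimConfig, simulate_dataset


def make_genotype_matrix(calls, chroms=None, positions=None, sample_ids=None):
    """Small helper to build a GenotypeMatrix from a raw array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    chroms = chroms or ["1A"] * m
    positions = positions or list(range(100, 100 + 50 * m, 50))
    markers = pd.DataFrame({
        "id": marker_ids(chroms, positions),
        "chrom": chroms,
        "pos": positions,
    })
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(calls, sample_ids, markers)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel with one strong sprouting-extent QTN."""
    cfg = SimConfig(
        n_accessions=120, n_markers=300, n_qtn=1, qtn_targets=("a",),
        qtn_effect_sd=3.0, maf_range=(0.1, 0.3), baseline_a=6.0,
        marker_missing_rate=0.02, seed=11,
    )
    G, truth, table = simulate_dataset(cfg)
    return cfg, G, truth, table


@pytest.fixture()
def score_table():
    """A tiny clean long-format score table: 2 genotypes x 2 replicates."""
    rows = []
    scores = {
        ("G1", 1): [0, 1, 1, 3, 5, 7, 9],
        ("G1", 2): [0, 1, 3, 3, 5, 7, 9],
        ("G2", 1): [1, 3, 5, 7, 9, 9, 9],
        ("G2", 2): [1, 3, 5, 5, 9, 9, 9],
        ("G2", 3): [0, 1, 3, 5, 7, 9, 9],
    }
    for (gid, rep), traj in scores.items():
        for day, s in enumerate(traj, start=1):
            rows.append({
                "genotype_id": gid, "planting_date": "PD1", "batch": "B1",
                "replicate": rep, "day": day, "score": s,
            })
    return pd.DataFrame(rows)
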