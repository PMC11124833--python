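"""AA design construction, covariate-adjusted scan, PVE, multi-locus."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotype_matrix
from quinoaphs.association import (bonferroni_threshold, build_aa_design,
                                   compute_pve, glm_scan, multilocus_scan,
                                   recode_aa)
from quinoaphs.errors import ConfigError, DataError
from quinoaphs.genotype import filter_markers, impute
from quinoaphs.simulate import SimConfig, simulate_genotypes
from quinoaphs.structure import build_cv_matrix, compute_pcs


def _series(values, ids):
    return pd.Series(np.asarray(values, float), index=ids)


def _random_design(seed, n1=40, n2=30, p=25, cov=True, y=None):
    rng = np.random.default_rng(seed)
    G = make_genotype_matrix(rng.integers(0, 3, size=(n1 + n2, p)).astype(float))
    ids = G.sample_ids
    ids1, ids2 = ids[:n1], ids[n1 - 5:]  # overlap of 5 accessions
    if y is None:
        y1 = _series(rng.normal(size=n1), ids1)
        y2 = _series(rng.normal(size=len(ids2)), ids2)
    else:
        y1, y2 = y
    cv = (pd.DataFrame({"PC1": rng.normal(size=len(ids))}, index=ids)
          if cov else None)
    return build_aa_design(G.take_samples(ids1), y1, cv,
                           G.take_samples(ids2), y2, cv), G


def test_recode_exhaustive():
    assert recode_aa(np.array([[0.0, 1.0, 2.0]])).tolist() == [[1, 0, 1]]


def test_recode_refuses_mean_imputed():
    with pytest.raises(DataError, match="modal"):
        recode_aa(np.array([0.0, 1.5, 2.0]))
    with pytest.raises(DataError):
        recode_aa(np.array([0.0, np.nan]))


def test_design_shapes_and_zero_blocks():
    rng = np.random.default_rng(0)
    G = make_genotype_matrix(rng.integers(0, 3, size=(5, 4)).astype(float))
    ids = G.sample_ids
    y1 = _series([1, 2, 3], ids[:3])
    y2 = _series([4, 5], ids[3:])
    d = build_aa_design(G.take_samples(ids[:3]), y1, None,
                        G.take_samples(ids[3:]), y2, None)
    X = d.genotype_block()
    assert X.shape == (5, 8)
    assert np.all(np.isin(X, (0, 1)))
    assert np.all(X[:3, 4:] == 0) and np.all(X[3:, :4] == 0)
    assert d.covariate_names == ["intercept", "planting_date"]
    assert np.array_equal(d.covariates[:, -1], [0, 0, 0, 1, 1])
    cmap = d.pseudo_column_map()
    assert list(cmap["planting_date"]) == ["PD1"] * 4 + ["PD2"] * 4


def test_shared_accession_contributes_two_rows():
    d, _ = _random_design(1)
    shared = set(d.samples_pd1) & set(d.samples_pd2)
    assert len(shared) == 5
    assert d.y.size == d.n1 + d.n2


def test_marker_set_mismatch_rejected():
    G1 = make_genotype_matrix(np.zeros((3, 2)))
    G2 = make_genotype_matrix(np.zeros((3, 3)))
    with pytest.raises(DataError, match="marker set"):
        build_aa_design(G1, _series([1, 2, 3], G1.sample_ids), None,
                        G2, _series([1, 2, 3], G2.sample_ids), None)


def test_single_pd_design_matches_plain_ols_scan():
    """An empty PD2 reduces to an ordinary covariate-adjusted scan.

    Oracle: per-marker OLS with statsmodels on the same covariates.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    n, p = 60, 8
    G = make_genotype_matrix(rng.integers(0, 3, size=(n, p)).astype(float))
    ids = G.sample_ids
    cv = pd.DataFrame({"PC1": rng.normal(size=n)}, index=ids)
    y = _series(rng.normal(size=n), ids)
    d = build_aa_design(G, y, cv)
    assert d.n2 == 0
    res = glm_scan(d)
    Xaa = recode_aa(G.calls)
    for j in range(p):
        if np.ptp(Xaa[:, j]) == 0:
            assert res.loc[j, "p_joint"] == 1.0
            continue
        X = sm.add_constant(np.column_stack([cv["PC1"], Xaa[:, j]]))
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert res.loc[j, "p_pd1"] == pytest.approx(fit.pvalues[-1], rel=1e-6)
        assert res.loc[j, "effect_pd1"] == pytest.approx(fit.params[-1], rel=1e-6)
        assert res.loc[j, "p_joint"] == pytest.approx(
            fit.f_test([0, 0, 1]).pvalue, rel=1e-6)


def test_noiseless_pd1_effect_recovered():
    rng = np.random.default_rng(7)
    G = make_genotype_matrix(rng.integers(0, 3, size=(30, 5)).astype(float))
    ids = G.sample_ids
    x = recode_aa(G.calls)[:, 2].astype(float)
    y1 = _series(2.0 * x[:15] + 0.01 * rng.normal(size=15), ids[:15])
    y2 = _series(0.01 * rng.normal(size=15), ids[15:])
    d = build_aa_design(G.take_samples(ids[:15]), y1, None,
                        G.take_samples(ids[15:]), y2, None)
    res = glm_scan(d)
    assert res.loc[2, "effect_pd1"] == pytest.approx(2.0, abs=0.05)
    assert res.loc[2, "p_joint"] < 1e-12


def test_constant_marker_flagged_p_one():
    G = make_genotype_matrix(np.column_stack([
        np.ones(20), np.random.default_rng(0).integers(0, 3, 20)]).astype(float))
    ids = G.sample_ids
    y = _series(np.random.default_rng(1).normal(size=20), ids)
    d = build_aa_design(G, y, None)
    res = glm_scan(d)
    assert res.loc[0, "flag"] == "constant" and res.loc[0, "p_joint"] == 1.0


def test_scan_invariant_to_marker_and_sample_order():
    d, G = _random_design(5)
    base = glm_scan(d).set_index("marker_id")

    perm = np.random.default_rng(2).permutation(G.n_markers)
    Gp = G.take_markers(perm)
    ids = G.sample_ids
    y1 = _series(d.y[:d.n1], d.samples_pd1)
    y2 = _series(d.y[d.n1:], d.samples_pd2)
    dp = build_aa_design(Gp.take_samples(d.samples_pd1), y1, None,
                         Gp.take_samples(d.samples_pd2), y2, None)
    # rebuild without covariates for comparability
    d0 = build_aa_design(G.take_samples(d.samples_pd1), y1, None,
                         G.take_samples(d.samples_pd2), y2, None)
    res0 = glm_scan(d0).set_index("marker_id")
    resp = glm_scan(dp).set_index("marker_id")
    pd.testing.assert_frame_equal(res0.sort_index(), resp.sort_index())

    shuffled1 = list(np.random.default_rng(3).permutation(d.samples_pd1))
    ds = build_aa_design(G.take_samples(shuffled1), y1, None,
                         G.take_samples(d.samples_pd2), y2, None)
    ress = glm_scan(ds).set_index("marker_id")
    for col in ("p_joint", "pve_pct"):
        assert np.allclose(res0[col], ress[col], rtol=1e-8)


def test_pve_extremes():
    rng = np.random.default_rng(11)
    n = 40
    G = make_genotype_matrix(rng.integers(0, 3, size=(n, 3)).astype(float))
    ids = G.sample_ids
    x = recode_aa(G.calls).astype(float)
    y = _series(x[:, 0] * 3.0, ids)  # marker 0 reproduces the phenotype
    d = build_aa_design(G, y, None)
    assert compute_pve(d, d.markers["id"][0]) == pytest.approx(100.0, abs=1e-8)
    # a marker orthogonal to the residual phenotype explains ~0
    y_orth = _series(rng.normal(size=n), ids)
    d2 = build_aa_design(G, y_orth - np.mean(y_orth), None)
    res = glm_scan(d2)
    assert (res["pve_pct"] >= 0).all() and (res["pve_pct"] <= 100).all()


def test_pve_unknown_marker_rejected():
    d, _ = _random_design(13)
    with pytest.raises(DataError):
        compute_pve(d, "Cq1A_999999999")


@pytest.mark.parametrize("alpha,m,expected", [
    (0.05, 48025, 0.05 / 48025),
    (0.05, 1, 0.05),
])
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)
    assert bonferroni_threshold(alpha, m) >= bonferroni_threshold(alpha, m + 1)


def test_bonferroni_invalid_inputs():
    with pytest.raises(ConfigError):
        bonferroni_threshold(0.05, 0)
    with pytest.raises(ConfigError):
        bonferroni_threshold(1.5, 10)


def test_dosage_encoding_comparison_run():
    """The 0/1/2 dosage option sees additive signal that the hom/het
    recode cannot: an additive QTN at MAF ~0.5 is near-orthogonal to the
    het-vs-hom contrast but trivially detected under dosage coding."""
    rng = np.random.default_rng(19)
    n, p = 120, 40
    calls = rng.binomial(2, 0.5, size=(n, p)).astype(float)
    G = make_genotype_matrix(calls)
    ids = G.sample_ids
    j = 7
    y1 = _series(1.0 * calls[:, j] + 0.3 * rng.normal(size=n), ids)
    y2 = _series(1.0 * calls[:, j] + 0.3 * rng.normal(size=n), ids)
    d_dos = build_aa_design(G, y1, None, G, y2, None, encoding="dosage")
    assert np.all(np.isin(d_dos.genotype_block(), (0, 1, 2)))
    res = glm_scan(d_dos)
    assert res.loc[j, "significant"]
    assert res.loc[j, "effect_pd1"] == pytest.approx(1.0, abs=0.1)
    assert res.sort_values("p_joint").iloc[0]["marker_id"] == G.markers["id"][j]
    with pytest.raises(DataError):
        build_aa_design(G, y1, None, encoding="additive")


def _structured_panel(seed, n=200, p=300):
    cfg = SimConfig(n_accessions=n, n_markers=p, n_qtn=0,
                    marker_missing_rate=0.0, seed=seed)
    G = impute(filter_markers(simulate_genotypes(cfg))[0])
    cv = build_cv_matrix(compute_pcs(G))
    return G, cv


def test_multilocus_null_usually_selects_nothing():
    empty = 0
    runs = 12
    for s in range(runs):
        G, cv = _structured_panel(100 + s)
        rng = np.random.default_rng(900 + s)
        ids = G.sample_ids
        y1 = _series(rng.normal(size=len(ids)), ids)
        y2 = _series(rng.normal(size=len(ids)), ids)
        d = build_aa_design(G, y1, cv, G, y2, cv)
        ml = multilocus_scan(d)
        empty += not ml.selected
        assert ml.converged
    assert empty / runs >= 0.9


def test_multilocus_recovers_planted_qtns():
    G, cv = _structured_panel(77, n=250, p=400)
    rng = np.random.default_rng(42)
    maf = G.maf()
    elig = np.nonzero(maf >= 0.15)[0]
    Z = recode_aa(G.calls).astype(float)
    j1 = int(elig[0])
    # second QTN chosen with low LD to the first
    r2 = np.array([np.corrcoef(Z[:, j1], Z[:, j])[0, 1] ** 2 for j in elig])
    j2 = int(elig[np.argmin(r2)])
    beta = 1.2
    noise = rng.normal(0, 1, size=(2, len(G.sample_ids)))
    y1 = _series(beta * Z[:, j1] + beta * Z[:, j2] + noise[0], G.sample_ids)
    y2 = _series(beta * Z[:, j1] + beta * Z[:, j2] + noise[1], G.sample_ids)
    d = build_aa_design(G, y1, cv, G, y2, cv)
    ml = multilocus_scan(d)
    planted = {G.markers["id"][j1], G.markers["id"][j2]}

    def tags_planted(mid):
        j = G.markers["id"].tolist().index(mid)
        return any(np.corrcoef(Z[:, j], Z[:, jq])[0, 1] ** 2 > 0.7
                   for jq in (j1, j2))

    assert len(ml.selected) >= 2
    assert all(tags_planted(mid) for mid in ml.selected[:2])
    # single-QTN variant: the planted marker is the top hit
    res = glm_scan(d)
    top = res.sort_values("p_joint").iloc[0]["marker_id"]
    assert tags_planted(top)
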