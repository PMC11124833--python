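"""Additive-additive (AA) two-planting-date design and covariate-adjusted scan.

The AA design folds two planting dates (PD1, PD2) of the same diversity
panel into one association problem:

* genotypes {0,1,2} are recoded hom -> 1, het -> 0 (the two homozygote
  classes are deliberately collapsed; the tested contrast is het vs hom);
* the recoded PD1 and PD2 matrices are placed block-diagonally, padded with
  zero matrices, giving each marker two *pseudo-marker* columns — one per
  planting date;
* phenotypes are stacked, and fixed covariates (intercept, PC1-PC3, the
  PC1-sign indicator, and a planting-date column) are stacked alongside.

For each marker the scan fits ``y ~ covariates + x_PD1 + x_PD2`` by least
squares.  Per-PD p-values come from t-statistics; the marker-level p-value
is the joint 2-df F-test of both pseudo-marker coefficients; significance
is Bonferroni at ``alpha / n_markers``.  Per-marker PVE (percent
phenotypic variation explained) is the incremental R^2 of the marker's
pseudo-columns over the covariate-only model, on the covariate-adjusted
total sum of squares.

Accessions appearing in both planting dates contribute two rows that are
treated as independent — a simplification of the AA construction noted in
the methods document.

A simplified multi-locus option iterates the scan while conditioning on
Bonferroni-significant, LD-pruned, BIC-selected pseudo-QTNs; it
approximates the behaviour of iterative multi-locus methods (BLINK-style)
without reproducing their internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "marker_id", "chrom", "pos", "effect_pd1", "effect_pd2",
    "p_pd1", "p_pd2", "p_joint", "pve_pct", "significant", "flag",
)


def recode_aa(calls) -> np.ndarray:
    """Recode integer dosages for the AA design: {0 -> 1, 1 -> 0, 2 -> 1}.

    Homozygous calls (0 or 2 non-reference alleles) become 1, heterozygous
    calls become 0.  Non-integer dosages (e.g. mean-imputed) are refused.
    """
    arr = np.asarray(calls, dtype=float)
    if np.isnan(arr).any():
        raise DataError("recode_aa requires a fully imputed matrix")
    if not np.all(np.isin(arr, (0.0, 1.0, 2.0))):
        raise DataError(
            "recode_aa requires integer dosages in {0,1,2}; use "
            "major-allele (modal) imputation instead of mean imputation"
        )
    return (arr != 1.0).astype(np.int8)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold ``alpha / m`` for ``m`` markers."""
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    if m <= 0:
        raise ConfigError("number of markers must be positive")
    return alpha / m


@dataclass
class AADesign:
    """Stacked two-planting-date design for the AA association scan.

    ``X1``/``X2`` are the recoded (0/1; or 0/1/2 under the dosage
    comparison encoding) per-PD genotype blocks; the full pseudo-marker
    matrix is their block-diagonal arrangement with zero off-diagonal
    blocks.  ``covariates`` has an intercept first and a planting-date
    column last.
    """

    y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    covariates: np.ndarray
    covariate_names: list
    markers: pd.DataFrame
    samples_pd1: list
    samples_pd2: list

    @property
    def n1(self) -> int:
        return self.X1.shape[0]

    @property
    def n2(self) -> int:
        return self.X2.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def genotype_block(self) -> np.ndarray:
        """Full (n1+n2) x 2p block-diagonal pseudo-marker matrix.

        Columns 1..p are the PD1 pseudo-markers, p+1..2p the PD2
        pseudo-markers; off-diagonal blocks are exactly zero.
        """
        p = self.n_markers
        out = np.zeros((self.n1 + self.n2, 2 * p), dtype=np.int8)
        out[: self.n1, :p] = self.X1
        out[self.n1:, p:] = self.X2
        return out

    def pseudo_column_map(self) -> pd.DataFrame:
        """Map pseudo-column index -> (marker_id, planting date)."""
        p = self.n_markers
        return pd.DataFrame({
            "column": np.arange(2 * p),
            "marker_id": np.concatenate([self.markers["id"], self.markers["id"]]),
            "planting_date": ["PD1"] * p + ["PD2"] * p,
        })


def _phenotype_rows(geno: GenotypeMatrix, y: pd.Series):
    y = pd.Series(y).astype(float)
    samples = [s for s in geno.sample_ids if s in y.index and np.isfinite(y[s])]
    if not samples:
        return [], np.empty(0), None
    sub = geno.take_samples(samples)
    return samples, y.loc[samples].to_numpy(), sub


def build_aa_design(
    geno1: GenotypeMatrix,
    y1: pd.Series,
    cov1: pd.DataFrame | None = None,
    geno2: GenotypeMatrix | None = None,
    y2: pd.Series | None = None,
    cov2: pd.DataFrame | None = None,
    encoding: str = "aa",
) -> AADesign:
    """Assemble the stacked AA design from per-planting-date inputs.

    ``y1``/``y2`` are phenotype Series indexed by sample id (one phenotype:
    SI, slope, a, b or c); accessions present in only one PD contribute
    only that PD's row.  ``cov1``/``cov2`` are covariate DataFrames indexed
    by sample id (typically PC1..PC3 + indicator); both PDs must use the
    same covariate columns.  ``geno2=None`` or an empty ``y2`` degrades to
    a single-planting-date scan.

    ``encoding`` selects the marker coding: ``"aa"`` (default) is the
    hom -> 1 / het -> 0 recode of the AA model; ``"dosage"`` keeps the
    standard additive 0/1/2 coding for comparison runs.  The block-diagonal
    stacking is identical in both cases.
    """
    if encoding not in ("aa", "dosage"):
        raise DataError(f"encoding must be 'aa' or 'dosage', got {encoding!r}")

    def _encode(calls):
        if encoding == "aa":
            return recode_aa(calls)
        arr = np.asarray(calls, dtype=float)
        if np.isnan(arr).any() or not np.all(np.isin(arr, (0.0, 1.0, 2.0))):
            raise DataError("dosage encoding requires imputed integer calls")
        return arr.astype(np.int8)

    if geno2 is not None:
        if list(geno1.markers["id"]) != list(geno2.markers["id"]):
            raise DataError("PD1 and PD2 genotype matrices must share the "
                            "same marker set in the same order")

    samples1, yv1, sub1 = _phenotype_rows(geno1, y1)
    if sub1 is None:
        raise DataError("no usable PD1 phenotype rows")
    X1 = _encode(sub1.calls)
    if geno2 is not None and y2 is not None:
        samples2, yv2, sub2 = _phenotype_rows(geno2, y2)
    else:
        samples2, yv2, sub2 = [], np.empty(0), None
    X2 = (_encode(sub2.calls) if sub2 is not None
          else np.zeros((0, geno1.n_markers), dtype=np.int8))

    cov_cols: list[str] = []
    if cov1 is not None:
        cov_cols = list(cov1.columns)
        if samples2 and (cov2 is None or list(cov2.columns) != cov_cols):
            raise DataError("PD1 and PD2 covariates must share columns")
    n = len(samples1) + len(samples2)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for cname in cov_cols:
        col1 = cov1.loc[samples1, cname].to_numpy(float)
        col2 = (cov2.loc[samples2, cname].to_numpy(float)
                if samples2 else np.empty(0))
        blocks.append(np.concatenate([col1, col2])[:, None])
        names.append(cname)
    pd_col = np.concatenate([np.zeros(len(samples1)), np.ones(len(samples2))])
    blocks.append(pd_col[:, None])
    names.append("planting_date")
    C = np.hstack(blocks)

    keep = [0] + [j for j in range(1, C.shape[1]) if np.ptp(C[:, j]) > 1e-12]
    dropped = [names[j] for j in range(C.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping constant covariate columns: %s", dropped)
    C = C[:, keep]
    names = [names[j] for j in keep]

    return AADesign(
        y=np.concatenate([yv1, yv2]),
        X1=X1, X2=X2, covariates=C, covariate_names=names,
        markers=geno1.markers.copy().reset_index(drop=True),
        samples_pd1=samples1, samples_pd2=samples2,
    )


# ---------------------------------------------------------------------------
# scan internals
# ---------------------------------------------------------------------------

def _scan_stats(y, C, A1, A2):
    """Vectorised per-marker least-squares tests.

    ``A1``/``A2`` are the full-height (n x p) pseudo-marker matrices (zeros
    outside their PD's rows).  Returns a dict of per-marker arrays.
    """
    n, k = C.shape
    p = A1.shape[1]
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    tss = float(yr @ yr)
    R1 = A1 - Q @ (Q.T @ A1)
    R2 = A2 - Q @ (Q.T @ A2)

    s11 = np.einsum("ij,ij->j", R1, R1)
    s22 = np.einsum("ij,ij->j", R2, R2)
    s12 = np.einsum("ij,ij->j", R1, R2)
    t1 = yr @ R1
    t2 = yr @ R2

    eps = 1e-9 * max(n, 1)
    ok1 = s11 > eps
    ok2 = s22 > eps
    det = s11 * s22 - s12 ** 2
    full = ok1 & ok2 & (det > 1e-10 * np.maximum(s11 * s22, eps))

    beta1 = np.full(p, np.nan)
    beta2 = np.full(p, np.nan)
    p_pd1 = np.full(p, np.nan)
    p_pd2 = np.full(p, np.nan)
    p_joint = np.ones(p)
    pve = np.zeros(p)
    flag = np.full(p, "constant", dtype=object)

    def _finish(mask, expl, dfree, which):
        if not mask.any():
            return
        rssf = np.maximum(tss - expl[mask], 0.0)
        if dfree <= 0 or tss <= 0:
            return
        sigma2 = rssf / dfree
        with np.errstate(divide="ignore", invalid="ignore"):
            ndf = 2 if which == "both" else 1
            F = (expl[mask] / ndf) / np.where(sigma2 > 0, sigma2, np.nan)
            pj = stats.f.sf(F, ndf, dfree)
        pj = np.where(np.isnan(pj), 0.0, pj)  # sigma2==0: perfect fit
        p_joint[mask] = np.clip(pj, np.finfo(float).tiny, 1.0)
        pve[mask] = 100.0 * np.clip(expl[mask] / tss, 0.0, 1.0)
        if which == "both":
            d = det[mask]
            b1 = (s22[mask] * t1[mask] - s12[mask] * t2[mask]) / d
            b2 = (s11[mask] * t2[mask] - s12[mask] * t1[mask]) / d
            beta1[mask], beta2[mask] = b1, b2
            with np.errstate(divide="ignore", invalid="ignore"):
                se1 = np.sqrt(sigma2 * s22[mask] / d)
                se2 = np.sqrt(sigma2 * s11[mask] / d)
                p_pd1[mask] = 2 * stats.t.sf(np.abs(b1 / se1), dfree)
                p_pd2[mask] = 2 * stats.t.sf(np.abs(b2 / se2), dfree)
            flag[mask] = "ok"
        elif which == "pd1":
            b1 = t1[mask] / s11[mask]
            beta1[mask] = b1
            with np.errstate(divide="ignore", invalid="ignore"):
                se1 = np.sqrt(sigma2 / s11[mask])
                p_pd1[mask] = 2 * stats.t.sf(np.abs(b1 / se1), dfree)
            flag[mask] = "single_pd"
        else:
            b2 = t2[mask] / s22[mask]
            beta2[mask] = b2
            with np.errstate(divide="ignore", invalid="ignore"):
                se2 = np.sqrt(sigma2 / s22[mask])
                p_pd2[mask] = 2 * stats.t.sf(np.abs(b2 / se2), dfree)
            flag[mask] = "single_pd"

    with np.errstate(divide="ignore", invalid="ignore"):
        expl_full = np.where(
            det != 0,
            (s22 * t1 ** 2 - 2 * s12 * t1 * t2 + s11 * t2 ** 2) / det,
            0.0,
        )
        expl_pd1 = np.where(s11 > 0, t1 ** 2 / s11, 0.0)
        expl_pd2 = np.where(s22 > 0, t2 ** 2 / s22, 0.0)

    _finish(full, expl_full, n - k - 2, "both")
    only1 = ok1 & ~full
    only2 = ok2 & ~ok1 & ~full
    # collinear-but-nonconstant pairs fall back to the stronger single column
    _finish(only1, expl_pd1, n - k - 1, "pd1")
    _finish(only2, expl_pd2, n - k - 1, "pd2")
    rankdef = (ok1 & ok2 & ~full)
    flag[rankdef] = "rank_deficient"

    return {
        "effect_pd1": beta1, "effect_pd2": beta2,
        "p_pd1": p_pd1, "p_pd2": p_pd2, "p_joint": p_joint,
        "pve_pct": pve, "flag": flag, "tss": tss,
    }


def _full_height(design: AADesign):
    n1, n2, p = design.n1, design.n2, design.n_markers
    A1 = np.zeros((n1 + n2, p))
    A1[:n1] = design.X1
    A2 = np.zeros((n1 + n2, p))
    A2[n1:] = design.X2
    return A1, A2


def glm_scan(
    design: AADesign,
    alpha: float = 0.05,
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-marker covariate-adjusted scan over the AA design.

    Returns one row per marker with per-PD effects and p-values, the joint
    2-df F-test p-value, incremental-R^2 PVE (%), and a Bonferroni
    ``significant`` flag at ``alpha / n_markers``.
    """
    if design.y.size == 0:
        raise DataError("empty design")
    if np.ptp(design.y) < 1e-15:
        raise DataError("phenotype has zero variance")
    C = design.covariates
    if extra_covariates is not None and extra_covariates.size:
        C = np.hstack([C, extra_covariates])
    A1, A2 = _full_height(design)
    out = _scan_stats(design.y, C, A1, A2)
    threshold = bonferroni_threshold(alpha, design.n_markers)
    res = pd.DataFrame({
        "marker_id": design.markers["id"].to_numpy(),
        "chrom": design.markers["chrom"].to_numpy(),
        "pos": design.markers["pos"].to_numpy(),
        "effect_pd1": out["effect_pd1"],
        "effect_pd2": out["effect_pd2"],
        "p_pd1": out["p_pd1"],
        "p_pd2": out["p_pd2"],
        "p_joint": out["p_joint"],
        "pve_pct": out["pve_pct"],
        "significant": out["p_joint"] < threshold,
        "flag": out["flag"],
    })
    return res


def compute_pve(design: AADesign, marker_id: str) -> float:
    """Incremental-R^2 PVE (%) of one marker's pseudo-columns.

    ``100 * (RSS_reduced - RSS_full) / TSS`` where the reduced model omits
    the marker's two pseudo-columns and TSS is covariate-adjusted.
    """
    ids = design.markers["id"].to_numpy()
    hits = np.nonzero(ids == marker_id)[0]
    if hits.size != 1:
        raise DataError(f"marker {marker_id!r} not found in design")
    j = int(hits[0])
    sub = AADesign(
        y=design.y, X1=design.X1[:, [j]], X2=design.X2[:, [j]],
        covariates=design.covariates, covariate_names=design.covariate_names,
        markers=design.markers.iloc[[j]].reset_index(drop=True),
        samples_pd1=design.samples_pd1, samples_pd2=design.samples_pd2,
    )
    A1, A2 = _full_height(sub)
    out = _scan_stats(sub.y, sub.covariates, A1, A2)
    tss = out["tss"]
    if tss <= 0:
        raise DataError("covariate-adjusted total sum of squares is zero; "
                        "PVE is undefined")
    return float(out["pve_pct"][0])


# ---------------------------------------------------------------------------
# simplified multi-locus scan
# ---------------------------------------------------------------------------

@dataclass
class MultilocusResult:
    """Final conditioned scan, the selected pseudo-QTNs and convergence."""

    results: pd.DataFrame
    selected: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _marker_r2(Z: np.ndarray, j: int, ks) -> np.ndarray:
    """Squared correlation between marker column j and columns ks of Z."""
    zj = Z[:, j] - Z[:, j].mean()
    out = np.zeros(len(ks))
    denom_j = zj @ zj
    for i, k in enumerate(ks):
        zk = Z[:, k] - Z[:, k].mean()
        denom = denom_j * (zk @ zk)
        out[i] = ((zj @ zk) ** 2 / denom) if denom > 0 else 1.0
    return out


def _pseudo_columns(design: AADesign, idx) -> np.ndarray:
    cols = []
    n1, n2 = design.n1, design.n2
    for j in idx:
        c1 = np.concatenate([design.X1[:, j].astype(float), np.zeros(n2)])
        c2 = np.concatenate([np.zeros(n1), design.X2[:, j].astype(float)])
        for col in (c1, c2):
            if np.ptp(col) > 1e-12:
                cols.append(col)
    return np.column_stack(cols) if cols else np.empty((n1 + n2, 0))


def _bic_prefix(design: AADesign, ordered_idx) -> list:
    """Keep the prefix of ordered candidate markers minimising BIC."""
    y = design.y
    n = y.size
    C = design.covariates
    best_m, best_bic = 0, None
    for m in range(0, len(ordered_idx) + 1):
        X = np.hstack([C, _pseudo_columns(design, ordered_idx[:m])])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        if rss <= 0:
            rss = np.finfo(float).tiny
        bic = n * np.log(rss / n) + X.shape[1] * np.log(n)
        if best_bic is None or bic < best_bic - 1e-9:
            best_bic, best_m = bic, m
    return list(ordered_idx[:best_m])


def multilocus_scan(
    design: AADesign,
    r2_threshold: float = 0.7,
    max_iter: int = 10,
    alpha: float = 0.05,
) -> MultilocusResult:
    """Iterative pseudo-QTN conditioning scan (simplified multi-locus model).

    Each iteration: (1) scan all markers conditioning on the current
    pseudo-QTN set (markers in LD, r^2 > ``r2_threshold``, with a
    conditioning pseudo-QTN have that pseudo-QTN excluded for their test);
    (2) order Bonferroni-significant markers by joint p; (3) greedily keep
    those not in LD with an already-kept one; (4) trim the kept list to the
    BIC-minimising prefix.  Stops when the selected set is unchanged or
    ``max_iter`` is reached (then flagged non-converged).
    """
    ids = design.markers["id"].to_numpy()
    p = design.n_markers
    threshold = bonferroni_threshold(alpha, p)
    Z = np.vstack([design.X1, design.X2]).astype(float)  # concatenated recode

    selected: list[int] = []
    converged = False
    n_iter = 0
    res = None
    for n_iter in range(1, max_iter + 1):
        res = _conditioned_scan(design, selected, Z, r2_threshold, alpha)
        cand = res.loc[res["p_joint"] < threshold].sort_values("p_joint")
        cand_idx = [int(np.nonzero(ids == mid)[0][0]) for mid in cand["marker_id"]]
        pruned: list[int] = []
        for j in cand_idx:
            if not pruned or np.all(_marker_r2(Z, j, pruned) <= r2_threshold):
                pruned.append(j)
        new_sel = _bic_prefix(design, pruned)
        if set(new_sel) == set(selected):
            converged = True
            break
        selected = new_sel
    if not converged:
        logger.warning("multilocus scan did not converge in %d iterations", max_iter)
        res = _conditioned_scan(design, selected, Z, r2_threshold, alpha)
    return MultilocusResult(results=res, selected=[ids[j] for j in selected],
                            converged=converged, n_iter=n_iter)


def _conditioned_scan(design, selected, Z, r2_threshold, alpha):
    if not selected:
        return glm_scan(design, alpha=alpha)
    p = design.n_markers
    # exclusion pattern per tested marker: which selected markers are in LD
    excl = np.zeros((p, len(selected)), dtype=bool)
    for i, s in enumerate(selected):
        r2 = _marker_r2(Z, s, list(range(p)))
        excl[:, i] = r2 > r2_threshold
    results = []
    for pattern in np.unique(excl, axis=0):
        mask = np.all(excl == pattern, axis=1)
        keep_sel = [s for i, s in enumerate(selected) if not pattern[i]]
        sub = AADesign(
            y=design.y,
            X1=design.X1[:, mask], X2=design.X2[:, mask],
            covariates=design.covariates,
            covariate_names=design.covariate_names,
            markers=design.markers.loc[mask].reset_index(drop=True),
            samples_pd1=design.samples_pd1, samples_pd2=design.samples_pd2,
        )
        extra = _pseudo_columns(design, keep_sel)
        part = glm_scan(sub, alpha=alpha, extra_covariates=extra)
        # re-flag significance against the full marker count
        part["significant"] = part["p_joint"] < bonferroni_threshold(alpha, p)
        results.append(part)
    out = pd.concat(results, ignore_index=True)
    order = {mid: i for i, mid in enumerate(design.markers["id"])}
    return out.sort_values("marker_id", key=lambda s: s.map(order)).reset_index(drop=True)


def write_results_tsv(results: pd.DataFrame, path) -> None:
    """Write the association results table as TSV."""
    results.to_csv(path, sep="\t", index=False)
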