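"""End-to-end orchestration: config, pipeline stages, reports, plot tables.

``run_pipeline`` chains the whole analysis: read the long-format score
table, validate it, average replicates per genotype (pooled for rankings,
per planting date for GWAS), derive SI / slope / sigmoid phenotypes, read
and QC the genotype matrix, impute, compute structure covariates, build
the AA design for the chosen phenotype, scan, and write every output
table plus a JSON run manifest that fully determines a reproduction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .association import (build_aa_design, bonferroni_threshold, glm_scan,
                          multilocus_scan, write_results_tsv)
from .errors import ConfigError, DataError
from .genotype import filter_markers, impute, read_genotypes
from .phenotypes import correlate_metrics, derive_phenotypes, rank_genotypes
from .scoring import daily_genotype_means, read_score_table, validate_scores
from .structure import build_cv_matrix, compute_pcs, write_covariates

logger = logging.getLogger(__name__)

PHENOTYPE_CHOICES = ("SI", "slope", "a", "b", "c")
SCAN_MODES = ("single", "multilocus")


@dataclass
class PipelineConfig:
    """Paths, thresholds and analysis choices for one pipeline run."""

    phenotype_csv: str
    genotype_path: str
    outdir: str
    genotype_format: str | None = None
    max_missing: float = 0.20
    min_maf: float = 0.05
    alpha: float = 0.05
    phenotype: str = "SI"
    scan_mode: str = "single"
    min_replicates: int = 3
    n_pcs: int = 3
    sigmoid_form: str = "logistic"
    controls: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.phenotype not in PHENOTYPE_CHOICES:
            raise ConfigError(f"phenotype must be one of {PHENOTYPE_CHOICES}")
        if self.scan_mode not in SCAN_MODES:
            raise ConfigError(f"scan_mode must be one of {SCAN_MODES}")
        for name, lo, hi in (("max_missing", 0, 1), ("min_maf", 0, 0.5),
                             ("alpha", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if not Path(self.phenotype_csv).exists():
            raise DataError(f"phenotype file not found: {self.phenotype_csv}")
        if not Path(self.genotype_path).exists():
            raise DataError(f"genotype file not found: {self.genotype_path}")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p with a pointwise 95% null band.

    Observed: sorted ascending p as -log10.  Expected: -log10((i-0.5)/m).
    Band: Beta(i, m-i+1) order-statistic quantiles at 2.5% / 97.5%.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise DataError("no p-values for QQ table")
    m = p.size
    i = np.arange(1, m + 1)
    p_sorted = np.sort(p)
    expected = -np.log10((i - 0.5) / m)
    observed = -np.log10(np.clip(p_sorted, np.finfo(float).tiny, 1.0))
    lower = -np.log10(stats.beta.ppf(0.975, i, m - i + 1))
    upper = -np.log10(stats.beta.ppf(0.025, i, m - i + 1))
    return pd.DataFrame({"expected": expected, "observed": observed,
                         "band_lower": lower, "band_upper": upper})


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 p) table from scan results."""
    neglog = -np.log10(np.clip(results["p_joint"].to_numpy(float),
                               np.finfo(float).tiny, 1.0))
    return pd.DataFrame({
        "marker_id": results["marker_id"],
        "chrom": results["chrom"],
        "pos": results["pos"],
        "neglog10_p": neglog,
        "significant": results["significant"],
    })


def ranking_report(records: pd.DataFrame, controls=None) -> dict:
    """Full ascending slope and SI rankings with control genotypes flagged.

    ``records`` needs columns genotype_id, SI, slope.  Returns the ranking
    table (rank_by_slope, rank_by_SI), the slope-SI Pearson r, and each
    control's ranks and metric values (a missing control id is a warning).
    """
    ranked = rank_genotypes(records, by="slope")
    ranked = rank_genotypes(ranked, by="SI")
    ranked = ranked.sort_values("rank_by_slope").reset_index(drop=True)
    r = correlate_metrics(ranked["slope"], ranked["SI"])
    control_rows = {}
    for cid in controls or ():
        hit = ranked.loc[ranked["genotype_id"] == cid]
        if hit.empty:
            logger.warning("control genotype %r absent from ranking", cid)
            continue
        row = hit.iloc[0]
        control_rows[cid] = {
            "rank_by_slope": int(row["rank_by_slope"]),
            "rank_by_SI": int(row["rank_by_SI"]),
            "slope": float(row["slope"]),
            "SI": float(row["SI"]),
        }
    return {"ranking": ranked, "pearson_r_slope_si": r,
            "n_genotypes": len(ranked), "controls": control_rows}


def _stage(name, t0):
    logger.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Returns the run manifest (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- phenotypes -------------------------------------------------------
    table = read_score_table(config.phenotype_csv)
    report = validate_scores(table, min_replicates=config.min_replicates)
    if not report.duplicate_keys.empty or not report.out_of_scale.empty:
        raise DataError(f"score table failed validation: {report.summary()}")
    t0 = _stage("validate", t0)

    pooled = daily_genotype_means(table, by_planting_date=False)
    by_pd = daily_genotype_means(table, by_planting_date=True)
    pheno_pooled = derive_phenotypes(pooled, form=config.sigmoid_form)
    pheno_by_pd = derive_phenotypes(by_pd, form=config.sigmoid_form)
    t0 = _stage("phenotypes", t0)

    controls = config.controls
    if controls is None and "is_control" in table.columns:
        controls = sorted(table.loc[table["is_control"], "genotype_id"].unique())
    ranking = ranking_report(pheno_pooled, controls=controls)
    ranking["ranking"].to_csv(outdir / "rankings.csv", index=False)
    pheno_by_pd.to_csv(outdir / "phenotypes_by_pd.csv", index=False)
    t0 = _stage("rankings", t0)

    # --- genotypes --------------------------------------------------------
    G_raw = read_genotypes(config.genotype_path, fmt=config.genotype_format)
    G_filt, qc = filter_markers(G_raw, max_missing=config.max_missing,
                                min_maf=config.min_maf)
    qc.write_tsv(outdir / "qc_report.tsv")
    if G_filt.n_markers == 0:
        raise DataError("no markers survived QC filters")
    G = impute(G_filt, method="major_allele")
    t0 = _stage("genotype QC", t0)

    pca = compute_pcs(G, k=config.n_pcs)
    cv = build_cv_matrix(pca)
    write_covariates(cv, outdir / "covariates.tsv")
    t0 = _stage("structure", t0)

    # --- association ------------------------------------------------------
    pheno = pheno_by_pd.copy()
    if config.phenotype in ("b", "c"):
        pheno = pheno.loc[pheno["converged"]]
    series = {
        pdate: grp.set_index("genotype_id")[config.phenotype]
        for pdate, grp in pheno.groupby("planting_date")
    }
    y1 = series.get("PD1", pd.Series(dtype=float))
    y2 = series.get("PD2", pd.Series(dtype=float))
    in_geno = set(G.sample_ids)
    y1 = y1[[g for g in y1.index if g in in_geno]]
    y2 = y2[[g for g in y2.index if g in in_geno]]
    design = build_aa_design(G, y1, cv, G, y2, cv)
    if config.scan_mode == "multilocus":
        ml = multilocus_scan(design, alpha=config.alpha)
        results = ml.results
        selected = ml.selected
    else:
        results = glm_scan(design, alpha=config.alpha)
        selected = list(results.loc[results["significant"], "marker_id"])
    write_results_tsv(results, outdir / "association_results.tsv")
    manhattan_table(results).to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    qq_table(results["p_joint"]).to_csv(outdir / "qq.tsv", sep="\t", index=False)
    t0 = _stage("association", t0)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_genotypes_scored": int(pheno_pooled.shape[0]),
        "n_markers_input": int(G_raw.n_markers),
        "n_markers_after_filter": int(G_filt.n_markers),
        "bonferroni_threshold": bonferroni_threshold(config.alpha, G.n_markers),
        "n_significant": int(results["significant"].sum()),
        "significant_markers": selected,
        "evp_pct": [float(v) for v in pca.evp],
        "pearson_r_slope_si": ranking["pearson_r_slope_si"],
        "controls": ranking["controls"],
        "n_rows_pd1": design.n1,
        "n_rows_pd2": design.n2,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline complete: %d markers scanned, %d significant",
                len(results), manifest["n_significant"])
    return manifest
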