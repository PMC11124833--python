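"""Synthetic diversity-panel generator for the PHS pipeline.

Generates, deterministically from a seed, everything the analysis chain
consumes: a structured genotype matrix, planted QTNs acting on the sigmoid
trajectory parameters, replicate panicle score tables for two planting
dates with batch structure and control genotypes, and a truth file for
parameter-recovery tests.

Model
-----
* **Genotypes** — Balding-Nichols: ancestral allele frequencies are uniform
  on ``maf_range``; each of ``n_clusters`` subpopulations draws its own
  frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = fst``;
  accession genotypes are Binomial(2, p_cluster); entries go missing
  independently at ``marker_missing_rate``.  Markers are spread over the 18
  quinoa chromosomes (1A..9B) with strictly increasing positions.
* **QTNs** — sampled without replacement among markers with MAF >= 0.1;
  each QTN targets one sigmoid parameter (cycling through ``qtn_targets``)
  with an additive effect on the *centred* dosage.  True per-accession
  parameters are ``a`` clamped to [0, 9], ``b`` floored at 0.1 (> 0), and
  ``c`` shifted by ``pd_effect_on_c`` for PD2.
* **Trajectories** — the latent percent-sprouting on day t is
  ``pct(t) = (100/9) * a / (1 + exp(-b (t - c)))`` plus a batch offset and
  Gaussian percent noise, truncated to [0, 100], then discretised through
  the 6-level scale into {0,1,3,5,7,9}.  The scale factor 100/9 maps
  score-scale ``a`` onto percent saturation, so the generator is the exact
  inverse of the analysis model.  Batch offsets are drawn once per
  (planting date, batch) in score units and applied on the percent scale
  through the same 100/9 mapping.
* **Controls** — the first two simulated accessions are controls; their
  replicates are spread round-robin over every batch so each batch carries
  both controls, while every other accession's replicates sit in a single
  batch (contiguous maturity groups).  Total rows stay at
  ``n_accessions x 2 PDs x n_reps`` per day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .genotype import GenotypeMatrix, marker_ids, write_hapmap, write_vcf
from .scoring import percent_to_score, write_score_table, read_score_table
from . import genotype as gio

#: Quinoa chromosome labels.
CHROMOSOMES = tuple(f"{i}{arm}" for i in range(1, 10) for arm in "AB")

#: Relative effect-size scale per sigmoid parameter: a in score units,
#: b (per day) and c (days) varied more gently around their baselines.
_EFFECT_SCALE = {"a": 1.0, "b": 0.25, "c": 0.5}


@dataclass
class SimConfig:
    """Design of the simulated panel; the defaults are the study conditions.

    ~300 accessions scored on two planting dates with 4 panicle replicates
    each, in 4 batches per planting date, on a panel whose susceptible
    majority saturates the scale (baseline a = 9) with half-maximal
    sprouting near day 3.5; replicate noise is 8 percent points.
    """

    n_accessions: int = 300
    n_markers: int = 20000
    n_clusters: int = 2
    fst: float = 0.2
    maf_range: tuple = (0.05, 0.5)
    marker_missing_rate: float = 0.05
    n_qtn: int = 3
    qtn_targets: tuple = ("a", "b", "c")
    qtn_effect_sd: float = 1.0
    n_reps: int = 4
    n_batches: int = 4
    pd_effect_on_c: float = -0.5
    batch_sd: float = 0.3
    score_noise_sd: float = 8.0
    baseline_a: float = 9.0
    baseline_b: float = 1.2
    baseline_c: float = 3.5
    seed: int = None  # type: ignore[assignment]

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("SimConfig.seed is mandatory")
        for name in ("n_accessions", "n_markers", "n_clusters", "n_reps", "n_batches"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.fst < 1:
            raise ConfigError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("maf_range must be an ordered pair in [0, 1]")
        if not 0 <= self.marker_missing_rate <= 1:
            raise ConfigError("marker_missing_rate must lie in [0, 1]")
        if self.n_qtn < 0 or self.n_qtn > self.n_markers:
            raise ConfigError("n_qtn must lie in [0, n_markers]")
        if not set(self.qtn_targets) <= {"a", "b", "c"}:
            raise ConfigError("qtn_targets must be a subset of {'a','b','c'}")
        if self.n_qtn > 0 and not self.qtn_targets:
            raise ConfigError("qtn_targets may not be empty when n_qtn > 0")


@dataclass
class TruthSet:
    """Ground truth of one simulation run.

    ``qtns``: marker id, target parameter and effect size per planted QTN.
    ``params``: true (a, b, c) per accession per planting date.
    ``cluster_labels``: subpopulation per accession.
    ``control_ids``: the two control genotypes present in every batch.
    """

    qtns: pd.DataFrame
    params: pd.DataFrame
    cluster_labels: pd.Series
    control_ids: list = field(default_factory=list)

    @property
    def qtn_ids(self) -> list:
        return list(self.qtns["marker_id"])


def _rngs(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible substreams per stage
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed), stream)))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a structured {0,1,2,missing} genotype matrix (Balding-Nichols)."""
    cfg.validate()
    rng = _rngs(cfg, 1)
    n, m, F = cfg.n_accessions, cfg.n_markers, cfg.fst
    lo, hi = cfg.maf_range

    per_chrom = np.full(len(CHROMOSOMES), m // len(CHROMOSOMES))
    per_chrom[: m % len(CHROMOSOMES)] += 1
    chroms, positions = [], []
    for label, count in zip(CHROMOSOMES, per_chrom):
        if count == 0:
            continue
        gaps = rng.integers(1, 200_000, size=count)
        pos = np.cumsum(gaps)
        chroms.extend([label] * count)
        positions.extend(pos.tolist())

    clusters = np.repeat(np.arange(cfg.n_clusters),
                         int(np.ceil(n / cfg.n_clusters)))[:n]
    p_anc = rng.uniform(lo, hi, size=m)
    shape1 = p_anc * (1 - F) / F
    shape2 = (1 - p_anc) * (1 - F) / F
    p_sub = rng.beta(shape1, shape2, size=(cfg.n_clusters, m))
    p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    calls = rng.binomial(2, p_sub[clusters]).astype(float)
    if cfg.marker_missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.marker_missing_rate
        calls[miss] = np.nan

    markers = pd.DataFrame({
        "id": marker_ids(chroms, positions),
        "chrom": chroms, "pos": positions,
    })
    sample_ids = [f"ACC{i + 1:04d}" for i in range(n)]
    G = GenotypeMatrix(calls, sample_ids, markers)
    G.markers.attrs["cluster_labels"] = clusters
    return G


def plant_qtns(G: GenotypeMatrix, cfg: SimConfig) -> TruthSet:
    """Pick QTNs and derive true per-accession sigmoid parameters."""
    cfg.validate()
    rng = _rngs(cfg, 2)
    clusters = G.markers.attrs.get(
        "cluster_labels",
        np.repeat(np.arange(cfg.n_clusters),
                  int(np.ceil(G.n_samples / cfg.n_clusters)))[: G.n_samples],
    )
    eligible = np.nonzero(G.maf() >= 0.1)[0]
    if len(eligible) < cfg.n_qtn:
        raise SimulationError(
            f"only {len(eligible)} markers with MAF >= 0.1; "
            f"cannot place {cfg.n_qtn} QTNs"
        )
    qtn_idx = np.sort(rng.choice(eligible, size=cfg.n_qtn, replace=False))
    targets = [cfg.qtn_targets[i % len(cfg.qtn_targets)] for i in range(cfg.n_qtn)]
    effects = np.array([rng.normal(0.0, cfg.qtn_effect_sd * _EFFECT_SCALE[t])
                        for t in targets])

    n = G.n_samples
    shift = {"a": np.zeros(n), "b": np.zeros(n), "c": np.zeros(n)}
    for j, target, eff in zip(qtn_idx, targets, effects):
        dose = G.calls[:, j].copy()
        mean = np.nanmean(dose)
        dose = np.where(np.isnan(dose), mean, dose)
        shift[target] += eff * (dose - mean)

    a = np.clip(cfg.baseline_a + shift["a"], 0.0, 9.0)
    b = np.maximum(cfg.baseline_b + shift["b"], 0.1)
    c = cfg.baseline_c + shift["c"]

    rows = []
    for pdate in ("PD1", "PD2"):
        c_pd = c + (cfg.pd_effect_on_c if pdate == "PD2" else 0.0)
        rows.append(pd.DataFrame({
            "genotype_id": G.sample_ids, "planting_date": pdate,
            "a": a, "b": b, "c": c_pd,
        }))
    params = pd.concat(rows, ignore_index=True)
    qtns = pd.DataFrame({
        "marker_id": G.markers["id"].iloc[qtn_idx].to_numpy(),
        "target": targets, "effect": effects,
    })
    return TruthSet(
        qtns=qtns, params=params,
        cluster_labels=pd.Series(np.asarray(clusters), index=G.sample_ids,
                                 name="cluster"),
        control_ids=list(G.sample_ids[:2]),
    )


def simulate_trajectories(truth: TruthSet, cfg: SimConfig) -> pd.DataFrame:
    """Replicate daily panicle scores implied by the true parameters.

    Returns a long-format score table (see scoring.SCORE_COLUMNS) with an
    ``is_control`` flag column.
    """
    cfg.validate()
    rng = _rngs(cfg, 3)
    ids = list(truth.cluster_labels.index)
    controls = set(truth.control_ids)
    n_batches = min(cfg.n_batches, max(cfg.n_reps, 1))
    if n_batches < cfg.n_batches:
        import logging
        logging.getLogger(__name__).warning(
            "n_reps < n_batches: controls cover only %d batches", n_batches)

    params = truth.params.set_index(["genotype_id", "planting_date"])
    non_controls = [g for g in ids if g not in controls]
    batch_of = {g: (i * n_batches) // max(len(non_controls), 1)
                for i, g in enumerate(non_controls)}

    days = np.arange(1.0, 8.0)
    frames = []
    for pdate in ("PD1", "PD2"):
        offsets = rng.normal(0.0, cfg.batch_sd, size=n_batches) * (100.0 / 9.0)
        for gid in ids:
            a, b, c = params.loc[(gid, pdate), ["a", "b", "c"]]
            latent = (100.0 / 9.0) * a / (1.0 + np.exp(-b * (days - c)))
            for rep in range(1, cfg.n_reps + 1):
                batch = ((rep - 1) % n_batches if gid in controls
                         else batch_of[gid])
                noise = rng.normal(0.0, cfg.score_noise_sd, size=7)
                pct = np.clip(latent + offsets[batch] + noise, 0.0, 100.0)
                frames.append(pd.DataFrame({
                    "genotype_id": gid,
                    "planting_date": pdate,
                    "batch": f"B{batch + 1}",
                    "replicate": rep,
                    "day": days.astype(int),
                    "score": percent_to_score(pct),
                    "is_control": gid in controls,
                }))
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(cfg: SimConfig):
    """Run the full generator: genotypes, truth, score table."""
    G = simulate_genotypes(cfg)
    truth = plant_qtns(G, cfg)
    table = simulate_trajectories(truth, cfg)
    return G, truth, table


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_dataset(G: GenotypeMatrix, table: pd.DataFrame, truth: TruthSet,
                  outdir, cfg: SimConfig | None = None) -> dict:
    """Write genotypes (HapMap + VCF), phenotype CSV and truth JSON.

    Everything round-trips losslessly through the package's own readers.
    Returns the mapping of artefact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hapmap": outdir / "genotypes.hmp.txt",
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_hapmap(G, paths["hapmap"])
    write_vcf(G, paths["vcf"])
    write_score_table(table, paths["phenotypes"])
    payload = {
        "qtn_ids": truth.qtn_ids,
        "qtns": truth.qtns.to_dict(orient="records"),
        "params": truth.params.to_dict(orient="records"),
        "cluster_labels": {k: int(v) for k, v in truth.cluster_labels.items()},
        "control_ids": truth.control_ids,
    }
    if cfg is not None:
        payload["config"] = asdict(cfg)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_truth(path) -> TruthSet:
    """Read a truth JSON back into a :class:`TruthSet`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    labels = pd.Series(payload["cluster_labels"], name="cluster")
    return TruthSet(
        qtns=pd.DataFrame(payload["qtns"]),
        params=pd.DataFrame(payload["params"]),
        cluster_labels=labels,
        control_ids=payload["control_ids"],
    )


def read_dataset(outdir):
    """Read a written dataset back (HapMap genotypes, scores, truth)."""
    outdir = Path(outdir)
    G = gio.read_genotypes(outdir / "genotypes.hmp.txt", fmt="hapmap")
    table = read_score_table(outdir / "phenotypes.csv")
    truth = read_truth(outdir / "truth.json")
    return G, table, truth
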