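"""Genotype matrix I/O (HapMap / VCF), marker QC filters and imputation.

Genotypes are held as an accessions x markers array of non-reference allele
counts in {0, 1, 2}, with NaN for missing calls.  Marker IDs follow the
``Cq{chromosome}_{position}`` convention (e.g. ``Cq9B_243431086``) with
1-based positions; file-supplied IDs are overridden on read so that naming
is uniform across formats.

Supported formats:

* tab-separated HapMap (``rs# alleles chrom pos strand ... QCcode`` then one
  column per sample; diploid two-letter calls such as ``AG``, single-letter
  IUPAC codes, ``NN``/``N`` for missing);
* VCF v4.2 via :mod:`cyvcf2` (``GT`` field; ``./.`` missing).  Multiallelic
  records are dropped with a logged count.

QC follows the standard marker filters for this kind of diversity-panel
scan: missing rate <= 20% and minor allele frequency >= 5%, then modal
(major-genotype) imputation so the {0,1,2} alphabet is preserved for the
downstream hom/het recoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Default allele pairs cycled across markers when writing simulated data.
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))

_IUPAC_HET = set("RYSWKM")

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def marker_ids(chromosomes, positions) -> pd.Series:
    """Build ``Cq{chrom}_{pos}`` marker identifiers."""
    return pd.Series(
        [f"Cq{c}_{p}" for c, p in zip(chromosomes, positions)], dtype="object"
    )


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage matrix with marker metadata.

    ``calls`` is float with values in {0, 1, 2} and NaN for missing.
    ``markers`` has columns ``id``, ``chrom``, ``pos`` (1-based) and, when
    known, ``ref``/``alt`` alleles.
    """

    calls: np.ndarray
    sample_ids: list
    markers: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        ids = self.markers["id"]
        if ids.duplicated().any():
            raise DataError("marker IDs are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.mean(np.isnan(self.calls), axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency on non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.calls, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), list(self.sample_ids),
                              self.markers.copy().reset_index(drop=True))

    def take_markers(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(self.calls[:, idx], list(self.sample_ids),
                              self.markers.iloc[idx].reset_index(drop=True))

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataError(f"samples absent from genotype matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(self.calls[idx], list(sample_ids),
                              self.markers.copy().reset_index(drop=True))


def _marker_alleles(markers: pd.DataFrame) -> list:
    if {"ref", "alt"}.issubset(markers.columns):
        return list(zip(markers["ref"], markers["alt"]))
    return [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)] for i in range(len(markers))]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from HapMap or VCF.

    ``fmt`` is ``"hapmap"`` or ``"vcf"``; when None it is inferred from the
    file name (``.vcf`` -> VCF, otherwise HapMap).
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "hapmap"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "hapmap":
        return _read_hapmap(path)
    raise DataError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, chroms, positions, refs, alts = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        logger.info("dropped %d multiallelic VCF records", n_multi)
    calls = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    markers = pd.DataFrame({
        "id": marker_ids(chroms, positions),
        "chrom": chroms, "pos": positions, "ref": refs, "alt": alts,
    })
    return GenotypeMatrix(calls, samples, markers)


def _read_hapmap(path) -> GenotypeMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise DataError(f"{path}: not a HapMap file (fewer than 12 columns)")
        samples = header[11:]
        rows, chroms, positions, refs, alts = [], [], [], [], []
        n_multi = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 11 + len(samples):
                raise DataError(f"{path}:{lineno}: expected {11 + len(samples)} "
                                f"columns, found {len(fields)}")
            alleles = fields[1].split("/")
            if len(alleles) != 2:
                n_multi += 1
                continue
            ref, alt = alleles
            try:
                pos = int(fields[3])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad position {fields[3]!r}") from exc
            row = [_hapmap_call(call, ref, alt, path, lineno)
                   for call in fields[11:]]
            rows.append(row)
            chroms.append(fields[2])
            positions.append(pos)
            refs.append(ref)
            alts.append(alt)
    if n_multi:
        logger.info("dropped %d non-biallelic HapMap records", n_multi)
    calls = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    markers = pd.DataFrame({
        "id": marker_ids(chroms, positions),
        "chrom": chroms, "pos": positions, "ref": refs, "alt": alts,
    })
    return GenotypeMatrix(calls, samples, markers)


def _hapmap_call(call: str, ref: str, alt: str, path, lineno) -> float:
    call = call.strip().upper()
    if call in ("NN", "N", "--", ""):
        return np.nan
    if len(call) == 2:
        n_alt = (call[0] == alt) + (call[1] == alt)
        n_ref = (call[0] == ref) + (call[1] == ref)
        if n_alt + n_ref != 2:
            raise DataError(f"{path}:{lineno}: call {call!r} does not match "
                            f"alleles {ref}/{alt}")
        return float(n_alt)
    if len(call) == 1:
        if call in _IUPAC_HET:
            return 1.0
        if call == ref:
            return 0.0
        if call == alt:
            return 2.0
        raise DataError(f"{path}:{lineno}: unrecognised call {call!r}")
    raise DataError(f"{path}:{lineno}: unrecognised call {call!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_hapmap(G: GenotypeMatrix, path) -> None:
    """Write tab-separated HapMap with two-letter diploid calls."""
    alleles = _marker_alleles(G.markers)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + list(G.sample_ids)) + "\n")
        for j in range(G.n_markers):
            ref, alt = alleles[j]
            meta = [
                str(G.markers["id"].iloc[j]), f"{ref}/{alt}",
                str(G.markers["chrom"].iloc[j]), str(G.markers["pos"].iloc[j]),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            coded = {0: ref + ref, 1: ref + alt, 2: alt + alt}
            cells = []
            for v in G.calls[:, j]:
                cells.append("NN" if np.isnan(v) else coded[int(v)])
            fh.write("\t".join(meta + cells) + "\n")


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF v4.2 with GT-only records."""
    alleles = _marker_alleles(G.markers)
    chrom_max = G.markers.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=quinoaphs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={int(mx) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(G.n_markers):
            ref, alt = alleles[j]
            meta = [
                str(G.markers["chrom"].iloc[j]), str(G.markers["pos"].iloc[j]),
                str(G.markers["id"].iloc[j]), ref, alt, ".", "PASS", ".", "GT",
            ]
            cells = ["./." if np.isnan(v) else gt_code[int(v)]
                     for v in G.calls[:, j]]
            fh.write("\t".join(meta + cells) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-marker QC metrics and keep/drop flags."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_markers(
    G: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    MAF is min(f, 1-f) of the mean non-missing allele dosage / 2, computed
    before imputation.  An empty surviving set is a warning, not an error.
    """
    miss = G.missing_rate()
    maf = G.maf()
    maf_filled = np.where(np.isnan(maf), 0.0, maf)  # all-missing markers drop
    kept = (miss <= max_missing) & (maf_filled >= min_maf)
    report = FilterReport(pd.DataFrame({
        "marker_id": G.markers["id"].to_numpy(),
        "missing_rate": miss,
        "maf": maf,
        "kept": kept,
    }))
    if not kept.any():
        logger.warning("marker filters removed every marker")
    return G.take_markers(np.nonzero(kept)[0]), report


def impute(G: GenotypeMatrix, method: str = "major_allele") -> GenotypeMatrix:
    """Fill missing calls per marker.

    ``major_allele`` (default) fills the modal genotype among {0,1,2}
    (ties broken toward the lower code), preserving the integer alphabet
    required by the hom/het recoding.  ``mean`` fills the mean dosage
    (non-integer allowed, for comparison runs only).
    """
    if method not in ("major_allele", "mean"):
        raise DataError(f"unknown imputation method {method!r}")
    calls = G.calls.copy()
    nan_mask = np.isnan(calls)
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = G.markers["id"].iloc[np.nonzero(all_missing)[0][:5]].tolist()
        raise DataError(f"markers with all calls missing (filter first): {bad}")
    if method == "mean":
        fill = np.nanmean(calls, axis=0)
    else:
        counts = np.stack([np.nansum(calls == g, axis=0) for g in (0, 1, 2)])
        fill = np.argmax(counts, axis=0).astype(float)  # argmax takes lowest tie
    out = G.copy()
    out.calls[nan_mask] = np.broadcast_to(fill, calls.shape)[nan_mask]
    return out
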