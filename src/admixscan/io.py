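"""Tab-separated file dialects and VCF input for the pipeline.

All dialects are plain TSV with LF line endings and dot decimal
separators; lines starting with ``#`` are comments (subcommands record
their seed there).  The dialects:

* genotype TSV: header ``snp_id`` then one column per individual; cells
  are nonreference allele counts 0/1/2 (``NA`` = missing).  Counts are
  halved to dosages in {0, 0.5, 1} on load.
* genetic map TSV: ``snp_id, chrom, bp, cm`` (bp 1-based, cm
  non-decreasing).
* local-ancestry TSV (long): ``snp_id, individual`` then one dosage
  column per population, entries in {0, 0.5, 1}.
* phenotype TSV: ``id, age, sex, sbp, dbp, hyp``.
* frequency TSV: ``snp_id`` then one column per population.

VCF 4.x is supported read-only for genotypes (biallelic records;
multi-allelic records are skipped and counted).  SNPs with more than 20%
missing genotypes are dropped at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneticMap, LocalAncestryCallset

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_map_tsv",
    "write_map_tsv",
    "read_local_ancestry",
    "write_local_ancestry",
    "read_phenotypes",
    "write_phenotypes",
    "read_freq_table",
    "write_freq_table",
]


def _comment_lines(seed: int | None) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


def _write_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_comment_lines(seed))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def _read_tsv(path) -> pd.DataFrame:
    # round_trip parsing keeps read(write(x)) bit-exact for float columns
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


@dataclass(frozen=True)
class GenotypeData:
    """Genotype dosages plus identifiers (and a map when available)."""

    dosage: np.ndarray  # (n_snps, n_individuals), NaN = missing
    snp_ids: np.ndarray
    individual_ids: np.ndarray
    gmap: GeneticMap | None = None
    n_dropped_missing: int = 0
    n_skipped_multiallelic: int = 0


# -- genotypes ---------------------------------------------------------------


def write_genotypes_tsv(path, dosage, snp_ids, individual_ids, seed=None) -> None:
    """Write dosages as an allele-count genotype TSV (NA = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    counts = np.rint(2.0 * dosage)
    df = pd.DataFrame(counts, columns=list(individual_ids))
    df = df.astype("Int64")  # nullable ints keep NA cells intact
    df.insert(0, "snp_id", list(snp_ids))
    _write_tsv(df, path, seed=seed)


def _filter_missing(dosage: np.ndarray, snp_ids: np.ndarray, max_missing: float):
    miss = np.mean(np.isnan(dosage), axis=1)
    keep = miss <= max_missing
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        log.info("dropped %d SNPs with missingness > %.0f%%", n_dropped,
                 100 * max_missing)
    return dosage[keep], snp_ids[keep], keep, n_dropped


def _read_genotypes_tsv(path, max_missing: float) -> GenotypeData:
    df = _read_tsv(path)
    if df.columns[0] != "snp_id":
        raise ValueError(f"{path}: genotype TSV must start with a snp_id column")
    snp_ids = df["snp_id"].to_numpy(dtype=object)
    body = df.drop(columns="snp_id")
    counts = body.to_numpy(dtype=float)
    valid = np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"{path}: row {bad[0] + 1} column {body.columns[bad[1]]!r}: "
            "allele counts must be 0, 1, 2 or NA"
        )
    dosage = counts / 2.0
    dosage, snp_ids, _, n_dropped = _filter_missing(dosage, snp_ids, max_missing)
    return GenotypeData(
        dosage=dosage,
        snp_ids=snp_ids,
        individual_ids=body.columns.to_numpy(dtype=object),
        n_dropped_missing=n_dropped,
    )


def _read_genotypes_vcf(path, max_missing: float) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individual_ids = np.asarray(vcf.samples, dtype=object)
    rows, ids, bps, chroms = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt = np.asarray(var.gt_types, dtype=float)
        counts = np.where(gt == 3, np.nan, gt)
        rows.append(counts / 2.0)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        bps.append(var.POS)
        chroms.append(var.CHROM)
    vcf.close()
    if n_multi:
        log.info("skipped %d multi-allelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    order = np.argsort(np.asarray(bps), kind="stable")
    dosage = np.asarray(rows)[order]
    snp_ids = np.asarray(ids, dtype=object)[order]
    bp = np.asarray(bps, dtype=np.int64)[order]
    dosage, snp_ids, keep, n_dropped = _filter_missing(dosage, snp_ids, max_missing)
    bp = bp[keep]
    gmap = GeneticMap(
        snp_ids=snp_ids,
        positions_bp=bp,
        positions_cm=bp / 1e6,  # 1 cM/Mb convention when no map is supplied
        chrom=chroms[0],
    )
    return GenotypeData(
        dosage=dosage,
        snp_ids=snp_ids,
        individual_ids=individual_ids,
        gmap=gmap,
        n_dropped_missing=n_dropped,
        n_skipped_multiallelic=n_multi,
    )


def read_genotypes(path, format: str = "tsv", max_missing: float = 0.2) -> GenotypeData:
    """Load a genotype matrix from TSV or VCF.

    Dosages are in {0, 0.5, 1} with NaN for missing calls; SNPs whose
    missingness exceeds ``max_missing`` (default 20%) are dropped with a
    logged count.  VCF input keeps biallelic records only and sorts by
    position.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, max_missing)
    if format == "vcf":
        return _read_genotypes_vcf(path, max_missing)
    raise ValueError("format must be 'tsv' or 'vcf'")


def write_vcf(path, dosage, gmap: GeneticMap, individual_ids, seed=None) -> None:
    """Write dosages as a minimal VCF 4.2 file (GT only, A/G placeholder)."""
    dosage = np.asarray(dosage, dtype=float)
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##admixscan_seed={seed}\n")
        fh.write(f"##contig=<ID={gmap.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(dosage.shape[0]):
            counts = dosage[j] * 2.0
            gts = [
                "./." if np.isnan(c) else gt_map[int(round(c))] for c in counts
            ]
            fh.write(
                f"{gmap.chrom}\t{gmap.positions_bp[j]}\t{gmap.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# -- genetic map -------------------------------------------------------------


def write_map_tsv(path, gmap: GeneticMap, seed=None) -> None:
    df = pd.DataFrame(
        {
            "snp_id": gmap.snp_ids,
            "chrom": gmap.chrom,
            "bp": gmap.positions_bp,
            "cm": gmap.positions_cm,
        }
    )
    _write_tsv(df, path, seed=seed)


def read_map_tsv(path) -> GeneticMap:
    df = _read_tsv(path)
    needed = {"snp_id", "chrom", "bp", "cm"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: map TSV needs columns {sorted(needed)}")
    return GeneticMap(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        positions_bp=df["bp"].to_numpy(dtype=np.int64),
        positions_cm=df["cm"].to_numpy(dtype=float),
        chrom=str(df["chrom"].iloc[0]),
    )


# -- local ancestry ----------------------------------------------------------


def write_local_ancestry(path, callset: LocalAncestryCallset, seed=None) -> None:
    """Write a call set in the long TSV dialect (snp, individual, dosages)."""
    J, N, K = callset.dosage.shape
    df = pd.DataFrame(
        {
            "snp_id": np.repeat(callset.gmap.snp_ids, N),
            "individual": np.tile(callset.individual_ids, J),
        }
    )
    flat = callset.dosage.reshape(J * N, K)
    for k, lab in enumerate(callset.pop_labels):
        df[lab] = flat[:, k]
    _write_tsv(df, path, seed=seed)


def read_local_ancestry(path, gmap: GeneticMap) -> LocalAncestryCallset:
    """Read the long local-ancestry TSV back into a call set."""
    df = _read_tsv(path)
    if df.columns[0] != "snp_id" or df.columns[1] != "individual":
        raise ValueError(f"{path}: expected snp_id, individual leading columns")
    pop_labels = tuple(df.columns[2:])
    inds = pd.unique(df["individual"])
    N = len(inds)
    J = len(df) // N
    if J * N != len(df) or J != len(gmap):
        raise ValueError(f"{path}: rows do not tile (n_snps x n_individuals)")
    snp_order = df["snp_id"].to_numpy(dtype=object)[::N]
    if not np.array_equal(snp_order, gmap.snp_ids):
        raise ValueError(f"{path}: SNP order does not match the map")
    dosage = df[list(pop_labels)].to_numpy(dtype=float).reshape(J, N, len(pop_labels))
    return LocalAncestryCallset(
        dosage=dosage,
        gmap=gmap,
        pop_labels=pop_labels,
        individual_ids=np.asarray(inds, dtype=object),
    )


# -- phenotypes and frequencies ----------------------------------------------

PHENO_COLUMNS = ("id", "age", "sex", "sbp", "dbp", "hyp")


def write_phenotypes(path, phenotypes: pd.DataFrame, seed=None) -> None:
    missing = set(PHENO_COLUMNS) - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    _write_tsv(phenotypes[list(PHENO_COLUMNS)], path, seed=seed)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return df


def write_freq_table(path, freqs: pd.DataFrame, seed=None) -> None:
    if "snp_id" not in freqs.columns:
        raise ValueError("frequency table needs a snp_id column")
    _write_tsv(freqs, path, seed=seed)


def read_freq_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: frequency table needs a snp_id column")
    return df
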