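"""Fst computation and ancestry-informative-marker (AIM) panel selection.

An AIM panel for a three-way admixed cohort keeps SNPs whose allele
frequencies are (a) similar between the two available subpopulations of
the same continental ancestry, (b) strongly differentiated between each
continental outgroup and each of those subpopulations, and (c) mutually
uncorrelated (low LD r^2) so each marker contributes independent
ancestry information.

Fst here is the Nei-style (H_T - H_S)/H_T computed from population
allele frequencies with equal population weights: no sample sizes enter,
which matches working from published frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import GeneticMap

__all__ = ["AimPanel", "fst_two_pop", "fst_matrix", "ld_r2", "select_aims"]


def fst_two_pop(p1, p2):
    """Nei-style two-population Fst from allele frequencies.

    With mean frequency p̄ = (p1+p2)/2, total heterozygosity
    H_T = 2 p̄ (1-p̄) and mean subpopulation heterozygosity
    H_S = (2 p1 (1-p1) + 2 p2 (1-p2)) / 2, returns (H_T - H_S)/H_T,
    defined as 0 where H_T = 0 (both populations fixed for the same
    allele).  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    pbar = 0.5 * (p1 + p2)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    out = np.clip(fst, 0.0, None)
    return float(out) if out.ndim == 0 else out


def fst_matrix(freqs: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Per-SNP Fst for every unordered pair of populations.

    ``freqs`` is (n_snps, K); returns {(k1, k2): per-SNP Fst vector}.
    """
    freqs = np.asarray(freqs, dtype=float)
    return {
        (i, j): fst_two_pop(freqs[:, i], freqs[:, j])
        for i, j in combinations(range(freqs.shape[1]), 2)
    }


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two genotype-dosage vectors.

    This is composite LD: it needs no phasing, only per-individual
    dosages.  Constant input is an error (LD undefined).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or len(g1) < 2:
        raise ValueError("dosage vectors must be equal-length 1-D, length >= 2")
    s1 = g1 - g1.mean()
    s2 = g2 - g2.mean()
    v1 = s1 @ s1
    v2 = s2 @ s2
    if v1 == 0 or v2 == 0:
        raise ValueError("LD is undefined for a constant dosage vector")
    r = (s1 @ s2) / np.sqrt(v1 * v2)
    return float(r * r)


@dataclass(frozen=True)
class AimPanel:
    """Result of AIM selection.

    ``fst_table`` records, for every input SNP, each pairwise Fst used
    by the filters plus boolean columns for the two frequency conditions
    and final selection; ``snp_ids`` are the retained markers in map
    order.
    """

    snp_ids: np.ndarray
    fst_table: pd.DataFrame
    within_thresh: float
    between_thresh: float
    ld_cutoff: float

    @property
    def n_selected(self) -> int:
        return len(self.snp_ids)


def select_aims(
    freqs: pd.DataFrame,
    genotypes: np.ndarray,
    gmap: GeneticMap,
    within_pops: tuple[str, str] = ("MAY", "PMA"),
    outgroup_pops: tuple[str, str] = ("CEU", "YRI"),
    within_thresh: float = 0.1,
    between_thresh: float = 0.2,
    ld_cutoff: float = 0.1,
    ld_window: int = 250,
) -> AimPanel:
    """Select ancestry-informative markers by Fst filters plus LD pruning.

    A SNP is kept when (a) Fst between the two ``within_pops`` is below
    ``within_thresh`` (strict), (b) all four Fst values between an
    outgroup and a within-continent population exceed ``between_thresh``
    (strict), and (c) its genotype r^2 with every already-retained SNP
    in the trailing ``ld_window`` SNPs is below ``ld_cutoff``.  Pruning
    is greedy left-to-right in map order.

    ``freqs`` must carry ``snp_id`` plus one frequency column per named
    population, row-aligned with ``gmap`` and with the rows of
    ``genotypes`` (n_snps x n_individuals dosages).
    """
    needed = {"snp_id", *within_pops, *outgroup_pops}
    missing = needed - set(freqs.columns)
    if missing:
        raise ValueError(f"frequency table lacks columns: {sorted(missing)}")
    if len(freqs) != len(gmap):
        raise ValueError("frequency table and map differ in SNP count")
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.shape[0] != len(gmap):
        raise ValueError("genotype matrix rows must match the map")
    if not np.array_equal(
        np.asarray(freqs["snp_id"], dtype=object), gmap.snp_ids
    ):
        raise ValueError("frequency table SNP ids do not match the map")

    w1, w2 = within_pops
    fst_within = fst_two_pop(freqs[w1].to_numpy(), freqs[w2].to_numpy())
    between_cols: dict[str, np.ndarray] = {}
    for og in outgroup_pops:
        for wp in within_pops:
            between_cols[f"fst_{og}_{wp}"] = fst_two_pop(
                freqs[og].to_numpy(), freqs[wp].to_numpy()
            )

    cond_within = fst_within < within_thresh
    cond_between = np.all(
        np.column_stack([v > between_thresh for v in between_cols.values()]), axis=1
    )
    candidate = cond_within & cond_between

    selected: list[int] = []
    ld_dropped = np.zeros(len(gmap), dtype=bool)
    for j in np.flatnonzero(candidate):
        gj = genotypes[j]
        if np.ptp(gj) == 0:  # monomorphic in the sample: no LD info, drop
            ld_dropped[j] = True
            continue
        keep = True
        for i in reversed(selected):
            if j - i > ld_window:
                break
            gi = genotypes[i]
            if ld_r2(gi, gj) >= ld_cutoff:
                keep = False
                break
        if keep:
            selected.append(j)
        else:
            ld_dropped[j] = True

    sel_mask = np.zeros(len(gmap), dtype=bool)
    sel_mask[selected] = True
    table = pd.DataFrame(
        {
            "snp_id": gmap.snp_ids,
            "chrom": gmap.chrom,
            "bp": gmap.positions_bp,
            f"fst_{w1}_{w2}": fst_within,
            **between_cols,
            "pass_within": cond_within,
            "pass_between": cond_between,
            "ld_dropped": ld_dropped,
            "selected": sel_mask,
        }
    )
    return AimPanel(
        snp_ids=gmap.snp_ids[sel_mask],
        fst_table=table,
        within_thresh=within_thresh,
        between_thresh=between_thresh,
        ld_cutoff=ld_cutoff,
    )
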