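"""Shared data containers for admixed-cohort analysis.

The containers here are the common currency of the package: a genetic map,
a panel of ancestral allele frequencies, and a local-ancestry call set
(per-SNP, per-individual ancestry dosages).  Local ancestry for a diploid
individual at one SNP is summarised as a K-vector of dosages in
{0, 0.5, 1} that sums to 1: each of the two haplotypes contributes 0.5 to
the population it descends from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_POPS = ("EUR", "AFR", "NAM")

#: Valid per-(SNP, individual) dosage values after hard-calling.
HARD_CALL_VALUES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class GeneticMap:
    """Physical (bp, 1-based) and genetic (cM) positions of a SNP set.

    Physical positions must be strictly increasing; genetic positions
    non-decreasing.  Map length is reported in morgans.
    """

    snp_ids: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    chrom: str = "3"

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", np.asarray(self.snp_ids, dtype=object))
        object.__setattr__(
            self, "positions_bp", np.asarray(self.positions_bp, dtype=np.int64)
        )
        object.__setattr__(
            self, "positions_cm", np.asarray(self.positions_cm, dtype=float)
        )
        if not (
            len(self.snp_ids) == len(self.positions_bp) == len(self.positions_cm)
        ):
            raise ValueError("snp_ids, positions_bp and positions_cm lengths differ")
        if len(self.snp_ids) == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("physical positions must be strictly increasing")
        if np.any(np.diff(self.positions_cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")
        if np.any(self.positions_bp < 1):
            raise ValueError("physical positions are 1-based; found position < 1")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def length_morgans(self) -> float:
        """Total genetic length spanned by the map, in morgans."""
        return float(self.positions_cm[-1] - self.positions_cm[0]) / 100.0

    @property
    def span_cm(self) -> tuple[float, float]:
        return float(self.positions_cm[0]), float(self.positions_cm[-1])


@dataclass(frozen=True)
class AncestralPanel:
    """Per-SNP nonreference allele frequencies for K ancestral populations.

    ``freqs`` has one row per SNP in ``gmap`` and one column per
    population, every entry in [0, 1].
    """

    freqs: np.ndarray
    gmap: GeneticMap
    pop_labels: tuple[str, ...] = DEFAULT_POPS

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "pop_labels", tuple(self.pop_labels))
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be a 2-D (n_snps, K) array")
        if self.freqs.shape[0] != len(self.gmap):
            raise ValueError("freqs rows must match the genetic map")
        if self.freqs.shape[1] != len(self.pop_labels):
            raise ValueError("freqs columns must match pop_labels")
        if np.any(~np.isfinite(self.freqs)) or np.any(
            (self.freqs < 0) | (self.freqs > 1)
        ):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.freqs.shape[1]

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class LocalAncestryCallset:
    """Per-SNP, per-individual local-ancestry dosage tensor.

    ``dosage`` has shape (n_snps, n_individuals, K); each K-vector sums to
    1 and, for hard-called data, has entries in {0, 0.5, 1}.
    """

    dosage: np.ndarray
    gmap: GeneticMap
    pop_labels: tuple[str, ...] = DEFAULT_POPS
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dosage", np.asarray(self.dosage, dtype=float))
        object.__setattr__(self, "pop_labels", tuple(self.pop_labels))
        if self.dosage.ndim != 3:
            raise ValueError("dosage must be (n_snps, n_individuals, K)")
        if self.dosage.shape[0] != len(self.gmap):
            raise ValueError("dosage SNP axis must match the genetic map")
        if self.dosage.shape[2] != len(self.pop_labels):
            raise ValueError("dosage population axis must match pop_labels")
        if self.dosage.shape[1] < 1:
            raise ValueError("call set must contain at least one individual")
        sums = self.dosage.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each per-(SNP, individual) K-vector must sum to 1")
        if self.individual_ids is None:
            ids = np.array(
                [f"ind{i:04d}" for i in range(self.dosage.shape[1])], dtype=object
            )
            object.__setattr__(self, "individual_ids", ids)
        else:
            ids = np.asarray(self.individual_ids, dtype=object)
            if len(ids) != self.dosage.shape[1]:
                raise ValueError("individual_ids length mismatch")
            object.__setattr__(self, "individual_ids", ids)

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[1]

    @property
    def K(self) -> int:
        return self.dosage.shape[2]

    def pop_index(self, pop: str | int) -> int:
        if isinstance(pop, (int, np.integer)):
            if not 0 <= int(pop) < self.K:
                raise ValueError(f"population index {pop} out of range")
            return int(pop)
        try:
            return self.pop_labels.index(pop)
        except ValueError as exc:
            raise ValueError(
                f"unknown population {pop!r}; labels are {self.pop_labels}"
            ) from exc

    def dosage_for(self, pop: str | int) -> np.ndarray:
        """(n_snps, n_individuals) dosage matrix of one population."""
        return self.dosage[:, :, self.pop_index(pop)]


def diploid_states(K: int) -> list[tuple[int, int]]:
    """The K*(K+1)/2 unordered diploid ancestry states, in population order.

    For K = 3 these are the six states (0,0), (0,1), (0,2), (1,1), (1,2),
    (2,2); the lexicographic order is the tie-break order used when
    hard-calling fractional dosages.
    """
    return [(i, j) for i in range(K) for j in range(i, K)]


def state_dosages(K: int) -> np.ndarray:
    """Dosage K-vector of each unordered diploid state, shape (n_states, K)."""
    states = diploid_states(K)
    out = np.zeros((len(states), K))
    for s, (i, j) in enumerate(states):
        out[s, i] += 0.5
        out[s, j] += 0.5
    return out
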