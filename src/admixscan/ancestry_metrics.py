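"""Ancestry-segment counting, the generations-since-admixture estimator,
and metrics for comparing local-ancestry call sets.

The central estimator converts an individual's count of ancestry
segments A into the number of generations N since admixture,

    N = A / (4 a (1 - a) L),

where ``a`` is the admixture proportion of the ancestry of interest
(European here), ``4 a (1 - a)`` the expected number of ancestry-switch
recombination events per morgan in a diploid, and ``L`` the genetic map
length in morgans.  The formula is applied literally, without
subtracting the two baseline segments every diploid carries; for ~10
generations on a ~2.2-morgan chromosome the resulting upward bias is
about one generation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .core import LocalAncestryCallset, state_dosages

__all__ = [
    "SegmentSummary",
    "GlobalComparison",
    "count_segments",
    "estimate_generations",
    "compare_to_global",
    "diploid_inconsistency",
    "hard_call",
    "tract_lengths_morgans",
]


@dataclass(frozen=True)
class SegmentSummary:
    """Per-individual ancestry-segment counts with cohort mean and SD."""

    counts: np.ndarray
    binarized_to: int | str | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0


def _counts_from_paths(pairs, target_pop: int | None) -> np.ndarray:
    out = np.empty(len(pairs), dtype=np.int64)
    for i, pair in enumerate(pairs):
        total = 0
        for path in pair:
            p = path.binarize(target_pop) if target_pop is not None else path.collapse()
            total += p.n_segments
        out[i] = total
    return out


def _counts_from_dosage(callset: LocalAncestryCallset, target_pop) -> np.ndarray:
    # Allele-count representation: 2 * dosage is the integer count of
    # haplotypes assigned to each population at a (SNP, individual).
    counts = np.rint(2.0 * callset.dosage).astype(np.int64)  # (J, N, K)
    if target_pop is not None:
        k = callset.pop_index(target_pop)
        c = counts[:, :, k]
        switches = np.abs(np.diff(c, axis=0)).sum(axis=0)
    else:
        # Minimal haplotype-label changes between consecutive unordered
        # diploid states: 2 minus the multiset overlap.
        overlap = np.minimum(counts[:-1], counts[1:]).sum(axis=2)  # (J-1, N)
        switches = (2 - overlap).sum(axis=0)
    return 2 + switches


def count_segments(data, target_pop=None) -> SegmentSummary:
    """Count ancestry segments per individual (both haplotypes summed).

    ``data`` is either a :class:`LocalAncestryCallset` or a sequence of
    per-individual haplotype-path pairs (as stored on a simulated
    cohort).  With ``target_pop`` given, ancestry is first binarized to
    target-vs-other, the two-class process whose switch rate the
    generations estimator assumes; otherwise full multi-way segments are
    counted.  An individual of uniform ancestry has A = 2 (one segment
    per haplotype); from dosage-only input the count is the minimal
    number of haplotype segments consistent with the per-SNP diploid
    states.
    """
    if isinstance(data, LocalAncestryCallset):
        if data.n_snps < 1:
            raise ValueError("call set must contain at least one SNP")
        tp = data.pop_index(target_pop) if target_pop is not None else None
        counts = _counts_from_dosage(data, tp)
    else:
        pairs = list(data)
        if not pairs:
            raise ValueError("no individuals supplied")
        tp = int(target_pop) if target_pop is not None else None
        counts = _counts_from_paths(pairs, tp)
    return SegmentSummary(counts=counts, binarized_to=target_pop)


def estimate_generations(A, a, L: float):
    """Generations since admixture from segment counts: N = A/(4a(1-a)L).

    ``A`` and ``a`` may be scalars or broadcastable arrays (e.g.
    per-individual counts with per-individual admixture proportions, to
    be averaged by the caller).  ``a`` must lie strictly inside (0, 1)
    and ``L`` (morgans) must be positive.
    """
    A = np.asarray(A, dtype=float)
    a = np.asarray(a, dtype=float)
    if L <= 0:
        raise ValueError("map length must be positive")
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError("admixture proportion must lie strictly in (0, 1)")
    if np.any(A <= 0):
        raise ValueError("segment counts must be positive")
    out = A / (4.0 * a * (1.0 - a) * L)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GlobalComparison:
    """Agreement between locus-averaged local ancestry and global ancestry.

    ``pooled_r`` correlates the flattened (individual, population)
    means; ``mean_r``/``sd_r`` summarise per-individual correlations
    over the K populations; deviation is 100 * |local mean - global|,
    averaged per individual then summarised across the cohort.
    """

    pooled_r: float
    mean_r: float
    sd_r: float
    mean_deviation_pct: float
    sd_deviation_pct: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x - x.mean()
    sy = y - y.mean()
    vx = sx @ sx
    vy = sy @ sy
    if vx == 0 or vy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sx @ sy / np.sqrt(vx * vy))


def compare_to_global(
    local: LocalAncestryCallset, global_props: np.ndarray
) -> GlobalComparison:
    """Compare a local-ancestry call set against global ancestry proportions."""
    g = np.asarray(global_props, dtype=float)
    if g.shape != (local.n_individuals, local.K):
        raise ValueError("global_props must be (n_individuals, K)")
    m = local.dosage.mean(axis=0)  # (N, K) locus-averaged local ancestry
    pooled = _pearson(m.ravel(), g.ravel())
    # Per-individual r over the K populations; individuals whose local or
    # global vector is constant contribute no correlation (NaN, skipped).
    per_ind = np.full(len(g), np.nan)
    for i in range(len(g)):
        try:
            per_ind[i] = _pearson(m[i], g[i])
        except ValueError:
            pass
    if np.all(np.isnan(per_ind)):
        raise ValueError("correlation undefined: all per-individual vectors constant")
    dev = np.abs(m - g).mean(axis=1) * 100.0
    ok = per_ind[~np.isnan(per_ind)]
    return GlobalComparison(
        pooled_r=pooled,
        mean_r=float(ok.mean()),
        sd_r=float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
        mean_deviation_pct=float(dev.mean()),
        sd_deviation_pct=float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
    )


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Snap fractional ancestry dosages to the nearest valid diploid state.

    Each K-vector is replaced by the dosage vector of the nearest (in
    Euclidean distance) unordered diploid state; ties are broken in
    population order (lexicographically first state wins).
    """
    dosage = np.asarray(dosage, dtype=float)
    K = dosage.shape[-1]
    states = state_dosages(K)  # (S, K)
    flat = dosage.reshape(-1, K)
    d2 = ((flat[:, None, :] - states[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # first minimum wins the tie
    return states[idx].reshape(dosage.shape)


def _state_index(dosage: np.ndarray) -> np.ndarray:
    """Index of each (SNP, individual)'s unordered diploid state."""
    K = dosage.shape[-1]
    states = state_dosages(K)
    flat = hard_call(dosage).reshape(-1, K)
    d2 = ((flat[:, None, :] - states[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(dosage.shape[:-1])


def diploid_inconsistency(a: LocalAncestryCallset, b: LocalAncestryCallset) -> float:
    """Percentage of (SNP, individual) pairs with differing diploid states.

    Each call is hard-called to one of the K(K+1)/2 unordered diploid
    ancestry states (six for three populations); the metric is 100 times
    the fraction of (SNP, individual) cells whose states differ.
    """
    if a.dosage.shape != b.dosage.shape:
        raise ValueError("call sets differ in shape")
    sa = _state_index(a.dosage)
    sb = _state_index(b.dosage)
    return float(100.0 * np.mean(sa != sb))


def tract_lengths_morgans(hap_paths, target_pop: int) -> np.ndarray:
    """Lengths (morgans) of all target-ancestry segments across haplotypes.

    ``hap_paths`` is a sequence of per-individual (path, path) pairs.
    Each path is binarized to target-vs-other before measuring maximal
    runs, so lengths refer to contiguous target-ancestry tracts.
    """
    lengths: list[np.ndarray] = []
    for pair in hap_paths:
        for path in pair:
            binar = path.binarize(int(target_pop))
            seg = binar.segment_lengths_cm() / 100.0
            lengths.append(seg[binar.labels == 1])
    return np.concatenate(lengths) if lengths else np.empty(0)
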