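"""Simulator for recently admixed cohorts with known local ancestry.

The generator emulates the statistical structure a chromosome-wide
admixture-mapping analysis assumes for a Hispanic/Latino-like cohort:

* three ancestral populations (European, African, Native American by
  default) whose allele frequencies diverged from a shared ancestral
  frequency under drift (Balding-Nichols model);
* per-individual global ancestry proportions drawn from a Dirichlet
  distribution centred near (0.6, 0.1, 0.3);
* ancestry tracts laid down by a Poisson switch process along the genetic
  map, at a rate of ``g`` switches per morgan per haplotype after ``g``
  generations of admixture;
* genotypes drawn per haplotype from the allele frequency of that
  haplotype's local ancestry (sites independent given ancestry);
* blood-pressure-like traits: log-normal systolic/diastolic pressure
  around a linear predictor in age, sex, ancestry and an optional causal
  genotype, plus a binary hypertension status.

All randomness flows from one master seed; each stage (and each
individual haplotype within a stage) uses a substream derived from a
fixed spawn key, so any subset of the cohort is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AncestralPanel, GeneticMap, LocalAncestryCallset, DEFAULT_POPS

__all__ = [
    "TraitSpec",
    "HaplotypePath",
    "SimCohort",
    "draw_ancestral_freqs",
    "simulate_haplotype_path",
    "simulate_cohort",
    "perturb_ancestry",
    "derive_subpop_freqs",
    "stage_rng",
]

# Fixed stage identifiers for seed substreams.
_STAGE_FREQS = 0
_STAGE_MAP = 1
_STAGE_PROPS = 2
_STAGE_PATHS = 3
_STAGE_ALLELES = 4
_STAGE_COVARIATES = 5
_STAGE_TRAITS = 6
_STAGE_PERTURB = 7
_STAGE_SUBPOP = 8


def stage_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for one substream of the master seed.

    Substreams are addressed by a fixed tuple of non-negative integers
    (stage index, then e.g. individual and haplotype index), so the same
    (seed, key) pair always yields the same stream regardless of what
    else has been simulated.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class TraitSpec:
    """Generative model for the blood-pressure-like traits.

    The linear predictor (on the log-mmHg scale) is

        eta_i = intercept + age_effect*age_i + sex_effect*sex_i
                + ancestry_effect*Z_i + genotype_effect*G_i,

    where ``Z_i`` is either the individual's global ancestry proportion
    for ``ancestry_pop`` (``ancestry_scope="global"``) or the local
    ancestry dosage at ``causal_snp`` (``ancestry_scope="local"``), and
    ``G_i`` is the genotype dosage at ``causal_snp`` (0 when no causal
    SNP is set).  SBP is exp(eta + noise); DBP is exp(eta + dbp_offset +
    noise') with independent noise.  Hypertension is either a threshold
    on the SBP liability (threshold chosen to hit ``prevalence``) or a
    Bernoulli draw from a logistic link centred at ``prevalence``.
    """

    intercept: float = math.log(120.0)
    age_effect: float = 0.003
    sex_effect: float = 0.04
    ancestry_effect: float = 0.0
    ancestry_scope: str = "global"  # "global" | "local"
    ancestry_pop: int = 0
    causal_snp: int | None = None
    genotype_effect: float = 0.0
    noise_sd: float = 0.12
    dbp_offset: float = math.log(78.0 / 120.0)
    prevalence: float = 0.33
    binary_mode: str = "liability"  # "liability" | "logistic"

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.ancestry_scope not in ("global", "local"):
            raise ValueError("ancestry_scope must be 'global' or 'local'")
        if self.binary_mode not in ("liability", "logistic"):
            raise ValueError("binary_mode must be 'liability' or 'logistic'")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.ancestry_scope == "local" and self.causal_snp is None:
            raise ValueError("local ancestry effect requires a causal_snp")


@dataclass(frozen=True)
class HaplotypePath:
    """One haplotype's ancestry along the chromosome.

    ``breakpoints_cm`` are the ordered switch positions strictly inside
    ``span_cm``; ``labels`` (one more than the breakpoints) give the
    ancestral-population index of each segment.  Adjacent equal labels
    may occur when self-switches have not been collapsed.
    """

    breakpoints_cm: np.ndarray
    labels: np.ndarray
    span_cm: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "breakpoints_cm", np.asarray(self.breakpoints_cm, dtype=float)
        )
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))
        if len(self.labels) != len(self.breakpoints_cm) + 1:
            raise ValueError("need exactly one more label than breakpoints")
        if np.any(np.diff(self.breakpoints_cm) < 0):
            raise ValueError("breakpoints must be ordered")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative population indices")

    @property
    def n_segments(self) -> int:
        return len(self.labels)

    def collapse(self) -> "HaplotypePath":
        """Merge adjacent segments with identical labels (self-switches)."""
        if len(self.labels) == 1:
            return self
        keep = np.r_[True, np.diff(self.labels) != 0]
        return HaplotypePath(
            breakpoints_cm=self.breakpoints_cm[keep[1:]],
            labels=self.labels[keep],
            span_cm=self.span_cm,
        )

    def binarize(self, target_pop: int) -> "HaplotypePath":
        """Collapse to a two-state path: target population vs everything else."""
        binary = (self.labels == target_pop).astype(np.int64)
        return HaplotypePath(self.breakpoints_cm, binary, self.span_cm).collapse()

    def labels_at(self, positions_cm: np.ndarray) -> np.ndarray:
        """Ancestry label of each query position (cM) along the haplotype."""
        pos = np.asarray(positions_cm, dtype=float)
        idx = np.searchsorted(self.breakpoints_cm, pos, side="right")
        return self.labels[idx]

    def segment_lengths_cm(self) -> np.ndarray:
        """Length in cM of every segment of the (possibly uncollapsed) path."""
        edges = np.r_[self.span_cm[0], self.breakpoints_cm, self.span_cm[1]]
        return np.diff(edges)


@dataclass(frozen=True)
class SimCohort:
    """A simulated admixed cohort with full ground truth."""

    panel: AncestralPanel
    global_props: np.ndarray  # (n, K), rows sum to 1
    hap_paths: tuple[tuple[HaplotypePath, HaplotypePath], ...]
    geno_dosage: np.ndarray  # (n_snps, n), values in {0, 0.5, 1}
    callset: LocalAncestryCallset  # true local ancestry dosages
    phenotypes: pd.DataFrame  # id, age, sex, sbp, dbp, hyp
    g_true: float
    seed: int

    @property
    def n(self) -> int:
        return self.global_props.shape[0]

    @property
    def individual_ids(self) -> np.ndarray:
        return self.callset.individual_ids

    @property
    def local_dosage(self) -> np.ndarray:
        return self.callset.dosage


def _as_probs(v, K: int | None = None) -> np.ndarray:
    p = np.asarray(v, dtype=float)
    if p.ndim != 1 or (K is not None and len(p) != K):
        raise ValueError("ancestry proportions must be a 1-D K-vector")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("ancestry proportions must be non-negative and sum to 1")
    return p / p.sum()


def _balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, drift: float
) -> np.ndarray:
    """Draw derived-population frequencies given ancestral means and drift F.

    Frequencies follow Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance
    F p(1-p).  F -> 0 recovers the ancestral frequency exactly.
    """
    scale = (1.0 - drift) / drift
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def draw_ancestral_freqs(
    n_snps: int,
    K: int = 3,
    divergence: float | tuple[float, ...] = (0.15, 0.15, 0.15),
    seed: int = 0,
    pop_labels: tuple[str, ...] | None = None,
    freq_range: tuple[float, float] = (0.1, 0.9),
    map_length_morgans: float = 2.217,
    chrom: str = "3",
) -> AncestralPanel:
    """Draw an ancestral allele-frequency panel plus a genetic map.

    Per SNP a shared ancestral frequency is drawn uniformly on
    ``freq_range`` (default [0.1, 0.9], avoiding near-fixed sites), then
    each population's frequency is drawn from the Balding-Nichols
    distribution with that mean and the population's drift parameter.
    SNP genetic positions are uniform over a map of
    ``map_length_morgans``; physical positions follow the 1 cM ~ 1 Mb
    convention.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    if K < 1:
        raise ValueError("K must be at least 1")
    div = np.broadcast_to(np.asarray(divergence, dtype=float), (K,)).copy()
    if np.any((div <= 0) | (div >= 1)):
        raise ValueError("each divergence must lie in the open interval (0, 1)")
    if pop_labels is None:
        pop_labels = DEFAULT_POPS[:K] if K <= 3 else tuple(
            f"POP{k}" for k in range(K)
        )
    if len(pop_labels) != K:
        raise ValueError("pop_labels length must equal K")

    rng_map = stage_rng(seed, _STAGE_MAP)
    cm = np.sort(rng_map.uniform(0.0, map_length_morgans * 100.0, size=n_snps))
    if n_snps >= 2:
        # pin the ends so the realized map spans the nominal length exactly
        cm = (cm - cm[0]) / (cm[-1] - cm[0]) * map_length_morgans * 100.0
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    bp = np.maximum.accumulate(bp + np.arange(n_snps))  # enforce strict increase
    gmap = GeneticMap(
        snp_ids=np.array([f"snp{i:05d}" for i in range(n_snps)], dtype=object),
        positions_bp=bp,
        positions_cm=cm,
        chrom=chrom,
    )

    rng_freq = stage_rng(seed, _STAGE_FREQS)
    ancestral = rng_freq.uniform(freq_range[0], freq_range[1], size=n_snps)
    freqs = np.empty((n_snps, K))
    for k in range(K):
        freqs[:, k] = _balding_nichols(rng_freq, ancestral, div[k])
    return AncestralPanel(freqs=freqs, gmap=gmap, pop_labels=tuple(pop_labels))


def simulate_haplotype_path(
    global_props,
    g: float,
    gmap: GeneticMap,
    rng: np.random.Generator | int,
    collapse: bool = True,
) -> HaplotypePath:
    """Simulate one haplotype's ancestry tracts.

    Switch points form a Poisson process of rate ``g`` per morgan along
    the map span; the ancestry at the start and after each switch is an
    independent draw from ``global_props``.  With ``collapse=True``
    (default) switches into the same ancestry are merged, which is the
    convention used for segment counting.
    """
    if g < 0:
        raise ValueError("generations since admixture must be non-negative")
    props = _as_probs(global_props)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = gmap.span_cm
    length_m = (hi - lo) / 100.0
    n_switch = rng.poisson(g * length_m)
    breakpoints = np.sort(rng.uniform(lo, hi, size=n_switch))
    labels = rng.choice(len(props), size=n_switch + 1, p=props)
    path = HaplotypePath(breakpoints, labels, (lo, hi))
    return path.collapse() if collapse else path


def _dirichlet_props(
    rng: np.random.Generator, n: int, mean_props: np.ndarray, concentration: float
) -> np.ndarray:
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    alpha = concentration * mean_props
    props = rng.dirichlet(alpha, size=n)
    # Guard against exact zeros from extreme draws; renormalise.
    props = np.clip(props, 1e-12, None)
    return props / props.sum(axis=1, keepdims=True)


def simulate_cohort(
    panel: AncestralPanel,
    n: int,
    mean_props=(0.6, 0.1, 0.3),
    concentration: float = 10.0,
    g: float = 10.0,
    trait: TraitSpec | None = None,
    seed: int = 0,
) -> SimCohort:
    """Simulate a full admixed cohort with known ground truth.

    Per individual, global ancestry proportions are drawn from
    Dirichlet(concentration * mean_props); two haplotype ancestry paths
    are laid down by the Poisson switch process; each haplotype's allele
    at each SNP is Bernoulli with the panel frequency of that
    haplotype's local ancestry.  Genotype dosage is half the summed
    allele count; the local-ancestry dosage is the average of the two
    haplotype ancestry indicators.  Traits follow ``trait``
    (:class:`TraitSpec`; defaults give null BP-like traits).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    trait = trait or TraitSpec()
    mean = _as_probs(mean_props, panel.K)
    if trait.causal_snp is not None and not (
        0 <= trait.causal_snp < panel.n_snps
    ):
        raise ValueError("causal_snp index outside the panel")

    K = panel.K
    gmap = panel.gmap
    J = panel.n_snps
    cm = gmap.positions_cm

    props = _dirichlet_props(stage_rng(seed, _STAGE_PROPS), n, mean, concentration)

    hap_paths: list[tuple[HaplotypePath, HaplotypePath]] = []
    hap_anc = np.empty((2, J, n), dtype=np.int64)
    for i in range(n):
        pair = []
        for h in range(2):
            path = simulate_haplotype_path(
                props[i], g, gmap, stage_rng(seed, _STAGE_PATHS, i, h)
            )
            pair.append(path)
            hap_anc[h, :, i] = path.labels_at(cm)
        hap_paths.append((pair[0], pair[1]))

    rng_allele = stage_rng(seed, _STAGE_ALLELES)
    q = panel.freqs  # (J, K)
    alleles = np.empty((2, J, n), dtype=np.int8)
    for h in range(2):
        p_h = np.take_along_axis(q, hap_anc[h], axis=1)  # (J, n)
        alleles[h] = (rng_allele.random((J, n)) < p_h).astype(np.int8)
    geno_dosage = (alleles[0] + alleles[1]) / 2.0

    eye = np.eye(K)
    local = 0.5 * (eye[hap_anc[0]] + eye[hap_anc[1]])  # (J, n, K)
    ids = np.array([f"ind{i:04d}" for i in range(n)], dtype=object)
    callset = LocalAncestryCallset(
        dosage=local, gmap=gmap, pop_labels=panel.pop_labels, individual_ids=ids
    )

    rng_cov = stage_rng(seed, _STAGE_COVARIATES)
    age = rng_cov.uniform(20.0, 70.0, size=n)
    sex = rng_cov.integers(0, 2, size=n).astype(np.int64)

    rng_trait = stage_rng(seed, _STAGE_TRAITS)
    if trait.ancestry_scope == "global":
        z = props[:, trait.ancestry_pop]
    else:
        z = local[trait.causal_snp, :, trait.ancestry_pop]
    gcaus = (
        geno_dosage[trait.causal_snp]
        if trait.causal_snp is not None
        else np.zeros(n)
    )
    eta = (
        trait.intercept
        + trait.age_effect * age
        + trait.sex_effect * sex
        + trait.ancestry_effect * z
        + trait.genotype_effect * gcaus
    )
    sbp = np.exp(eta + trait.noise_sd * rng_trait.standard_normal(n))
    dbp = np.exp(
        eta + trait.dbp_offset + trait.noise_sd * rng_trait.standard_normal(n)
    )
    liability = eta + trait.noise_sd * rng_trait.standard_normal(n)
    if trait.binary_mode == "liability":
        thresh = np.quantile(liability, 1.0 - trait.prevalence)
        hyp = (liability > thresh).astype(np.int64)
    else:
        from scipy.special import expit, logit

        lp = logit(trait.prevalence) + (liability - liability.mean()) / trait.noise_sd
        hyp = (rng_trait.random(n) < expit(lp)).astype(np.int64)

    phenotypes = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": sex,
            "sbp": sbp,
            "dbp": dbp,
            "hyp": hyp,
        }
    )
    return SimCohort(
        panel=panel,
        global_props=props,
        hap_paths=tuple(hap_paths),
        geno_dosage=geno_dosage,
        callset=callset,
        phenotypes=phenotypes,
        g_true=float(g),
        seed=int(seed),
    )


def _haploid_pairs(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose hard-called dosage K-vectors into unordered label pairs.

    Returns two (n_snps, n) integer arrays (first label <= second label).
    """
    nz = dosage > 0.25
    first = np.argmax(nz, axis=2)
    last = dosage.shape[2] - 1 - np.argmax(nz[:, :, ::-1], axis=2)
    return first, last


def perturb_ancestry(
    truth: LocalAncestryCallset, flip_rate: float, seed: int = 0
) -> LocalAncestryCallset:
    """Corrupt a call set to emulate disagreement between inference methods.

    At each (SNP, individual) independently with probability
    ``flip_rate``, one of the two haploid ancestry labels (chosen at
    random) is replaced by a different label drawn uniformly from the
    remaining populations.  Dosage invariants are preserved.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    if flip_rate == 0.0:
        return truth
    K = truth.K
    if K < 2:
        raise ValueError("perturbation requires at least two populations")
    rng = stage_rng(seed, _STAGE_PERTURB)
    a, b = _haploid_pairs(truth.dosage)
    J, N = a.shape
    flip = rng.random((J, N)) < flip_rate
    which = rng.integers(0, 2, size=(J, N))
    # new label: uniform over the K-1 labels different from the one replaced
    old = np.where(which == 0, a, b)
    shift = rng.integers(1, K, size=(J, N))
    new = (old + shift) % K
    a2 = np.where(flip & (which == 0), new, a)
    b2 = np.where(flip & (which == 1), new, b)
    eye = np.eye(K)
    dosage = 0.5 * (eye[a2] + eye[b2])
    return LocalAncestryCallset(
        dosage=dosage,
        gmap=truth.gmap,
        pop_labels=truth.pop_labels,
        individual_ids=truth.individual_ids,
    )


def derive_subpop_freqs(
    panel: AncestralPanel,
    pop: str,
    drift: float = 0.02,
    seed: int = 0,
    labels: tuple[str, str] = ("NAM1", "NAM2"),
) -> pd.DataFrame:
    """Split one ancestral population into two weakly drifted subpopulations.

    Emulates having allele frequencies for two tribes of the same
    continental ancestry (e.g. Mayan and Pima for the Native American
    component): each subpopulation's frequencies are Balding-Nichols
    draws around the parent population's frequency with a small drift.
    Returns a frequency table (``snp_id`` plus one column per
    population) suitable for AIM selection.
    """
    if not 0.0 < drift < 1.0:
        raise ValueError("drift must lie in (0, 1)")
    k = panel.pop_labels.index(pop) if pop in panel.pop_labels else None
    if k is None:
        raise ValueError(f"unknown population {pop!r}")
    rng = stage_rng(seed, _STAGE_SUBPOP)
    parent = np.clip(panel.freqs[:, k], 1e-6, 1 - 1e-6)
    out = {"snp_id": panel.gmap.snp_ids}
    for j, lab in enumerate(panel.pop_labels):
        if j != k:
            out[lab] = panel.freqs[:, j]
    for lab in labels:
        out[lab] = _balding_nichols(rng, parent, drift)
    return pd.DataFrame(out)
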