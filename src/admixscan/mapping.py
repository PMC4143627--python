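"""Admixture-mapping and ancestry-adjusted association scans.

Two per-SNP linear regressions drive the analysis of an admixed cohort:

* the admixture-mapping (ancestry-deviation) scan

      y_i = b0 + b1 * Sbar_i + b2 * (S_ij - Sbar_i) + e_i,

  where ``S_ij`` is individual i's local-ancestry dosage for the tested
  population at SNP j and ``Sbar_i`` its chromosome-wide mean; the null
  hypothesis is b2 = 0, i.e. the local ancestry at j carries no signal
  beyond the individual's global ancestry;

* the ancestry-adjusted genotype association

      y_i = b * G_ij + sum_k b_k * (alpha_ijk * q_jk) + e_i,

  where ``G_ij`` is half the nonreference allele count, ``alpha_ijk``
  the local ancestry dosage of population k and ``q_jk`` that
  population's panel allele frequency; the null is b = 0.  The
  ancestry regressors carry each population's expected contribution to
  the genotype, so ancestry-driven (spurious) genotype-trait
  correlation is absorbed.  Following the printed model the fit has no
  intercept by default; ``intercept=True`` adds one.

The trait ``y`` is the residual of the (optionally log-transformed) raw
trait after ordinary least-squares adjustment for age and sex.
Multiple-testing machinery: Benjamini-Hochberg FDR, the median-based
genomic-control inflation factor, and a permutation test on the count of
SNPs whose t-statistic exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import LocalAncestryCallset

__all__ = [
    "ScanResult",
    "PermutationResult",
    "residualize_trait",
    "prepare_trait",
    "AdmixtureScanEngine",
    "AncestryAdjustedScanEngine",
    "GenotypeScanEngine",
    "admixture_scan",
    "ancestry_adjusted_scan",
    "genotype_scan",
    "bh_fdr",
    "genomic_control",
    "permutation_excess_test",
]

_CHI2_1DF_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.454936...
_P_FLOOR = 1e-300  # keep p strictly positive for downstream chi-square maps


def residualize_trait(values, age, sex, log_transform: bool = True) -> np.ndarray:
    """Residuals of a (log-)trait after OLS adjustment for age and sex."""
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if not (len(values) == len(age) == len(sex)):
        raise ValueError("trait and covariate vectors differ in length")
    if log_transform:
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        values = np.log(values)
    X = np.column_stack([np.ones_like(age), age, sex])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def prepare_trait(
    phenotypes: pd.DataFrame, trait: str, log_transform: bool = True
) -> np.ndarray:
    """Residualized analysis trait from a phenotype table.

    Quantitative traits (``sbp``, ``dbp``) are log-transformed by
    default; the binary ``hyp`` status is residualized on age and sex
    without transformation (linear model on 0/1 status).
    """
    if trait not in phenotypes.columns:
        raise ValueError(f"phenotype table has no column {trait!r}")
    log = log_transform and trait != "hyp"
    return residualize_trait(
        phenotypes[trait].to_numpy(),
        phenotypes["age"].to_numpy(),
        phenotypes["sex"].to_numpy(),
        log_transform=log,
    )


@dataclass(frozen=True)
class ScanResult:
    """Per-SNP output of a regression scan."""

    snp_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    df: int
    model: str
    flagged: np.ndarray
    lambda_gc: float

    def __len__(self) -> int:
        return len(self.p)

    @property
    def n_significant(self) -> int:
        """SNPs passing the q < 0.05 FDR cut."""
        return int(np.sum(self.q < 0.05))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "flagged": self.flagged,
            }
        )


class _LinearScanEngine:
    """Batched per-SNP OLS with one target coefficient.

    Precomputes, for every SNP's design matrix X_j (n x p), the
    pseudo-solution operator (X'X)^-1 X' and the target coefficient's
    unscaled variance, so that t-statistics for many trait vectors (e.g.
    permutations) cost only matrix products.  Rank-deficient designs are
    flagged and reported with t = 0, p = 1.
    """

    model = "linear"

    def __init__(self, X: np.ndarray, coef_idx: int, snp_ids=None):
        X = np.asarray(X, dtype=float)
        J, n, p = X.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} individuals for {p} parameters")
        self.X = X
        self.n = n
        self.p = p
        self.df = n - p
        self.coef_idx = coef_idx
        self.snp_ids = (
            np.asarray(snp_ids, dtype=object)
            if snp_ids is not None
            else np.array([f"snp{j:05d}" for j in range(J)], dtype=object)
        )

        xtx = np.einsum("jnp,jnq->jpq", X, X)
        sv = np.linalg.svd(xtx, compute_uv=False)
        self.flagged = sv[:, -1] <= sv[:, 0] * 1e-10
        safe = np.where(self.flagged[:, None, None], np.eye(p)[None], xtx)
        inv = np.linalg.inv(safe)
        self._pinv = np.einsum("jpq,jnq->jpn", inv, X)  # (J, p, n)
        self._dvar = inv[:, coef_idx, coef_idx]  # (J,)

    def t_stats(self, Y: np.ndarray) -> np.ndarray:
        """t-statistics of the target coefficient; Y is (n,) or (m, n)."""
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 1
        if single:
            Y = Y[None, :]
        if Y.shape[1] != self.n:
            raise ValueError("trait vector length does not match the design")
        beta, t = self._fit(Y)[:2]
        return (t[:, 0] if single else t.T)  # (J,) or (m, J)

    def _fit(self, Y: np.ndarray):
        """Full fit for batched traits: beta, t, se arrays of shape (J, m)."""
        B = np.einsum("jpn,mn->jpm", self._pinv, Y)  # coefficients
        xty = np.einsum("jnp,mn->jpm", self.X, Y)
        yty = np.einsum("mn,mn->m", Y, Y)
        rss = np.maximum(yty[None, :] - np.einsum("jpm,jpm->jm", B, xty), 0.0)
        sigma2 = rss / self.df
        se = np.sqrt(np.maximum(self._dvar[:, None] * sigma2, 0.0))
        bt = B[:, self.coef_idx, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, bt / np.where(se > 0, se, 1.0), 0.0)
        t[self.flagged] = 0.0
        return bt, t, se

    def scan(self, y: np.ndarray) -> ScanResult:
        """Run the scan for one trait vector."""
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("scan expects a single trait vector")
        beta, t, se = self._fit(y[None, :])
        beta, t, se = beta[:, 0], t[:, 0], se[:, 0]
        p = 2.0 * stats.t.sf(np.abs(t), self.df)
        p[self.flagged] = 1.0
        p = np.clip(p, _P_FLOOR, 1.0)
        q = bh_fdr(p)
        lam = genomic_control(p) if len(p) >= 10 else float("nan")
        beta = np.where(self.flagged, np.nan, beta)
        se = np.where(self.flagged, np.nan, se)
        return ScanResult(
            snp_ids=self.snp_ids,
            beta=beta,
            se=se,
            t=t,
            p=p,
            q=q,
            df=self.df,
            model=self.model,
            flagged=self.flagged.copy(),
            lambda_gc=lam,
        )


class AdmixtureScanEngine(_LinearScanEngine):
    """Ancestry-deviation scan: y ~ 1 + Sbar + (S_j - Sbar), testing b2."""

    model = "admixmap"

    def __init__(self, callset: LocalAncestryCallset, ancestry="EUR"):
        if callset.n_individuals < 4:
            raise ValueError("admixture scan needs at least 4 individuals")
        S = callset.dosage_for(ancestry)  # (J, n)
        J, n = S.shape
        sbar = S.mean(axis=0)  # unweighted SNP mean per individual
        X = np.empty((J, n, 3))
        X[:, :, 0] = 1.0
        X[:, :, 1] = sbar[None, :]
        X[:, :, 2] = S - sbar[None, :]
        super().__init__(X, coef_idx=2, snp_ids=callset.gmap.snp_ids)
        self.sbar = sbar
        self.ancestry = ancestry


class AncestryAdjustedScanEngine(_LinearScanEngine):
    """Genotype association adjusted for local ancestry, testing b on G."""

    model = "assoc"

    def __init__(
        self,
        geno_dosage: np.ndarray,
        callset: LocalAncestryCallset,
        panel_freqs: np.ndarray,
        intercept: bool = False,
    ):
        G = np.asarray(geno_dosage, dtype=float)
        q = np.asarray(panel_freqs, dtype=float)
        J, n = G.shape
        K = callset.K
        if callset.dosage.shape[:2] != (J, n):
            raise ValueError("genotypes and call set are misaligned")
        if q.shape != (J, K):
            raise ValueError("panel_freqs must be (n_snps, K)")
        p = K + 1 + (1 if intercept else 0)
        X = np.empty((J, n, p))
        X[:, :, 0] = G
        X[:, :, 1 : K + 1] = callset.dosage * q[:, None, :]
        if intercept:
            X[:, :, K + 1] = 1.0
        super().__init__(X, coef_idx=0, snp_ids=callset.gmap.snp_ids)
        self.intercept = intercept


class GenotypeScanEngine(_LinearScanEngine):
    """Unadjusted baseline: y ~ 1 + G_j, testing the genotype slope.

    Provided for contrast with the ancestry-adjusted scan: under
    ancestry confounding this regression rejects far above its nominal
    level.
    """

    model = "naive"

    def __init__(self, geno_dosage: np.ndarray, snp_ids=None):
        G = np.asarray(geno_dosage, dtype=float)
        J, n = G.shape
        X = np.empty((J, n, 2))
        X[:, :, 0] = 1.0
        X[:, :, 1] = G
        super().__init__(X, coef_idx=1, snp_ids=snp_ids)


def admixture_scan(y, callset: LocalAncestryCallset, ancestry="EUR") -> ScanResult:
    """Per-SNP ancestry-deviation regression; tests b2 = 0 (see module docs)."""
    return AdmixtureScanEngine(callset, ancestry).scan(y)


def ancestry_adjusted_scan(
    y,
    geno_dosage: np.ndarray,
    callset: LocalAncestryCallset,
    panel_freqs: np.ndarray,
    intercept: bool = False,
) -> ScanResult:
    """Per-SNP genotype association with local-ancestry adjustment; tests b = 0."""
    return AncestryAdjustedScanEngine(
        geno_dosage, callset, panel_freqs, intercept=intercept
    ).scan(y)


def genotype_scan(y, geno_dosage: np.ndarray, snp_ids=None) -> ScanResult:
    """Per-SNP regression of the trait on genotype only (no adjustment)."""
    return GenotypeScanEngine(geno_dosage, snp_ids=snp_ids).scan(y)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p-values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_control(scan) -> float:
    """Median-based genomic-control inflation factor.

    Each two-sided p-value is mapped to its 1-df chi-square quantile;
    lambda is the median of those quantiles divided by the 1-df
    chi-square median (~0.4549).  Accepts a :class:`ScanResult` or a
    p-value vector of at least 10 entries.
    """
    p = scan.p if isinstance(scan, ScanResult) else np.asarray(scan, dtype=float)
    if len(p) < 10:
        raise ValueError("genomic control needs at least 10 SNPs")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.all(p == 1.0):
        warnings.warn("all p-values equal 1; genomic control degenerate", stacklevel=2)
        return 0.0
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1DF_MEDIAN)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the excess-signal permutation test."""

    threshold: float
    observed: int
    perm_counts: np.ndarray
    p_value: float
    signed: bool

    @property
    def B(self) -> int:
        return len(self.perm_counts)


def permutation_excess_test(
    y,
    scan,
    threshold: float = 3.0,
    B: int = 3000,
    seed: int = 0,
    signed: bool = False,
    chunk: int = 256,
) -> PermutationResult:
    """Permutation test on the count of SNPs with extreme t-statistics.

    The observed statistic is the number of SNPs whose t exceeds
    ``threshold`` (in absolute value by default; ``signed=True`` counts
    t > threshold only).  The trait is permuted uniformly ``B`` times,
    the scan re-fitted, and the count recorded; the empirical p-value is
    (1 + #{b : count_b >= observed}) / (B + 1), never zero.

    ``scan`` may be a scan engine (batched, fast) or any callable
    mapping a trait vector to a t-statistic vector.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def count(t: np.ndarray) -> np.ndarray:
        stat = t if signed else np.abs(t)
        return (stat > threshold).sum(axis=-1)

    if hasattr(scan, "t_stats"):
        observed = int(count(scan.t_stats(y)))
        counts = np.empty(B, dtype=np.int64)
        done = 0
        while done < B:
            m = min(chunk, B - done)
            perms = np.stack([y[rng.permutation(len(y))] for _ in range(m)])
            counts[done : done + m] = count(scan.t_stats(perms))
            done += m
    else:
        observed = int(count(np.asarray(scan(y))))
        counts = np.empty(B, dtype=np.int64)
        for b in range(B):
            counts[b] = count(np.asarray(scan(y[rng.permutation(len(y))])))
    p = (1.0 + np.sum(counts >= observed)) / (B + 1.0)
    return PermutationResult(
        threshold=float(threshold),
        observed=observed,
        perm_counts=counts,
        p_value=float(p),
        signed=signed,
    )
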