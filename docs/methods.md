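# Methods

This note records the models behind `admixscan`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions a maintainer needs.

## The simulator (`simpop`)

The generator emulates the statistical structure of a three-way admixed
blood-pressure cohort on a single chromosome.

**Ancestral allele frequencies.** Per SNP a shared ancestral frequency
is drawn uniformly on [0.1, 0.9] (avoiding near-fixed sites;
configurable), then each population's frequency is a Balding–Nichols
draw, Beta(p(1−F)/F, (1−p)(1−F)/F), with per-population drift F
(default 0.15 each). Note that with two populations each drifted F from
the shared ancestor, the *pairwise* Nei Fst between them is roughly
(F/2)/(1−F/2), about 0.072 at F = 0.15 — the drift parameter is not
itself the pairwise Fst.

**Genetic map.** SNP genetic positions are uniform over the chromosome,
with the first and last SNP pinned so the map spans exactly the nominal
length (default 2.217 morgans, the chromosome-3 figure the admixture
date refers to). Physical positions are 1-based and follow the
1 cM ≈ 1 Mb convention.

**Global ancestry.** Per-individual proportions are
Dirichlet(c · mean) with mean (0.6, 0.1, 0.3) (European, African,
Native American) and concentration c = 10, giving an SD of the
European proportion of ≈ 0.148, in line with the spread reported for
Mexican-American reference cohorts such as 1000 Genomes MXL.

**Tracts.** Each haplotype's ancestry is a Poisson switch process: g
switch points per morgan after g generations of admixture (default 10),
with the ancestry after each switch an independent draw from the
individual's own proportions. Self-switches are collapsed for segment
counting. This yields the two-class diploid switch rate 4a(1−a)g per
morgan that the dating estimator assumes, and interior tract lengths
that are exactly exponential.

**Genotypes.** Each haplotype's allele is Bernoulli with the panel
frequency of its local ancestry — sites are independent given ancestry.
Genotype dosage is half the allele count (0, 0.5, 1); the diploid
local-ancestry dosage is the average of the two haplotype indicators.

**Traits.** Systolic/diastolic pressure are log-normal around a linear
predictor in age (Uniform(20, 70) years), sex (Bernoulli(½)), an
optional ancestry effect (global proportion or local dosage at a causal
SNP) and an optional causal-genotype effect; defaults give a null trait
with intercept log 120 mmHg (DBP offset log 78/120), age slope 0.003
per year and noise SD 0.12 on the log scale (≈ 12% coefficient of
variation). Hypertension is by default a threshold on the SBP liability
calibrated to 33% prevalence (the prevalence of the motivating cohort);
a logistic link is available since the original case definition
("diagnosed at least once") does not pin down a generative model.

**Seeding.** One master seed; every stage, individual and haplotype
draws from a substream addressed by a fixed spawn key, so identical
seeds give bit-identical cohorts and any subset is reproducible.

**What the simulator does not emulate** — and hence what passing tests
do not establish about real data: linkage disequilibrium within
ancestral populations (sites are exchangeable given ancestry, so
window-based LD-aware inference cannot be benchmarked), genotyping
error, family structure, sex chromosomes, and coalescent variation in
tract lengths. Local-ancestry *inference* error is emulated only
abstractly, by `perturb_ancestry` flipping one haploid label per
affected cell; real callers err in spatially correlated blocks.

## AIM selection (`aims`)

Fst is the Nei-style (H_T − H_S)/H_T from population frequencies with
equal weights — the natural estimator when only published frequency
tables (not sample sizes) are available. A SNP enters the panel when
(a) Fst between the two same-continent subpopulations is < 0.1,
(b) all four outgroup-vs-subpopulation Fst values are > 0.2 (strict
inequalities as stated), and (c) greedy left-to-right pruning in map
order finds no retained SNP within a 250-SNP window with genotype
r² ≥ 0.1. Composite (dosage) r² is used so no phasing is required.
Whether the two outgroups must also be differentiated from *each other*
is left to the caller (the condition set is configurable) rather than
hard-coded.

## Segment counting and admixture dating (`ancestry_metrics`)

Segment counts binarize ancestry to target-vs-other, since the
estimator's 4a(1−a) is a two-class switch rate. From haplotype paths
the count is exact; from diploid dosages it is the minimal number of
haplotype changes consistent with consecutive unordered diploid states
(for the binarized case, Σ|Δdosage|/0.5), which can only undercount
switches that fall between adjacent SNPs — negligible at realistic SNP
density (measured < 0.5 segments at 2,000 SNPs).

`N = A/(4a(1−a)L)` is implemented literally, without subtracting the
two baseline segments every diploid carries, to reproduce the printed
arithmetic (A = 25.49 → N ≈ 12.0; A = 22.40 → N ≈ 10.5). The recovery
suite documents the consequence: the estimate exceeds the true g by
about 2/(4a(1−a)L) ≈ 1 generation at these settings. When per-individual
truth is available the package averages per-individual estimates
N_i = A_i/(4a_i(1−a_i)L); with heterogeneous ancestry this has a
constant ≈ +1 bias at every g, whereas plugging the cohort-mean count
into a single a additionally shrinks the estimate by
E[a_i(1−a_i)]/(ā(1−ā)) (≈ 0.91 at concentration 10) per generation.

Hard-calling snaps each dosage K-vector to the nearest of the
K(K+1)/2 unordered diploid states in Euclidean distance, ties broken in
population order. Diploid inconsistency is the percentage of
(SNP, individual) cells whose states differ. Comparison against global
ancestry reports both a pooled correlation (all individual × population
cells) and per-individual correlations over the K populations
(individuals with constant vectors are skipped), plus the mean absolute
deviation in percent.

## Scans and multiple testing (`mapping`)

Traits are log-transformed (binary status is left on the 0/1 scale) and
residualized on intercept + age + sex by OLS; scans therefore test the
residual trait, and permutations permute this residualized vector (the
alternative — re-residualizing within every permutation — changes
nothing in balanced designs and is not done).

Both scans are ordinary least squares with analytic per-SNP designs,
vectorized across SNPs (precomputed (XᵀX)⁻¹Xᵀ per SNP), so thousands of
permutation refits cost matrix products only. S̄_i is the unweighted
SNP mean over the analyzed chromosome. The ancestry-adjusted model is
fitted without an intercept, exactly as written (the α·q regressors do
not span a constant in general); `intercept=True` adds one. Binary
outcomes use the same linear models by default; a logistic route is
deliberately not the reference path. Rank-deficient designs (constant
local ancestry; genotype exactly explained by the ancestry regressors)
are flagged and reported with p = 1 rather than fitted.

FDR is Benjamini–Hochberg step-up (statsmodels) at q < 0.05. Genomic
control maps two-sided p-values to 1-df chi-square quantiles and
divides the median by 0.4549; it is computed from p-values rather than
raw t² so the t-distribution's df matters at small n. A single scan's
λ on one chromosome is inherently noisy (SD ≈ 0.4): ancestry tracts
decorrelate only over ~1/(2g) morgans, leaving ~40 effectively
independent tests regardless of SNP count. Calibration statements in
the test suite therefore pool p-values across independent replicate
cohorts.

The permutation test counts SNPs with |t| above a threshold (default
3; a signed mode counts t > threshold), permutes the trait B times
(default 3,000) and reports the add-one empirical p-value
(1 + #{count_b ≥ observed})/(B + 1), which is never zero. With a high
threshold the count is nearly always zero under the null and the
p-value piles up at 1; uniformity checks use a threshold of 1 where the
count statistic is nearly continuous.

## Power (`powercalc`)

Two-sided two-proportion z-test with pooled-proportion SE under the
null and unpooled SE under the alternative. No method was named for
the original computation; this standard form reproduces the printed
80%/14.4 pair from the printed inputs (MAF 5% → exposure 9.75%,
α = 0.05/37,438, 36 cases/72 controls), and the two-sided choice is
retained for that reason. `grr_for_power` inverts by bisection on
[1, 1000]. At very small samples the continuous approximation differs
from the discrete Monte-Carlo rejection rate by a few percent (≈ 0.83
vs 0.80 at the 36/72 design); agreement is within 0.005 at moderate
sample sizes.

## Problem sizes in the test suite

The statistical acceptance tests use 200 null replicates of 500 SNPs ×
200 individuals for calibration, cohorts of 500 individuals for
parameter recovery at g ∈ {5, 10, 20}, 50 confounded replicates of 300
SNPs × 200 individuals, and 200 permutation runs at B = 99; these sizes
give Monte-Carlo standard errors several times smaller than the asserted
tolerances while keeping the whole suite under a minute of compute.

## I/O conventions (`io`, `cli`)

TSV dialects are tab-delimited, LF-terminated, dot-decimal; `#` lines
are comments, and every CLI subcommand records its `--seed` there.
Genotype files store allele counts 0/1/2 (`NA` missing), halved to
dosages on load; SNPs with > 20% missingness are dropped at load time,
mirroring the usual QC rule. VCF input (cyvcf2) keeps biallelic records
only and assumes pre-harmonized strand orientation; without a genetic
map, cM positions default to the 1 cM/Mb convention. Positions are
1-based; centimorgans in files, morgans in rate formulas. Floats
round-trip bit-exactly (writers use shortest-repr, the reader parses in
round-trip mode).
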