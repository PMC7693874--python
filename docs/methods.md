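# Methods

This note documents the models implemented in `plastiqtl`, the defaults and
numerical choices, what the bundled simulator does and does not emulate, and
the known limitations.

## Data model

Genotypes are haploid dosages coded 0/2 (minor/major parental allele) for n
segregants × M biallelic markers, with a marker map of 1-based physical bp
positions, strictly increasing within chromosomes. Phenotypes are an n × E
matrix of normalized growth, one column per environment; missing values are
explicit NaN ("NA" on disk), never silent zeros. Row alignment between the
two containers is validated, not assumed. Monomorphic markers are rejected
at construction: they carry no mapping information and break the
frequency-weighted kinship and LD computations.

Missing-data policy: measures and scans drop individuals per-analysis rather
than imputing. PCA and the Finlay–Wilkinson fit use complete rows only
(dropped rows carry NaN scores); VAR, DIFF and DOT are row/pairwise
complete; each association scan subsets individuals with an observed
phenotype and recomputes the kinship eigensystem on that subset. Dropping is
conservative and keeps every reported quantity attributable to observed
data.

## Plasticity measures

With Y the n × E phenotype matrix:

- **PCA1/PCA2** — scores on the first two right-singular directions of the
  column-centered Y. Columns are centered but not scaled by default, since
  growth phenotypes are assumed pre-normalized per environment; a scaling
  flag exists. Sign convention: the largest-magnitude element of each
  loading vector is positive, which fixes the arbitrary SVD sign and makes
  scores reproducible across runs and BLAS builds.
- **VAR** — per-row sample variance with denominator E−1.
- **FWR** — per-segregant ordinary least squares of y_ij on the environment
  index E_j = (column mean) − (grand mean), the classic Finlay–Wilkinson
  setup when no external environment covariate exists. The plasticity score
  is the slope b_i itself, not b_i − 1 (a monotone rescaling that leaves
  association results unchanged). Σ_j E_j = 0 by construction and the mean
  slope over complete rows is exactly 1. A degenerate run with all
  environment means equal (zero index spread) is rejected.
- **DIFF(e1,e2)** — raw difference of the two columns, pairs enumerated in
  lexicographic label order; antisymmetric under pair reversal.
- **DOT(e1,e2)** — product of the two columns after centering and scaling
  each to unit *sum of squares* (not unit variance — the two differ by a
  factor n−1), so the scores of a pair sum exactly to the Pearson
  correlation of the environments. This identity is tested to 1e−10.

With E = 18 environments the specific measures number 2·C(18,2) = 2·153.
DIFF is sensitive to per-environment location shifts; DOT and PCA are not.

## Kinship and variance components

The genomic relationship matrix is the allele-frequency-weighted IBS matrix

  G_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m) / (4 p_m (1 − p_m)),

with p_m the sample frequency of the allele coded 2. For haploid dosages
each standardized marker has unit variance, so diag(G) has expectation 1 and
unrelated pairs expectation 0. Allele frequencies always come from the
sample itself.

Heritability is the intraclass correlation σ²_g/(σ²_g+σ²_e) of the polygenic
model y = Xb + g + e, g ~ N(0, σ²_g G), e ~ N(0, σ²_e I), fitted by REML.
The random effect is realized through one eigendecomposition G = U S U'
(equivalent to any factorization Z with ZZ' = G, and robust when G is near
singular). In the rotated basis the covariance is diagonal, so the
restricted likelihood reduces to a 1-D profile over the variance ratio
δ = σ²_e/σ²_g, maximized by bounded Brent search on log δ ∈ [−14, 14] with
tolerance 1e−8; an optimum at either end is flagged `at_boundary` (the high
end encodes σ²_g → 0, i.e. h² ≈ 0). The restricted log-likelihood includes
its full constant (with log|X'X|), so it is directly comparable to a dense
multivariate-normal evaluation; the test suite checks agreement to 1e−6.
Tiny negative eigenvalues beyond −1e−8 (relative) are rejected as non-PSD;
smaller ones are floored at zero.

## Association scans

Scans are two-stage, the common mixed-model GWAS compromise: variance
components are estimated once under the null (covariates in the fixed part)
and held fixed while each marker is tested by generalized least squares
under V = σ²_g G + σ²_e I. After rotating y, the covariates and the
genotype matrix by U', each marker test is O(n) via a Schur-complement
update of the covariate block. This is approximate relative to per-marker
REML; the approximation is standard and the zero-kinship limit collapses
exactly to OLS with the null-model residual variance. The Wald statistic is
referred to the standard normal; p-values are clipped into (0, 1].

Markers collinear with the covariates (e.g. a marker conditioned on itself,
or a perfect LD proxy) are recorded with β = 0, p = 1 and a `collinear`
flag rather than raising — a scan always returns M rows.

The kinship includes all markers (no leave-one-chromosome-out). One
consequence, documented deliberately: part of a strong causal marker's
signal is absorbed by G, so realized standard errors exceed the naive
σ/√n figure — effect sizes for power planning should be calibrated by
simulation, as done for the bundled study presets (below).

**Effective marker number.** Me is computed per chromosome from the
eigenvalues λ of the marker–marker correlation matrix with the Li–Ji
composition f(λ) = 1(λ ≥ 1) + (λ − ⌊λ⌋), summed over chromosomes
(cross-chromosome LD is 0 in expectation in an intercross; this avoids an
M × M eigendecomposition). Eigenvalues within numerical noise (1e−9,
relative) of an integer are snapped before flooring, since f is
discontinuous there — a duplicated marker pair has spectrum {2, 0} and must
count as exactly 1. The estimator is selected by name and pluggable. The
genome-wide threshold is α/Me (default α = 0.05); Bonferroni over M is
available as the conservative fallback.

**Peaks and conditional analysis.** Significant markers are grouped per
chromosome, joining consecutive significant markers closer than a merge
window (default 100 kb — above the local LD scale of a dense cross, well
below chromosome arms); the lead is the minimum p, ties broken toward the
smaller position. Conditional analysis re-scans with all current peak leads
as fixed covariates, adding leads of any newly significant peaks, until a
round adds nothing or 10 rounds elapse. It operates on individual-level
data, not summary statistics.

## Hub overlap and profiles

A peak and a hub locus overlap when the lead marker is within 50 kb of the
hub position **and** r² between lead and the hub's nearest genotyped marker
exceeds 0.5. Both quantities are always computed and reported; pairs on
different chromosomes are non-overlapping with r² undefined. Hub positions
resolve to the nearest marker with a hard 10 kb cap, beyond which resolution
fails loudly (reported rows are flagged unresolved, not dropped). Distances
are measured between lead-marker and hub positions, matching the convention
of naming loci by single positions. The criteria are monotone: relaxing
either bound never removes an overlap.

Detection frequency counts, per locus and per scan category, the scans in
which an overlapping peak exists; the unique-QTL count merges peaks across
scans by single linkage under the same distance+LD rule (one defensible
choice among several; single linkage is the most inclusive).

The hub profile regresses each environment's growth on the hub marker (same
LMM machinery, genome-wide kinship) and reports the Pearson correlation,
with two-sided p, between the per-environment β vector and the number of
active epistatic interactors per environment. Constant interactor counts
leave the correlation undefined and are flagged rather than guessed.

## The simulator

`simulate_cross` draws each haploid segregant as a mosaic of the two
parental haplotypes under Haldane's no-interference model: crossover counts
per chromosome are Poisson(length_cM/100) with uniform positions, which
makes the number of crossovers in each inter-marker interval independent
Poisson(d/100) draws; an odd count switches parental origin. Marker
positions are evenly spaced in cM and bp. The Haldane recombination fraction
r = (1 − e^(−2d/100))/2 gives closed-form oracles for the tests. Markers
monomorphic by sampling chance (only relevant at small n) are repaired by
flipping one random segregant.

`simulate_phenotypes` draws

  y_ie = μ_e + Σ_k β_ke x_ik + Σ_hub Σ_radial mask_e γ (x_hub/2)(x_radial/2)
         + g_i + ε_ie,

with μ_e ~ N(0, mu_env_sd²) once per simulation, ε ~ N(0, σ²_e), and a
polygenic g built from one small random effect per marker, rescaled so its
realized variance is exactly h²/(1−h²)·σ²_e (so the per-environment
heritability equals `h2_polygenic` when the architecture is empty). The
polygenic term is shared across environments: it moves trait means, not
plasticity. Epistatic terms use dosage/2 ∈ {0,1} products, so γ is the
effect of carrying both "1" alleles. Everything is deterministic given the
seed, with independent substreams for genotypes and phenotypes.

The recorded truth includes, per hub, the per-environment interactor count
(mask column sums) and the per-environment marginal additive effect defined
as the regression slope of the noise-free genetic value on hub dosage — for
unlinked radials at frequency ½ this is γ·k_e/4 per unit dosage in an
environment with k_e active radials.

### Default study conditions

The desk-scale preset is n = 1000 segregants, 16 chromosomes × 125 markers
(M = 2000), each 300 cM / 750 kb, E = 18 environments, h² polygenic 0.3,
σ_e = 1, mu_env_sd = 0.5. The genome mimics yeast: ~4800 cM and ~12 Mb
total at ~0.4 cM/kb, giving the extensive LD of a dense biparental cross
(Me ≈ 500 of 2000 markers; genome-wide cutoff ≈ 1×10⁻⁴). The default hub
architecture is one hub with 8 unlinked radial partners, each active in a
random half of the environments, so the interactor count varies between 1
and 7 across environments.

Two effect sizes ship as calibrated defaults, chosen by simulation so the
focal test clears the Me threshold with high (>90%) power under the preset:
the hub interaction γ = 0.6 and the two-locus additive effect β = 0.42 (per
unit dosage). Closed-form non-centrality calculations understate the
required effects here for two reasons: the genome-wide kinship absorbs part
of a tested marker's signal, and the random covariation between environment
means and hub activity adds noise to the Finlay–Wilkinson slope signal that
scales linearly in γ while the systematic signal scales quadratically.
Calibration was therefore done by pilot simulation, once, and frozen.

### What the simulator does not emulate

Crossover interference, mutation, segregation distortion, genotyping error,
missing genotypes, allele frequencies away from ½, more than two parental
haplotypes, shared environmental (batch) effects, non-Gaussian growth noise
and heteroscedasticity across environments. Passing tests on simulated data
therefore demonstrate the statistical machinery — identities, calibration,
power and mechanism recovery under the stated model — not robustness to the
measurement artifacts of real colony-size data.

## Pipeline

`pipeline.run` executes simulate/read → plasticity → kinship → Me/threshold
→ per-phenotype heritability and scans (trait means, overall measures,
specific measures) with optional conditional analysis → peaks → hub overlap
and detection frequency → summary, writing every stage artifact and a
manifest under the output directory; every summary number is recomputable
from the stage files. Runs are deterministic given the seed; scans are
independent across phenotypes, so results do not depend on execution order.
Full-scan tables are written for overall/trait-mean scans by default
("all"/"none" configurable) to keep output volumes sensible with hundreds
of specific scans.

Problem sizes used by the verification studies (tests and
`scripts/acceptance.py`) follow the preset: n = 1000, M = 2000, with 20
replicates for the stochastic recovery studies and 15 phenotype replicates
for null calibration — sizes at which each study completes in seconds to a
couple of minutes on one CPU while leaving Monte-Carlo margins well clear of
the thresholds checked.

## Known limitations

- Two-stage scans understate per-marker uncertainty slightly relative to
  per-marker REML; with n = 1000 the difference is negligible and the dense
  GLS equivalence is exact by construction.
- No LOCO kinship: strong loci lose some power (documented above); mapping
  positions are unaffected.
- The GenABEL `ibs(weight='freq')` matrix used in the original analyses may
  differ from the standardization here by a constant factor; the contract
  enforced (unit-diagonal expectation, zero expectation for unrelateds)
  makes h² invariant to such rescaling.
- The Finlay–Wilkinson score maps plasticity onto a single slope; genotypes
  whose response pattern is orthogonal to the environment-mean axis appear
  non-plastic to FWR (but not to VAR/PCA/pairwise measures).
- PLINK input is read-only and restricted to homozygous calls, as produced
  by haploid data coded diploid-homozygous; heterozygous or missing bed
  codes are rejected rather than imputed.
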