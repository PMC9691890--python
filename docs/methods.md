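# Methods

`hybridgp` analyses North Carolina II (NC-II) breeding experiments: a set of
candidate inbred lines is crossed to a small set of testers, the hybrids are
phenotyped in multi-environment replicated trials, and the parents are
genotyped on a SNP panel. The package covers the whole chain from parental
VCF to cross-validated genomic-prediction accuracies, plus a synthetic-data
generator that makes every stage testable without field data.

## The NC-II mixed model

For hybrid phenotypes `y` the model is

    y = mu + E + R(E) + GCA_L + GCA_T + SCA
        + GCA_L×E + GCA_T×E + SCA×E + eps

with environment `E` and replicate-within-environment `R(E)` fixed, and line
GCA, tester GCA, SCA and their environment interactions random with
independent variances. Replicates are treated as nested in environments —
the standard randomized-complete-block trial structure — although the model
formula is often written with an unnested `R`.

Variance components are estimated by average-information REML on the
marginal covariance `V = Σ_k σ²_k Z_k Z_kᵀ + σ²_e I`, with:

* step-halving only as a divergence guard (near the optimum the restricted
  likelihood can be numerically flat in small components, so Newton steps
  are accepted on the strength of the score);
* a trust region (at most a five-fold change per component per iteration) —
  degenerate noise-free responses otherwise drive the ill-conditioned AI
  matrix to propose wild steps along a likelihood ridge;
* an active set: components at the positivity floor with negative score are
  pinned there, which is both the correct boundary solution and necessary
  for fast convergence when a true component is zero;
* truncation at zero on exit, with a flag per component.

On balanced complete layouts the REML solution coincides with the closed-form
expected-mean-squares ANOVA estimator whenever the latter is in the interior
of the parameter space; `anova_mom_ncii` implements that estimator
independently and the test suite asserts agreement to 1e-6 relative
(machine precision in practice).

GCA/SCA effects are BLUPs given the estimated components
(`û_k = σ²_k Z_kᵀ P y`); on balanced data they sum to zero within each margin
because the projector `P` annihilates the intercept.

Heritabilities:

* GCA heritability on the line-mean basis:
  `H²_GCA = (σ²_GCA_L + σ²_GCA_T) / (σ²_GCA_L + σ²_GCA_T + σ²_SCA/t +
  σ²_GCA_L×E/e + σ²_GCA_T×E/e + σ²_SCA×E/(t·e) + σ²_eps/(t·e·r))`
  with `t` testers, `e` environments, `r` replicates.
* Entry-mean heritability from a hybrid-level random model:
  `h² = σ²_G / (σ²_G + σ²_GE/e + σ²_eps/(e·r))`.

Entry means for prediction are BLUEs from the fixed model
`y = mu + env + rep(env) + hybrid` with sum-to-zero environment and
replicate contrasts, so on balanced data the BLUE equals the raw hybrid mean
and on unbalanced data it is the least-squares adjusted mean. A disconnected
hybrid × environment layout is rejected.

## Marker filtering and diversity

Per-call masking sets genotypes with read depth < 11 or genotype quality
< 20 to missing. Marker-level filters then remove markers with minor allele
frequency ≤ 0.05 (the boundary is removed), missing rate > 10%, or
heterozygous-call rate > 1% — the parents are inbred lines, so residual
heterozygosity flags unreliable assays. Heterozygosity is a per-marker rate
by default (a per-sample view can be derived from the dosage matrix
directly); allele frequencies are estimated from non-missing calls only,
with a heterozygote contributing one copy of each allele.

Diversity statistics per biallelic marker with allele frequencies `p, q`:
gene diversity `GD = 1 − p² − q² = 2pq` and polymorphic information content
`PIC = 1 − (p² + q²) − 2p²q² = GD − 2p²q²`, with maxima 0.5 and 0.375 at
`p = 0.5`.

## Predictor codings

* Parental coding (GCA prediction): hom-ref −1, het 0, hom-alt +1. Missing
  cells are imputed by seeded random draws from the marker's observed
  genotype-class frequencies, applied to the parents before any hybrid
  coding (hybrids are in-silico and inherit the imputed parental calls).
* Hybrid additive code `A = E[F1 alt dosage] − 1`: −1/0/+1 for hom × hom
  matings, −0.5 and +0.5 for hom × het matings, 0 for het × het.
* Hybrid dominance code `D = P(F1 heterozygous)`: 0 for identical
  homozygotes, 1 for opposite homozygotes, 0.5 whenever one parent is
  heterozygous — including the het × het mating, which is not covered by
  the ±0.5 rules; the expectation logic that generates those half-codes
  gives it 0.5 as well.

The orientation (which homozygote is −1) is fixed to the reference allele;
the sign is irrelevant to every downstream model but pinned for
reproducibility.

## Genomic-prediction models

All five models share the form `y = 1·mu + Σ_t g_t + e` with one genetic
term per coding (A, or A and D with independent variances).

* **GBLUP**: `g_t ~ N(0, σ²_t K_t)` with `K_t = Z_c Z_cᵀ / c`, `Z_c` the
  column-centred coded matrix and `c` the sum of its column variances. This
  scaling stays meaningful for the fractional hybrid codes, where
  allele-frequency-based scalings are undefined. Components by REML: an
  exact eigenbasis profile-likelihood search for a single kernel, the
  general AI-REML engine for several.
* **RKHS**: Gaussian kernels `K_h = exp(−h · D / mean(D))` with `D` the
  squared-Euclidean row distances of the coded matrix, over bandwidths
  `h ∈ {0.1, 0.5, 2.5}` fitted jointly, each with its own variance (kernel
  averaging). Dividing `D` by its mean makes the stated bandwidths span
  weak-to-strong locality regardless of marker count. Components by Gibbs
  sampling on the kernel eigenbasis (orthonormal eigenvectors make the
  coefficient full-conditionals diagonal), scaled-inverse-χ² updates for the
  variances.
* **Bayes A**: per-marker scaled-inverse-χ² effect variances (scaled-t
  shrinkage), single-site Gibbs.
* **Bayes C**: spike-and-slab with a common slab variance per term and the
  inclusion probability `π` estimated under a Beta(1, 9) prior.
* **Bayesian LASSO**: Park–Casella normal–exponential scale mixture with a
  per-term Gamma hyperprior on λ².

Hyperpriors are weakly informative throughout: df = 5 for effect and
residual scaled-inverse-χ² priors, prior scales solved so that half the
response variance is attributed to the genetic terms (split equally across
terms) and half to the residual. Default chain settings are 12,000 Gibbs
iterations, 3,000 burn-in, thinning 5; posterior means are taken over
retained draws. The demo profile reduces this to 2,000/500 — enough for
point prediction, as the convergence-stability test (doubling iterations
changes genetic values negligibly) shows at desk scale. The marker samplers
are numba-compiled: single-site updates are inherently sequential and would
otherwise dominate the runtime.

Prediction for new rows uses `X_new β̂` for marker models and cross-kernel
BLUP (`K_cross α` with training `α = σ² V⁻¹(y − Xβ̂)`, or its posterior-mean
analogue `K⁻¹u` for sampled kernel models). Predicting a training row
reproduces its fitted value exactly for GBLUP.

## Cross-validation

Repeated k-fold CV (default 10 folds × 100 repeats; desk-scale runs use
fewer repeats) with seeded partitions: fold sizes differ by at most one,
every row is in exactly one test fold per repeat, and the partition is
asserted valid on every run. Accuracy is the Pearson correlation between
predictions and observed response per test fold, averaged over folds and
repeats; the pooled-per-repeat correlation is reported alongside. Folds with
a constant observed response are recorded as undefined and excluded from
the mean with a count.

GCA prediction cross-validates lines only (4–8 testers are too few to fold)
against the mixed-model GCA estimates; hybrid prediction uses entry-mean
BLUEs. Model comparisons report `100·(acc_b − acc_a)/acc_a` plus paired
per-fold differences. Marker-subset experiments pair a "functional" subset
with a same-size seeded random draw from the disjoint remainder. Cross-panel
work intersects markers on (chrom, pos, ref, alt), flagging allele-swapped
matches for downstream sign-flipping.

A note on null calibration: for a fixed response/genotype draw the
fold-mean correlation has a chance component of magnitude ~sqrt(2/n) that
repeats cannot average away (correlation is scale-invariant, so shrinkage
does not suppress it). Null checks therefore re-permute the response per
repeat; with 20 permutation repeats at n = 400 the null band ±0.05 holds
with a comfortable margin.

## Population structure

Identity-by-state distance `d(i,j) = 1 − mean(1 − |a − b|/2)` over markers
non-missing in both samples, and UPGMA (proportional average linkage) with
ultrametric heights equal to half the merge distance, exported as Newick.
The linkage step uses scipy's average-linkage implementation; tree
construction, cophenetic distances and Newick serialization are local so
branch lengths and tie behaviour are fully specified. Cluster-vs-truth
concordance cuts the tree at k clusters and greedily matches clusters to
true groups.

## Synthetic data

The generator emulates the study design end to end:

* **Founders**: ancestral allele frequencies uniform(0.1, 0.9); per
  subpopulation frequencies Beta-distributed around the ancestral value with
  dispersion governed by `fst` (Balding–Nichols construction); samples
  assigned to subpopulations round-robin; fully inbred genotypes (one allele
  draw doubled) with residual heterozygous calls at 0.5% and missing calls
  at a configurable rate; markers spread evenly over 10 chromosomes with
  increasing positions.
* **Traits**: `n_qtl` markers receive additive effects ~N(0,1) and dominance
  effects rescaled so the realized dominance/additive variance ratio equals
  `dominance_ratio`. Hybrid genotypic values use the expected-F1 codes, so
  the A/D coding invariants hold by construction at the QTL.
* **Truth**: GCA = marginal means of genotypic values, SCA the remainder;
  `mu + GCA_L + GCA_T + SCA` reconstructs every genotypic value exactly,
  also on incomplete designs.
* **Phenotypes**: environment and replicate main effects at fixed relative
  scale (σ_E = 0.5·σ_G, σ_R = 0.1·σ_G — real trials show clear environment
  effects but the scale is a convention); per-hybrid-per-environment G×E
  draws at `gxe_ratio·σ²_G` (iid cell effects, which is exactly an SCA×E
  term); residual variance solved so the entry-mean heritability equals
  `h2_entry`, with unreachable targets rejected.

Defaults (120 lines × 4 testers, 1000 markers, 3 subpopulations, Fst 0.15,
50 QTL, dominance ratio 0.5, h² 0.7, 2 environments × 2 replicates) mirror a
mid-sized maize breeding population. What the generator does **not**
emulate: linkage and recombination (markers are exchangeable within
chromosomes), multi-generation selection, non-Gaussian trait architectures,
and assay artefacts beyond random missingness — so passing tests demonstrate
correctness of the estimators under the stated model, not robustness to
real-data pathologies such as LD structure or batch effects.

All randomness in a simulation flows from one seed through spawned
generator streams, and the pipeline derives every stage seed from a single
global seed, making full runs byte-for-byte reproducible.

## Problem sizes and numerical choices

Desk-scale test sizes were chosen so each property is measured well away
from its tolerance: REML-vs-ANOVA agreement and parameter recovery on
100 × 4 × 2 × 2 balanced trials (1600 observations, 20 seeds); sampler
calibration on n = 400, 500 markers, 20 QTL, h² = 0.6 (10 seeds); AD-vs-A
directionality on 60 × 4 designs (10 seeds per dominance level). REML
converges at relative log-likelihood change < 1e-12 (60 iterations max);
kernel eigenvalues below 1e-8 of the maximum are dropped; Gibbs chains in
tests use 4,000–6,000 iterations. Known limitations: no multi-trait REML,
no spatial field models, no epistasis, no untested-line CV partitions
(plain random folds only), and component standard errors come from the
asymptotic AI-matrix inverse.
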