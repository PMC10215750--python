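# Methods

## The problem

Embryo-transfer centers repeatedly superovulate donor cows and record,
per flush, the total number of embryos and oocytes collected (TNE) and
the number of good (freezable, grade-1) embryos (NGE).  Both traits are
lowly-to-moderately heritable and repeatable, so donors can be ranked
by estimated breeding values (EBVs).  Only a minority of donors are
genotyped, which makes single-step GBLUP (ssGBLUP) — BLUP on a combined
pedigree/genomic relationship matrix **H** — the natural evaluation:
non-genotyped animals stay in the analysis through the pedigree while
genotyped animals contribute realized marker-based relationships.

This package implements that evaluation end to end: relationship
matrices, variance-component estimation, breeding-value prediction with
reliabilities, and a selection/kinship diagnostic, together with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes so every stage is testable without proprietary herd
data.

## Model

For traits *i* ∈ {TNE, NGE},

    y_i = X_i b_i + Z_i a_i + W_i pe_i + e_i

with fixed effects year, month, superovulation program, technician, and
linear plus quadratic age-in-months covariates; additive genetic
effects `a` with var(a) = Ga ⊗ K for K ∈ {A, H}; permanent
environmental effects `pe` (one level per donor, shared by all her
flushes) with var(pe) = Gpe ⊗ I; and residuals with var(e) = Re ⊗ I.
Both traits are measured on every flush, so residuals are correlated
within a record.  Ga, Gpe, Re are free 2×2 covariance blocks.

Derived parameters: h² = σ²ₐ/(σ²ₐ+σ²ₚₑ+σ²ₑ), repeatability =
(σ²ₐ+σ²ₚₑ)/(same), genetic correlation r_g = σ_a12/√(σ²ₐ₁σ²ₐ₂).

The model is Gaussian although the traits are counts; this follows
standard practice for these traits and the generator's default output
is accordingly on the raw Gaussian scale (a count-rounding mode exists
to probe robustness, and the strict readers validate count files).

## Relationship matrices

* **A** — numerator relationship matrix by the tabular method (dense
  recursion, parents before offspring).  Dense O(n²) memory is a
  deliberate choice for desk-scale pedigrees (≤ ~10⁴ animals);
  transparency beats the indirect sparse methods of national
  evaluations at this size.
* **A⁻¹** — Henderson's rules with Mendelian-sampling variances that
  use parental inbreeding (Meuwissen–Luo-style inbreeding computation),
  so the inverse is exact on inbred pedigrees.  Unknown parents are
  unrelated, non-inbred base animals; no unknown-parent groups or
  metafounders.
* **G** — VanRaden method 1, `G = ZZ'/(2Σp(1−p))` with dosages centered
  at twice the counted-allele frequency.  Frequencies are computed from
  the genotyped animals themselves (a documented source of possible
  scale bias; the frequency source is a config field).  QC order is
  samples → markers → frequencies → imputation → G; all thresholds
  (MAF > 0.01, call rate > 0.95, HWE p > 0.001) are strict
  inequalities.  The HWE test is a 1-df χ² goodness-of-fit without
  continuity correction.  Missing-dosage fill-in is frequency-based
  (expected dosage 2p, or a binomial draw) — a stand-in for haplotype
  phasing that preserves first moments and ignores linkage, which is
  second-order for G at sub-percent missingness.
* **G\*** = 0.95 G + 0.05 A22 (configurable τ/ω with τ+ω = 1).  No
  additional compatibility scaling of G toward A22 is applied by
  default; a scaling option exists but is off.
* **H** — the block-correction identity on (non-genotyped, genotyped)
  ordering, and H⁻¹ = A⁻¹ plus the genotyped-block update
  G\*⁻¹ − A22⁻¹.  All inversions use symmetric (Cholesky)
  factorization; singularity is reported as an error with a remedy
  hint, never silently pseudo-inverted.

The kinship coefficient used throughout the selection diagnostics is
the correlation-style standardization R_ij = m_ij/√(m_ii m_jj) — not
the classical coancestry ½a_ij.  R_ii = 1 for every individual, and
genomic R_ij can be negative.

## Mixed-model equations and reliability

Henderson's MME are assembled trait-major (trait ⊗ level) from
single-trait cross-products and solved by dense Cholesky.  `Z` spans
every pedigree animal, so relatives without records receive EBVs.
Identifiability uses one intercept with drop-first reference coding per
factor; the age covariate is centered at the sample mean (recorded in
the design metadata) with the quadratic computed on the centered value.
Estimable functions, EBVs and the likelihood are invariant to these
choices (tested).

PEVs are the animal-block diagonal of the inverse coefficient matrix —
a dense symmetric inverse, no approximation — and reliability is
rel = 1 − PEV/(k_ii·σ²ₐ) with k_ii from the same K used in the solve.
Negative values larger than −1e-10 (roundoff) are clamped to 0.  Four
prediction settings are crossed: {A, H} for the MME × {A-estimated,
H-estimated} components, each result tagged with both matrices.

## AI-REML

The restricted likelihood is evaluated through the MME factorization
(log|C|, log|K|, log-determinants of the covariance blocks and y'Py),
so cost scales with the number of equations rather than records.
Parameters are the distinct entries of Ga, Gpe, Re.

* 3 EM-REML warm-up iterations, then average-information updates.
* Step-halving (≤ 10 times) guarantees the restricted likelihood never
  decreases across accepted iterations (asserted in tests).  Proposals
  that leave the positive-definite cone are first handled by shortening
  the step — this keeps iterates interior and well-conditioned when the
  optimum sits on a boundary (e.g. r_g → 1) — with eigenvalue flooring
  at 1e-6 × trace only as a last resort (every bend is logged).  If no
  AI step improves, an EM update is taken instead (EM cannot decrease
  the likelihood).
* Convergence: relative parameter-update norm < 1e-8, or two
  consecutive accepted iterations gaining < 1e-7 in −2logL.  The second
  rule terminates boundary optima where parameters creep along a flat
  likelihood ridge; it was verified to leave estimates unchanged to
  four decimals relative to running the ridge out for hundreds of
  iterations.  An absolute gradient-norm gate is not used because the
  gradient scale depends on the data; the gradient norm is recorded in
  the result instead.  Non-convergence at `max_iter` is flagged, with
  the last iterate retained.
* Starting values: equal thirds of the phenotypic variance per trait,
  zero covariances.
* Standard errors: inverse of the final AI matrix; derived-parameter
  SEs by the delta method with a central-difference Jacobian.  Reported
  SEs calibrate within a factor 1.5 of the replicate-to-replicate SD of
  estimates in simulation (tested).

## Selection diagnostics

Top-n truncation selection on EBVs (ties at the cutoff break by id
order, logged).  Agreement between settings: concordance rate
100·|A∩B|/n, plus Pearson/Spearman EBV correlations.  The mean pairwise
kinship of a selected set is compared against an empirical null built
from uniform random n-subsets of the candidates (default 10⁶ draws as
configured, scaled to 10³–10⁵ in tests; the Monte-Carlo standard error
is reported alongside).  The p-value is the simple upper-tail
proportion #{draws ≥ observed}/N — elevated kinship among selected
elites is the anomaly of interest — with a (k+1)/(N+1) variant as an
option.  Pedigree kinship for this diagnostic always comes from the
full-pedigree A (enforced by matrix kind), not from A22.

## Synthetic data generator

The generator emulates a donor herd at desk scale:

* **Pedigree** — generation 0 founders; each later generation's females
  are sired from a small pool with geometrically decaying use
  (0.5, 0.25, … — a few sires dominate, as in intensively selected
  beef cattle); a fraction (default 0.15) of donors are "introduced":
  recorded with unknown parents but truly descended from a pool sire
  and an outside dam.  Genotypes are gene-dropped through this *true*
  pedigree while analyses see only the recorded one — exactly the
  mechanism by which genomic relationships add information for
  shallow-pedigree animals in real donor herds.
* **Genotypes** — unlinked biallelic markers (founder frequencies
  ~ U(0.1, 0.9)), one uniformly chosen allele transmitted per parent
  per marker.  No linkage map: the G-matrix expectation and all ssGBLUP
  machinery need none at this scale (documented limitation: no LD, no
  chip-ascertainment emulation).  E[G] ≈ A over replicates (tested).
* **True breeding values** — drawn with covariance Ga ⊗ K where K is
  the pedigree A, the single-step H built from the gene-dropped
  genotypes (so genomic-model recovery is tested against a matching
  generative truth), or from iid marker effects scaled to Ga.
* **Records** — flush counts 1 + Poisson(mean − 1) with mean 13.5
  flushes/cow (the study-scale intensity; the real distribution beyond
  its mean is unknown and the shifted Poisson is an assumption recorded
  in truth.json); year/month/program/technician levels with effects
  drawn once per level (SDs 1.0 and 0.5 trait-wise); age advancing 2.5
  months per flush with small linear/quadratic effects; pe once per
  cow, residuals per record.  Trait means default to (16.3, 6.7).
* **Component truth** — the published estimates for this trait pair:
  pedigree-matrix set (additive 28.07/5.57, permanent environment
  10.87/3.63, residual 68.15/26.32, r_g 0.66 → h² 0.26/0.16,
  repeatability 0.36/0.26) and single-step set (19.19/3.99,
  17.49/4.93, 68.16/26.32, r_g 0.61 → h² 0.18/0.11).  The
  permanent-environment and residual cross-trait correlations are not
  published; 0.5 is used for both as a realistic one-time default for a
  part-whole trait pair.  Heritability and repeatability recovery do
  not depend on that choice.

All randomness flows from one seed through named substreams
(pedigree/genotype/effects/records), so each stage is independently
reproducible and datasets are bit-stable under a fixed seed.

What passing tests on these data do **not** show: behavior under real
linkage disequilibrium and chip ascertainment, under non-Gaussian count
noise, under selection-driven allele-frequency change across
generations, or with the real herd's pedigree depth and record
distribution.

## Problem sizes and numerical behavior

The parameter-recovery experiments run 30 seeded replicates of a
three-generation, 450-cow herd with ~10 flushes per cow (2,000 markers
and 40% genotyped in the single-step experiment); the in-suite recovery
tests use 150 cows so the whole suite stays fast.  At these sizes the
mean estimate over replicates recovers each generative parameter within
two Monte-Carlo standard errors.

Two finite-sample behaviors are worth knowing about.  First, with the
low-signal single-step component set, per-replicate two-trait estimates
are heavy-tailed: occasional replicates push the genetic correlation to
its +1 boundary (flagged non-converged when the ridge does not
terminate) or inflate one additive variance, so the replicate mean of
TNE heritability tends to sit slightly above the generative 0.18 at
desk scale — single-trait recovery with the same H is unbiased, and the
effect shrinks with herd size.  Second, REML estimates at variance
boundaries are truncated rather than bias-corrected; no REML-to-ML or
boundary-adjusted inference is attempted.

Degenerate inputs are errors, not warnings: empty QC survivors,
monomorphic-only marker sets, singular A22/G*/coefficient matrices,
phenotyped cows absent from the pedigree, NGE > TNE in count data.
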