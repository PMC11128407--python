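# Methods

## Model

For line *i* = 1..n_j observed in environment *j* = 1..m:

    y_ij = β₀ + β₀j + α_i + Σ_{k,l} x_ikl β_kl + Σ_{k,l} x_ikl β_jkl + e_ij

* x_ikl ∈ {−1, 0, 1}: coded genotype of SNP *l* in LD block *k* (AA/AB/BB).
* β₀, β₀j: fixed global and per-environment intercepts, flat priors.
  Because both are flat the pair is only identified through its sum; after
  each sweep the environment intercepts are recentred to sum to zero and
  the mean absorbed into β₀ (fitted values unchanged).
* α_i ~ N(0, σ²_α): per-line random intercept, shared across environments.
  It induces COV(y_ij, y_ij′) = σ²_α for j ≠ j′ and VAR(y_ij) = σ²_α + σ₀²
  net of genetics — the standard random-intercept algebra.  (An alternative
  printed convention swaps the two components' roles in the
  cross-environment covariance; we implement the standard algebra.)
* β_kl (main) and β_jkl (G×E): spike-and-slab, β ~ γ·N(0, σ²_jk) +
  (1−γ)·δ₀, γ ~ Bernoulli(ω).  All SNPs in block *k* (per layer and
  environment) share σ²_jk — the feature that distinguishes the block
  model from Bayes C (one global slab variance) and Bayes B (one variance
  per SNP, i.e. a scaled-t slab).  One ω is shared by every indicator.
* ω ~ Beta(a, b) with a = b = 25 (prior mean 0.5, no inclusion
  preference).
* e_ij ~ N(0, σ₀²) independent.

Variance priors.  σ₀², σ²_α and every σ²_jk carry
Inverse-Gamma(shape c, rate d) priors, c = 5/2 — equivalently
Scaled-Inv-χ²(ν = 2c = 5, s² = d/c) — with rates

    d₀   = var(y) · (1 − R²) · (c + 1)
    d_jk = var(y) · R² · (c + 1) / mean(diag(XᵀX))
    d_α  = 5/2

so the prior *mode* d/(c+1) of the residual variance is var(y)(1 − R²)
and of a slab variance var(y)·R²/mean(diag(XᵀX)) — the usual
mode-matching defaults of Bayesian genomic-regression software.  R²
("`r2_assumed`", default 0.5) is the assumed proportion of phenotype
variance that is genetic; it only scales the priors.  Sampled variances
are floored at 1e−10.

## Gibbs sampler

One unified numba kernel serves the whole family via a SNP→variance-group
map (blocks → LD model; one group per SNP → Bayes B; a single group →
Bayes C).  Updates per sweep: intercepts (normal), per-line intercepts
(normal), then per SNP a **joint** (γ, β) move — γ from its marginalised
Bernoulli conditional

    log-odds = log ω/(1−ω) + ½·log σ₀²/(σ₀² + vS) + v(xᵀr)²/(2σ₀²(σ₀² + vS)),

with S = Σx² over the layer's observations and r the residual with this
SNP removed, then β | γ=1 ~ N(v·xᵀr/(vS + σ₀²), σ₀²v/(vS + σ₀²)) —
followed by ω ~ Beta(a + Σγ, b + K − Σγ), per-group slab variances
Inv-Gamma(c + n_active/2, d + Σβ²/2), σ²_α and σ₀².  Sampling γ and β
jointly avoids the mixing pathology of updating them separately.  The
schedule defaults to 60 000 iterations, 10 000 burn-in, thinning 50
(exactly 1000 kept draws); chains are bit-reproducible given a seed.

Correctness is validated against an independent oracle: with σ₀², the
slab variance and ω fixed and no intercept, the marginal likelihood of
each indicator configuration is a zero-mean multivariate normal, so
inclusion probabilities on 3-SNP problems are computed exactly by
enumerating all 8 configurations; the chain agrees within Monte-Carlo
error (max |Δ| ≈ 0.001 at 50 000 draws, tolerance 0.03).

Bayesian G-BLUP (y = 1μ + u + e, u ~ N(0, G·σ²_g)) is sampled in the
eigenbasis of the VanRaden matrix G, where the genetic coefficients are
conditionally independent scalars; eigenvalues ≤ 1e−8 are excluded from
the genetic term (regularisation of a singular G).

## LD blocks

Per chromosome, SNPs (sorted by position) are chunked into
roughly-equal windows of at most w₂ = 100 consecutive SNPs; within a
window an average-linkage tree on 1 − r² is cut top-down, accepting a
node's leaf set as a block when its minimum pairwise r² ≥ r₁ = 0.5 *and*
median r² ≥ r₂ = 0.7, else descending; leaves end as singletons.  The
contract is LD-network-clustering-compatible in spirit, not bit-identical
to any particular package: the source procedure defers its internals to
an external implementation, so we fix this concrete, testable rule.  The
hotspot parameter w₁ = 10 is honoured as the minimum run of consecutive
low-LD adjacent pairs (r² < r₁) at which a window boundary is forced
(`use_hotspots=True`); by default plain w₂ chunking is used.  Top-down
cutting makes the block count monotone non-decreasing in both
thresholds.

## Decision rules

* Block inclusion: P(Z_jk = 1 | Y) = fraction of kept draws in which any
  member SNP's indicator is 1 (per layer; environments are tested
  separately).
* Bayes factor: BF = [P(Z=1|Y)/P(Z=0|Y)] · [P(Z=0)/P(Z=1)] with
  P(Z=0) = (1 − ω̂)^{q_k}, ω̂ the posterior mean of ω.  log₁₀ BF > 2
  (BF > 100) is decisive.  Finite chains cannot resolve posterior
  probabilities of exactly 0 or 1, so ±∞ is clamped to
  ±(log₁₀ n_draws + 2) — with 1000 kept draws the largest reportable
  value is 5.0, making the cap explicit rather than implicit.
* BFDR: local FDR = 1 − inclusion probability; sort ascending and select
  the longest prefix whose running mean stays below α (default 0.05).
  Ties are sorted stably by block id and treated as a unit: a tie group
  split by the cut is included only if the extended running mean stays
  below α, else dropped whole.  Selections are nested in α.
* PVE of a block: Var over lines of (member SNP columns × posterior-mean
  effects, zeros included) divided by Var(y), clipped to [0, 1] — a
  shrunken, conservative convention chosen here because no closed
  definition is standard; blocks selected at α ≤ 0.05 with PVE ≥ 0.05
  are flagged "major".

## Heritability

* VanRaden (method 1) GRM: allele counts centred at 2p per SNP, scaled
  by 2Σp(1−p); monomorphic SNPs are excluded (they contribute no scale).
  For fully inbred lines the mean diagonal is ≈ 2 (= 1 + F), not 1.
* ASV genomic heritability: h_g² = [tr(G)/(n−1)·σ²_g] /
  [tr(G)/(n−1)·σ²_g + σ²_e], evaluated per G-BLUP posterior draw; the
  point estimate is the posterior mean, the SE the posterior SD.
* Narrow-sense point estimate for inbred-line means:
  h_N² = (σ²_g/2)/(σ²_g + v̄/2), where σ²_additive ≈ σ²_g/2 (RIL
  approximation, no epistasis) and v̄ is the mean variance of a
  difference between two adjusted line means.  In synthetic runs v̄ is
  computed as 2σ²_ε/r from the replicate-level residual variance, an
  explicit stand-in for mixed-model s.e.d. output.  By construction
  h_N² ≤ 0.5.  No delta-method SE is provided.

## Prediction and selection

GEBV of a line = Σ coded genotype × posterior-mean main effect (+ fitted
intercept when requested); G×E effects are excluded because a breeding
value is the across-environment worth.  Cross-validation partitions
lines into five random folds (seeded, unstratified), trains on the
non-test lines' training-environment phenotypes, and scores
cor(GEBV, held-out-environment phenotype)/√h_g²; h_g² is estimated once
per trait from G-BLUP on the full training data (a per-fold estimate
would add noise without changing the comparison).  G-BLUP predictions
for unphenotyped lines use the conditional mean G_newᵀG⁻¹û.  Sequential
truncation selection applies (trait, threshold) cuts in order with ≥
semantics (ties retained); phenotype-scale thresholds are mapped to the
shrunken GEBV scale by inverting the least-squares line of phenotype on
GEBV, which compresses cut points toward the mean.

## Synthetic MAGIC generator

`simulate_magic_genotypes` builds a four-founder pedigree: founders are
paired into two F1s, the F1s intercrossed, and each offspring selfed for
six generations of single-seed descent (residual heterozygosity
≈ 0.5·2⁻⁶).  Meioses recombine along a clumped genetic map — tight
clumps of SNPs (≈ 0.01 cM span) at random positions on 150 cM
chromosomes, 1 cM ≈ 1 Mb for reported positions — so clumps become LD
blocks in the offspring.  Clump sizes are drawn from a mix averaging
≈ 3.2 SNPs with ~40 % singletons and a thin tail of 10–15-SNP clumps,
mirroring a genotyping panel whose LD clusters have that spectrum.
Founder alleles within a clump derive from one polymorphic base pattern
with small per-SNP jitter calibrated so the realised median within-clump
r² stays at or above the `within_block_r2` target (default 0.75;
realised median ≈ √target).  Per-SNP allele labels are then randomised:
which homozygote is coded −1 is arbitrary in real calling, so
within-block correlations have random sign and multi-SNP effect sums can
partially cancel — an essential feature for realistic power studies.  A
direct block-correlated generator (`mode="block"`) provides a fast
pedigree-free alternative.  Defaults: 256 lines, 10 chromosomes × 150
SNPs.

What the generator does not emulate: real MAF spectra beyond the
four-founder {¼, ½, ¾} lattice, selection or segregation distortion,
genotyping error and missingness patterns, LD decay within clumps, or
inter-chromosomal structure.  Passing power studies therefore show the
method behaves as designed under blocky LD, not that real-data counts
will match exactly.

## Simulation study

`simulate_phenotypes` places additive effects at 55 causal SNPs in 10
distinct LD blocks: 5 single-SNP majors (3 common to both seasons, 2
season-specific, effects ~ N(5, 1.5²)) and 5 ten-SNP minor blocks (3
common, 2 season-specific, per-SNP effects ~ N(1.5, 0.5²)); residuals
~ N(0, 10²) per line and season.  Distribution second parameters are
variances (2.25 = 1.5², 0.25 = 0.5²).  Season-specific QTLs alternate
over seasons.  `run_replicate_study` fixes one genotype panel, block
set and causal architecture (placement *and* drawn effects) per study
seed and redraws only residuals across replicates, so each QTL's
detection frequency reflects noise, not architecture turnover.
Significance: block-level BF > 100 for the LD model (any layer);
per-SNP BF > 100 for Bayes B/C fitted to across-season line means,
credited to the host block; significant calls outside every true block
count as false positives.

Problem sizes.  The package's replicate-study operating point is 256
lines × 1500 SNPs, 4 architectures × 5 residual replicates, with a
reduced chain (2000 iterations, 500 burn-in, thin 3 = 500 kept draws;
Bayes B/C get 3× that schedule since their sweeps are cheap).  A
longer 6000/1000/5 schedule gave identical detection counts in side-by-
side runs, so the shorter chain is the default; the full 60 000-
iteration schedule remains available via `MCMCConfig`.

Known scale effect: the posterior mean ω̂ enters the Bayes-factor prior
odds, and at p = 1500 SNPs ω̂ = (a + Σγ)/(a + b + K) is several-fold
larger than at a 6500-SNP panel because the number of included effects
saturates near the sample size while K grows with p.  The BF > 100 bar
therefore corresponds to a stricter posterior-probability threshold at
reduced p (≈ 0.985 vs ≈ 0.91 for a 10-SNP block).  This depresses
detection counts for borderline blocks — most visibly for the per-SNP
samplers, whose inclusion mass is additionally diluted across correlated
block members — relative to a full-size panel.  Bayes C further tends to
a collapsed common-slab regime (many tiny included effects) under the
Beta(25, 25) prior when p ≫ n, which suppresses its major-QTL calls;
Bayes B, whose per-SNP variances adapt, remains sparse at full panel
size.

## Limitations

* Additive effects only; no dominance or epistasis terms.
* The LD clustering is a fixed, documented contract, not a bit-exact
  reimplementation of any network-clustering package; block counts on
  real panels may differ.
* Mode/frequency imputation only (ties to the smaller code for
  determinism); no haplotype-aware imputation, so downstream results on
  sparsely genotyped data inherit that crudeness.
* Multi-allelic sites are skipped (or rejected in strict mode).
* Heterozygote calls are accepted but the models treat them simply as
  the 0 dose; panels far from inbred violate the h_N² approximation.
* BFDR control is exact only under the model; with few blocks the
  running-mean rule is conservative.
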