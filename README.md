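# ldbayes

Bayesian LD-block QTL mapping and genomic prediction for inbred-line
panels (RILs, MAGIC populations and similar), with the comparison
fitters, heritability estimators, selection tools and a synthetic MAGIC
simulator needed to study the method end to end.

## The problem and the model

Dense marker panels carry strong local linkage disequilibrium: runs of
SNPs inherited together segregate as a unit, so per-SNP variable
selection dilutes the evidence for a causal region across its correlated
neighbours.  This package instead clusters SNPs into **LD blocks**
(windowed network clustering: a group is accepted when its minimum
pairwise r² ≥ r₁ = 0.5 and its median r² ≥ r₂ = 0.7, within windows of
at most w₂ = 100 consecutive SNPs) and treats the block as the unit of
inference in a multi-environment spike-and-slab regression:

    y_ij = β₀ + β₀j + α_i + Σ_k Σ_l x_ikl β_kl + Σ_k Σ_l x_ikl β_jkl + e_ij

for line *i* in environment *j*, genotypes coded x ∈ {−1, 0, 1}.  Every
SNP effect has a spike-and-slab prior β ~ γ·N(0, σ²_jk) + (1−γ)·δ₀ with
γ ~ Bernoulli(ω), ω ~ Beta(25, 25); SNPs in block *k* **share** the slab
variance σ²_jk.  α_i is a per-line random intercept (covariance across
environments), β_jkl an environment-specific (G×E) effect, and
e_ij ~ N(0, σ₀²).  Variances carry Inverse-Gamma(shape 5/2, rate d)
priors with data-scaled rates.  The posterior is sampled by a Gibbs
chain (default 60 000 iterations, 10 000 burn-in, thinned to 1000 kept
draws) whose full conditionals are validated against exhaustive
enumeration on small problems.

QTL calling is block-level: the inclusion event Z_k = 1 (any member SNP
selected) gives a posterior probability P(Z_k = 1 | Y), a Bayes factor
BF_k = posterior odds / prior odds with P(Z_k = 0) = (1 − ω̂)^{q_k}
(log₁₀ BF > 2 is decisive), and a Bayesian-FDR rule that selects the
longest ascending-LFDR prefix whose running mean stays below α.
Companion fitters — Bayes B (per-SNP scaled-t slab), Bayes C (common
slab) and Bayesian G-BLUP on the VanRaden relationship matrix — support
comparisons, ASV genomic heritability and GEBV-based prediction and
truncation selection.

## Worked example

```python
from ldbayes import (MCMCConfig, cluster_ld_blocks, fit_ldbayes,
                     qtl_report, simulate_magic_genotypes,
                     simulate_phenotypes)
import numpy as np

g = simulate_magic_genotypes(seed=1)          # 256 RILs x 1500 SNPs
blocks = cluster_ld_blocks(g)                 # 423 LD blocks
pheno, truth = simulate_phenotypes(g, blocks, seed=2)
fit = fit_ldbayes(g, pheno, blocks, mcmc=MCMCConfig(2000, 500, 3, seed=3))
y = np.nanmean(pheno.trait_matrix("sim", list(g.lines)), axis=1)
report = qtl_report(fit, g, y, alpha=0.05)
print(report[report.bfdr_selected & (report.effect_type == "main")])
```

prints (abridged)

```
 block_id chrom   start_kb     end_kb  q_k  log10_bf      pve
      307 chr07 149025.585 149034.474    9   4.69897 0.126842
      342 chr09   5835.060   5841.727    3   4.69897 0.119691
      419 chr10 129849.519 129849.519    1   4.69897 0.060926
```

— three genomic regions pass the Bayesian-FDR screen at α = 0.05, each
with decisive Bayes factors (log₁₀ BF ≫ 2) and explaining 6–13 % of the
phenotype variance; all three contain simulated causal SNPs.  The
scripts in `examples/` walk through clustering, QTL mapping,
heritability, prediction/selection and the replicate benchmark, each
printing what its numbers mean.

A thin CLI mirrors the pipeline:
`ldbayes simulate | ldblocks | fit | map-qtl | predict | cv | select |
benchmark` (see `ldbayes --help`).

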