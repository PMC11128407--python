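"""Genomic (ASV) and narrow-sense heritability on simulated line means.

Bayesian G-BLUP links the VanRaden relationship matrix to the trait; the
average-semivariance estimator converts its posterior variance-component
draws into h_g² = [tr(G)/(n−1)·σ²_g] / [tr(G)/(n−1)·σ²_g + σ²_e].  The
narrow-sense point estimate for an inbred-line panel uses
h_N² = (σ²_g/2) / (σ²_g + v̄/2) with v̄ the variance of a difference
between two line means.
"""

import numpy as np

from ldbayes import (MCMCConfig, VarianceComponents, asv_h2, fit_gblup,
                     narrow_sense_h2, sed_variance_from_replicates,
                     simulate_magic_genotypes, vanraden_grm)

g = simulate_magic_genotypes(seed=5)
G = vanraden_grm(g)
print(f"VanRaden GRM: mean diagonal {np.diag(G).mean():.2f} "
      "(~2 for fully inbred lines, 1 + F)")

# simulate a trait with known variance components: u ~ N(0, G * 4), e ~ N(0, 4)
rng = np.random.default_rng(6)
lam, U = np.linalg.eigh(G)
lam = np.clip(lam, 0, None)
u = U @ (np.sqrt(lam * 4.0) * rng.standard_normal(g.n_lines))
y = u + rng.normal(0, 2.0, g.n_lines)
k = np.trace(G) / (g.n_lines - 1)
print(f"true ASV heritability: {k * 4 / (k * 4 + 4):.3f}")

res = fit_gblup(g, y, MCMCConfig(3000, 1000, 2, seed=7))
vc = VarianceComponents.from_gblup(res)
h2, se = asv_h2(vc, res.G)
print(f"estimated h_g^2 = {h2:.3f} +- {se:.3f} "
      f"(posterior means: sigma2_g {res.sigma2_g.mean():.2f}, "
      f"sigma2_e {res.sigma2_e.mean():.2f})")

# narrow-sense point estimate with a replicate-based stand-in for v̄
vbar = sed_variance_from_replicates(residual_var=4.0, n_reps=2)
vc_n = VarianceComponents(res.sigma2_g.mean(), res.sigma2_e.mean(),
                          n=g.n_lines, mean_sed=vbar)
print(f"h_N^2 = {narrow_sense_h2(vc_n):.3f} "
      "(bounded by 0.5: additive variance is half the line variance)")
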