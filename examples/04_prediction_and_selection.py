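"""Genomic prediction accuracy and GEBV-based sequential selection.

Fivefold cross-validation: train on season-1 phenotypes of 4/5 of the
lines, predict GEBVs for the held-out fifth, and score them against
their season-2 phenotypes, scaled by sqrt(h_g²).  Selection then culls
lines trait by trait; because GEBVs are shrunken, phenotype-scale cut
points are mapped onto the GEBV scale by inverting the regression of
phenotype on GEBV.
"""

import numpy as np
import pandas as pd

from ldbayes import (MCMCConfig, cluster_ld_blocks, cv_accuracy, fit_ldbayes,
                     map_cutpoints, predict_gebv, selection_overlap,
                     SelectionScenario, sequential_select,
                     simulate_magic_genotypes, simulate_phenotypes)

g = simulate_magic_genotypes(seed=11)
blocks = cluster_ld_blocks(g)
pheno, _ = simulate_phenotypes(g, blocks, seed=12)
mcmc = MCMCConfig(2000, 500, 3, seed=13)

for method in ("ldbayes", "bayesc", "gblup"):
    acc, _ = cv_accuracy(g, pheno, blocks, mcmc=mcmc, folds=5, seed=14,
                         method=method, train_envs=[1], test_env=2)
    print(f"fivefold CV accuracy, {method:8s}: {acc:.3f}")

# GEBVs from a fit on all lines, and selection vs the phenotypic means
fit = fit_ldbayes(g, pheno, blocks, mcmc=mcmc)
gebv = predict_gebv(fit, g)
y_mean = np.nanmean(pheno.trait_matrix("sim", list(g.lines)), axis=1)
print(f"\ncor(GEBV, phenotypic mean) = "
      f"{np.corrcoef(gebv, y_mean)[0, 1]:.3f}")

pheno_cut = float(np.quantile(y_mean, 0.8))
gebv_cut = float(map_cutpoints(y_mean, gebv.to_numpy(), [pheno_cut])[0])
print(f"phenotype cut {pheno_cut:.2f} maps to GEBV cut {gebv_cut:.2f} "
      "(compressed toward the mean by shrinkage)")

values = pd.DataFrame({"sim_pheno": y_mean, "sim_gebv": gebv.to_numpy()},
                      index=list(g.lines))
by_pheno, _ = sequential_select(values, SelectionScenario(
    cuts=[("sim_pheno", pheno_cut)], basis="phenotype"))
by_gebv, _ = sequential_select(values, SelectionScenario(
    cuts=[("sim_gebv", gebv_cut)], basis="gebv"))
n, frac_a, frac_b = selection_overlap(by_pheno, by_gebv)
print(f"selected {len(by_pheno)} by phenotype, {len(by_gebv)} by GEBV; "
      f"{n} in common ({100 * frac_a:.0f}% of the phenotypic selection)")
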