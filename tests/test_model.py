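import numpy as np
import pytest

from ldbayes import (MCMCConfig, ModelSpec, VarianceComponents, asv_h2,
                     block_inclusion_prob, fit_bayes_b, fit_bayes_c,
                     fit_gblup, fit_ldbayes, singleton_blocks, vanraden_grm)

from conftest import make_genotypes, make_pheno
from oracle import enumerate_pips


def test_mcmc_schedule_validation():
    assert MCMCConfig().n_kept == 1000
    assert MCMCConfig(2000, 500, 3).n_kept == 500
    with pytest.raises(ValueError):
        MCMCConfig(1000, 1000, 10)
    with pytest.raises(ValueError):
        MCMCConfig(1000, 100, 7)  # 900/7 not integer


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(a=0)
    with pytest.raises(ValueError):
        ModelSpec(r2_assumed=1.5)
    d0, d_slab = ModelSpec(r2_assumed=0.5, c=2.5).scales(4.0, 100.0)
    assert d0 == pytest.approx(4.0 * 0.5 * 3.5)
    assert d_slab == pytest.approx(4.0 * 0.5 * 3.5 / 100.0)


def _oracle_problem(seed=7, n=20):
    rng = np.random.default_rng(seed)
    base = rng.choice([-1.0, 1.0], size=n)
    X = np.column_stack([
        base,
        np.where(rng.random(n) < 0.2, -base, base),
        rng.choice([-1.0, 1.0], size=n)])
    y = X @ np.array([1.2, 0.0, -0.8]) + rng.normal(0, 1.0, n)
    return X, y


def _gibbs_pips(X, y, s0, v, om, mcmc):
    g = make_genotypes(X.astype(np.int8))
    pheno = make_pheno(g.lines, y)
    spec = ModelSpec(fixed_sigma2_0=s0, fixed_slab_var=v, fixed_omega=om,
                     fit_intercept=False)
    fit = fit_ldbayes(g, pheno, singleton_blocks(g), spec, mcmc)
    return fit, fit.pip()


def test_gibbs_matches_enumeration_oracle_quickly():
    """Short-chain version of the enumeration check (the full-length run
    lives in the acceptance suite)."""
    X, y = _oracle_problem()
    s0, v, om = 1.0, 1.0, 0.3
    exact = enumerate_pips(X, y, s0, v, om)
    fit, pips = _gibbs_pips(X, y, s0, v, om, MCMCConfig(11000, 1000, 1, seed=3))
    assert np.abs(pips - exact).max() < 0.05
    # block inclusion of a singleton equals its SNP inclusion mean
    assert block_inclusion_prob(fit, 0) == pytest.approx(pips[0])


def test_strong_signal_recovery_matches_oracle():
    rng = np.random.default_rng(0)
    n = 40
    X = rng.choice([-1.0, 1.0], size=(n, 3))
    y = 5.0 * X[:, 0] + rng.normal(0, 1.0, n)
    s0, v, om = 1.0, 4.0, 0.1
    exact = enumerate_pips(X, y, s0, v, om)
    _, pips = _gibbs_pips(X, y, s0, v, om, MCMCConfig(11000, 1000, 1, seed=4))
    assert pips[0] >= 0.95 and exact[0] >= 0.95
    assert (pips[1:] <= 0.2).all() and (exact[1:] <= 0.2).all()
    assert np.abs(pips - exact).max() < 0.05


def test_null_data_keeps_omega_near_prior_mean():
    rng = np.random.default_rng(2)
    g = make_genotypes(rng.choice([-1, 1], size=(40, 3)))
    pheno = make_pheno(g.lines, rng.normal(0, 1, 40))
    fit = fit_ldbayes(g, pheno, singleton_blocks(g),
                      mcmc=MCMCConfig(6000, 1000, 5, seed=5))
    assert 0.35 < fit.omega_mean < 0.65        # Beta(25,25) prior mean 0.5
    assert (fit.pip() < 0.6).all()


def test_chain_is_deterministic_and_respects_contract():
    rng = np.random.default_rng(3)
    g = make_genotypes(rng.choice([-1, 0, 1], size=(30, 6)))
    y = rng.normal(0, 1, size=(30, 2))
    y[5, 0] = np.nan                            # unbalanced is allowed
    pheno = make_pheno(g.lines, y)
    mcmc = MCMCConfig(3000, 1000, 4, seed=9)
    a = fit_ldbayes(g, pheno, singleton_blocks(g), mcmc=mcmc)
    b = fit_ldbayes(g, pheno, singleton_blocks(g), mcmc=mcmc)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.gamma, b.gamma)
    assert np.array_equal(a.sigma2_0, b.sigma2_0)
    # contract: beta zero wherever gamma is zero; positive variances;
    # correct draw count; indicators binary
    assert a.n_kept == mcmc.n_kept
    assert np.all(a.beta[a.gamma == 0] == 0.0)
    assert set(np.unique(a.gamma)) <= {0, 1}
    assert (a.sigma2_0 > 0).all() and (a.sigma2_block > 0).all()
    assert (a.omega > 0).all() and (a.omega < 1).all()
    assert a.gamma_gxe is not None and a.sigma2_alpha is not None


def test_random_intercept_absorbs_line_effects():
    rng = np.random.default_rng(6)
    n = 60
    g = make_genotypes(rng.choice([-1, 1], size=(n, 4)))
    alpha = rng.normal(0, 3.0, n)
    y = np.column_stack([alpha + rng.normal(0, 0.5, n),
                         alpha + rng.normal(0, 0.5, n)])
    pheno = make_pheno(g.lines, y)
    fit = fit_ldbayes(g, pheno, singleton_blocks(g),
                      ModelSpec(include_gxe=False),
                      MCMCConfig(4000, 1000, 3, seed=1))
    # within-line cross-environment covariance is carried by sigma2_alpha
    assert fit.sigma2_alpha.mean() > 4 * fit.sigma2_0.mean()
    assert fit.sigma2_0.mean() < 1.5


def test_phenotype_validation_errors():
    import pandas as pd

    from ldbayes import PhenotypeTable

    rng = np.random.default_rng(0)
    g = make_genotypes(rng.choice([-1, 1], size=(10, 2)))
    pheno = PhenotypeTable(pd.DataFrame({
        "line": list(g.lines), "env": 1, "trait": "t",
        "value": [np.nan] + [1.0] * 9}))
    with pytest.raises(ValueError, match="finite|phenotype"):
        fit_ldbayes(g, pheno, singleton_blocks(g), mcmc=MCMCConfig(100, 50, 1))
    bad = make_pheno(["nobody"] + list(g.lines)[1:], np.ones(10))
    with pytest.raises(ValueError, match="absent"):
        fit_ldbayes(g, bad, singleton_blocks(g), mcmc=MCMCConfig(100, 50, 1))


@pytest.mark.parametrize("fitter", [fit_bayes_b, fit_bayes_c])
def test_single_snp_signal_detected_by_snp_fitters(fitter):
    rng = np.random.default_rng(4)
    n, p = 150, 30
    g = make_genotypes(rng.choice([-1, 1], size=(n, p)))
    y = 3.0 * g.calls[:, 7] + rng.normal(0, 1.0, n)
    fit = fitter(g, y, MCMCConfig(3000, 1000, 2, seed=2))
    assert fit.pip()[7] >= 0.9
    assert fit.method in ("bayesb", "bayesc")


def test_bayes_c_dilutes_over_near_duplicates_but_block_model_does_not():
    """Ten near-duplicate SNPs carrying one signal: per-SNP inclusion
    under a per-SNP-indicator model spreads over the copies, while the
    block-level inclusion event stays near one."""
    rng = np.random.default_rng(10)
    n = 200
    base = rng.choice([-1, 1], size=n)
    dup = np.column_stack(
        [np.where(rng.random(n) < 0.03, -base, base) for _ in range(10)])
    noise = rng.choice([-1, 1], size=(n, 20))
    g = make_genotypes(np.column_stack([dup, noise]))
    y = 2.0 * base + rng.normal(0, 1.0, n)
    mcmc = MCMCConfig(3000, 1000, 2, seed=3)
    c = fit_bayes_c(g, y, mcmc)
    from ldbayes.ldblocks import cluster_ld_blocks
    blocks = cluster_ld_blocks(g)
    ld = fit_ldbayes(g, make_pheno(g.lines, y), blocks, mcmc=mcmc)
    blk = int(blocks.snp_to_block[0])
    assert len(blocks.members(blk)) == 10
    p_block = block_inclusion_prob(ld, blk)
    assert p_block > 0.95
    assert c.pip()[:10].max() < p_block


def test_posterior_draws_export_round_trip():
    rng = np.random.default_rng(7)
    g = make_genotypes(rng.choice([-1, 1], size=(25, 4)))
    pheno = make_pheno(g.lines, rng.normal(0, 1, size=(25, 2)))
    fit = fit_ldbayes(g, pheno, singleton_blocks(g),
                      mcmc=MCMCConfig(600, 200, 2, seed=1))
    tidy = fit.to_frame()
    assert set(tidy.columns) == {"draw", "layer", "name", "value"}
    eff = tidy[tidy["layer"] == "main_effect"].pivot(
        index="draw", columns="name", values="value")
    assert np.allclose(eff[[str(s) for s in g.snp_ids]].to_numpy(),
                       fit.beta)
    assert tidy[tidy["name"] == "omega"]["value"].mean() == \
        pytest.approx(fit.omega_mean)


def test_gblup_limits_and_determinism():
    from ldbayes import simulate_magic_genotypes

    g = simulate_magic_genotypes(n_lines=200, n_chrom=2, snps_per_chrom=50,
                                 seed=13)
    G = vanraden_grm(g)
    lam, U = np.linalg.eigh(G)
    lam = np.clip(lam, 0, None)
    rng = np.random.default_rng(5)
    u = U @ (np.sqrt(lam * 2.0) * rng.standard_normal(200))
    mcmc = MCMCConfig(2000, 500, 3, seed=8)
    noiseless = fit_gblup(g, u, mcmc)
    # heritability-1 data: residual variance collapses
    h2, _ = asv_h2(VarianceComponents.from_gblup(noiseless), noiseless.G)
    assert noiseless.sigma2_e.mean() < 0.1 * noiseless.sigma2_g.mean()
    assert h2 > 0.9
    # permuted phenotypes: genetic variance (and heritability) shrink
    perm = fit_gblup(g, rng.permutation(u), mcmc)
    h2_perm, _ = asv_h2(VarianceComponents.from_gblup(perm), perm.G)
    assert perm.sigma2_g.mean() < 0.7 * noiseless.sigma2_g.mean()
    assert h2_perm < 0.45 < h2
    again = fit_gblup(g, u, mcmc)
    assert np.array_equal(noiseless.u, again.u)
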