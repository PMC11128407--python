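import numpy as np
import pandas as pd
import pytest

from ldbayes import (MCMCConfig, SelectionScenario, cv_accuracy,
                     map_cutpoints, predict_gebv, selection_overlap,
                     sequential_select, singleton_blocks)

from conftest import make_genotypes, make_pheno
from test_qtl import make_samples


def _samples_with_effects(effects, g):
    draws = 20
    p = len(effects)
    beta = np.tile(np.asarray(effects, dtype=float), (draws, 1))
    gamma = (beta != 0).astype(np.uint8)
    s = make_samples(gamma, beta=beta)
    s.snp_ids = g.snp_ids
    s.line_ids = list(g.lines)
    return s


def test_gebv_linear_score_and_intercept():
    g = make_genotypes([[-1, 0], [0, 0], [1, 0]])
    s = _samples_with_effects([2.0, 0.0], g)
    s.beta0 = np.full(s.n_kept, 10.0)
    gebv = predict_gebv(s, g)
    assert np.allclose(gebv.to_numpy(), [8.0, 10.0, 12.0])
    zero = _samples_with_effects([0.0, 0.0], g)
    zero.beta0 = np.full(zero.n_kept, 10.0)
    assert np.allclose(predict_gebv(zero, g).to_numpy(), 10.0)


def test_gebv_snp_mismatch_lists_offenders():
    g = make_genotypes([[-1, 0], [0, 1]])
    s = _samples_with_effects([1.0, 1.0], g)
    g_other = make_genotypes([[-1], [0]])
    g_other.snp_ids = np.array(["weird"], dtype=object)
    with pytest.raises(ValueError, match="weird"):
        predict_gebv(s, g_other)


def test_gebv_consistent_with_fitted_genetic_values():
    from ldbayes import fit_ldbayes

    rng = np.random.default_rng(0)
    g = make_genotypes(rng.choice([-1, 1], size=(60, 8)))
    y = g.calls[:, 2] * 2.0 + rng.normal(0, 0.8, 60)
    fit = fit_ldbayes(g, make_pheno(g.lines, y), singleton_blocks(g),
                      mcmc=MCMCConfig(3000, 1000, 2, seed=1))
    gebv = predict_gebv(fit, g, include_intercept=False)
    fitted = g.calls.astype(float) @ fit.mean_effects()
    r = np.corrcoef(gebv.to_numpy(), fitted)[0, 1]
    assert r > 0.99


def test_map_cutpoints_inverts_regression():
    rng = np.random.default_rng(1)
    gebv = rng.normal(0, 2.0, 40)
    # identity relation leaves thresholds unchanged
    assert map_cutpoints(gebv, gebv, [1.0, -0.5]) == pytest.approx([1.0, -0.5])
    # phenotype = 2*gebv + 1: phenotype threshold 41 -> gebv cut 20
    pheno = 2.0 * gebv + 1.0
    assert map_cutpoints(pheno, gebv, [41.0])[0] == pytest.approx(20.0)
    # shrunken GEBVs (slope > 1) compress cuts toward the GEBV mean
    shrunk = 0.4 * gebv
    wide = map_cutpoints(pheno, gebv, [41.0, -39.0])
    tight = map_cutpoints(pheno, shrunk, [41.0, -39.0])
    assert np.ptp(tight) < np.ptp(wide) + 1e-9
    assert np.ptp(tight) == pytest.approx(0.4 * np.ptp(wide))


def test_map_cutpoints_errors():
    with pytest.raises(ValueError, match="10"):
        map_cutpoints(np.ones(5), np.arange(5.0), [1.0])
    with pytest.raises(ValueError, match="variance"):
        map_cutpoints(np.arange(12.0), np.ones(12), [1.0])


def _toy_values():
    return pd.DataFrame(
        {"LP": [42.0, 41.0, 40.0, 43.0, 41.5, 39.0],
         "SI": [8.9, 8.7, 9.1, 8.4, 8.8, 9.0],
         "SOC": [19.5, 20.1, 18.9, 19.2, 20.5, 21.0]},
        index=[f"l{i}" for i in range(6)])


def test_sequential_select_toy_enumerated_by_hand():
    values = _toy_values()
    scenario = SelectionScenario(cuts=[("LP", 41.0), ("SI", 8.7),
                                       ("SOC", 19.5)])
    retained, report = sequential_select(values, scenario)
    # LP>=41: l0,l1,l3,l4; then SI>=8.7: l0,l1,l4; then SOC>=19.5: l0,l1,l4
    assert retained == ["l0", "l1", "l4"]
    assert report["retained"].tolist() == [4, 3, 3]
    assert report["reduced_by"].tolist() == [2, 1, 0]
    # bookkeeping identity: initial - final = sum of stage reductions
    assert 6 - len(retained) == report["reduced_by"].sum()
    assert report["pct_of_population"].iloc[-1] == pytest.approx(50.0)


def test_sequential_select_edges_and_monotonicity():
    values = _toy_values()
    lax = SelectionScenario(cuts=[("LP", 0.0), ("SI", 0.0)])
    retained, _ = sequential_select(values, lax)
    assert len(retained) == 6              # thresholds below all minima
    prev = 7
    for lp_cut in (39.0, 41.0, 42.0, 43.5):
        r, _ = sequential_select(values, SelectionScenario(
            cuts=[("LP", lp_cut), ("SI", 8.7)]))
        assert len(r) <= prev
        prev = len(r)
    with pytest.raises(ValueError, match="missing"):
        sequential_select(values, SelectionScenario(cuts=[("XX", 1.0)]))


def test_selection_overlap_arithmetic():
    assert selection_overlap({"a", "b"}, {"a", "b"}) == (2, 1.0, 1.0)
    assert selection_overlap({"a"}, {"b"}) == (0, 0.0, 0.0)
    a = {f"x{i}" for i in range(10)}
    b = {f"x{i}" for i in range(6, 14)}
    assert selection_overlap(a, b) == (4, 0.4, 0.5)


def test_cv_accuracy_reproducible_and_null_near_zero():
    from ldbayes import simulate_magic_genotypes
    from ldbayes.ldblocks import cluster_ld_blocks

    g = simulate_magic_genotypes(n_lines=90, n_chrom=2, snps_per_chrom=60,
                                 seed=3)
    blocks = cluster_ld_blocks(g)
    rng = np.random.default_rng(4)
    signal = g.calls[:, 5] * 2.0 + g.calls[:, 40] * 1.5
    y = np.column_stack([signal + rng.normal(0, 1, 90),
                         signal + rng.normal(0, 1, 90)])
    pheno = make_pheno(g.lines, y)
    mcmc = MCMCConfig(1500, 500, 2, seed=0)
    acc1, folds1 = cv_accuracy(g, pheno, blocks, mcmc=mcmc, folds=3, seed=5,
                               train_envs=[1], test_env=2, method="bayesc")
    acc2, folds2 = cv_accuracy(g, pheno, blocks, mcmc=mcmc, folds=3, seed=5,
                               train_envs=[1], test_env=2, method="bayesc")
    assert folds1 == folds2
    assert acc1 > 0.5                      # strong heritable signal
    # permuted phenotype: accuracy collapses towards zero
    perm = y.copy()
    perm[:, 1] = rng.permutation(perm[:, 1])
    acc_null, _ = cv_accuracy(g, make_pheno(g.lines, perm), blocks,
                              mcmc=mcmc, folds=3, seed=5, train_envs=[1],
                              test_env=2, method="bayesc", h2_g=1.0)
    assert abs(acc_null) < 0.35


def test_cv_accuracy_invariant_to_line_order():
    """Folds are keyed to sorted line ids, so shuffling the rows of the
    genotype matrix (and phenotype records) leaves the accuracy
    unchanged."""
    from ldbayes import simulate_magic_genotypes
    from ldbayes.ldblocks import cluster_ld_blocks

    g = simulate_magic_genotypes(n_lines=60, n_chrom=2, snps_per_chrom=50,
                                 seed=8)
    blocks = cluster_ld_blocks(g)
    rng = np.random.default_rng(2)
    y = np.column_stack([g.calls[:, 3] * 2.0 + rng.normal(0, 1, 60),
                         g.calls[:, 3] * 2.0 + rng.normal(0, 1, 60)])
    pheno = make_pheno(g.lines, y)
    kw = dict(mcmc=MCMCConfig(800, 200, 2, seed=0), folds=3, seed=5,
              train_envs=[1], test_env=2, method="bayesc", h2_g=1.0)
    acc, _ = cv_accuracy(g, pheno, blocks, **kw)
    perm = rng.permutation(60)
    g_shuf = g.subset_lines(perm)
    acc_shuf, _ = cv_accuracy(g_shuf, pheno, blocks, **kw)
    assert acc_shuf == pytest.approx(acc)


def test_block_model_accuracy_not_below_bayes_c():
    """Soft superiority on LD-structured data: over 20 replicates the
    block model's mean CV accuracy is no more than 0.02 below Bayes C
    (it aggregates within-block evidence instead of diluting it)."""
    from ldbayes import (SimDesign, cluster_ld_blocks,
                         simulate_magic_genotypes, simulate_phenotypes)

    g = simulate_magic_genotypes(n_lines=120, n_chrom=3, snps_per_chrom=80,
                                 seed=21)
    blocks = cluster_ld_blocks(g)
    design = SimDesign(n_minor_blocks=3, n_minor_common=2,
                       snps_per_minor_block=6)
    mcmc = MCMCConfig(1000, 250, 3, seed=0)
    gains = []
    for rep in range(20):
        pheno, _ = simulate_phenotypes(g, blocks, design, seed=300 + rep)
        accs = {}
        for meth in ("ldbayes", "bayesc"):
            accs[meth], _ = cv_accuracy(g, pheno, blocks, mcmc=mcmc,
                                        folds=2, seed=rep, method=meth,
                                        train_envs=[1], test_env=2,
                                        h2_g=1.0)
        gains.append(accs["ldbayes"] - accs["bayesc"])
    assert np.mean(gains) >= -0.02


def test_cv_accuracy_rejects_tiny_folds():
    from ldbayes import simulate_magic_genotypes
    from ldbayes.ldblocks import cluster_ld_blocks

    g = simulate_magic_genotypes(n_lines=10, n_chrom=1, snps_per_chrom=20,
                                 seed=9)
    blocks = cluster_ld_blocks(g)
    y = np.ones((10, 2))
    y[0, 0] = 2.0
    with pytest.raises(ValueError, match="fewer than 3"):
        cv_accuracy(g, make_pheno(g.lines, y), blocks,
                    mcmc=MCMCConfig(200, 100, 1), folds=5, seed=1,
                    train_envs=[1], test_env=2, h2_g=1.0)
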