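import numpy as np
import pytest

from ldbayes import (MCMCConfig, ModelSpec, bayes_factor, bfdr_select,
                     block_inclusion_prob, block_pve)
from ldbayes.ldblocks import LDBlockSet
from ldbayes.model import PosteriorSamples
from ldbayes.qtl import qtl_report

from conftest import make_genotypes


def make_samples(gamma, beta=None, omega=0.1, block_of_snp=None):
    """Hand-built PosteriorSamples for decision-rule tests."""
    gamma = np.asarray(gamma, dtype=np.uint8)
    n_draws, p = gamma.shape
    beta = np.zeros_like(gamma, dtype=float) if beta is None \
        else np.asarray(beta, dtype=float)
    block_of_snp = np.arange(p) if block_of_snp is None \
        else np.asarray(block_of_snp)
    ids = np.unique(block_of_snp)
    blocks = LDBlockSet(
        [(int(b), "1", np.flatnonzero(block_of_snp == b)) for b in ids],
        block_of_snp, {})
    return PosteriorSamples(
        method="ldbayes", line_ids=["l0"], snp_ids=np.arange(p).astype(str),
        block_of_snp=block_of_snp, blocks=blocks, m=1,
        beta0=np.zeros(n_draws), beta0j=np.zeros((n_draws, 1)), alpha=None,
        beta=beta, gamma=gamma, beta_gxe=None, gamma_gxe=None,
        omega=np.full(n_draws, omega), sigma2_0=np.ones(n_draws),
        sigma2_alpha=None, sigma2_block=np.ones((n_draws, len(ids))),
        sigma2_block_gxe=None, spec=ModelSpec(),
        mcmc=MCMCConfig(n_draws * 2, n_draws, 1))


def test_block_inclusion_prob_counts_union_of_members():
    # 2-SNP block over 4 draws: indicators (1,0),(0,0),(0,1),(1,1) -> 3/4
    s = make_samples([[1, 0], [0, 0], [0, 1], [1, 1]],
                     block_of_snp=[0, 0])
    assert block_inclusion_prob(s, 0) == pytest.approx(0.75)
    # singleton block equals the SNP's indicator mean; all-on block is 1
    s2 = make_samples([[1, 1], [0, 1], [1, 1], [0, 1]])
    assert block_inclusion_prob(s2, 0) == pytest.approx(0.5)
    assert block_inclusion_prob(s2, 1) == pytest.approx(1.0)


def test_union_bound_on_random_draws():
    rng = np.random.default_rng(0)
    gamma = (rng.random((200, 6)) < 0.3).astype(np.uint8)
    s = make_samples(gamma, block_of_snp=[0, 0, 0, 1, 1, 2])
    for b, members in ((0, [0, 1, 2]), (1, [3, 4]), (2, [5])):
        pips = gamma[:, members].mean(axis=0)
        p_block = block_inclusion_prob(s, b)
        assert pips.max() <= p_block + 1e-12
        assert p_block <= min(1.0, pips.sum()) + 1e-12


def test_bayes_factor_formula_and_clamping():
    # posterior odds equal to prior odds -> BF 1 -> log10 0
    om = 0.2
    p1_prior = 1.0 - (1.0 - om) ** 3
    assert bayes_factor(p1_prior, om, 3, 1000) == pytest.approx(0.0)
    # worked single-SNP example: (0.99/0.01) * (0.99/0.01) = 9801
    assert bayes_factor(0.99, 0.01, 1, 1000) == pytest.approx(
        np.log10(9801), abs=1e-6)
    assert bayes_factor(0.99, 0.01, 1, 1000) > 2.0  # decisive call
    # saturated probabilities clamp at +-(log10(draws) + 2)
    assert bayes_factor(1.0, 0.01, 1, 1000) == pytest.approx(5.0)
    assert bayes_factor(0.0, 0.01, 1, 1000) == pytest.approx(-5.0)
    with pytest.raises(ValueError):
        bayes_factor(0.5, 0.01, 0, 1000)


def test_bfdr_worked_example_and_edges():
    lfdrs = list(zip("abcd", [0.01, 0.02, 0.10, 0.90]))
    # running means 0.01, 0.015, 0.0433 < 0.05; adding 0.90 gives 0.2575
    assert bfdr_select(lfdrs, alpha=0.05) == ["a", "b", "c"]
    assert bfdr_select([("a", 0.0), ("b", 0.0)], 0.05) == ["a", "b"]
    assert bfdr_select([("a", 0.5), ("b", 0.9)], 0.05) == []
    assert bfdr_select([], 0.05) == []


def test_bfdr_selection_nested_in_alpha():
    rng = np.random.default_rng(1)
    lfdrs = [(i, v) for i, v in enumerate(rng.random(30))]
    prev: set = set()
    for alpha in (0.01, 0.05, 0.1, 0.3, 0.9):
        sel = set(bfdr_select(lfdrs, alpha))
        assert prev <= sel
        prev = sel


def test_bfdr_ties_kept_together():
    lfdrs = [("a", 0.01), ("b", 0.04), ("c", 0.04), ("d", 0.9)]
    # prefix of 2 has mean 0.025 < 0.05; the tie group b,c extends to
    # mean 0.03 < 0.05, so both stay
    assert bfdr_select(lfdrs, 0.05) == ["a", "b", "c"]
    # with a tighter level the whole tie group is dropped as a unit
    assert bfdr_select(lfdrs, 0.028) == ["a"]


def test_block_pve_closed_form_and_limits():
    rng = np.random.default_rng(2)
    g = make_genotypes(rng.choice([-1, 0, 1], size=(50, 2)))
    # single-SNP block with constant effect b: PVE = b^2 var(x) / var(y)
    b = 0.7
    draws = 40
    beta = np.zeros((draws, 2))
    beta[:, 0] = b
    gamma = np.zeros((draws, 2), dtype=np.uint8)
    gamma[:, 0] = 1
    s = make_samples(gamma, beta=beta)
    y = rng.normal(0, 2.0, 50)
    expect = b ** 2 * np.var(g.calls[:, 0].astype(float)) / np.var(y)
    assert block_pve(s, g, 0, y) == pytest.approx(expect)
    # all-zero effects -> 0; y equal to the contribution -> 1
    assert block_pve(s, g, 1, y) == 0.0
    y_exact = g.calls[:, 0].astype(float) * b
    assert block_pve(s, g, 0, y_exact) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero-variance"):
        block_pve(s, g, 0, np.ones(50))


def test_pve_of_orthogonal_blocks_sums_to_one():
    # exactly orthogonal +-1 columns (tiled Hadamard pattern)
    block = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
    X = np.tile(block, (100, 1))
    g = make_genotypes(X)
    effects = np.array([1.0, -2.0, 0.5])
    y = X.astype(float) @ effects          # noiseless additive
    draws = 10
    beta = np.tile(effects, (draws, 1))
    gamma = np.ones((draws, 3), dtype=np.uint8)
    s = make_samples(gamma, beta=beta)
    total = sum(block_pve(s, g, k, y) for k in range(3))
    assert total == pytest.approx(1.0, abs=0.01)


def test_qtl_report_layers_and_flags():
    gamma = np.zeros((100, 3), dtype=np.uint8)
    gamma[:, 0] = 1                         # block 0 always in
    beta = np.zeros((100, 3))
    beta[:, 0] = 2.0
    s = make_samples(gamma, beta=beta, omega=0.05)
    rng = np.random.default_rng(4)
    g = make_genotypes(rng.choice([-1, 1], size=(60, 3)), pos=[10, 2000, 3500])
    y = 2.0 * g.calls[:, 0].astype(float) + rng.normal(0, 0.5, 60)
    rep = qtl_report(s, g, y, alpha=0.05)
    assert set(rep["effect_type"]) == {"main"}
    row0 = rep[rep["block_id"] == 0].iloc[0]
    assert row0["bfdr_selected"] and row0["major"]
    assert row0["local_fdr"] == pytest.approx(1 - row0["inclusion_prob"])
    assert not rep[rep["block_id"] == 1].iloc[0]["bfdr_selected"]
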