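"""Bayesian multiple-locus multi-environment SNP regression fitters.

The LD-aware model for line *i* in environment *j* is

    y_ij = β0 + β0j + α_i + Σ_k Σ_l x_ikl β_kl + Σ_k Σ_l x_ikl β_jkl + e_ij

with spike-and-slab priors on every SNP effect: β ~ γ·N(0, σ²_jk) +
(1−γ)·δ₀, γ ~ Bernoulli(ω), ω ~ Beta(a, b).  SNPs within an LD block k
share the slab variance σ²_jk, which is what distinguishes the LD-aware
model from Bayes C (one common slab variance) and Bayes B (one slab
variance per SNP, i.e. a scaled-t slab).  α_i is a per-line random
intercept inducing a within-line covariance σ²_α across environments;
e_ij ~ N(0, σ²₀).

Variance components carry Inverse-Gamma(shape=c, rate=d) priors
(equivalently Scaled-Inv-χ²(ν=2c, s²=d/c), prior mode d/(c+1)) with
BGLR-style default scales derived from var(y), the assumed genetic R²,
and mean(diag(XᵀX)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _gibbs
from .genotypes import GenotypeMatrix, PhenotypeTable
from .ldblocks import LDBlockSet


@dataclass
class ModelSpec:
    """Hyperparameters of the spike-and-slab model.

    a, b : Beta prior on the inclusion proportion ω (default 25, 25:
        prior mean 0.5, no preference for inclusion).
    c : shape of the Inverse-Gamma variance priors (default 5/2).
    r2_assumed : assumed proportion of phenotype variance explained by
        the genetic component; sets the variance-prior scales.
    d_alpha : rate of the random-intercept variance prior (default 5/2).
    include_gxe : fit the environment-specific effect layer.
    fixed_* / fit_intercept : validation knobs that pin σ²₀, the slab
        variance, or ω to known values (None = sample them).
    """

    a: float = 25.0
    b: float = 25.0
    c: float = 2.5
    r2_assumed: float = 0.5
    d_alpha: float = 2.5
    include_gxe: bool = True
    fixed_sigma2_0: Optional[float] = None
    fixed_slab_var: Optional[float] = None
    fixed_omega: Optional[float] = None
    fit_intercept: bool = True

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("a, b, c must be positive")
        if not 0 < self.r2_assumed < 1:
            raise ValueError("r2_assumed must lie in (0, 1)")

    def scales(self, var_y: float, mean_diag_xtx: float):
        """Variance-prior rates (d0 residual, d_slab SNP effects)."""
        d0 = var_y * (1.0 - self.r2_assumed) * (self.c + 1.0)
        d_slab = var_y * self.r2_assumed * (self.c + 1.0) / mean_diag_xtx
        return d0, d_slab


@dataclass
class MCMCConfig:
    """Gibbs schedule; defaults give (60000-10000)/50 = 1000 kept draws."""

    n_iter: int = 60000
    burn_in: int = 10000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        kept = (self.n_iter - self.burn_in) / self.thin
        if kept <= 0 or kept != int(kept):
            raise ValueError("(n_iter - burn_in)/thin must be a positive integer")
        self.seed = int(self.seed) % 2**31   # numba RNG takes uint32 seeds

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


#: reduced schedule used for replicate simulation studies (500 kept draws)
REPLICATE_MCMC = dict(n_iter=2000, burn_in=500, thin=3)


@dataclass
class PosteriorSamples:
    """Kept MCMC draws of all model parameters.

    Effect/indicator draws have shape (n_kept, p); the G×E layer, when
    fitted, has shape (n_kept, m, p).  β is exactly 0 wherever γ is 0.
    """

    method: str
    line_ids: list
    snp_ids: np.ndarray
    block_of_snp: np.ndarray
    blocks: Optional[LDBlockSet]
    m: int
    beta0: np.ndarray
    beta0j: np.ndarray
    alpha: Optional[np.ndarray]
    beta: np.ndarray
    gamma: np.ndarray
    beta_gxe: Optional[np.ndarray]
    gamma_gxe: Optional[np.ndarray]
    omega: np.ndarray
    sigma2_0: np.ndarray
    sigma2_alpha: Optional[np.ndarray]
    sigma2_block: np.ndarray
    sigma2_block_gxe: Optional[np.ndarray]
    spec: ModelSpec = field(default_factory=ModelSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    @property
    def n_kept(self) -> int:
        return self.beta.shape[0]

    @property
    def n_snps(self) -> int:
        return self.beta.shape[1]

    def pip(self, env: Optional[int] = None) -> np.ndarray:
        """Per-SNP posterior inclusion probability (main layer, or the
        G×E layer of environment ``env`` counted 1..m)."""
        if env is None:
            return self.gamma.mean(axis=0)
        if self.gamma_gxe is None:
            raise ValueError("model fitted without a G×E layer")
        return self.gamma_gxe[:, env - 1, :].mean(axis=0)

    def mean_effects(self, env: Optional[int] = None) -> np.ndarray:
        """Posterior-mean SNP effects, averaged over draws including the
        zero draws (shrunken estimates)."""
        if env is None:
            return self.beta.mean(axis=0)
        if self.beta_gxe is None:
            raise ValueError("model fitted without a G×E layer")
        return self.beta_gxe[:, env - 1, :].mean(axis=0)

    @property
    def omega_mean(self) -> float:
        return float(self.omega.mean())

    def block_members(self, block_id: int) -> np.ndarray:
        if self.blocks is not None:
            return self.blocks.members(block_id)
        return np.flatnonzero(self.block_of_snp == block_id)

    def to_frame(self):
        """Kept draws in tidy long form: one row per (draw, layer,
        parameter), columns draw/layer/name/value — suitable for CSV or
        parquet persistence."""
        import pandas as pd

        frames = []

        def melt(arr, layer, names):
            df = pd.DataFrame(np.asarray(arr, dtype=float), columns=names)
            df.insert(0, "draw", np.arange(len(df)))
            long = df.melt(id_vars="draw", var_name="name",
                           value_name="value")
            long.insert(1, "layer", layer)
            frames.append(long)

        snps = [str(s) for s in self.snp_ids]
        melt(self.beta0[:, None], "intercept", ["beta0"])
        melt(self.beta0j, "intercept", [f"beta0_env{j + 1}"
                                        for j in range(self.m)])
        melt(self.beta, "main_effect", snps)
        melt(self.gamma, "main_indicator", snps)
        if self.beta_gxe is not None:
            for j in range(self.m):
                melt(self.beta_gxe[:, j, :], f"gxe_effect_env{j + 1}", snps)
                melt(self.gamma_gxe[:, j, :], f"gxe_indicator_env{j + 1}",
                     snps)
        melt(self.omega[:, None], "hyper", ["omega"])
        melt(self.sigma2_0[:, None], "variance", ["sigma2_0"])
        if self.sigma2_alpha is not None:
            melt(self.sigma2_alpha[:, None], "variance", ["sigma2_alpha"])
        melt(self.sigma2_block, "block_variance",
             [f"block{b}" for b in range(self.sigma2_block.shape[1])])
        return pd.concat(frames, ignore_index=True)


def _stack_observations(y_mat: np.ndarray):
    """Stack a (n_lines, m) trait matrix (NaN = unobserved) into
    environment-sorted observation vectors plus CSR index arrays."""
    n, m = y_mat.shape
    obs_line, obs_env, y = [], [], []
    env_ptr = [0]
    for j in range(m):
        for i in range(n):
            if np.isfinite(y_mat[i, j]):
                obs_line.append(i)
                obs_env.append(j)
                y.append(y_mat[i, j])
        env_ptr.append(len(y))
    obs_line = np.asarray(obs_line, dtype=np.int64)
    y = np.asarray(y, dtype=np.float64)
    env_ptr = np.asarray(env_ptr, dtype=np.int64)
    # CSR of observations per line
    order = np.argsort(obs_line, kind="stable")
    line_idx = order.astype(np.int64)
    counts = np.bincount(obs_line, minlength=n)
    line_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return y, obs_line, env_ptr, line_ptr, line_idx


def _run_chain(X: np.ndarray, y_mat: np.ndarray, group: np.ndarray,
               n_groups: int, spec: ModelSpec, mcmc: MCMCConfig,
               include_alpha: bool, include_gxe: bool):
    y, obs_line, env_ptr, line_ptr, line_idx = _stack_observations(y_mat)
    if not np.isfinite(y).all() or y.size == 0:
        raise ValueError("non-finite or empty phenotype vector")
    m = y_mat.shape[1]
    Xt = np.ascontiguousarray(X.T, dtype=np.float64)
    var_y = float(np.var(y))
    mean_diag = float(np.mean(np.sum(X * X, axis=0)))
    if mean_diag <= 0:
        raise ValueError("degenerate genotype matrix (all-zero columns)")
    d0, d_slab = spec.scales(var_y if var_y > 0 else 1.0, mean_diag)
    res = _gibbs.spike_slab_chain(
        Xt, y, obs_line, env_ptr, line_ptr, line_idx,
        group.astype(np.int64), n_groups, m,
        spec.a, spec.b, spec.c, d0, spec.d_alpha, d_slab,
        include_alpha, include_gxe, spec.fit_intercept,
        mcmc.n_iter, mcmc.burn_in, mcmc.thin, mcmc.seed,
        -1.0 if spec.fixed_sigma2_0 is None else spec.fixed_sigma2_0,
        -1.0 if spec.fixed_slab_var is None else spec.fixed_slab_var,
        -1.0 if spec.fixed_omega is None else spec.fixed_omega)
    return res


def _prepare_xy(g: GenotypeMatrix, y: PhenotypeTable, trait: Optional[str]):
    if g.has_missing:
        raise ValueError("impute genotypes before fitting")
    traits = y.traits
    if trait is None:
        if len(traits) != 1:
            raise ValueError(f"specify one of the traits {traits}")
        trait = traits[0]
    unknown = set(y.data["line"]) - set(g.lines)
    if unknown:
        raise ValueError(f"phenotype lines absent from genotypes: "
                         f"{sorted(unknown)[:5]}")
    y_mat = y.trait_matrix(trait, g.lines)
    if not np.isfinite(y.data["value"]).all():
        raise ValueError("non-finite phenotype values")
    return g.calls.astype(np.float64), y_mat, trait


def fit_ldbayes(g: GenotypeMatrix, y: PhenotypeTable, blocks: LDBlockSet,
                spec: Optional[ModelSpec] = None,
                mcmc: Optional[MCMCConfig] = None,
                trait: Optional[str] = None) -> PosteriorSamples:
    """Fit the LD-block multiple-locus multi-environment model by Gibbs
    sampling.  SNPs within a block share their slab variance; with more
    than one environment a per-line random intercept and (optionally) the
    G×E effect layer are included.  Reproducible given ``mcmc.seed``."""
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    X, y_mat, trait = _prepare_xy(g, y, trait)
    group = blocks.snp_to_block
    if (group < 0).any():
        raise ValueError("some SNPs are not assigned to any LD block")
    m = y_mat.shape[1]
    include_alpha = m > 1
    include_gxe = spec.include_gxe and m > 1
    res = _run_chain(X, y_mat, group, blocks.n_blocks, spec, mcmc,
                     include_alpha, include_gxe)
    (b0, b0j, al, be, ga, beg, gag, om, s20, s2a, s2b, s2bg) = res
    return PosteriorSamples(
        method="ldbayes", line_ids=list(g.lines), snp_ids=g.snp_ids,
        block_of_snp=group.copy(), blocks=blocks, m=m,
        beta0=b0, beta0j=b0j, alpha=al if include_alpha else None,
        beta=be, gamma=ga,
        beta_gxe=beg if include_gxe else None,
        gamma_gxe=gag if include_gxe else None,
        omega=om, sigma2_0=s20,
        sigma2_alpha=s2a if include_alpha else None,
        sigma2_block=s2b,
        sigma2_block_gxe=s2bg if include_gxe else None,
        spec=spec, mcmc=mcmc)


def _fit_single_env(g: GenotypeMatrix, y, mcmc, spec, group, n_groups,
                    method: str) -> PosteriorSamples:
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    y_vec = _as_single_env_vector(g, y)
    X = g.calls.astype(np.float64)
    if g.has_missing:
        raise ValueError("impute genotypes before fitting")
    res = _run_chain(X, y_vec[:, None], group, n_groups, spec, mcmc,
                     include_alpha=False, include_gxe=False)
    (b0, b0j, _, be, ga, _, _, om, s20, _, s2b, _) = res
    return PosteriorSamples(
        method=method, line_ids=list(g.lines), snp_ids=g.snp_ids,
        block_of_snp=group.copy(), blocks=None, m=1,
        beta0=b0, beta0j=b0j, alpha=None, beta=be, gamma=ga,
        beta_gxe=None, gamma_gxe=None, omega=om, sigma2_0=s20,
        sigma2_alpha=None, sigma2_block=s2b, sigma2_block_gxe=None,
        spec=spec, mcmc=mcmc)


def _as_single_env_vector(g: GenotypeMatrix, y) -> np.ndarray:
    if isinstance(y, PhenotypeTable):
        if len(y.environments) != 1:
            raise ValueError("single-environment fitter got multi-env data")
        mat = y.trait_matrix(y.traits[0], g.lines)
        vec = mat[:, 0]
    else:
        vec = np.asarray(y, dtype=np.float64)
    if vec.shape[0] != g.n_lines:
        raise ValueError("response length does not match line count")
    if not np.isfinite(vec).all():
        raise ValueError("non-finite phenotype values")
    return vec


def fit_bayes_b(g: GenotypeMatrix, y, mcmc: Optional[MCMCConfig] = None,
                spec: Optional[ModelSpec] = None) -> PosteriorSamples:
    """Bayes B: per-SNP indicators with a scaled-t slab, realised as a
    spike-and-slab with one slab-variance component per SNP."""
    group = np.arange(g.n_snps, dtype=np.int64)
    return _fit_single_env(g, y, mcmc, spec, group, g.n_snps, "bayesb")


def fit_bayes_c(g: GenotypeMatrix, y, mcmc: Optional[MCMCConfig] = None,
                spec: Optional[ModelSpec] = None) -> PosteriorSamples:
    """Bayes C: per-SNP indicators with a single common normal slab."""
    group = np.zeros(g.n_snps, dtype=np.int64)
    return _fit_single_env(g, y, mcmc, spec, group, 1, "bayesc")


# ---------------------------------------------------------------------------
# Bayesian G-BLUP
# ---------------------------------------------------------------------------

@dataclass
class GBLUPResult:
    """Posterior draws from the Bayesian G-BLUP random-effect model
    y = 1μ + u + e, u ~ N(0, G σ²_g), e ~ N(0, I σ²_e)."""

    line_ids: list
    G: np.ndarray
    mu: np.ndarray
    u: np.ndarray               # (n_kept, n) genetic values
    sigma2_g: np.ndarray
    sigma2_e: np.ndarray

    @property
    def u_mean(self) -> np.ndarray:
        return self.u.mean(axis=0)

    def predict(self, G_cross: np.ndarray) -> np.ndarray:
        """Conditional-mean genetic values of new lines given a
        (new × trained) relationship block."""
        Gt = self.G + 1e-8 * np.eye(len(self.line_ids))
        return G_cross @ np.linalg.solve(Gt, self.u_mean)


def fit_gblup(g_or_grm, y, mcmc: Optional[MCMCConfig] = None,
              spec: Optional[ModelSpec] = None) -> GBLUPResult:
    """Fit Bayesian G-BLUP by Gibbs sampling in the eigenbasis of the
    VanRaden genomic relationship matrix.

    ``g_or_grm`` may be a GenotypeMatrix (the GRM is computed) or a
    precomputed relationship matrix.  Eigenvalues below 1e-8 are dropped
    from the genetic term (singular-G regularisation).
    """
    from .heritability import vanraden_grm

    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    if isinstance(g_or_grm, GenotypeMatrix):
        line_ids = list(g_or_grm.lines)
        G = vanraden_grm(g_or_grm)
        y_vec = _as_single_env_vector(g_or_grm, y)
    else:
        G = np.asarray(g_or_grm, dtype=np.float64)
        line_ids = list(range(G.shape[0]))
        y_vec = np.asarray(y, dtype=np.float64)
    n = G.shape[0]
    lam, U = np.linalg.eigh(G)
    lam = np.clip(lam, 0.0, None)
    pos = lam > 1e-8
    y_t = U.T @ y_vec
    one_t = U.T @ np.ones(n)

    var_y = float(np.var(y_vec))
    c = spec.c
    d0 = var_y * (1.0 - spec.r2_assumed) * (c + 1.0)
    mdg = float(np.mean(np.diag(G)))
    dg = var_y * spec.r2_assumed * (c + 1.0) / max(mdg, 1e-12)

    rng = np.random.default_rng(mcmc.seed)
    mu = float(y_vec.mean())
    u_t = np.zeros(n)
    s2g, s2e = dg / (c + 1.0), d0 / (c + 1.0)
    n_keep = mcmc.n_kept
    keep_mu = np.zeros(n_keep)
    keep_u = np.zeros((n_keep, n))
    keep_g = np.zeros(n_keep)
    keep_e = np.zeros(n_keep)
    kept = 0
    npos = int(pos.sum())
    for it in range(mcmc.n_iter):
        # mu (flat prior)
        r = y_t - one_t * mu - u_t
        mu = mu + (one_t @ r) / n + np.sqrt(s2e / n) * rng.standard_normal()
        # genetic values in the eigenbasis (independent scalars)
        resid = y_t - one_t * mu
        prec = 1.0 / s2e + 1.0 / np.maximum(lam * s2g, 1e-300)
        mean = (resid / s2e) / prec
        u_t = np.where(pos, mean + rng.standard_normal(n) / np.sqrt(prec), 0.0)
        # variance components
        ssg = float(np.sum(u_t[pos] ** 2 / lam[pos]))
        s2g = max(1.0 / rng.gamma(c + 0.5 * npos, 1.0 / (dg + 0.5 * ssg)),
                  _gibbs.VAR_FLOOR)
        sse = float(np.sum((resid - u_t) ** 2))
        s2e = max(1.0 / rng.gamma(c + 0.5 * n, 1.0 / (d0 + 0.5 * sse)),
                  _gibbs.VAR_FLOOR)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
            keep_mu[kept] = mu
            keep_u[kept] = U @ u_t
            keep_g[kept] = s2g
            keep_e[kept] = s2e
            kept += 1
    return GBLUPResult(line_ids, G, keep_mu, keep_u, keep_g, keep_e)
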