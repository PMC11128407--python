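"""Block-level QTL calling from posterior samples.

A block's inclusion event Z_k = 1 means at least one member SNP carries a
non-zero effect in a draw.  The block Bayes factor converts posterior to
prior odds of that event, with prior P(Z_k = 0) = (1 − ω̂)^{q_k}.
Multiplicity is handled by the Bayesian FDR rule on local FDRs
(1 − inclusion probability).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .model import PosteriorSamples

#: log10(BF) above which a block is conventionally called decisive
DECISIVE_LOG10_BF = 2.0


def _member_gamma(s: PosteriorSamples, block_id: int, env: Optional[int]):
    members = s.block_members(block_id)
    if len(members) == 0:
        raise ValueError(f"block {block_id} has no member SNPs")
    if env is None:
        return s.gamma[:, members]
    if s.gamma_gxe is None:
        raise ValueError("model fitted without a G×E layer")
    return s.gamma_gxe[:, env - 1, members]


def block_inclusion_prob(s: PosteriorSamples, block_id: int,
                         env: Optional[int] = None) -> float:
    """Fraction of kept draws in which any member SNP has γ = 1."""
    gam = _member_gamma(s, block_id, env)
    return float((gam.any(axis=1)).mean())


def bayes_factor(p_incl: float, omega_hat: float, q_k: int,
                 n_draws: int) -> float:
    """log10 Bayes factor of Z=1 vs Z=0 from a posterior inclusion
    probability, the posterior mean of ω, and the block size q_k.

    BF = [P(Z=1|Y) / P(Z=0|Y)] · [P(Z=0) / P(Z=1)] with
    P(Z=0) = (1 − ω̂)^{q_k}.  Posterior probabilities of exactly 0 or 1
    are beyond the resolution of a finite chain, so ±inf is clamped to
    ±(log10(n_draws) + 2).
    """
    if q_k < 1:
        raise ValueError("block size q_k must be >= 1")
    clamp = np.log10(n_draws) + 2.0
    p0_prior = (1.0 - omega_hat) ** q_k
    prior_odds = (1.0 - p0_prior) / p0_prior
    if p_incl >= 1.0:
        return clamp
    if p_incl <= 0.0:
        return -clamp
    post_odds = p_incl / (1.0 - p_incl)
    val = np.log10(post_odds / prior_odds)
    return float(np.clip(val, -clamp, clamp))


def block_bayes_factor(s: PosteriorSamples, block_id: int,
                       env: Optional[int] = None,
                       omega_hat: Optional[float] = None) -> float:
    """log10 Bayes factor for one block (Bayes-factor clamping as in
    :func:`bayes_factor`)."""
    p_incl = block_inclusion_prob(s, block_id, env)
    om = s.omega_mean if omega_hat is None else omega_hat
    q_k = len(s.block_members(block_id))
    return bayes_factor(p_incl, om, q_k, s.n_kept)


def bfdr_select(local_fdrs: Sequence, alpha: float = 0.05) -> list:
    """Bayesian-FDR selection at level ``alpha``.

    ``local_fdrs`` is a sequence of (id, LFDR) pairs.  LFDRs are sorted
    ascending (ties broken by id, kept together); the largest prefix
    whose running mean stays below ``alpha`` is selected.  If the cut
    would split a group of exactly equal LFDRs, the whole group is
    included only when the extended running mean remains below alpha,
    otherwise the whole group is dropped.
    """
    items = sorted(local_fdrs, key=lambda kv: (kv[1], str(kv[0])))
    if not items:
        return []
    vals = np.array([v for _, v in items], dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("LFDRs must lie in [0, 1]")
    means = np.cumsum(vals) / np.arange(1, len(vals) + 1)
    admissible = means < alpha
    r = int(np.max(np.flatnonzero(admissible)) + 1) if admissible.any() else 0
    if 0 < r < len(vals) and vals[r] == vals[r - 1]:
        # extend over the tie group if the mean allows, else drop it
        hi = r
        while hi < len(vals) and vals[hi] == vals[r - 1]:
            hi += 1
        if means[hi - 1] < alpha:
            r = hi
        else:
            lo = r
            while lo > 0 and vals[lo - 1] == vals[r - 1]:
                lo -= 1
            r = lo
    return [items[i][0] for i in range(r)]


def block_pve(s: PosteriorSamples, g: GenotypeMatrix, block_id: int,
              y: np.ndarray, env: Optional[int] = None) -> float:
    """Proportion of phenotype variance explained by a block: variance
    over lines of the member-SNP contribution at posterior-mean
    (shrunken) effects, divided by Var(y); clipped to [0, 1]."""
    y = np.asarray(y, dtype=float)
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("zero-variance response")
    members = s.block_members(block_id)
    eff = s.mean_effects(env)[members]
    contrib = g.calls[:, members].astype(float) @ eff
    return float(np.clip(np.var(contrib) / vy, 0.0, 1.0))


def qtl_report(s: PosteriorSamples, g: GenotypeMatrix, y: np.ndarray,
               alpha: float = 0.05, major_pve: float = 0.05,
               include_gxe: bool = True) -> pd.DataFrame:
    """Per-block QTL report for the main-effect layer and, if fitted,
    each environment's G×E layer.

    Columns: effect_type, block_id, chrom, start_kb, end_kb, q_k,
    inclusion_prob, log10_bf, local_fdr, pve, bfdr_selected, major.
    BFDR selection is run separately per layer; "major" flags selected
    blocks with PVE at or above ``major_pve``.
    """
    if s.blocks is None:
        raise ValueError("qtl_report requires a block-level fit")
    layers = [("main", None)]
    if include_gxe and s.gamma_gxe is not None:
        layers += [(f"gxe_env{j}", j) for j in range(1, s.m + 1)]
    rows = []
    om = s.omega_mean
    for name, env in layers:
        lfdrs = []
        for bid, chrom, members in s.blocks.blocks:
            p_incl = block_inclusion_prob(s, bid, env)
            lfdrs.append((bid, 1.0 - p_incl))
            rows.append({
                "effect_type": name, "block_id": bid, "chrom": chrom,
                "start_kb": g.pos[members].min() / 1e3,
                "end_kb": g.pos[members].max() / 1e3,
                "q_k": len(members),
                "inclusion_prob": p_incl,
                "log10_bf": bayes_factor(p_incl, om, len(members), s.n_kept),
                "local_fdr": 1.0 - p_incl,
                "pve": block_pve(s, g, bid, y, env),
            })
        selected = set(bfdr_select(lfdrs, alpha))
        for row in rows:
            if row["effect_type"] == name:
                row["bfdr_selected"] = row["block_id"] in selected
                row["major"] = row["bfdr_selected"] and row["pve"] >= major_pve
    return pd.DataFrame(rows)


def significant_blocks(s: PosteriorSamples, bf_threshold: float = 100.0,
                       env: Optional[int] = None) -> list:
    """Blocks whose Bayes factor exceeds ``bf_threshold`` (decisive
    evidence at the default 100)."""
    if s.blocks is None:
        raise ValueError("requires a block-level fit")
    thr = np.log10(bf_threshold)
    out = []
    for bid, _, _ in s.blocks.blocks:
        if block_bayes_factor(s, bid, env) > thr:
            out.append(bid)
    return out


def significant_snps(s: PosteriorSamples, bf_threshold: float = 100.0) -> list:
    """SNP indices whose per-SNP Bayes factor (q_k = 1) exceeds the
    threshold — the per-SNP calling rule used with Bayes B / Bayes C."""
    thr = np.log10(bf_threshold)
    pips = s.pip()
    om = s.omega_mean
    return [int(l) for l in range(s.n_snps)
            if bayes_factor(float(pips[l]), om, 1, s.n_kept) > thr]
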