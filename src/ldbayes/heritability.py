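"""Genomic relationship matrix and heritability estimators.

Two heritabilities are computed for line-mean data from replicated
trials:

* genomic heritability h_g² by the average-semivariance (ASV) estimator,
  h_g² = [tr(G)/(n−1)·σ²_g] / [tr(G)/(n−1)·σ²_g + σ²_e], evaluated per
  posterior draw of the Bayesian G-BLUP variance components;
* a narrow-sense point estimate for near-homozygous inbred-line panels,
  h_N² = (σ²_g/2) / (σ²_g + v̄/2), where the additive variance is
  approximated by half the line variance and v̄ is the mean variance of a
  difference between two adjusted line means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class VarianceComponents:
    """Genetic/residual variance estimates feeding the heritability
    formulas.  ``sigma2_g``/``sigma2_e`` may be scalars or posterior draw
    arrays (source "bgblup_posterior").  ``mean_sed`` is v̄, the mean
    variance of a difference between two adjusted line means, i.e. the
    square of the average s.e.d. from a mixed-model analysis."""

    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    n: int
    mean_sed: float = 0.0
    source: str = "external"

    def __post_init__(self):
        self.sigma2_g = np.atleast_1d(np.asarray(self.sigma2_g, dtype=float))
        self.sigma2_e = np.atleast_1d(np.asarray(self.sigma2_e, dtype=float))
        if (self.sigma2_g < 0).any() or (self.sigma2_e < 0).any():
            raise ValueError("variances must be non-negative")
        if self.n < 2:
            raise ValueError("need at least two lines")

    @classmethod
    def from_gblup(cls, res, mean_sed: float = 0.0) -> "VarianceComponents":
        return cls(res.sigma2_g, res.sigma2_e, n=len(res.line_ids),
                   mean_sed=mean_sed, source="bgblup_posterior")


def vanraden_grm(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    Allele counts (0/1/2 from the −1/0/1 coding) are centred at 2p per
    SNP and the cross-product scaled by 2Σp(1−p).  Monomorphic SNPs
    contribute no scale and are excluded with a warning.
    """
    if g.has_missing:
        raise ValueError("impute genotypes before computing the GRM")
    M = g.calls.astype(np.float64) + 1.0      # 0/1/2 allele counts
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs "
                      "from the GRM")
    M, p = M[:, poly], p[poly]
    if M.shape[1] == 0:
        raise ValueError("no polymorphic SNPs")
    Z = M - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    return (Z @ Z.T) / scale


def asv_h2(vc: VarianceComponents, G: np.ndarray):
    """Average-semivariance genomic heritability.

    Evaluated per posterior draw when draws are supplied; returns
    ``(mean, se)`` where the SE is the posterior SD of the draws (0.0 for
    scalar inputs).
    """
    k = np.trace(G) / (vc.n - 1)
    if not np.isfinite(k):
        raise ValueError("non-finite trace of G")
    num = k * vc.sigma2_g
    den = num + vc.sigma2_e
    if np.any(den == 0):
        raise ValueError("undefined heritability: both variances are zero")
    draws = num / den
    se = float(draws.std(ddof=1)) if draws.size > 1 else 0.0
    return float(draws.mean()), se


def narrow_sense_h2(vc: VarianceComponents) -> float:
    """Narrow-sense point estimate h_N² = (σ²_g/2)/(σ²_g + v̄/2) using the
    half-line-variance additive approximation; v̄ is ``vc.mean_sed``
    (see :func:`sed_variance_from_replicates` for the synthetic-run
    stand-in)."""
    s2g = float(np.mean(vc.sigma2_g))
    vbar = vc.mean_sed
    if vbar < 0:
        raise ValueError("mean s.e.d. variance must be non-negative")
    den = s2g + 0.5 * vbar
    if den == 0:
        raise ValueError("zero denominator in narrow-sense heritability")
    return (0.5 * s2g) / den


def sed_variance_from_replicates(residual_var: float, n_reps: int) -> float:
    """Stand-in v̄ for synthetic data: the variance of a difference of two
    line means, 2σ²_ε/r, when no mixed-model s.e.d. output is available."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    return 2.0 * residual_var / n_reps
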