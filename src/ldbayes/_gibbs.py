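"""Numba Gibbs kernel for spike-and-slab SNP regression.

One kernel covers the whole model family:

* main additive SNP effects with spike-and-slab priors, where the slab
  variance is shared within *groups* of SNPs (LD blocks for the LD-aware
  model; one group per SNP for a scaled-t slab; a single group for a
  common-variance slab);
* optional environment-specific (G×E) effect layer with per-(env, group)
  slab variances;
* optional per-line random intercepts (multi-environment data);
* global and per-environment fixed intercepts with flat priors;
* Beta-distributed inclusion proportion ω shared by all indicators;
* Inverse-Gamma(shape=c, rate=d) priors on every variance component
  (equivalently Scaled-Inv-χ²(ν=2c, s²=d/c)); prior mode d/(c+1).

Observations are stacked (line, environment) records sorted by
environment; CSR index arrays give the observations of each environment
and of each line.  (γ, β) are updated jointly per SNP: γ from its
marginalised Bernoulli conditional, then β | γ=1 from its normal
conditional.  Fixed-value overrides (pass > 0) pin σ₀², the slab
variance, or ω for validation against exhaustive enumeration.
"""

import numpy as np
from numba import njit

VAR_FLOOR = 1e-10


@njit(cache=False)
def _inv_gamma(shape, rate):
    g = np.random.gamma(shape, 1.0 / rate)
    if g < 1e-300:
        g = 1e-300
    v = 1.0 / g
    return v if v > VAR_FLOOR else VAR_FLOOR


@njit(cache=False)
def spike_slab_chain(Xt, y, obs_line, env_ptr, line_ptr, line_idx,
                     group, n_groups, m,
                     a, b, c, d0, d_alpha, d_slab,
                     include_alpha, include_gxe, fit_intercept,
                     n_iter, burn_in, thin, seed,
                     fixed_sigma2_0, fixed_slab_var, fixed_omega):
    """Run the Gibbs chain; returns the kept (thinned, post-burn-in) draws.

    Parameters are documented in :func:`ldbayes.model.fit_ldbayes`; this
    kernel is not part of the public API.
    """
    np.random.seed(seed)
    p, n = Xt.shape
    N = y.shape[0]
    n_keep = (n_iter - burn_in) // thin

    # sufficient statistics
    sxx_all = np.zeros(p)
    sxx_env = np.zeros((m, p))
    for l in range(p):
        s = 0.0
        for o in range(N):
            v = Xt[l, obs_line[o]]
            s += v * v
        sxx_all[l] = s
        for j in range(m):
            se = 0.0
            for o in range(env_ptr[j], env_ptr[j + 1]):
                v = Xt[l, obs_line[o]]
                se += v * v
            sxx_env[j, l] = se

    # state
    beta0 = 0.0
    beta0j = np.zeros(m)
    alpha = np.zeros(n)
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.uint8)
    beta_g = np.zeros((m, p))
    gamma_g = np.zeros((m, p), dtype=np.uint8)
    s2_blk = np.full(n_groups, d_slab / (c + 1.0))
    s2_gxe = np.full((m, n_groups), d_slab / (c + 1.0))
    omega = a / (a + b) if fixed_omega <= 0.0 else fixed_omega
    s2_0 = d0 / (c + 1.0) if fixed_sigma2_0 <= 0.0 else fixed_sigma2_0
    s2_a = d_alpha / (c + 1.0)
    if fixed_slab_var > 0.0:
        s2_blk[:] = fixed_slab_var
        s2_gxe[:, :] = fixed_slab_var

    r = y.copy()  # residual: y minus every fitted term

    # draw storage
    keep_beta0 = np.zeros(n_keep)
    keep_beta0j = np.zeros((n_keep, m))
    keep_alpha = np.zeros((n_keep, n))
    keep_beta = np.zeros((n_keep, p))
    keep_gamma = np.zeros((n_keep, p), dtype=np.uint8)
    keep_beta_g = np.zeros((n_keep, m, p)) if include_gxe else np.zeros((1, 1, 1))
    keep_gamma_g = np.zeros((n_keep, m, p), dtype=np.uint8) if include_gxe \
        else np.zeros((1, 1, 1), dtype=np.uint8)
    keep_omega = np.zeros(n_keep)
    keep_s2_0 = np.zeros(n_keep)
    keep_s2_a = np.zeros(n_keep)
    keep_s2_blk = np.zeros((n_keep, n_groups))
    keep_s2_gxe = np.zeros((n_keep, m, n_groups)) if include_gxe \
        else np.zeros((1, 1, 1))

    kept = 0
    for it in range(n_iter):
        # ---- intercepts (flat priors) --------------------------------
        if fit_intercept:
            sr = 0.0
            for o in range(N):
                sr += r[o]
            new = beta0 + sr / N + np.sqrt(s2_0 / N) * np.random.normal()
            delta = new - beta0
            beta0 = new
            for o in range(N):
                r[o] -= delta
            if m > 1:
                for j in range(m):
                    lo, hi = env_ptr[j], env_ptr[j + 1]
                    nj = hi - lo
                    sr = 0.0
                    for o in range(lo, hi):
                        sr += r[o]
                    new = beta0j[j] + sr / nj + \
                        np.sqrt(s2_0 / nj) * np.random.normal()
                    delta = new - beta0j[j]
                    beta0j[j] = new
                    for o in range(lo, hi):
                        r[o] -= delta
                # recentre: absorb the mean into beta0 (sum-to-zero)
                mb = 0.0
                for j in range(m):
                    mb += beta0j[j]
                mb /= m
                beta0 += mb
                for j in range(m):
                    beta0j[j] -= mb

        # ---- per-line random intercepts ------------------------------
        if include_alpha:
            for i in range(n):
                lo, hi = line_ptr[i], line_ptr[i + 1]
                ni = hi - lo
                if ni == 0:
                    alpha[i] = np.sqrt(s2_a) * np.random.normal()
                    continue
                sr = 0.0
                for t in range(lo, hi):
                    sr += r[line_idx[t]]
                prec = ni / s2_0 + 1.0 / s2_a
                mean = (sr / s2_0 + ni * alpha[i] / s2_0) / prec
                new = mean + np.random.normal() / np.sqrt(prec)
                delta = new - alpha[i]
                alpha[i] = new
                for t in range(lo, hi):
                    r[line_idx[t]] -= delta
            ssa = 0.0
            for i in range(n):
                ssa += alpha[i] * alpha[i]
            s2_a = _inv_gamma(c + 0.5 * n, d_alpha + 0.5 * ssa)

        # ---- main SNP effects: joint (gamma, beta) per SNP -----------
        log_odds_prior = np.log(omega) - np.log1p(-omega)
        for l in range(p):
            v = s2_blk[group[l]]
            bold = beta[l]
            xr = sxx_all[l] * bold
            for o in range(N):
                xr += Xt[l, obs_line[o]] * r[o]
            denom = v * sxx_all[l] + s2_0
            lo_ = log_odds_prior + 0.5 * np.log(s2_0 / denom) + \
                0.5 * v * xr * xr / (s2_0 * denom)
            # P(gamma=1 | rest)
            if lo_ > 35.0:
                p1 = 1.0
            elif lo_ < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-lo_))
            if np.random.random() < p1:
                gamma[l] = 1
                post_var = s2_0 * v / denom
                bnew = xr * v / denom + np.sqrt(post_var) * np.random.normal()
            else:
                gamma[l] = 0
                bnew = 0.0
            if bnew != bold:
                beta[l] = bnew
                delta = bnew - bold
                for o in range(N):
                    r[o] -= Xt[l, obs_line[o]] * delta

        # ---- G×E SNP effects -----------------------------------------
        if include_gxe:
            for j in range(m):
                elo, ehi = env_ptr[j], env_ptr[j + 1]
                for l in range(p):
                    v = s2_gxe[j, group[l]]
                    bold = beta_g[j, l]
                    xr = sxx_env[j, l] * bold
                    for o in range(elo, ehi):
                        xr += Xt[l, obs_line[o]] * r[o]
                    denom = v * sxx_env[j, l] + s2_0
                    lo_ = log_odds_prior + 0.5 * np.log(s2_0 / denom) + \
                        0.5 * v * xr * xr / (s2_0 * denom)
                    if lo_ > 35.0:
                        p1 = 1.0
                    elif lo_ < -35.0:
                        p1 = 0.0
                    else:
                        p1 = 1.0 / (1.0 + np.exp(-lo_))
                    if np.random.random() < p1:
                        gamma_g[j, l] = 1
                        post_var = s2_0 * v / denom
                        bnew = xr * v / denom + \
                            np.sqrt(post_var) * np.random.normal()
                    else:
                        gamma_g[j, l] = 0
                        bnew = 0.0
                    if bnew != bold:
                        beta_g[j, l] = bnew
                        delta = bnew - bold
                        for o in range(elo, ehi):
                            r[o] -= Xt[l, obs_line[o]] * delta

        # ---- inclusion proportion ------------------------------------
        k1 = 0
        K = p
        for l in range(p):
            k1 += gamma[l]
        if include_gxe:
            K += m * p
            for j in range(m):
                for l in range(p):
                    k1 += gamma_g[j, l]
        if fixed_omega <= 0.0:
            omega = np.random.beta(a + k1, b + K - k1)
            if omega < 1e-12:
                omega = 1e-12
            elif omega > 1.0 - 1e-12:
                omega = 1.0 - 1e-12

        # ---- slab variances (shared within group) --------------------
        if fixed_slab_var <= 0.0:
            cnt = np.zeros(n_groups)
            ssq = np.zeros(n_groups)
            for l in range(p):
                if gamma[l] == 1:
                    cnt[group[l]] += 1.0
                    ssq[group[l]] += beta[l] * beta[l]
            for gidx in range(n_groups):
                s2_blk[gidx] = _inv_gamma(c + 0.5 * cnt[gidx],
                                          d_slab + 0.5 * ssq[gidx])
            if include_gxe:
                for j in range(m):
                    cnt[:] = 0.0
                    ssq[:] = 0.0
                    for l in range(p):
                        if gamma_g[j, l] == 1:
                            cnt[group[l]] += 1.0
                            ssq[group[l]] += beta_g[j, l] * beta_g[j, l]
                    for gidx in range(n_groups):
                        s2_gxe[j, gidx] = _inv_gamma(
                            c + 0.5 * cnt[gidx], d_slab + 0.5 * ssq[gidx])

        # ---- residual variance ---------------------------------------
        if fixed_sigma2_0 <= 0.0:
            sse = 0.0
            for o in range(N):
                sse += r[o] * r[o]
            s2_0 = _inv_gamma(c + 0.5 * N, d0 + 0.5 * sse)

        # ---- keep ----------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            keep_beta0[kept] = beta0
            for j in range(m):
                keep_beta0j[kept, j] = beta0j[j]
            for i in range(n):
                keep_alpha[kept, i] = alpha[i]
            for l in range(p):
                keep_beta[kept, l] = beta[l]
                keep_gamma[kept, l] = gamma[l]
            if include_gxe:
                for j in range(m):
                    for l in range(p):
                        keep_beta_g[kept, j, l] = beta_g[j, l]
                        keep_gamma_g[kept, j, l] = gamma_g[j, l]
            keep_omega[kept] = omega
            keep_s2_0[kept] = s2_0
            keep_s2_a[kept] = s2_a
            for gidx in range(n_groups):
                keep_s2_blk[kept, gidx] = s2_blk[gidx]
            if include_gxe:
                for j in range(m):
                    for gidx in range(n_groups):
                        keep_s2_gxe[kept, j, gidx] = s2_gxe[j, gidx]
            kept += 1

    return (keep_beta0, keep_beta0j, keep_alpha, keep_beta, keep_gamma,
            keep_beta_g, keep_gamma_g, keep_omega, keep_s2_0, keep_s2_a,
            keep_s2_blk, keep_s2_gxe)
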