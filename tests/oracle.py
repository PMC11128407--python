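"""Independent exhaustive-enumeration oracle for spike-and-slab inclusion.

With the residual variance, slab variance and inclusion probability held
fixed and no intercept, the marginal likelihood of each indicator
configuration is a zero-mean multivariate normal with covariance
σ₀²I + v·X_γX_γᵀ, so posterior inclusion probabilities over p SNPs can
be computed exactly by summing over the 2^p configurations.  This never
touches the Gibbs code path.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def enumerate_pips(X, y, sigma2_0, slab_var, omega):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    configs = list(itertools.product([0, 1], repeat=p))
    logps = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        idx = [j for j in range(p) if cfg[j]]
        cov = sigma2_0 * np.eye(n)
        if idx:
            Xs = X[:, idx]
            cov = cov + slab_var * (Xs @ Xs.T)
        lp = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        lp += sum(np.log(omega) if c else np.log(1.0 - omega) for c in cfg)
        logps[i] = lp
    w = np.exp(logps - logps.max())
    w /= w.sum()
    return np.array([sum(w[i] for i, cfg in enumerate(configs) if cfg[j])
                     for j in range(p)])
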