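"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the colocalization
posterior is recomputed by exhaustive enumeration of per-SNP causal
configurations, and the Wakefield Bayes factor by numerical quadrature of
the Normal likelihood ratio.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.stats import norm


def quadrature_log_wabf(z: float, V: float, W: float) -> float:
    """log Bayes factor by numerical integration over the effect prior.

    beta-hat = z*sqrt(V) is Normal(beta, V); the alternative marginalizes
    beta over Normal(0, W), the null fixes beta = 0.
    """
    betahat = z * math.sqrt(V)
    sd = math.sqrt(V)

    def integrand(b):
        return norm.pdf(betahat, loc=b, scale=sd) * norm.pdf(b, loc=0.0, scale=math.sqrt(W))

    lim = 10.0 * math.sqrt(W) + abs(betahat)
    marg, _ = integrate.quad(integrand, -lim, lim, limit=200, epsabs=0, epsrel=1e-12)
    null = norm.pdf(betahat, loc=0.0, scale=sd)
    return math.log(marg) - math.log(null)


def brute_force_posterior(log_a: np.ndarray, log_b: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Five-hypothesis posterior by enumerating causal configurations.

    A configuration is (causal GWAS SNP or none, causal eQTL SNP or none);
    within a hypothesis every admissible configuration is equally likely.
    """
    a = np.exp(np.asarray(log_a, dtype=float))
    b = np.exp(np.asarray(log_b, dtype=float))
    K = a.size
    mass = np.zeros(5)
    mass[0] = pi[0] * 1.0
    for j in range(K):
        mass[1] += pi[1] / K * a[j]
        mass[2] += pi[2] / K * b[j]
        mass[4] += pi[4] / K * a[j] * b[j]
    if K > 1:
        for j in range(K):
            for l in range(K):
                if j != l:
                    mass[3] += pi[3] / (K * (K - 1)) * a[j] * b[l]
    return mass / mass.sum()


def bh_cutoff_enumeration(pvals, fdr) -> float:
    """BH step-up cutoff by direct enumeration of the rule."""
    p = sorted(pvals)
    m = len(p)
    best = 0.0
    for i, pi in enumerate(p, start=1):
        if pi <= i * fdr / m:
            best = pi
    return best
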