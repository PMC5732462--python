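"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written without calling into psaboot's
estimation code paths: brute-force likelihood maximization, a textbook
Cholesky multivariate-Normal sampler, a plain resampling bootstrap, and
closed-form expectations.
"""

from __future__ import annotations

import numpy as np


def weibull_loglik(k: float, s: float, t: np.ndarray) -> float:
    if k <= 0 or s <= 0:
        return -np.inf
    z = t / s
    return float(t.size * (np.log(k) - np.log(s))
                 + (k - 1.0) * np.log(z).sum() - np.sum(z ** k))


def _golden_max(f, lo: float, hi: float, iters: int = 80) -> float:
    """Golden-section maximization of a unimodal 1-D function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def weibull_mle_oracle(t: np.ndarray, n_grid: int = 60,
                       n_sweeps: int = 40) -> tuple[float, float]:
    """Brute-force Weibull MLE: dense 2-D grid search followed by
    coordinate-wise golden-section refinement of the log-likelihood."""
    t = np.asarray(t, dtype=float)
    ks = np.linspace(0.1, 8.0, n_grid)
    ss = np.linspace(0.2 * t.mean(), 4.0 * t.mean(), n_grid)
    best = (-np.inf, ks[0], ss[0])
    for k in ks:
        for s in ss:
            ll = weibull_loglik(k, s, t)
            if ll > best[0]:
                best = (ll, k, s)
    _, k, s = best
    dk = ks[1] - ks[0]
    ds = ss[1] - ss[0]
    for _ in range(n_sweeps):
        k = _golden_max(lambda kk: weibull_loglik(kk, s, t),
                        max(1e-6, k - dk), k + dk)
        s = _golden_max(lambda sss: weibull_loglik(k, sss, t),
                        max(1e-6, s - ds), s + ds)
        dk *= 0.5
        ds *= 0.5
    return k, s


def mvn_sample_oracle(mean: np.ndarray, cov: np.ndarray, r: int,
                      seed: int) -> np.ndarray:
    """Textbook multivariate-Normal sampler: mean + L z with L the Cholesky
    factor and z iid standard Normal, independently seeded."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((r, mean.size))
    return mean + z @ L.T


def exponential_bootstrap_oracle(times: np.ndarray, r: int, seed: int) -> np.ndarray:
    """Direct resampling bootstrap of the exponential rate n/Σt."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    n = t.size
    rates = np.empty(r)
    for i in range(r):
        rates[i] = n / t[rng.integers(0, n, n)].sum()
    return rates


def gaussian_kl(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """Closed-form KL(N(mu1,s1²) ‖ N(mu2,s2²))."""
    return float(np.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5)
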