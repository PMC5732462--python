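"""Parametric time-to-event families.

Four right-skewed families commonly used to describe patient-level variation
in time-to-event data: exponential, Weibull, gamma and log-normal. Each
family knows its parameter names, its support constraints, how to evaluate
its log-likelihood, how to draw variates, and how to compute its maximum
likelihood estimate on a sample of uncensored, strictly positive times.

Parameterizations (time ``t > 0``):

=============  ==================  =========================================
family         parameters          density
=============  ==================  =========================================
exponential    rate λ > 0          λ·exp(−λt)
weibull        shape k, scale s    (k/s)·(t/s)^{k−1}·exp(−(t/s)^k)
gamma          shape a, scale s    t^{a−1}·exp(−t/s) / (Γ(a)·s^a)
lognormal      mu ∈ ℝ, sigma > 0   exp(−(ln t − mu)²/2σ²) / (t·σ·√(2π))
=============  ==================  =========================================

MLEs use the exact closed form where one exists (exponential, log-normal)
and otherwise a one-dimensional profile-likelihood root solve (Weibull,
gamma), which is fast and reliable enough to run thousands of times inside
bootstrap loops. A sample with fewer than two distinct values makes the
two-parameter families unidentifiable (the likelihood is unbounded as the
shape grows), and is rejected as unfittable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, special, stats

from .exceptions import DataError, UnfittableError

__all__ = ["Family", "get_family", "FAMILIES"]


def _softmax_weights(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    w = np.exp(z)
    return w / w.sum()


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        t = t.ravel()
    if t.size == 0:
        raise UnfittableError("empty time sample")
    if not np.all(np.isfinite(t)):
        raise DataError("non-finite time value in sample")
    if np.any(t <= 0.0):
        raise DataError("times must be strictly positive")
    return t


# ---------------------------------------------------------------------------
# per-family MLE routines


def _mle_exponential(t: np.ndarray) -> np.ndarray:
    return np.array([t.size / t.sum()])


def _mle_lognormal(t: np.ndarray) -> np.ndarray:
    logs = np.log(t)
    mu = logs.mean()
    sigma = np.sqrt(np.mean((logs - mu) ** 2))
    if sigma <= 0.0:
        raise UnfittableError("degenerate sample: zero log-scale variance")
    return np.array([mu, sigma])


def _weibull_profile_score(k: float, logs: np.ndarray, mean_log: float) -> float:
    # d(profile loglik)/dk up to positive factor: 1/k + E[ln t] - Σ w_i ln t_i
    w = _softmax_weights(k * logs)
    return 1.0 / k + mean_log - float(w @ logs)


def _mle_weibull(t: np.ndarray) -> np.ndarray:
    logs = np.log(t)
    mean_log = logs.mean()
    lo, hi = 1e-4, 1e4
    f = lambda k: _weibull_profile_score(k, logs, mean_log)  # noqa: E731
    if f(lo) <= 0.0 or f(hi) >= 0.0:
        raise UnfittableError("Weibull profile score has no root; sample degenerate")
    k = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    scale = np.exp((special.logsumexp(k * logs) - np.log(t.size)) / k)
    return np.array([k, scale])


def _mle_gamma(t: np.ndarray) -> np.ndarray:
    s = np.log(t.mean()) - np.log(t).mean()
    if s <= 0.0:
        raise UnfittableError("degenerate sample for gamma fit")
    f = lambda a: np.log(a) - special.digamma(a) - s  # noqa: E731
    lo, hi = 1e-8, 1e8
    if f(hi) >= 0.0:
        raise UnfittableError("gamma shape diverges; sample degenerate")
    a = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return np.array([a, t.mean() / a])


# ---------------------------------------------------------------------------


# direct log-density sums (avoid scipy frozen-distribution overhead inside
# bootstrap/Hessian loops; each is the standard closed form)


def _ll_exponential(th, t):
    return t.size * np.log(th[0]) - th[0] * t.sum()


def _ll_weibull(th, t):
    k, s = th
    z = t / s
    return (t.size * (np.log(k) - np.log(s)) + (k - 1.0) * np.log(z).sum()
            - np.sum(z**k))


def _ll_gamma(th, t):
    a, s = th
    return ((a - 1.0) * np.log(t).sum() - t.sum() / s
            - t.size * (special.gammaln(a) + a * np.log(s)))


def _ll_lognormal(th, t):
    mu, sig = th
    z = (np.log(t) - mu) / sig
    return -(np.log(t).sum() + t.size * (np.log(sig) + 0.5 * np.log(2 * np.pi))
             + 0.5 * np.sum(z * z))


# direct variate draws via numpy Generator primitives


def _rvs_exponential(th, size, rng):
    return rng.exponential(1.0 / th[0], size)


def _rvs_weibull(th, size, rng):
    return th[1] * rng.weibull(th[0], size)


def _rvs_gamma(th, size, rng):
    return rng.gamma(th[0], th[1], size)


def _rvs_lognormal(th, size, rng):
    return rng.lognormal(th[0], th[1], size)


@dataclass(frozen=True)
class Family:
    """A parametric time-to-event family.

    Parameters are handled as plain ``numpy`` arrays in the order given by
    :attr:`param_names`; ``positive`` marks which entries are constrained to
    (0, ∞) (all of them except the log-normal location).
    """

    name: str
    param_names: tuple[str, ...]
    positive: tuple[bool, ...]
    _frozen: Callable[[np.ndarray], stats.rv_continuous]
    _mle: Callable[[np.ndarray], np.ndarray]
    _ll: Callable[[np.ndarray, np.ndarray], float]
    _rvs: Callable[[np.ndarray, int, np.random.Generator], np.ndarray]
    needs_two_distinct: bool

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def dist(self, theta: np.ndarray):
        """Frozen scipy distribution at parameter vector ``theta``."""
        return self._frozen(np.asarray(theta, dtype=float))

    def support_ok(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,) or not np.all(np.isfinite(theta)):
            return False
        for value, pos in zip(theta, self.positive):
            if pos and value <= 0.0:
                return False
        return True

    def loglik(self, theta: np.ndarray, times: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not self.support_ok(theta):
            return -np.inf
        return float(self._ll(theta, np.asarray(times, dtype=float)))

    def mle(self, times: np.ndarray) -> np.ndarray:
        """Maximum likelihood estimate on strictly positive times.

        Raises
        ------
        UnfittableError
            Fewer observations than parameters, or a degenerate sample
            (all values identical for a two-parameter family).
        DataError
            Non-positive or non-finite times.
        """
        t = _check_times(times)
        if t.size < max(2, self.n_params):
            raise UnfittableError(
                f"{self.name}: need >= {max(2, self.n_params)} observations, got {t.size}"
            )
        if self.needs_two_distinct and np.unique(t).size < 2:
            raise UnfittableError(f"{self.name}: all observations identical")
        return self._mle(t)

    def rvs(self, theta: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._rvs(np.asarray(theta, dtype=float), size, rng)

    def mean(self, theta: np.ndarray) -> float:
        return float(self.dist(theta).mean())


FAMILIES: dict[str, Family] = {
    "exponential": Family(
        name="exponential",
        param_names=("rate",),
        positive=(True,),
        _frozen=lambda th: stats.expon(scale=1.0 / th[0]),
        _mle=_mle_exponential,
        _ll=_ll_exponential,
        _rvs=_rvs_exponential,
        needs_two_distinct=False,
    ),
    "weibull": Family(
        name="weibull",
        param_names=("shape", "scale"),
        positive=(True, True),
        _frozen=lambda th: stats.weibull_min(c=th[0], scale=th[1]),
        _mle=_mle_weibull,
        _ll=_ll_weibull,
        _rvs=_rvs_weibull,
        needs_two_distinct=True,
    ),
    "gamma": Family(
        name="gamma",
        param_names=("shape", "scale"),
        positive=(True, True),
        _frozen=lambda th: stats.gamma(a=th[0], scale=th[1]),
        _mle=_mle_gamma,
        _ll=_ll_gamma,
        _rvs=_rvs_gamma,
        needs_two_distinct=True,
    ),
    "lognormal": Family(
        name="lognormal",
        param_names=("mu", "sigma"),
        positive=(False, True),
        _frozen=lambda th: stats.lognorm(s=th[1], scale=np.exp(th[0])),
        _mle=_mle_lognormal,
        _ll=_ll_lognormal,
        _rvs=_rvs_lognormal,
        needs_two_distinct=True,
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; supported: {sorted(FAMILIES)}"
        ) from None
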