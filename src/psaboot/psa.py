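"""Probabilistic sensitivity analysis over a two-strategy DES model.

Each PSA run consumes one row of a :class:`~psaboot.uncertainty.ParamSetTable`
(the time-to-event hyperparameters), draws the cost and utility parameters
once from their declared PSA distributions, simulates a cohort per strategy,
and records one (mean cost, mean effect) pair per strategy. The resulting
cloud of incremental points is summarized on the cost-effectiveness plane
(confidence ellipses) and as cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .des import ModelConfig, implied_mean_time, simulate_cohort
from .exceptions import ConfigurationError
from .uncertainty import ParamSetTable

__all__ = ["PSACloud", "Ellipse", "CEACCurve", "run_psa", "confidence_ellipse",
           "ceac", "mean_ceac_band"]


@dataclass
class PSACloud:
    """Per-run mean costs/effects per strategy and incrementals.

    ``d_cost``/``d_effect`` are strategy[1] minus strategy[0] (intervention
    minus control, in the order the config lists them). ``flagged`` marks
    runs whose parameter draw implies mean survival beyond the horizon.
    """

    data: pd.DataFrame
    strategies: tuple[str, str]
    provenance: str
    seed: int | None

    @property
    def r(self) -> int:
        return len(self.data)

    @property
    def d_cost(self) -> np.ndarray:
        return self.data["d_cost"].to_numpy()

    @property
    def d_effect(self) -> np.ndarray:
        return self.data["d_effect"].to_numpy()

    def nmb(self, wtp: float) -> np.ndarray:
        """Incremental net monetary benefit λ·ΔE − ΔC per run."""
        return wtp * self.d_effect - self.d_cost

    def icer(self) -> float:
        return float(self.d_cost.mean() / self.d_effect.mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")


def run_psa(config: ModelConfig, param_sets: ParamSetTable, n_patients: int,
            seed: int | None = None, econ_fixed: bool = False) -> PSACloud:
    """Run the PSA: one cohort per strategy per parameter row.

    Run ``i`` binds row ``i`` of ``param_sets`` for both strategies (each
    strategy reads the columns of its own parameter group), draws the
    economic parameters once from their PSA distributions (or pins them at
    their means when ``econ_fixed``), and simulates ``n_patients`` per
    strategy. Random streams derive from ``seed`` per (run, strategy); with
    ``config.use_crn`` both strategies share the run's patient stream.
    """
    if len(config.strategies) != 2:
        raise ConfigurationError("PSA requires exactly two strategies")
    if param_sets.r < 1:
        raise ConfigurationError("parameter-set table is empty")
    sa, sb = config.strategies
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(param_sets.r)
    econ_names = sorted(config.econ_params)
    records = []
    for i in range(param_sets.r):
        binding = param_sets.row(i).to_dict()
        s_econ, s_a, s_b = children[i].spawn(3)
        rng_econ = np.random.default_rng(s_econ)
        if econ_fixed:
            econ = {k: config.econ_params[k].mean for k in econ_names}
        else:
            econ = {k: config.econ_params[k].draw(rng_econ) for k in econ_names}
        rng_a = np.random.default_rng(s_a)
        rng_b = np.random.default_rng(s_a if config.use_crn else s_b)
        ca = simulate_cohort(n_patients, binding, sa, config, rng_a, econ)
        cb = simulate_cohort(n_patients, binding, sb, config, rng_b, econ)
        flagged = False
        for strat in (sa, sb):
            mt = implied_mean_time(binding, strat, config)
            if np.isfinite(mt) and mt > config.horizon:
                flagged = True
        records.append({
            "run": i,
            f"cost_{sa.name}": ca.mean_cost, f"effect_{sa.name}": ca.mean_qaly,
            f"cost_{sb.name}": cb.mean_cost, f"effect_{sb.name}": cb.mean_qaly,
            "d_cost": cb.mean_cost - ca.mean_cost,
            "d_effect": cb.mean_qaly - ca.mean_qaly,
            "flagged": flagged,
        })
    data = pd.DataFrame.from_records(records)
    return PSACloud(data=data, strategies=(sa.name, sb.name),
                    provenance=param_sets.provenance, seed=seed)


# ---------------------------------------------------------------------------
# cost-effectiveness plane


@dataclass
class Ellipse:
    """Bivariate-Normal confidence ellipse of the (ΔE, ΔC) cloud.

    Semi-axes are √(q·eigenvalue) with q the χ²(2 df) quantile at ``level``;
    ``angle`` is the major axis' angle (radians) against the ΔE axis.
    """

    center: tuple[float, float]
    cov: np.ndarray
    level: float
    semi_axes: tuple[float, float]
    angle: float
    degenerate: bool = False

    @property
    def area(self) -> float:
        q = stats.chi2.ppf(self.level, df=2)
        det = float(np.linalg.det(self.cov))
        return float(np.pi * q * np.sqrt(max(det, 0.0)))

    def boundary(self, n: int = 200) -> np.ndarray:
        """(n, 2) points on the ellipse boundary, for plotting."""
        phi = np.linspace(0, 2 * np.pi, n)
        a, b = self.semi_axes
        xy = np.stack([a * np.cos(phi), b * np.sin(phi)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return (rot @ xy).T + np.asarray(self.center)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "center": [float(x) for x in self.center],
                "cov": self.cov.tolist(),
                "level": self.level,
                "semi_axes": [float(x) for x in self.semi_axes],
                "angle": float(self.angle),
                "degenerate": self.degenerate,
                "area": self.area,
            }, fh, indent=2, sort_keys=True)


def confidence_ellipse(cloud: PSACloud, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of the incremental cloud on the (ΔE, ΔC) plane.

    Center is the sample mean, shape the sample covariance; a cloud with
    (numerically) zero variance yields a degenerate ellipse flag rather
    than an error.
    """
    if cloud.r < 3:
        raise ConfigurationError("need >= 3 PSA runs for an ellipse")
    x = cloud.d_effect
    y = cloud.d_cost
    center = (float(x.mean()), float(y.mean()))
    cov = np.cov(np.stack([x, y]), ddof=1)
    q = stats.chi2.ppf(level, df=2)
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    semi = (float(np.sqrt(q * w[0])), float(np.sqrt(q * w[1])))
    angle = float(np.arctan2(V[1, 0], V[0, 0]))
    scale = max(abs(x).max(), abs(y).max(), 1.0)
    degenerate = bool(w[1] <= (1e-12 * scale) ** 2)
    return Ellipse(center=center, cov=cov, level=level, semi_axes=semi,
                   angle=angle, degenerate=degenerate)


# ---------------------------------------------------------------------------
# CEACs


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"lambda": self.lambdas, "probability": self.probabilities}
        if self.lower is not None:
            d["lower"] = self.lower
            d["upper"] = self.upper
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def ceac(cloud: PSACloud, lambda_grid) -> CEACCurve:
    """Fraction of runs with positive incremental net monetary benefit at
    each willingness-to-pay value (a tie, NMB exactly 0, counts as not
    cost-effective)."""
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(lam < 0) or np.any(np.diff(lam) <= 0):
        raise ValueError("willingness-to-pay grid must be non-negative and "
                         "strictly increasing")
    if cloud.r == 0:
        raise ValueError("empty PSA cloud")
    nmb = lam[:, None] * cloud.d_effect[None, :] - cloud.d_cost[None, :]
    return CEACCurve(lambdas=lam, probabilities=(nmb > 0).mean(axis=1))


def mean_ceac_band(curves: list[CEACCurve], level: float = 0.95) -> CEACCurve:
    """Pointwise mean CEAC with a percentile confidence band across trials."""
    if len(curves) < 2:
        raise ValueError("need >= 2 curves")
    grid = curves[0].lambdas
    for c in curves[1:]:
        if c.lambdas.shape != grid.shape or not np.allclose(c.lambdas, grid):
            raise ValueError("willingness-to-pay grids differ across curves")
    mat = np.stack([c.probabilities for c in curves])
    alpha = (1.0 - level) / 2.0
    return CEACCurve(
        lambdas=grid,
        probabilities=mat.mean(axis=0),
        lower=np.quantile(mat, alpha, axis=0),
        upper=np.quantile(mat, 1.0 - alpha, axis=0),
    )
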