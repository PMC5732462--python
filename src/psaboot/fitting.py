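"""Fitting parametric time-to-event models to IPD.

The building blocks mirror how competing risks are commonly handled in
patient-level simulation models built from trial data: within a source
health state, the chance of each competing event is taken from the observed
event counts, and the time at which the event happens is described by a
parametric distribution fitted to the times of patients who experienced
that event. Events seen fewer than ``min_events`` times cannot support a
distribution fit and receive probability exactly zero (the scarce-event
rule); censored records are excluded from both the counts and the time
samples.

Parameter uncertainty in each fitted distribution is captured by the
inverse of the observed information matrix, evaluated numerically at the
MLE (analytically for the exponential), so that downstream code can define
a multivariate Normal over the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoModelError, UnfittableError
from .families import Family, get_family
from .ipd import CENSORED, ModelSpec

__all__ = [
    "FittedDist", "EventMix", "TransitionModel", "ModelSet",
    "fit_time_to_event", "fit_event_mix", "fit_transition_model", "fit_model_set",
]


# ---------------------------------------------------------------------------
# observed information


def _numerical_hessian(f, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of scalar f at theta.

    Step per coordinate: max(1e-5, 1e-5*|theta_i|); symmetrized.
    """
    p = theta.size
    h = np.maximum(1e-5, 1e-5 * np.abs(theta))
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


@dataclass
class FittedDist:
    """A fitted parametric distribution with estimation uncertainty.

    Attributes
    ----------
    family : Family
    theta : pd.Series
        Parameter estimates, indexed by the family's parameter names.
    vcov : pd.DataFrame
        Variance-covariance matrix of the estimates (inverse observed
        information at the MLE).
    loglik : float
    n_obs : int
    converged : bool
        False when the information matrix could not be inverted or produced
        a negative variance; the point estimates are still usable but the
        multivariate-Normal approach is not.
    """

    family: Family
    theta: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_obs: int
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return self.theta.to_numpy()

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.theta.index)

    def mean(self) -> float:
        return self.family.mean(self.params)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.family.rvs(self.params, size, rng)

    def summary(self) -> str:
        lines = [f"{self.family.name} fit  (n={self.n_obs}, loglik={self.loglik:.3f}, "
                 f"converged={self.converged})"]
        se = self.bse()
        for name in self.theta.index:
            lines.append(f"  {name:>8s} = {self.theta[name]:.6g}  (se {se[name]:.3g})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family.name,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "vcov": [[float(x) for x in row] for row in self.vcov.to_numpy()],
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDist":
        fam = get_family(d["family"])
        names = list(fam.param_names)
        theta = pd.Series({k: d["theta"][k] for k in names})
        vcov = pd.DataFrame(np.array(d["vcov"], dtype=float), index=names, columns=names)
        return cls(fam, theta, vcov, d["loglik"], d["n_obs"], d["converged"])


def fit_time_to_event(times, family: str | Family) -> FittedDist:
    """Fit one parametric family to uncensored event times by maximum
    likelihood.

    The covariance of the estimates is the inverse observed information
    matrix at the MLE (closed form for the exponential, for which
    ``var(rate) = rate^2 / n`` exactly; numerically differentiated for the
    two-parameter families).

    Raises
    ------
    DataError
        Any non-positive time.
    UnfittableError
        Fewer than two observations, or fewer than two distinct values for
        a two-parameter family.
    """
    fam = get_family(family) if isinstance(family, str) else family
    t = np.asarray(times, dtype=float).ravel()
    theta = fam.mle(t)  # raises on degenerate input
    names = list(fam.param_names)
    ll = fam.loglik(theta, t)

    converged = True
    if fam.name == "exponential":
        rate = theta[0]
        vcov = np.array([[rate * rate / t.size]])
    else:
        H = _numerical_hessian(lambda th: fam.loglik(th, t), theta)
        info = -H
        try:
            vcov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            vcov = np.full((fam.n_params, fam.n_params), np.nan)
            converged = False
        else:
            if np.any(np.diag(vcov) < 0) or not np.all(np.isfinite(vcov)):
                converged = False
            vcov = 0.5 * (vcov + vcov.T)

    return FittedDist(
        family=fam,
        theta=pd.Series(theta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=ll,
        n_obs=int(t.size),
        converged=converged,
    )


@dataclass
class EventMix:
    """Competing-event probabilities from observed counts.

    Events with fewer than ``min_events`` observations get probability
    exactly 0; the rest are the counts renormalized over retained events.
    """

    counts: dict[str, int]
    probabilities: dict[str, float]
    min_events: int = 2

    @property
    def retained(self) -> list[str]:
        return [e for e, p in self.probabilities.items() if p > 0.0]

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts),
                "probabilities": dict(self.probabilities),
                "min_events": self.min_events}


def fit_event_mix(counts: dict[str, int], min_events: int = 2) -> EventMix:
    """Event-type probabilities with the scarce-event rule applied.

    An event observed fewer than ``min_events`` times cannot support a
    distribution fit, so its probability is set to exactly zero and the
    remaining counts are renormalized.

    Raises
    ------
    NoModelError
        Every event is below ``min_events``.
    """
    counts = {e: int(c) for e, c in counts.items()}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative event count")
    retained = {e: c for e, c in counts.items() if c >= min_events}
    total = sum(retained.values())
    if total == 0:
        raise NoModelError(
            f"all events below min_events={min_events}: counts={counts}"
        )
    probs = {e: (counts[e] / total if e in retained else 0.0) for e in counts}
    return EventMix(counts=counts, probabilities=probs, min_events=min_events)


@dataclass
class TransitionModel:
    """Event mix plus one fitted conditional time distribution per retained
    event, for a single (group, transition)."""

    transition_id: str
    group: str
    mix: EventMix
    conditional_dists: dict[str, FittedDist] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [e for e in self.mix.retained if e not in self.conditional_dists]
        if missing:
            raise NoModelError(
                f"{self.group}.{self.transition_id}: retained events without "
                f"fitted distribution: {missing}"
            )

    def to_dict(self) -> dict:
        return {
            "transition_id": self.transition_id,
            "group": self.group,
            "mix": self.mix.to_dict(),
            "conditional_dists": {e: d.to_dict() for e, d in self.conditional_dists.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        mix = EventMix(counts=d["mix"]["counts"],
                       probabilities=d["mix"]["probabilities"],
                       min_events=d["mix"].get("min_events", 2))
        dists = {e: FittedDist.from_dict(v) for e, v in d["conditional_dists"].items()}
        return cls(d["transition_id"], d["group"], mix, dists)


def fit_transition_model(records: pd.DataFrame, transition_id: str, group: str,
                         spec: ModelSpec) -> TransitionModel:
    """Fit the competing-risks model for one (group, transition).

    Censored records are excluded from both the mix denominator and the
    time samples. Events below the scarce-event threshold keep probability
    zero and no conditional distribution; fit failures on a retained event
    propagate with transition/event context.
    """
    sub = records[(records["transition"] == transition_id) & (records["group"] == group)]
    sub = sub[sub["event"] != CENSORED]
    if sub.empty:
        raise NoModelError(f"no records for {group}.{transition_id}")
    vocab = spec.transitions[transition_id]
    counts = {e: int((sub["event"] == e).sum()) for e in vocab}
    mix = fit_event_mix(counts, min_events=spec.min_events)
    dists: dict[str, FittedDist] = {}
    for event in mix.retained:
        fam = spec.family_for(transition_id, event)
        t = sub.loc[sub["event"] == event, "time"].to_numpy()
        try:
            dists[event] = fit_time_to_event(t, fam)
        except UnfittableError as err:
            raise UnfittableError(
                f"{group}.{transition_id}.{event}: {err}"
            ) from err
    return TransitionModel(transition_id, group, mix, dists)


@dataclass
class ModelSet:
    """All fitted transition models of a study, keyed by (group, transition).

    This is the fitted-model object the uncertainty-set generators and the
    simulation engine consume; `param_names()` defines the canonical flat
    parameter ordering ``group.transition.event.{prob|param}`` used by
    parameter-set tables.
    """

    spec: ModelSpec
    models: dict[tuple[str, str], TransitionModel]

    @property
    def groups(self) -> list[str]:
        return sorted({g for g, _ in self.models})

    def __getitem__(self, key: tuple[str, str]) -> TransitionModel:
        return self.models[key]

    def param_names(self) -> list[str]:
        names: list[str] = []
        for (group, trans) in sorted(self.models):
            tm = self.models[(group, trans)]
            for event in self.spec.transitions[trans]:
                if event not in tm.mix.counts:
                    continue
                names.append(f"{group}.{trans}.{event}.prob")
                fam = get_family(self.spec.family_for(trans, event))
                for p in fam.param_names:
                    names.append(f"{group}.{trans}.{event}.{p}")
        return names

    def point_estimates(self) -> pd.Series:
        """Flat named vector of MLE probabilities and parameters.

        Suppressed (probability-zero) events carry NaN distribution
        parameters: they are never sampled from.
        """
        values: dict[str, float] = {}
        for (group, trans) in sorted(self.models):
            tm = self.models[(group, trans)]
            for event in self.spec.transitions[trans]:
                if event not in tm.mix.counts:
                    continue
                base = f"{group}.{trans}.{event}"
                values[f"{base}.prob"] = tm.mix.probabilities[event]
                fam = get_family(self.spec.family_for(trans, event))
                fitted = tm.conditional_dists.get(event)
                for p in fam.param_names:
                    values[f"{base}.{p}"] = (
                        float(fitted.theta[p]) if fitted is not None else np.nan
                    )
        return pd.Series(values, index=self.param_names())

    def summary(self) -> str:
        lines = ["Fitted transition models", "=" * 24]
        for (group, trans) in sorted(self.models):
            tm = self.models[(group, trans)]
            lines.append(f"[{group} / {trans}]")
            for event in sorted(tm.mix.counts):
                p = tm.mix.probabilities[event]
                lines.append(f"  P({event}) = {p:.4f}  (count {tm.mix.counts[event]})")
                if event in tm.conditional_dists:
                    for ln in tm.conditional_dists[event].summary().splitlines():
                        lines.append("    " + ln)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "models": {f"{g}|{t}": m.to_dict() for (g, t), m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSet":
        spec = ModelSpec.from_dict(d["spec"])
        models = {}
        for key, md in d["models"].items():
            g, t = key.split("|", 1)
            models[(g, t)] = TransitionModel.from_dict(md)
        return cls(spec, models)


def fit_model_set(records: pd.DataFrame, spec: ModelSpec) -> ModelSet:
    """Fit every (group, transition) present in the spec/data.

    Groups default to those observed in the data (sorted) unless the spec
    pins them. A transition absent for some group raises, as the model
    would be unusable for simulation.
    """
    groups = spec.groups if spec.groups is not None else sorted(records["group"].unique())
    if not groups:
        raise NoModelError("no groups in record set")
    models: dict[tuple[str, str], TransitionModel] = {}
    for group in groups:
        for trans in spec.transitions:
            models[(group, trans)] = fit_transition_model(records, trans, group, spec)
    return ModelSet(spec=spec, models=models)
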