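"""YAML configuration loading.

A scenario file has up to three top-level sections:

``model``
    The DES model: state structure, families per (state, event), the two
    strategies with their economic inputs, the PSA distributions of cost
    and utility parameters, discounting, horizon, willingness-to-pay grid.
``population``
    The true data-generating process for synthetic IPD (per-group risks);
    its structure defaults to the model's.
``study``
    Dimensions of the nested simulation study (sample sizes, trials, PSA
    runs, cohort size, approaches, master seed).

Fixture scenarios shipped with the package carry synthetic illustrative
parameter values and are loadable by name via :func:`load_fixture`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .des import EconParamSpec, ModelConfig, StrategyConfig
from .exceptions import ConfigurationError
from .study import StudyConfig
from .synthetic import RiskSpec, TruePopulation

__all__ = ["load_model_config", "load_population", "load_study_config",
           "load_scenario", "load_fixture", "fixture_path"]


def _read(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def _lambda_grid(d) -> np.ndarray | None:
    if d is None:
        return None
    if isinstance(d, dict):
        return np.linspace(float(d["start"]), float(d["stop"]), int(d["num"]))
    return np.asarray(d, dtype=float)


def load_model_config(source) -> ModelConfig:
    d = _read(source)
    if "model" in d:
        d = d["model"]
    try:
        strategies = [StrategyConfig(
            name=s["name"], group=s.get("group", s["name"]),
            mechanism=s.get("mechanism", "event_probability"),
            utilities=dict(s.get("utilities", {})),
            cost_rates=dict(s.get("cost_rates", {})),
            event_costs=dict(s.get("event_costs", {})),
        ) for s in d["strategies"]]
        econ = {k: EconParamSpec(dist=v["dist"], mean=float(v["mean"]),
                                 se=float(v.get("se", 0.0)))
                for k, v in d.get("econ_params", {}).items()}
        return ModelConfig(
            structure={s: dict(ev) for s, ev in d["structure"].items()},
            strategies=strategies,
            econ_params=econ,
            families=dict(d.get("families", {})),
            min_events=int(d.get("min_events", 2)),
            discount_rate=float(d.get("discount_rate", 0.03)),
            horizon=float(d.get("horizon", 480.0)),
            initial_state=d.get("initial_state", "healthy"),
            lambda_grid=_lambda_grid(d.get("lambda_grid")),
            wtp_reference=float(d.get("wtp_reference", 50000.0)),
            use_crn=bool(d.get("use_crn", False)),
        )
    except KeyError as err:
        raise ConfigurationError(f"model config missing key {err.args[0]!r}") from None


def load_population(source, structure: dict | None = None) -> TruePopulation:
    d = _read(source)
    if "population" in d:
        structure = structure or d.get("model", {}).get("structure")
        d = d["population"]
    try:
        groups = {}
        for g, states in d["groups"].items():
            groups[g] = {}
            for s, events in states.items():
                groups[g][s] = {}
                for e, rs in events.items():
                    params = {k: float(v) for k, v in rs.items() if k != "family"}
                    groups[g][s][e] = RiskSpec(family=rs["family"], params=params)
        struct = d.get("structure") or structure
        if struct is None:
            raise ConfigurationError("population needs a structure (own or model's)")
        return TruePopulation(
            structure={s: dict(ev) for s, ev in struct.items()},
            groups=groups,
            frailty_sd=float(d.get("frailty_sd", 0.0)),
            censor_time=(None if d.get("censor_time") in (None, "null")
                         else float(d["censor_time"])),
            initial_state=d.get("initial_state", "healthy"),
        )
    except KeyError as err:
        raise ConfigurationError(f"population config missing key {err.args[0]!r}") from None


def load_scenario(source) -> tuple[ModelConfig, TruePopulation]:
    d = _read(source)
    model = load_model_config(d)
    pop = load_population(d, structure=d.get("model", {}).get("structure"))
    return model, pop


def load_study_config(source) -> StudyConfig:
    d = _read(source)
    model, pop = load_scenario(d)
    s = d.get("study", {})
    return StudyConfig(
        population=pop,
        model=model,
        sample_sizes=[int(x) for x in s.get("sample_sizes", [500, 100, 50, 25])],
        n_trials=int(s.get("n_trials", 20)),
        r=int(s.get("r", 200)),
        n_patients=int(s.get("n_patients", 1000)),
        approaches=tuple(s.get("approaches", ["fixed", "bootstrap", "mvnorm"])),
        seed=int(s.get("seed", 0)),
        max_attempts=int(s.get("max_attempts", 1000)),
    )


def fixture_path(name: str) -> Path:
    """Path of a fixture scenario shipped with the package."""
    base = resources.files("psaboot") / "fixtures" / f"{name}.yaml"
    with resources.as_file(base) as p:
        if not p.exists():
            raise FileNotFoundError(f"no fixture named {name!r}")
        return Path(p)


def load_fixture(name: str):
    """Load a shipped fixture scenario; returns (ModelConfig, TruePopulation)."""
    return load_scenario(fixture_path(name))
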