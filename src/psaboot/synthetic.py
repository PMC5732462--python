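"""Synthetic individual patient data with the structure the methods assume.

A :class:`TruePopulation` describes, per strategy group, a state-transition
process with competing risks: latent event times are drawn per risk from
declared parametric distributions and the earliest one is realized. An
optional patient-level frailty (log-Normal multiplier on all of a patient's
latent times) induces correlation between a patient's transitions, and an
optional administrative censoring time truncates follow-up, producing
``"censored"`` records.

The generator writes the same record schema the fitting layer consumes, so
the whole pipeline — fit, parameter-set generation, PSA, simulation study —
is exercisable without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .families import get_family
from .ipd import CENSORED, IPD_COLUMNS, ModelSpec

__all__ = ["RiskSpec", "TruePopulation", "generate_ipd", "scarce_event_fixture"]


@dataclass(frozen=True)
class RiskSpec:
    """One latent risk: a parametric family and its true parameter values."""

    family: str
    params: dict[str, float]

    def theta(self) -> np.ndarray:
        fam = get_family(self.family)
        try:
            th = np.array([self.params[p] for p in fam.param_names], dtype=float)
        except KeyError as err:
            raise ConfigurationError(
                f"{self.family}: missing parameter {err.args[0]!r}") from None
        if not fam.support_ok(th):
            raise ConfigurationError(f"{self.family}: parameters outside support")
        return th


@dataclass
class TruePopulation:
    """True data-generating process, per strategy group.

    ``structure`` maps state → {event: next state}; ``groups`` maps
    group → state → {event: RiskSpec}. ``frailty_sd`` is the SD of the
    log-Normal patient frailty on the log scale (0 disables it);
    ``censor_time`` is an administrative censoring horizon in months.
    """

    structure: dict[str, dict[str, str]]
    groups: dict[str, dict[str, dict[str, RiskSpec]]]
    frailty_sd: float = 0.0
    censor_time: float | None = None
    initial_state: str = "healthy"

    def __post_init__(self) -> None:
        if self.frailty_sd < 0:
            raise ConfigurationError("frailty_sd must be >= 0")
        if self.censor_time is not None and self.censor_time <= 0:
            raise ConfigurationError("censor_time must be > 0")
        for group, states in self.groups.items():
            for s, events in states.items():
                if s not in self.structure:
                    raise ConfigurationError(f"{group}: unknown state {s!r}")
                declared = set(self.structure[s])
                if set(events) != declared:
                    raise ConfigurationError(
                        f"{group}.{s}: risks {sorted(events)} do not match "
                        f"declared events {sorted(declared)}")
                for spec in events.values():
                    spec.theta()  # validates

    def model_spec(self, families: dict[str, str] | None = None,
                   min_events: int = 2) -> ModelSpec:
        """Fitting spec matching this population's structure.

        By default each (transition, event) is assigned its true family —
        the matched-family setting that avoids distributional mismatch bias.
        """
        if families is None:
            families = {}
            any_group = next(iter(self.groups.values()))
            for s, events in any_group.items():
                for e, spec in events.items():
                    families[f"{s}.{e}"] = spec.family
        return ModelSpec(
            transitions={s: sorted(ev) for s, ev in self.structure.items()},
            families=families,
            min_events=min_events,
        )


def generate_ipd(pop: TruePopulation, n: int, seed=None) -> pd.DataFrame:
    """Simulate ``n`` patients per group and return their transition records.

    Per patient and state, one latent time per declared risk is drawn and
    the earliest is realized; records after the absorbing event are not
    generated. With administrative censoring the final record is labelled
    ``"censored"`` at the residual time. ``seed`` may be an integer or a
    ``numpy`` Generator/SeedSequence.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols: dict[str, list] = {c: [] for c in IPD_COLUMNS}
    entry: list[np.ndarray] = []

    for group in sorted(pop.groups):
        if n == 0:
            continue
        risks = pop.groups[group]
        frail = (np.exp(rng.normal(0.0, pop.frailty_sd, size=n))
                 if pop.frailty_sd > 0 else np.ones(n))
        pids = np.array([f"{group}-{i:06d}" for i in range(n)])
        state = np.full(n, 0)
        states = list(pop.structure)
        sidx = {s: i for i, s in enumerate(states)}
        absorb_base = len(states)
        absorbing = sorted({nxt for evs in pop.structure.values()
                            for nxt in evs.values()} - set(states))
        for i, s in enumerate(absorbing):
            sidx[s] = absorb_base + i
        state = np.full(n, sidx[pop.initial_state])
        t_total = np.zeros(n)
        active = np.ones(n, dtype=bool)

        for _ in range(len(states) + 1):
            if not active.any():
                break
            for s in states:
                idx = np.flatnonzero(active & (state == sidx[s]))
                if idx.size == 0:
                    continue
                events = sorted(risks[s])
                latent = np.vstack([
                    get_family(risks[s][e].family).rvs(risks[s][e].theta(),
                                                       idx.size, rng)
                    for e in events
                ]) * frail[idx]
                which = np.argmin(latent, axis=0)
                dwell = latent[which, np.arange(idx.size)]
                labels = np.array(events, dtype=object)[which]
                t_new = t_total[idx] + dwell
                rec_time = dwell.copy()
                rec_event = labels.copy()
                if pop.censor_time is not None:
                    cmask = t_new > pop.censor_time
                    rec_time[cmask] = pop.censor_time - t_total[idx][cmask]
                    rec_event[cmask] = CENSORED
                else:
                    cmask = np.zeros(idx.size, dtype=bool)

                cols["patient_id"].extend(pids[idx])
                cols["group"].extend([group] * idx.size)
                cols["transition"].extend([s] * idx.size)
                cols["time"].extend(rec_time)
                cols["event"].extend(rec_event)
                entry.append(t_total[idx].copy())

                active[idx[cmask]] = False
                fired = idx[~cmask]
                t_total[fired] = t_new[~cmask]
                nxt = np.array([sidx[pop.structure[s][e]] for e in events])
                state[fired] = nxt[which[~cmask]]
                done = np.array([pop.structure[s][e] not in pop.structure
                                 for e in events])
                active[fired[done[which[~cmask]]]] = False

    df = pd.DataFrame(cols)
    df["time"] = df["time"].astype(float)
    if len(df):
        df["_entry"] = np.concatenate(entry)
        df = df.sort_values(["group", "patient_id", "_entry"], kind="stable")
        df = df.drop(columns="_entry").reset_index(drop=True)
    return df


def scarce_event_fixture(seed=None) -> pd.DataFrame:
    """A small single-group dataset (n = 50) with exactly one observed death
    from the initial state.

    Engineered to exercise the scarce-event paths: the solitary death falls
    below the default ``min_events`` threshold, so fitting assigns it
    probability zero, bootstrap resamples may or may not retain it, and the
    multivariate-Normal generator sees very small conditional samples.
    """
    rng = np.random.default_rng(seed)
    wb = get_family("weibull")
    n = 50
    rows = []
    for i in range(n - 1):
        pid = f"obs-{i:06d}"
        t_prog = float(wb.rvs(np.array([1.4, 16.0]), 1, rng)[0])
        rows.append((pid, "observation", "healthy", t_prog, "progression"))
        t_death = float(wb.rvs(np.array([1.2, 10.0]), 1, rng)[0])
        rows.append((pid, "observation", "progressed", t_death, "death"))
    t_d = float(wb.rvs(np.array([1.1, 30.0]), 1, rng)[0])
    rows.append((f"obs-{n-1:06d}", "observation", "healthy", t_d, "death"))
    return pd.DataFrame(rows, columns=IPD_COLUMNS)
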