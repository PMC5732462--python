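"""Individual patient data (IPD) containers and I/O.

IPD is held as a pandas DataFrame with one row per (patient, transition)
observation and columns ``patient_id, group, transition, time, event``.
``time`` is the elapsed time in months since entering the source state,
strictly positive. ``event`` is an event label from the transition's
declared vocabulary or the reserved label ``"censored"``.

A :class:`ModelSpec` declares the transitions, their event vocabularies and
the parametric family assigned to each (transition, event); it is what turns
a raw IPD table into a fittable model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .exceptions import DataError
from .families import FAMILIES

__all__ = ["CENSORED", "IPD_COLUMNS", "ModelSpec", "read_ipd_csv", "write_ipd_csv",
           "validate_ipd", "time_sample"]

CENSORED = "censored"
IPD_COLUMNS = ["patient_id", "group", "transition", "time", "event"]


@dataclass
class ModelSpec:
    """Declares model structure for fitting.

    Parameters
    ----------
    transitions
        Mapping transition id -> list of event labels (excluding
        ``"censored"``, which is always allowed).
    families
        Mapping ``"transition.event"`` -> family name. A bare transition id
        key acts as a default for all its events.
    min_events
        Scarce-event threshold: an event observed fewer than this many times
        gets probability zero and no fitted distribution.
    groups
        Optional explicit list of group (strategy/subgroup) labels; by
        default the groups present in the data are used, sorted.
    """

    transitions: dict[str, list[str]]
    families: dict[str, str] = field(default_factory=dict)
    min_events: int = 2
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        for trans, events in self.transitions.items():
            if CENSORED in events:
                raise DataError(f"transition {trans!r}: {CENSORED!r} is reserved")
            for ev in events:
                fam = self.family_for(trans, ev)
                if fam not in FAMILIES:
                    raise DataError(
                        f"unknown family {fam!r} for {trans}.{ev}"
                    )

    def family_for(self, transition: str, event: str) -> str:
        key = f"{transition}.{event}"
        if key in self.families:
            return self.families[key]
        if transition in self.families:
            return self.families[transition]
        return "weibull"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "transitions": {k: list(v) for k, v in self.transitions.items()},
            "families": dict(self.families),
            "min_events": self.min_events,
            "groups": None if self.groups is None else list(self.groups),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            transitions={k: list(v) for k, v in d["transitions"].items()},
            families=dict(d.get("families", {})),
            min_events=int(d.get("min_events", 2)),
            groups=d.get("groups"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_ipd(records: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Validate an IPD table in place and return it.

    Checks the schema, strict positivity of times and, when a spec is
    supplied, membership of transition ids and event labels in the declared
    vocabulary. Errors name the offending (0-based) data row.
    """
    missing = [c for c in IPD_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"IPD table missing columns: {missing}")
    times = pd.to_numeric(records["time"], errors="coerce")
    bad = records.index[~(times > 0) | ~times.notna()]
    if len(bad):
        raise DataError(f"non-positive or non-numeric time at row {bad[0]}")
    records = records.assign(time=times.astype(float))
    if spec is not None:
        for i, (trans, event) in enumerate(zip(records["transition"], records["event"])):
            if trans not in spec.transitions:
                raise DataError(f"unknown transition {trans!r} at row {records.index[i]}")
            if event != CENSORED and event not in spec.transitions[trans]:
                raise DataError(
                    f"event {event!r} not in vocabulary of transition {trans!r} "
                    f"at row {records.index[i]}"
                )
    return records


def read_ipd_csv(path, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Read and validate an IPD CSV (header required)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "group": str,
                                  "transition": str, "event": str})
    if df.empty and df.columns.tolist() != IPD_COLUMNS:
        raise DataError("empty IPD file")
    return validate_ipd(df, spec)


def write_ipd_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=IPD_COLUMNS, float_format="%.17g")


def time_sample(records: pd.DataFrame, transition: str, event: str,
                group: str | None = None) -> pd.Series:
    """Observed (uncensored) times for one (transition, event[, group])."""
    mask = (records["transition"] == transition) & (records["event"] == event)
    if group is not None:
        mask &= records["group"] == group
    return records.loc[mask, "time"]
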