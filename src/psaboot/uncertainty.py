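"""Correlated parameter-set generation for probabilistic sensitivity analysis.

A PSA over a patient-level model needs, for each of its ``r`` runs, one
complete set of values for every hyperparameter of the time-to-event
distributions (and the competing-event probabilities). Because the
parameters of a fitted distribution are correlated — and, across
distributions fitted on the same patients, so are the distributions — the
sets must be generated jointly. Two generators are provided:

``bootstrap_param_sets``
    Resample patients with replacement (all of a patient's transition
    records travel together, and group sizes are preserved), refit the full
    model on each resample, and keep one row of fitted values per feasible
    resample. Correlation is preserved automatically because every
    distribution is refitted on the same resample.

``mvnorm_param_sets``
    Draw each fitted distribution's parameters from a multivariate Normal
    centred at the MLE with the inverse-observed-information covariance
    (correlated within a distribution, independent across distributions),
    and the competing-event probabilities from a Dirichlet over the
    retained-event counts. Draws outside a family's support are rejected
    and redrawn; the rejection count is reported because it is the symptom
    of the small-sample regime in which the Normal approximation breaks
    down.

``fixed_param_sets``
    The comparator that ignores parameter uncertainty: ``r`` identical
    rows of point estimates.

Every generator returns a :class:`ParamSetTable` whose rows share a fixed
column order of fully-qualified names ``group.transition.event.{prob|param}``.
Events suppressed by the scarce-event rule carry probability 0 and NaN
distribution parameters (they are never sampled from).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FeasibilityError, NoModelError, UnfittableError
from .families import get_family
from .fitting import ModelSet, fit_model_set
from .ipd import ModelSpec

__all__ = ["ParamSetTable", "bootstrap_param_sets", "mvnorm_param_sets",
           "fixed_param_sets", "resample_patients"]


@dataclass
class ParamSetTable:
    """r correlated parameter rows, one consumed per PSA run."""

    data: pd.DataFrame
    provenance: str  # fixed | bootstrap | mvnorm
    seed: int | None
    n_attempted: int
    n_rejected: int

    @property
    def r(self) -> int:
        return len(self.data)

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_attempted if self.n_attempted else 0.0

    def row(self, i: int) -> pd.Series:
        return self.data.iloc[i]

    def validate(self, model_set: ModelSet) -> None:
        """Assert every row satisfies the parameter-vector invariants."""
        spec = model_set.spec
        for (group, trans) in sorted(model_set.models):
            vocab = spec.transitions[trans]
            prob_cols = [f"{group}.{trans}.{e}.prob" for e in vocab]
            probs = self.data[prob_cols].to_numpy()
            if np.any(probs < 0) or np.any(probs > 1):
                raise AssertionError(f"probability outside [0,1] in {group}.{trans}")
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
                raise AssertionError(f"probabilities do not sum to 1 in {group}.{trans}")
            for event in vocab:
                fam = get_family(spec.family_for(trans, event))
                cols = [f"{group}.{trans}.{event}.{p}" for p in fam.param_names]
                th = self.data[cols].to_numpy()
                active = self.data[f"{group}.{trans}.{event}.prob"].to_numpy() > 0
                for rowvals in th[active]:
                    if not fam.support_ok(rowvals):
                        raise AssertionError(
                            f"parameters outside support for {group}.{trans}.{event}"
                        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """CSV of the rows plus a `.json` sidecar with provenance metadata."""
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"provenance": self.provenance, "seed": self.seed,
                       "n_attempted": self.n_attempted,
                       "n_rejected": self.n_rejected}, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "ParamSetTable":
        path = Path(path)
        data = pd.read_csv(path).astype(float)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {"provenance": "unknown", "seed": None, "n_attempted": len(data),
                "n_rejected": 0}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta.update(json.load(fh))
        return cls(data=data, provenance=meta["provenance"], seed=meta["seed"],
                   n_attempted=meta["n_attempted"], n_rejected=meta["n_rejected"])


# ---------------------------------------------------------------------------
# bootstrap


class _PatientResampler:
    """Resamples patients with replacement, per group, preserving group sizes.

    All transition records of a resampled patient travel together so that
    within-patient correlation survives the resampling. Row positions per
    patient are indexed once up front; each draw is then a single `take`.
    """

    def __init__(self, records: pd.DataFrame):
        self.records = records.reset_index(drop=True)
        self.positions = {pid: np.asarray(idx)
                          for pid, idx in self.records.groupby("patient_id").indices.items()}
        first = self.records.drop_duplicates("patient_id")
        group_of = dict(zip(first["patient_id"], first["group"]))
        self.ids_by_group = {
            g: np.array(sorted(p for p, gg in group_of.items() if gg == g))
            for g in sorted(set(group_of.values()))
        }

    def draw(self, rng: np.random.Generator) -> pd.DataFrame:
        parts = []
        for group in self.ids_by_group:
            ids = self.ids_by_group[group]
            chosen = rng.choice(ids, size=ids.size, replace=True)
            parts.extend(self.positions[pid] for pid in chosen)
        return self.records.take(np.concatenate(parts)).reset_index(drop=True)


def resample_patients(records: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One patient-level bootstrap resample (convenience wrapper)."""
    return _PatientResampler(records).draw(rng)


def bootstrap_param_sets(records: pd.DataFrame, spec: ModelSpec, r: int,
                         max_attempts: int = 1000,
                         seed: int | None = None) -> ParamSetTable:
    """Generate ``r`` parameter rows by non-parametric bootstrap.

    Each row is the full model parameterization refitted on one feasible
    resample of the patients (sampled with replacement, group sizes equal
    to the original). The scarce-event rule is re-applied per resample, so
    an event may drop to probability 0 in some rows. Resamples on which any
    transition is unfittable are discarded, redrawn and counted in
    ``n_rejected``.

    Raises
    ------
    FeasibilityError
        More than ``max_attempts`` consecutive infeasible resamples while
        building one row.
    NoModelError / UnfittableError
        The original dataset itself is infeasible.
    """
    # the original dataset must itself be fittable before we resample it
    base = fit_model_set(records, spec)
    columns = base.param_names()
    resampler = _PatientResampler(records)

    rng = np.random.default_rng(seed)
    rows: list[pd.Series] = []
    n_attempted = 0
    n_rejected = 0
    last_err: Exception | None = None
    while len(rows) < r:
        consecutive = 0
        while True:
            n_attempted += 1
            resample = resampler.draw(rng)
            try:
                fitted = fit_model_set(resample, spec)
            except (NoModelError, UnfittableError) as err:
                n_rejected += 1
                consecutive += 1
                last_err = err
                if consecutive >= max_attempts:
                    raise FeasibilityError(
                        f"bootstrap: {max_attempts} consecutive infeasible "
                        f"resamples; last failure: {last_err}",
                        context=str(last_err),
                    ) from err
                continue
            rows.append(fitted.point_estimates())
            break
    data = pd.DataFrame(rows, columns=columns).reset_index(drop=True) if rows \
        else pd.DataFrame(columns=columns)
    return ParamSetTable(data=data, provenance="bootstrap", seed=seed,
                         n_attempted=n_attempted, n_rejected=n_rejected)


# ---------------------------------------------------------------------------
# multivariate Normal


def _psd_factor(vcov: np.ndarray, label: str) -> np.ndarray:
    """Square-root factor of a (possibly singular) covariance via eigen
    decomposition; rejects matrices that are meaningfully non-PSD."""
    vcov = np.asarray(vcov, dtype=float)
    if not np.all(np.isfinite(vcov)):
        raise ConfigurationError(f"{label}: non-finite covariance")
    w, V = np.linalg.eigh(0.5 * (vcov + vcov.T))
    tol = 1e-10 * max(1.0, float(np.abs(w).max()))
    if np.any(w < -tol):
        raise ConfigurationError(f"{label}: covariance not positive semidefinite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def mvnorm_param_sets(models: ModelSet, r: int, max_attempts: int = 1000,
                      seed: int | None = None) -> ParamSetTable:
    """Generate ``r`` parameter rows from multivariate Normal distributions.

    Each fitted distribution's parameters are drawn from
    ``MVN(theta_hat, vcov)`` (block-diagonal across distributions), and
    each transition's retained-event probabilities from a
    ``Dirichlet(counts)``. A drawn row is feasible only if every active
    distribution's parameters lie within the family support; infeasible
    rows are rejected, redrawn and counted.

    Raises
    ------
    ConfigurationError
        A fit did not converge, or a covariance matrix is not PSD.
    FeasibilityError
        More than ``max_attempts`` rejections while building one row.
    """
    spec = models.spec
    columns = models.param_names()
    template = models.point_estimates()

    # precompute Dirichlet alphas and Normal factors in deterministic order
    mixes: list[tuple[list[str], np.ndarray]] = []  # (prob column names, alphas)
    blocks: list[tuple[list[str], np.ndarray, np.ndarray, object]] = []
    for (group, trans) in sorted(models.models):
        tm = models.models[(group, trans)]
        retained = [e for e in spec.transitions[trans] if tm.mix.probabilities[e] > 0.0]
        mixes.append(([f"{group}.{trans}.{e}.prob" for e in retained],
                      np.array([tm.mix.counts[e] for e in retained], dtype=float)))
        for event in retained:
            fitted = tm.conditional_dists[event]
            label = f"{group}.{trans}.{event}"
            if not fitted.converged:
                raise ConfigurationError(f"{label}: fit not converged; "
                                         "cannot define a multivariate Normal")
            L = _psd_factor(fitted.vcov.to_numpy(), label)
            cols = [f"{label}.{p}" for p in fitted.family.param_names]
            blocks.append((cols, fitted.theta.to_numpy(), L, fitted.family))

    rng = np.random.default_rng(seed)
    rows = np.tile(template.to_numpy(), (r, 1)) if r else np.empty((0, len(columns)))
    col_idx = {c: i for i, c in enumerate(columns)}
    n_attempted = 0
    n_rejected = 0
    for i in range(r):
        for attempt in range(max_attempts + 1):
            n_attempted += 1
            ok = True
            draws: list[tuple[list[str], np.ndarray]] = []
            for cols, alpha in mixes:
                p = rng.dirichlet(alpha) if alpha.size > 1 else np.array([1.0])
                draws.append((cols, p))
            for cols, mean, L, fam in blocks:
                th = mean + L @ rng.standard_normal(mean.size)
                if not fam.support_ok(th):
                    ok = False
                draws.append((cols, th))
            if ok:
                for cols, vals in draws:
                    for c, v in zip(cols, vals):
                        rows[i, col_idx[c]] = v
                break
            n_rejected += 1
            if attempt >= max_attempts:
                raise FeasibilityError(
                    f"mvnorm: {max_attempts} rejected draws for row {i}; the "
                    "Normal approximation is infeasible at this sample size"
                )
    data = pd.DataFrame(rows, columns=columns)
    return ParamSetTable(data=data, provenance="mvnorm", seed=seed,
                         n_attempted=n_attempted, n_rejected=n_rejected)


def fixed_param_sets(models: ModelSet, r: int) -> ParamSetTable:
    """``r`` identical rows of point estimates — the comparator that ignores
    parameter uncertainty in the patient-level distributions."""
    template = models.point_estimates()
    data = pd.DataFrame([template] * r, columns=models.param_names()).reset_index(drop=True) \
        if r else pd.DataFrame(columns=models.param_names())
    return ParamSetTable(data=data, provenance="fixed", seed=None,
                         n_attempted=r, n_rejected=0)
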