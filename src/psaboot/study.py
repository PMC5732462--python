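"""Nested simulation study: trials × approaches × PSA runs × patients.

For each configured sample size, ``n_trials`` hypothetical trial datasets
are drawn from a true population. Each trial is analyzed under up to three
approaches to the hyperparameters of the patient-level time-to-event
distributions:

``fixed``       point estimates in every PSA run (parameter uncertainty
                in the patient-level distributions ignored);
``bootstrap``   one refitted parameter set per PSA run from patient-level
                resampling;
``mvnorm``      one multivariate-Normal draw per PSA run.

A reference ("true") sampling distribution is built by fitting each of
``n_trials`` independent draws from the population once and running the
model at the point estimates with the economic parameters pinned at their
means — the trial-to-trial spread of those fits and outcomes is what an
ideal uncertainty method should reproduce. Approaches are scored against
it with marginal Kullback-Leibler divergences of the hyperparameter and
incremental-outcome distributions, alongside cost-effectiveness planes,
ellipse areas, ΔNMB spreads and mean CEACs with confidence bands.

Per-cell failures (e.g. multivariate-Normal feasibility exhaustion at tiny
sample sizes) are recorded and do not abort the study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .des import ModelConfig
from .divergence import KLOptions, kl_divergence
from .exceptions import (ConfigurationError, EstimationError, FeasibilityError,
                         NoModelError, PsabootError, UnfittableError)
from .fitting import fit_model_set
from .psa import PSACloud, ceac, confidence_ellipse, mean_ceac_band, run_psa
from .synthetic import TruePopulation, generate_ipd
from .uncertainty import bootstrap_param_sets, fixed_param_sets, mvnorm_param_sets

__all__ = ["StudyConfig", "ReferenceResult", "StudyResult", "true_reference",
           "run_simulation_study"]

APPROACHES = ("fixed", "bootstrap", "mvnorm")


def _subseed(*parts: int) -> int:
    """Deterministic 31-bit seed derived from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] >> 1)


@dataclass
class StudyConfig:
    population: TruePopulation
    model: ModelConfig
    sample_sizes: list[int] = field(default_factory=lambda: [500, 100, 50, 25])
    n_trials: int = 20
    r: int = 200
    n_patients: int = 1000
    approaches: tuple[str, ...] = APPROACHES
    seed: int = 0
    max_attempts: int = 1000
    max_reference_redraws: int = 200

    def __post_init__(self) -> None:
        if min(self.sample_sizes, default=0) < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if min(self.n_trials, self.r, self.n_patients) < 1:
            raise ConfigurationError("counts must be >= 1")
        bad = set(self.approaches) - set(APPROACHES)
        if bad:
            raise ConfigurationError(f"unknown approaches: {sorted(bad)}")

    @property
    def lambda_grid(self) -> np.ndarray:
        grid = self.model.lambda_grid
        if grid is None:
            grid = np.linspace(0.0, 2.0 * self.model.wtp_reference, 41)
        return np.asarray(grid, dtype=float)


@dataclass
class ReferenceResult:
    """Trial-to-trial sampling distribution of fits and outcomes at one
    sample size: the 'true' distribution approaches are scored against."""

    sample_size: int
    params: pd.DataFrame     # one row of fitted point estimates per trial
    outcomes: pd.DataFrame   # one row of model outcomes per trial
    n_redrawn: int


def true_reference(config: StudyConfig,
                   sample_sizes: list[int] | None = None) -> dict[int, ReferenceResult]:
    """Build the reference sampling distribution per sample size.

    Each trial dataset is fitted once and the model evaluated at the point
    estimates (fixed provenance, r = 1) with economic parameters at their
    means. Unfittable datasets are redrawn and counted.
    """
    out: dict[int, ReferenceResult] = {}
    for si, size in enumerate(sample_sizes or config.sample_sizes):
        params_rows = []
        outcome_rows = []
        n_redrawn = 0
        trial = 0
        draw = 0
        while trial < config.n_trials:
            records = generate_ipd(config.population, size,
                                   seed=_subseed(config.seed, 1, si, draw))
            draw += 1
            try:
                fitted = fit_model_set(records, config.model.model_spec())
            except (NoModelError, UnfittableError):
                n_redrawn += 1
                if n_redrawn > config.max_reference_redraws:
                    raise FeasibilityError(
                        f"reference at n={size}: exceeded "
                        f"{config.max_reference_redraws} redraws")
                continue
            table = fixed_param_sets(fitted, 1)
            cloud = run_psa(config.model, table, config.n_patients,
                            seed=_subseed(config.seed, 2, si, trial),
                            econ_fixed=True)
            params_rows.append(fitted.point_estimates())
            outcome_rows.append(cloud.data.iloc[0].drop(labels=["run", "flagged"]))
            trial += 1
        out[size] = ReferenceResult(
            sample_size=size,
            params=pd.DataFrame(params_rows).reset_index(drop=True),
            outcomes=pd.DataFrame(outcome_rows).reset_index(drop=True).astype(float),
            n_redrawn=n_redrawn,
        )
    return out


@dataclass
class StudyResult:
    config: StudyConfig
    references: dict[int, ReferenceResult]
    trials: pd.DataFrame          # one row per (size, trial, approach)
    summary: pd.DataFrame         # one row per (size, approach)
    kl: pd.DataFrame              # (size, approach, quantity, kl)
    ceacs: dict[tuple[int, str], object]   # mean CEAC with band
    failures: pd.DataFrame        # recorded per-cell failures
    clouds: dict[tuple[int, int, str], PSACloud] | None = None

    def save(self, out_dir, version: str = "") -> dict:
        """Write the result tree (CSV tables + manifest) and return the
        manifest dict."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}

        def _write(name: str, df: pd.DataFrame):
            p = out / name
            df.to_csv(p, index=False, float_format="%.17g")
            files[name] = str(p)

        _write("study_summary.csv", self.summary)
        _write("kl_table.csv", self.kl)
        _write("trials.csv", self.trials)
        _write("failures.csv", self.failures)
        ceac_rows = []
        for (size, approach) in sorted(self.ceacs):
            c = self.ceacs[(size, approach)]
            for j, lam in enumerate(c.lambdas):
                ceac_rows.append({"sample_size": size, "approach": approach,
                                  "lambda": lam, "probability": c.probabilities[j],
                                  "lower": c.lower[j] if c.lower is not None else np.nan,
                                  "upper": c.upper[j] if c.upper is not None else np.nan})
        _write("ceac.csv", pd.DataFrame(ceac_rows))
        for size, ref in self.references.items():
            _write(f"reference_params_n{size}.csv", ref.params)
            _write(f"reference_outcomes_n{size}.csv", ref.outcomes)
        if self.clouds:
            for (size, trial, approach), cloud in sorted(self.clouds.items()):
                sub = out / f"n{size}" / f"trial{trial:04d}"
                sub.mkdir(parents=True, exist_ok=True)
                p = sub / f"psa_cloud_{approach}.csv"
                cloud.to_csv(p)
                files[str(p.relative_to(out))] = str(p)

        warn = []
        rej = self.trials[self.trials["rejection_rate"] > 0.01]
        for _, row in rej.iterrows():
            warn.append(f"rejection rate {row['rejection_rate']:.1%} at "
                        f"n={int(row['sample_size'])} trial={int(row['trial'])} "
                        f"approach={row['approach']}")
        manifest = {
            "seed": self.config.seed,
            "version": version,
            "written_utc": datetime.now(timezone.utc).isoformat(),
            "files": files,
            "warnings": warn,
            "n_failures": int(len(self.failures)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _gen_table(approach: str, records, fitted, config: StudyConfig, seed: int):
    if approach == "fixed":
        return fixed_param_sets(fitted, config.r)
    if approach == "bootstrap":
        return bootstrap_param_sets(records, config.model.model_spec(), config.r,
                                    max_attempts=config.max_attempts, seed=seed)
    if approach == "mvnorm":
        return mvnorm_param_sets(fitted, config.r,
                                 max_attempts=config.max_attempts, seed=seed)
    raise ConfigurationError(f"unknown approach {approach!r}")


def run_simulation_study(config: StudyConfig, keep_clouds: bool = False) -> StudyResult:
    """Execute the full nested design and aggregate across trials."""
    references = true_reference(config)
    lam = config.lambda_grid
    wtp = config.model.wtp_reference

    trial_rows = []
    failure_rows = []
    ceac_curves: dict[tuple[int, str], list] = {}
    pooled: dict[tuple[int, str], dict[str, list[np.ndarray]]] = {}
    clouds: dict[tuple[int, int, str], PSACloud] = {}

    for si, size in enumerate(config.sample_sizes):
        for trial in range(config.n_trials):
            records = generate_ipd(config.population, size,
                                   seed=_subseed(config.seed, 3, si, trial))
            try:
                fitted = fit_model_set(records, config.model.model_spec())
            except (NoModelError, UnfittableError) as err:
                for approach in config.approaches:
                    failure_rows.append({"sample_size": size, "trial": trial,
                                         "approach": approach, "stage": "fit",
                                         "error": str(err)})
                continue
            for ai, approach in enumerate(config.approaches):
                try:
                    table = _gen_table(approach, records, fitted, config,
                                       seed=_subseed(config.seed, 4, si, trial, ai))
                except (FeasibilityError, ConfigurationError, PsabootError) as err:
                    failure_rows.append({"sample_size": size, "trial": trial,
                                         "approach": approach, "stage": "gensets",
                                         "error": str(err)})
                    continue
                cloud = run_psa(config.model, table, config.n_patients,
                                seed=_subseed(config.seed, 5, si, trial))
                if keep_clouds:
                    clouds[(size, trial, approach)] = cloud
                ell = confidence_ellipse(cloud)
                curve = ceac(cloud, lam)
                ceac_curves.setdefault((size, approach), []).append(curve)
                bucket = pooled.setdefault((size, approach), {})
                for col in table.data.columns:
                    bucket.setdefault(col, []).append(table.data[col].to_numpy())
                bucket.setdefault("d_cost", []).append(cloud.d_cost)
                bucket.setdefault("d_effect", []).append(cloud.d_effect)
                trial_rows.append({
                    "sample_size": size, "trial": trial, "approach": approach,
                    "d_cost": float(cloud.d_cost.mean()),
                    "d_effect": float(cloud.d_effect.mean()),
                    "sd_nmb": float(cloud.nmb(wtp).std(ddof=1)),
                    "ellipse_area": ell.area,
                    "n_rejected": table.n_rejected,
                    "n_attempted": table.n_attempted,
                    "rejection_rate": table.rejection_rate,
                    "n_flagged": int(cloud.data["flagged"].sum()),
                })

    trials = pd.DataFrame(trial_rows, columns=[
        "sample_size", "trial", "approach", "d_cost", "d_effect", "sd_nmb",
        "ellipse_area", "n_rejected", "n_attempted", "rejection_rate",
        "n_flagged"])
    failures = pd.DataFrame(failure_rows, columns=[
        "sample_size", "trial", "approach", "stage", "error"])

    # per-cell aggregation and KL scoring against the reference
    summary_rows = []
    kl_rows = []
    ceacs = {}
    for (size, approach), bucket in sorted(pooled.items()):
        sub = trials[(trials["sample_size"] == size) & (trials["approach"] == approach)]
        summary_rows.append({
            "sample_size": size, "approach": approach,
            "n_trials_ok": len(sub),
            "mean_d_cost": sub["d_cost"].mean(),
            "mean_d_effect": sub["d_effect"].mean(),
            "mean_sd_nmb": sub["sd_nmb"].mean(),
            "mean_ellipse_area": sub["ellipse_area"].mean(),
            "mean_rejection_rate": sub["rejection_rate"].mean(),
            "share_trials_with_rejections": (sub["n_rejected"] > 0).mean(),
            "mean_n_flagged": sub["n_flagged"].mean(),
        })
        ref = references[size]
        for quantity, chunks in sorted(bucket.items()):
            if quantity in ("d_cost", "d_effect"):
                ref_values = ref.outcomes[quantity].to_numpy()
            elif quantity in ref.params.columns:
                ref_values = ref.params[quantity].to_numpy()
            else:
                continue
            draws = np.concatenate(chunks)
            try:
                res = kl_divergence(draws, ref_values, KLOptions())
                value = res.value
            except EstimationError:
                value = np.nan
            kl_rows.append({"sample_size": size, "approach": approach,
                            "quantity": quantity,
                            "n_draws": int(np.isfinite(draws).sum()),
                            "kl": value})
        curves = ceac_curves.get((size, approach), [])
        if len(curves) >= 2:
            ceacs[(size, approach)] = mean_ceac_band(curves)
        elif curves:
            ceacs[(size, approach)] = curves[0]

    summary = pd.DataFrame(summary_rows, columns=[
        "sample_size", "approach", "n_trials_ok", "mean_d_cost", "mean_d_effect",
        "mean_sd_nmb", "mean_ellipse_area", "mean_rejection_rate",
        "share_trials_with_rejections", "mean_n_flagged"])
    kl = pd.DataFrame(kl_rows, columns=["sample_size", "approach", "quantity",
                                        "n_draws", "kl"])
    return StudyResult(config=config, references=references, trials=trials,
                       summary=summary, kl=kl, ceacs=ceacs, failures=failures,
                       clouds=clouds if keep_clouds else None)
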