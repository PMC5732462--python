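# Methods

## The problem

A patient-level cost-effectiveness model represents stochastic
(first-order) uncertainty by drawing individual event times from parametric
distributions whose hyperparameters are estimated from individual patient
data (IPD). Probabilistic sensitivity analysis (PSA) is supposed to reflect
*parameter* (second-order) uncertainty, but the hyperparameters of the
patient-level distributions are correlated — within a distribution (e.g. a
Weibull's shape and scale) and across distributions fitted on the same
patients — so sampling each hyperparameter independently, or not sampling
them at all, misstates the outcome uncertainty. `psaboot` implements and
evaluates the two approaches that sample them jointly.

## Data model and fitting

IPD is one record per (patient, transition): the time in months from
entering a source health state to the first event, with an event label or
`censored`. Per (group, transition), the model is the standard
competing-risks convention for simulation models built from trial data:

* **Event mix** — the probability of each competing event is its observed
  count divided by the total of retained events. An event observed fewer
  than `min_events` (default 2) times cannot support a distribution fit and
  gets probability exactly zero (the scarce-event rule). Censored records
  are excluded from both the counts and the time samples; right-censored
  likelihood contributions are deliberately out of scope (this models
  complete-event data, and the synthetic generator produces exactly that
  unless administrative censoring is switched on).
* **Conditional time distributions** — one parametric family per retained
  event (exponential, Weibull, gamma, log-normal), fitted by maximum
  likelihood on that event's observed times.

MLEs use the exact closed form where one exists (exponential rate n/Σt,
log-normal moments of log-times) and otherwise a one-dimensional
profile-likelihood root solve (Brent's method to ~1e-12) for the shape,
with the scale recovered in closed form — Weibull:
1/k + mean(ln t) = Σtᵏ ln t / Σtᵏ; gamma: ln a − ψ(a) = ln t̄ − mean(ln t).
This is exact likelihood maximization, chosen over generic quasi-Newton
because it runs thousands of times inside bootstrap loops and has no
convergence tuning. Samples with fewer than two distinct values make the
two-parameter families unidentifiable (the likelihood diverges as the shape
grows) and raise an unfittable error; the caller decides the fallback.

The covariance of the estimates is the inverse of the observed information
matrix at the MLE: analytic for the exponential (rate²/n), otherwise a
central-difference Hessian with per-coordinate step max(1e-5, 1e-5·|θᵢ|),
symmetrized. If inversion fails or yields a negative variance the fit is
flagged not-converged, which blocks the MVNorm generator but not the
bootstrap.

Note on identifiability under competing risks: the conditional-on-event
distributions describe the *observed* process (times of patients whose
event of that type came first), not the latent marginal risks that generate
the synthetic data. Latent parameters are recovered directly only for
single-risk states; for competing states the tests validate the fitted mix
and conditional distributions against independent large draws from the same
truth. This mirrors the realistic analyst's position.

## Parameter-set generation

All three generators emit an `r × p` table with a fixed column order of
fully-qualified names `group.transition.event.{prob|param}`; one row is
consumed per PSA run. Suppressed (probability-zero) events carry NaN
parameters and are never sampled from.

* **fixed** — r identical rows of point estimates; the comparator that
  ignores hyperparameter uncertainty.
* **bootstrap** — patients are resampled with replacement per group
  (preserving each arm's sample size; all of a patient's transition records
  travel together, so within-patient correlation survives), and the full
  model is refitted on each resample. The scarce-event rule is re-applied
  per resample, so an event may drop to probability zero in some rows. A
  resample is *feasible* iff every retained (transition, event) has
  ≥ `min_events` observations with ≥ 2 distinct times and every fit
  succeeds; infeasible resamples are discarded, redrawn and counted, and
  more than `max_attempts` (default 1000) consecutive failures raise an
  error naming the failing transition/event.
* **mvnorm** — each fitted distribution's parameters are drawn from
  N(θ̂, vcov) via an eigen-decomposition square root (block-diagonal across
  distributions: cross-distribution correlation is zero by construction,
  which is exactly the approach's known limitation); the retained-event
  probabilities are drawn from a Dirichlet over the retained counts, a
  standard PSA treatment of multinomial probabilities added here because
  the bootstrap propagates mix uncertainty automatically and the comparison
  should not be confounded by its absence. A row is feasible iff every
  active block lies in the family support; rejected rows are redrawn and
  counted. The rejection count is deliberately surfaced (`n_rejected`,
  `rejection_rate`, CLI warnings above 1%) because a growing rejection rate
  is the operational symptom of the small-sample regime in which the Normal
  approximation of positively-supported parameters breaks down.

Rejection (not truncation-correction) is used for support violations, so
the returned rows are a conditioned Normal; at the sample sizes where that
conditioning matters the approach is already inadvisable, and the rate
makes that visible.

## The simulation engine

A discrete-event simulation over an acyclic state graph (canonically
healthy → progressed → death with progression and death competing from
healthy). Two competing-risk mechanisms per state: `event_probability`
(draw the label from the mix, then the dwell from that event's conditional
distribution — the parameterization produced by fitting) and `latent_min`
(draw one latent time per risk, earliest wins — the parameterization of a
true population). On entering a new state the clock restarts (semi-Markov),
the standard convention for this model shape.

Costs accrue as per-month state rates plus one-off event costs; utilities
are QALY weights per year. Discounting is continuous at
ρ = ln(1 + annual)/12 per month, so accrual over (t₁, t₂) is
rate·(e^(−ρt₁) − e^(−ρt₂))/ρ — there are no cycles in a DES to discount
over. The horizon (default 480 months; the fixture uses 240, ample for its
event scales) truncates accrual, not the event draws. Cohorts are simulated
vectorized per state; random streams derive from one seed per (run,
strategy) — per-patient streams were traded away for vectorization, with
determinism under a master seed preserved and asserted. Common random
numbers across strategies are off by default (`use_crn` enables them).

## PSA outcomes

Run *i* binds row *i* of the parameter-set table for both strategies, draws
the economic parameters once from their declared PSA distributions (gamma,
beta or Normal, parameterized by mean and SE with method-of-moments
conversion; `se = 0` or `fixed` pins them), simulates `n_patients` per
strategy, and records one (mean cost, mean effect) pair per strategy.
Incrementals are intervention minus control. Runs whose parameter row
implies mean survival beyond the horizon (closed-form state recursion over
the family means) are kept but flagged, preserving auditability rather than
silently excluding extreme draws.

* **Confidence ellipse** — bivariate-Normal ellipse of the (ΔE, ΔC) cloud:
  centre the sample means, shape the sample covariance, semi-axes
  √(q·eigenvalues) with q = χ²₂(level) (5.9915 at 95%); area
  π·q·√det Σ. Zero-variance clouds set a degenerate flag instead of
  failing.
* **CEAC** — the fraction of runs with λ·ΔE − ΔC > 0 per willingness-to-pay
  λ; a tie counts as not cost-effective (measure-zero in practice,
  deterministic for toy inputs). Across trials, the mean CEAC carries a
  pointwise percentile band (2.5/97.5 by default; simultaneous bands are
  out of scope).

## Kullback-Leibler divergence

Distributions of parameters and outcomes are compared marginally via
Gaussian-kernel density estimates (Silverman bandwidth) on a shared
512-point grid spanning the pooled range padded by three bandwidths.
Densities are floored at ε = 1e-12 and renormalized to integrate to one, so
KL(p‖q) = Σ p·log(p/q)·Δx is finite and non-negative up to roundoff even
with barely-overlapping supports. The default is the directed
KL(approach ‖ reference); a symmetrized average is available by option. All
options are carried in the result object for auditability. Fewer than 10
finite values or zero variance raise an estimation error rather than
returning a meaningless number.

## Nested simulation study

For each sample size, `n_trials` hypothetical trial datasets are drawn from
the true population; each is analyzed under the configured approaches
(parameter table of `r` rows → PSA of `r` runs × `n_patients` patients per
strategy). The **reference** ("true") distribution at each sample size is
built from `n_trials` independent datasets, each fitted once and run
through the model at the point estimates with the economic parameters
pinned at their means — so the reference isolates the sampling distribution
induced by the time-to-event estimation, which is exactly what the
approaches are supposed to reproduce. Unfittable reference datasets are
redrawn and counted. Per-cell failures in the study proper (e.g. MVNorm
feasibility exhaustion at n = 25) are recorded in a failures table and do
not abort the run.

Scoring per (sample size, approach): pooled-across-trials KL of each
hyperparameter and of ΔC and ΔE against the reference; trial-level ΔNMB
spread at a reference willingness-to-pay λ; ellipse areas; mean CEAC with
percentile band; rejection-rate summaries.

Default dimensions are `n_trials = 20`, `r = 200`, `n_patients = 1000` —
deliberately scaled-down study sizes that keep a full run in minutes while
leaving the Monte-Carlo error well below the effect sizes of interest (the
variance ordering shows ~3× separation); production-scale dimensions are
plain config values. The fixture's reference λ (134 000 per QALY) is twice
the scenario's true incremental cost-effectiveness ratio (~67 000),
measured once from a large-sample reference run (n = 40 000 fit, 400 000
patients per arm).

## Synthetic data

The generator draws latent times per declared risk (earliest realized) per
state, per strategy group — times in months from Weibull/gamma/log-normal/
exponential families. Optional log-Normal patient frailty multiplies all of
a patient's latent times, inducing the cross-transition correlation that
distinguishes the bootstrap (which preserves it) from the MVNorm approach
(which cannot); it is off by default. Optional administrative censoring
truncates follow-up with `censored` records. The shipped scenario —
identical progression/death risks from the healthy state in both arms, an
intervention that extends progressed-state survival (Weibull scale 18 vs 12
months) at a higher monthly cost (2000 vs 1200 per month) — follows the
classic "longer survival at higher cost in the progressed state" design;
all numeric values are invented and labelled as such in the fixture files.

What the generator does *not* emulate: covariate-driven heterogeneity,
informative censoring, time-varying hazards beyond the declared families,
or real-world cost/utility correlation with survival. Passing tests
demonstrate the method's internal correctness and its behaviour under the
stated generating process, not calibration to any particular disease.

A small engineered fixture (`scarce_event_fixture`, n = 50, exactly one
death from the initial state) exercises the scarce-event paths: the
zero-probability rule, per-resample re-suppression in the bootstrap, and
tiny conditional samples for the MVNorm generator.

## Numerical and design choices

* Time unit months everywhere; conversions are the caller's responsibility.
* Root solves bracketed in [1e-4, 1e4] (Weibull shape) and [1e-8, 1e8]
  (gamma shape) with softmax/logsumexp evaluation of Σtᵏ terms for
  overflow-safety.
* Parameter tables serialize as CSV with 17-significant-digit floats
  (bit-stable round trips) plus a JSON sidecar for provenance metadata.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  derivations; every public entry point is deterministic given its seed,
  asserted by byte-identity tests up to the full CLI study run.
* Exactly two strategies per model (as in the evaluated design); frontier
  analysis over more strategies, value-of-information analysis, parametric
  bootstrap, Bayesian posterior sampling and copula dependence modelling
  are out of scope.

## Known limitations

* No censored-likelihood fitting: heavy administrative censoring biases
  the fitted conditionals; the generator's default produces complete data.
* Marginal (not joint) KL scoring of outcome distributions.
* The MVNorm rejection step conditions the Normal on the support, slightly
  biasing its moments exactly in the regime where the approach is already
  discouraged.
* The flagged-run rule (implied mean survival beyond horizon) is a
  closed-form screen for the `event_probability` mechanism only.
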