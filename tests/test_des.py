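"""Discrete-event simulation engine: analytic expectations and invariants."""

import numpy as np
import pytest
from scipy import integrate, stats

from psaboot import ConfigurationError, ModelConfig, StrategyConfig
from psaboot.des import (discounted_integral, monthly_discount_rate,
                         simulate_cohort, simulate_patient)


def one_risk_config(rate=0.02, utility=0.8, cost_rate=0.0, discount=0.0,
                    horizon=1e5, event_cost=0.0, family="exponential"):
    strat = StrategyConfig(name="s", group="g",
                           utilities={"healthy": utility},
                           cost_rates={"healthy": cost_rate},
                           event_costs={"death": event_cost})
    return ModelConfig(structure={"healthy": {"death": "death"}},
                       strategies=[strat, strat],
                       families={"healthy": family},
                       discount_rate=discount, horizon=horizon), strat


def competing_config(mechanism, horizon=1e5):
    strat = StrategyConfig(name="s", group="g", mechanism=mechanism,
                           utilities={"healthy": 1.0})
    cfg = ModelConfig(structure={"healthy": {"progression": "gone",
                                             "death": "death"}},
                      strategies=[strat, strat],
                      families={"healthy": "exponential"},
                      discount_rate=0.0, horizon=horizon)
    return cfg, strat


def test_discounted_integral_matches_quadrature():
    rho = 0.007
    for t1, t2 in [(0.0, 10.0), (3.0, 120.0), (50.0, 50.0)]:
        num, _ = integrate.quad(lambda u: np.exp(-rho * u), t1, t2)
        assert discounted_integral(rho, t1, t2) == pytest.approx(num, abs=1e-10)
    assert discounted_integral(0.0, 2.0, 7.5) == 5.5


def test_monthly_discount_rate_conversion():
    assert monthly_discount_rate(0.0) == 0.0
    assert np.exp(12 * monthly_discount_rate(0.03)) == pytest.approx(1.03)


class TestClosedFormExpectations:
    def test_discounted_qaly_equals_u_over_lambda_plus_rho(self, rng):
        """Exponential survival at rate λ with continuous discounting at ρ
        gives E[discounted QALYs] = u/(λ+ρ) (in month-units, /12)."""
        lam, rho_m, u = 0.02, 0.015, 0.8
        annual = np.exp(12 * rho_m) - 1.0
        cfg, strat = one_risk_config(rate=lam, utility=u, discount=annual)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": lam}
        c = simulate_cohort(20_000, binding, strat, cfg, rng, keep_arrays=True)
        expected = u / (lam + rho_m) / 12.0
        se = c.qalys.std(ddof=1) / np.sqrt(c.n)
        assert abs(c.mean_qaly - expected) < 3 * se

    def test_discounted_event_cost(self, rng):
        """One-off cost C at an exponential event time has mean discounted
        value C·λ/(λ+ρ)."""
        lam, rho_m, C = 0.05, 0.01, 1000.0
        annual = np.exp(12 * rho_m) - 1.0
        cfg, strat = one_risk_config(rate=lam, utility=0.0, discount=annual,
                                     event_cost=C)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": lam}
        c = simulate_cohort(20_000, binding, strat, cfg, rng, keep_arrays=True)
        expected = C * lam / (lam + rho_m)
        se = c.costs.std(ddof=1) / np.sqrt(c.n)
        assert abs(c.mean_cost - expected) < 3 * se

    def test_zero_costs_and_time_alive_identity(self, rng):
        """With zero cost inputs total cost is exactly 0; with utility 1 and
        no discounting QALYs equal time alive (months/12) exactly."""
        cfg, strat = one_risk_config(rate=0.05, utility=1.0, horizon=60.0)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.05}
        for _ in range(20):
            p = simulate_patient(binding, strat, cfg, rng)
            assert p.cost == 0.0
            time_alive = p.path[-1][1] if len(p.path) > 1 else 60.0
            assert p.qaly == pytest.approx(min(time_alive, 60.0) / 12.0, abs=1e-12)


class TestCompetingRisks:
    def test_equal_rate_event_split_is_half(self, rng):
        cfg, strat = competing_config("latent_min")
        binding = {"g.healthy.progression.rate": 0.1, "g.healthy.death.rate": 0.1}
        n = 10_000
        progressed = sum(simulate_patient(binding, strat, cfg, rng).path[-1][0] == "gone"
                         for _ in range(200))
        # cheap path check on 200 patients, precise check via times below
        assert 60 <= progressed <= 140
        c = simulate_cohort(n, binding, strat, cfg, rng, keep_arrays=True)
        # fraction via qalys is not informative here; use a vectorized re-run
        a, b = 0.12, 0.04
        binding2 = {"g.healthy.progression.rate": a, "g.healthy.death.rate": b}
        frac = np.mean([simulate_patient(binding2, strat, cfg, rng).path[-1][0] == "gone"
                        for _ in range(2000)])
        assert abs(frac - a / (a + b)) < 3 * np.sqrt(0.25 / 2000)

    def test_time_to_first_event_is_exponential_sum_of_rates(self, rng):
        a, b = 0.06, 0.02
        cfg, strat = competing_config("latent_min")
        binding = {"g.healthy.progression.rate": a, "g.healthy.death.rate": b}
        c = simulate_cohort(20_000, binding, strat, cfg, rng, keep_arrays=True)
        times = c.qalys * 12.0  # utility 1, no discounting
        p = stats.kstest(times, "expon", args=(0, 1.0 / (a + b))).pvalue
        assert p > 0.01

    def test_mechanism_equivalence_in_distribution(self, rng):
        """latent_min with exponential risks (a, b) equals event_probability
        with mix (a, b)/(a+b) and conditional exponential(a+b)."""
        a, b = 0.08, 0.04
        cfg1, strat1 = competing_config("latent_min")
        b1 = {"g.healthy.progression.rate": a, "g.healthy.death.rate": b}
        cfg2, strat2 = competing_config("event_probability")
        b2 = {"g.healthy.progression.prob": a / (a + b),
              "g.healthy.death.prob": b / (a + b),
              "g.healthy.progression.rate": a + b,
              "g.healthy.death.rate": a + b}
        t1 = simulate_cohort(15_000, b1, strat1, cfg1, rng, keep_arrays=True).qalys
        t2 = simulate_cohort(15_000, b2, strat2, cfg2, rng, keep_arrays=True).qalys
        assert stats.ks_2samp(t1, t2).pvalue > 0.01


class TestStructuralBehaviour:
    def test_horizon_zero_gives_zero_outcomes(self, rng):
        cfg, strat = one_risk_config(rate=0.1, utility=0.9, cost_rate=100.0,
                                     horizon=0.0)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.1}
        c = simulate_cohort(50, binding, strat, cfg, rng)
        assert c.mean_cost == 0.0 and c.mean_qaly == 0.0

    def test_clock_restarts_after_progression(self, rng):
        """Semi-Markov: expected total survival is the sum of the state
        dwell means."""
        strat = StrategyConfig(name="s", group="g", utilities={"healthy": 1.0,
                                                               "progressed": 1.0})
        cfg = ModelConfig(structure={"healthy": {"progression": "progressed"},
                                     "progressed": {"death": "death"}},
                          strategies=[strat, strat],
                          families={"healthy": "exponential",
                                    "progressed": "exponential"},
                          discount_rate=0.0, horizon=1e5)
        binding = {"g.healthy.progression.prob": 1.0,
                   "g.healthy.progression.rate": 0.1,
                   "g.progressed.death.prob": 1.0,
                   "g.progressed.death.rate": 0.05}
        c = simulate_cohort(20_000, binding, strat, cfg, rng, keep_arrays=True)
        total = c.qalys * 12.0
        se = total.std(ddof=1) / np.sqrt(total.size)
        assert abs(total.mean() - 30.0) < 3 * se

    def test_cohort_of_one_equals_patient(self):
        cfg, strat = one_risk_config(rate=0.03, utility=0.7, cost_rate=50.0)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.03}
        c = simulate_cohort(1, binding, strat, cfg, np.random.default_rng(5))
        p = simulate_patient(binding, strat, cfg, np.random.default_rng(5))
        assert c.mean_cost == pytest.approx(p.cost)
        assert c.mean_qaly == pytest.approx(p.qaly)

    def test_same_seed_identical_summary(self):
        cfg, strat = one_risk_config(rate=0.03, utility=0.7, cost_rate=50.0)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.03}
        a = simulate_cohort(500, binding, strat, cfg, np.random.default_rng(8))
        b = simulate_cohort(500, binding, strat, cfg, np.random.default_rng(8))
        assert (a.mean_cost, a.mean_qaly) == (b.mean_cost, b.mean_qaly)

    def test_monte_carlo_error_scales_with_sqrt_n(self):
        cfg, strat = one_risk_config(rate=0.05, utility=0.0, cost_rate=100.0,
                                     horizon=240.0)
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.05}
        means_small, means_big = [], []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            means_small.append(simulate_cohort(200, binding, strat, cfg, rng).mean_cost)
            means_big.append(simulate_cohort(400, binding, strat, cfg, rng).mean_cost)
        ratio = np.std(means_small, ddof=1) / np.std(means_big, ddof=1)
        assert 1.2 <= ratio <= 1.7

    def test_missing_binding_raises_configuration_error(self, rng):
        cfg, strat = one_risk_config()
        with pytest.raises(ConfigurationError, match="g.healthy.death"):
            simulate_cohort(5, {"g.healthy.death.prob": 1.0}, strat, cfg, rng)

    def test_cohort_size_must_be_positive(self, rng):
        cfg, strat = one_risk_config()
        binding = {"g.healthy.death.prob": 1.0, "g.healthy.death.rate": 0.1}
        with pytest.raises(ValueError):
            simulate_cohort(0, binding, strat, cfg, rng)

    def test_cyclic_structure_rejected(self):
        strat = StrategyConfig(name="s", group="g")
        with pytest.raises(ConfigurationError, match="cycle"):
            ModelConfig(structure={"a": {"x": "b"}, "b": {"y": "a"}},
                        strategies=[strat, strat], initial_state="a")
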