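"""Bootstrap, multivariate-Normal and fixed parameter-set generation."""

import numpy as np
import pandas as pd
import pytest

from psaboot import (ConfigurationError, FeasibilityError, ModelSpec, RiskSpec,
                     TruePopulation, UnfittableError, bootstrap_param_sets,
                     fit_model_set, fixed_param_sets, generate_ipd,
                     mvnorm_param_sets)

from .oracles import exponential_bootstrap_oracle, mvn_sample_oracle


def _exp_records(n, rate, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "group": "a", "transition": "healthy",
        "time": rng.exponential(1.0 / rate, n), "event": "death"})


EXP_SPEC = ModelSpec(transitions={"healthy": ["death"]},
                     families={"healthy": "exponential"})


class TestBootstrap:
    def test_r_zero_gives_empty_table(self, ipd100, model):
        t = bootstrap_param_sets(ipd100, model.model_spec(), 0, seed=1)
        assert t.r == 0 and t.n_rejected == 0

    def test_rows_are_full_size_resample_fits(self, ipd100, model, fitted100):
        t = bootstrap_param_sets(ipd100, model.model_spec(), 3, seed=2)
        assert t.r == 3 and t.provenance == "bootstrap"
        assert list(t.data.columns) == fitted100.param_names()
        # rows differ from the original-fit point estimates (they are refits)
        assert not np.allclose(t.data.iloc[0].to_numpy(),
                               t.data.iloc[1].to_numpy(), equal_nan=True)

    def test_reproducible_bit_for_bit(self, ipd100, model):
        a = bootstrap_param_sets(ipd100, model.model_spec(), 5, seed=9)
        b = bootstrap_param_sets(ipd100, model.model_spec(), 5, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_every_row_satisfies_support(self, ipd100, model, fitted100):
        t = bootstrap_param_sets(ipd100, model.model_spec(), 10, seed=3)
        t.validate(fitted100)

    def test_degenerate_original_dataset_unfittable(self):
        rec = _exp_records(3, 0.1, 0)
        rec["time"] = 5.0
        spec = ModelSpec(transitions={"healthy": ["death"]},
                         families={"healthy": "weibull"})
        with pytest.raises(UnfittableError):
            bootstrap_param_sets(rec, spec, 2, seed=0)

    def test_degenerate_resamples_exhaust_feasibility(self):
        # 2 distinct values, one held by a single patient: a resample that
        # misses that patient is degenerate for a two-parameter family
        rec = pd.DataFrame({"patient_id": ["A", "B", "C"], "group": "a",
                            "transition": "healthy", "time": [5.0, 5.0, 7.0],
                            "event": "death"})
        spec = ModelSpec(transitions={"healthy": ["death"]},
                         families={"healthy": "weibull"})
        with pytest.raises(FeasibilityError, match="healthy.death"):
            bootstrap_param_sets(rec, spec, 2, max_attempts=1, seed=0)

    def test_rate_sd_matches_independent_resampling_oracle(self):
        rec = _exp_records(500, 0.1, 31)
        t = bootstrap_param_sets(rec, EXP_SPEC, 600, seed=32)
        sd = t.data["a.healthy.death.rate"].std(ddof=1)
        oracle = exponential_bootstrap_oracle(rec["time"].to_numpy(), 600, 77)
        assert sd == pytest.approx(oracle.std(ddof=1), rel=0.15)

    def test_scarce_event_rule_reapplied_per_resample(self):
        # 3 deaths among 60 patients: some resamples keep <2 deaths
        rng = np.random.default_rng(4)
        rows = [(f"p{i}", "a", "healthy", rng.gamma(2, 5), "progression")
                for i in range(57)]
        rows += [(f"d{i}", "a", "healthy", rng.gamma(2, 8), "death")
                 for i in range(3)]
        rec = pd.DataFrame(rows, columns=["patient_id", "group", "transition",
                                          "time", "event"])
        spec = ModelSpec(transitions={"healthy": ["progression", "death"]},
                         families={"healthy": "weibull"})
        t = bootstrap_param_sets(rec, spec, 60, seed=5)
        pd_col = t.data["a.healthy.death.prob"]
        assert (pd_col == 0.0).any() and (pd_col > 0.0).any()
        # suppressed rows carry NaN parameters but remain valid rows
        nan_rows = t.data.loc[pd_col == 0.0, "a.healthy.death.shape"]
        assert nan_rows.isna().all()


class TestMVNorm:
    def test_zero_vcov_reproduces_point_estimates(self, fitted100):
        import copy
        ms = copy.deepcopy(fitted100)
        for tm in ms.models.values():
            for fd in tm.conditional_dists.values():
                fd.vcov.iloc[:, :] = 0.0
        t = mvnorm_param_sets(ms, 4, seed=1)
        pe = ms.point_estimates()
        for _, row in t.data.iterrows():
            for col in t.data.columns:
                if col.endswith(".prob"):
                    continue
                if np.isnan(pe[col]):
                    assert np.isnan(row[col])
                else:
                    assert row[col] == pe[col]

    def test_moments_match_textbook_sampler(self, fitted100):
        r = 4000
        t = mvnorm_param_sets(fitted100, r, seed=6)
        fd = fitted100[("control", "healthy")].conditional_dists["progression"]
        cols = ["control.healthy.progression.shape",
                "control.healthy.progression.scale"]
        draws = t.data[cols].to_numpy()
        oracle = mvn_sample_oracle(fd.theta.to_numpy(), fd.vcov.to_numpy(), r, 99)
        for j in range(2):
            se = draws[:, j].std(ddof=1) / np.sqrt(r)
            assert abs(draws[:, j].mean() - oracle[:, j].mean()) < 4 * se
        np.testing.assert_allclose(np.cov(draws.T), np.cov(oracle.T), rtol=0.2)

    def test_small_sample_fits_produce_rejections(self, population, model):
        ipd = generate_ipd(population, 25, seed=100)
        ms = fit_model_set(ipd, model.model_spec())
        t = mvnorm_param_sets(ms, 200, seed=200)
        assert t.n_rejected > 0
        t.validate(ms)  # all *returned* rows are feasible

    def test_not_converged_fit_rejected(self, fitted100):
        import copy
        ms = copy.deepcopy(fitted100)
        next(iter(ms.models.values())).conditional_dists["progression"].converged = False
        with pytest.raises(ConfigurationError, match="not converged"):
            mvnorm_param_sets(ms, 2, seed=1)

    def test_reproducible(self, fitted100):
        a = mvnorm_param_sets(fitted100, 8, seed=42)
        b = mvnorm_param_sets(fitted100, 8, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestFixed:
    def test_identical_rows(self, fitted100):
        t = fixed_param_sets(fitted100, 5)
        assert t.r == 5 and t.provenance == "fixed"
        for i in range(1, 5):
            pd.testing.assert_series_equal(t.data.iloc[0], t.data.iloc[i],
                                           check_names=False)

    def test_single_row_equals_mle_vector(self, fitted100):
        t = fixed_param_sets(fitted100, 1)
        pd.testing.assert_series_equal(t.data.iloc[0], fitted100.point_estimates(),
                                       check_names=False)


class TestApproachAgreementAndCorrelation:
    def test_bootstrap_and_mvnorm_sds_agree_for_exponential_n500(self):
        rec = _exp_records(500, 0.1, 8)
        tb = bootstrap_param_sets(rec, EXP_SPEC, 400, seed=9)
        ms = fit_model_set(rec, EXP_SPEC)
        tm = mvnorm_param_sets(ms, 400, seed=10)
        col = "a.healthy.death.rate"
        ratio = tb.data[col].std(ddof=1) / tm.data[col].std(ddof=1)
        assert 0.8 <= ratio <= 1.25

    def test_bootstrap_preserves_cross_distribution_correlation(self):
        pop = TruePopulation(
            structure={"healthy": {"progression": "progressed", "death": "death"},
                       "progressed": {"death": "death"}},
            groups={"obs": {
                "healthy": {
                    "progression": RiskSpec("weibull", {"shape": 1.4, "scale": 18}),
                    "death": RiskSpec("weibull", {"shape": 1.2, "scale": 40})},
                "progressed": {
                    "death": RiskSpec("weibull", {"shape": 1.3, "scale": 12})}}},
            frailty_sd=0.6)
        ipd = generate_ipd(pop, 150, seed=21)
        spec = pop.model_spec()
        tb = bootstrap_param_sets(ipd, spec, 150, seed=22)
        tm = mvnorm_param_sets(fit_model_set(ipd, spec), 150, seed=23)
        c1, c2 = "obs.healthy.progression.scale", "obs.progressed.death.scale"
        assert tb.data[c1].corr(tb.data[c2]) > 0.15
        assert abs(tm.data[c1].corr(tm.data[c2])) < 0.15


def test_csv_round_trip(tmp_path, ipd100, model):
    t = bootstrap_param_sets(ipd100, model.model_spec(), 4, seed=13)
    path = tmp_path / "sets.csv"
    t.to_csv(path)
    back = type(t).from_csv(path)
    pd.testing.assert_frame_equal(back.data, t.data)
    assert back.provenance == "bootstrap" and back.seed == 13
    assert back.n_rejected == t.n_rejected
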