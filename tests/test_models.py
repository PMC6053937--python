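"""Tests for covariate preparation, AICc selection and the model suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

import alarmnet as an
from alarmnet.community import DEFAULT_TRUE_BETAS, generate_community
from alarmnet.design import DESIGN_TERMS
from alarmnet.models import (ModelSpec, aicc, build_candidate_set, fit_model,
                             preliminary_calltype_model, select_model,
                             standardize_covariates, term_lrt, term_parents,
                             wilcoxon_control_check)


class TestStandardise:
    def test_three_point_example(self):
        out, params = standardize_covariates(pd.DataFrame({"x": [1.0, 2, 3]}), ["x"])
        assert np.allclose(out["x"], [-1, 0, 1])
        assert params["x"] == (2.0, 1.0)

    def test_idempotent_to_numerics(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100)})
        once, _ = standardize_covariates(df, ["x"])
        twice, _ = standardize_covariates(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_moments_after_scaling(self, rng):
        df = pd.DataFrame({"x": rng.exponential(5, size=500)})
        out, _ = standardize_covariates(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="x"):
            standardize_covariates(pd.DataFrame({"x": [1.0, 1.0]}), ["x"])


class TestAicc:
    def test_closed_form(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24.0 + 12.0 / 7.0)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            ll = rng.normal(-100, 20)
            k = int(rng.integers(1, 10))
            n = int(rng.integers(k + 2, 500))
            assert aicc(ll, k, n) == pytest.approx(
                -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1))


class TestCandidateSet:
    def spec(self, terms):
        return ModelSpec("y", "binomial", tuple(terms))

    def test_two_main_effects_powerset(self):
        assert len(build_candidate_set(self.spec(["a", "b"]))) == 4

    def test_interaction_marginality(self):
        cands = build_candidate_set(self.spec(["a", "b", "a:b"]))
        for c in cands:
            if "a:b" in c.fixed_terms:
                assert {"a", "b"} <= set(c.fixed_terms)
        assert len(cands) == 5

    def test_quadratic_requires_linear(self):
        cands = build_candidate_set(self.spec(["a", "a^2"]))
        assert {c.fixed_terms for c in cands} == {(), ("a",), ("a", "a^2")}

    def test_full_playback_term_list_matches_enumeration_oracle(self):
        from alarmnet.models import PLAYBACK_TERM_PARENTS
        cands = build_candidate_set(self.spec(DESIGN_TERMS),
                                    parents=PLAYBACK_TERM_PARENTS)
        count = 0
        for r in range(len(DESIGN_TERMS) + 1):
            for combo in itertools.combinations(DESIGN_TERMS, r):
                s = set(combo)
                ok = (("size_ratio_sq" not in s or "size_ratio" in s)
                      and ("rbs_x_ratio" not in s
                           or {"receiver_size", "size_ratio"} <= s)
                      and ("rbs_x_ratio_sq" not in s
                           or {"receiver_size", "size_ratio_sq"} <= s))
                count += ok
        assert len(cands) == count

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            build_candidate_set(self.spec([f"x{i}" for i in range(20)]),
                                max_models=100)

    def test_term_parents_syntax(self):
        assert term_parents("a:b") == {"a", "b"}
        assert term_parents("a^2") == {"a"}
        assert term_parents("a:b^2") == {"a", "b^2"}


def logistic_data(rng, n, beta):
    x1, x2, x3 = rng.normal(size=(3, n))
    eta = beta * x1 + 0.0 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})


class TestSelection:
    def test_single_candidate_returned(self, rng):
        data = logistic_data(rng, 200, 1.0)
        spec = ModelSpec("y", "binomial", ("x1",))
        best, table = select_model([spec], data)
        assert best.spec == spec and len(table) == 1

    def test_strong_signal_model_beats_null(self, rng):
        data = logistic_data(rng, 2000, 2.0)
        cands = [ModelSpec("y", "binomial", ()), ModelSpec("y", "binomial", ("x1",))]
        best, table = select_model(cands, data)
        assert best.spec.fixed_terms == ("x1",)
        assert (table["aicc"].diff().dropna() >= 0).all()

    def test_selection_table_sorted_and_tiebreak_deterministic(self, rng):
        data = logistic_data(rng, 300, 0.0)
        cands = build_candidate_set(ModelSpec("y", "binomial", ("x1", "x2", "x3")))
        best, table = select_model(cands, data)
        assert (table["aicc"].diff().dropna() >= -1e-12).all()

    def test_aicc_invariant_to_covariate_relabeling(self, rng):
        data = logistic_data(rng, 400, 1.0)
        a = fit_model(ModelSpec("y", "binomial", ("x1", "x2")), data)
        renamed = data.rename(columns={"x1": "z1", "x2": "z2"})
        b = fit_model(ModelSpec("y", "binomial", ("z1", "z2")), renamed)
        assert a.aicc == pytest.approx(b.aicc, abs=1e-9)

    def test_term_lrt_detects_signal(self, rng):
        data = logistic_data(rng, 1500, 1.0)
        spec = ModelSpec("y", "binomial", ("x1", "x2"))
        lr1, p1 = term_lrt(spec, data, "x1")
        lr2, p2 = term_lrt(spec, data, "x2")
        assert p1 < 1e-6 and p2 > 0.01


class TestAlarmModelM1:
    def test_identical_data_identical_fits(self, predator_trials, cfg):
        a = an.fit_alarm_model_M1(predator_trials, cfg.epsilon)
        b = an.fit_alarm_model_M1(predator_trials, cfg.epsilon)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)

    def test_null_coupling_not_significant(self):
        c = generate_community(8)           # propensities independent of epsilon
        tr = an.simulate_predator_trials(c, 9, seed=5)
        fit = an.fit_alarm_model_M1(tr, c.epsilon, include_interaction=False)
        assert abs(fit.coefficients.loc["vulnerability", "statistic"]) < 1.96

    def test_coupled_propensities_recovered(self):
        c = generate_community(9, vulnerability_coupling=1.76)
        tr = an.simulate_predator_trials(c, 9, seed=6)
        fit = an.fit_alarm_model_M1(tr, c.epsilon, include_interaction=False)
        row = fit.coefficients.loc["vulnerability"]
        assert row["estimate"] > 0 and row["p"] < 0.05
        assert row["estimate"] - 1.96 * row["se"] < 1.76 < row["estimate"] + 1.96 * row["se"]


def null_community(seed, **beta_overrides):
    betas = {k: 0.0 for k in DEFAULT_TRUE_BETAS}
    betas.update(beta_overrides)
    return generate_community(seed, overrides={"true_betas": betas})


class TestPreliminaryModel:
    def test_alarm_vs_control_contrasts(self):
        c = null_community(3, intercept=np.log(0.7 / 0.3),
                           control=np.log(0.1 / 0.9))
        idx = an.true_indices(c)
        pb = an.simulate_playbacks(c, idx, 14, seed=4)
        fit, filtered = preliminary_calltype_model(pb, include_interaction=False)
        for kind in ("conspecific", "heterospecific"):
            row = fit.coefficients.loc[kind]
            assert row["estimate"] > 0 and row["p"] < 0.05
        assert (filtered["call_kind"] != "control").all()

    def test_equal_rates_null_contrasts(self):
        c = null_community(5)               # every condition at logit 0
        idx = an.true_indices(c)
        c.random_intercept_sd = 0.0
        pb = an.simulate_playbacks(c, idx, 14, seed=6)
        fit, _ = preliminary_calltype_model(pb, include_interaction=False)
        for kind in ("conspecific", "heterospecific"):
            assert abs(fit.coefficients.loc[kind, "statistic"]) < 3.0

    def test_missing_level_rejected(self, playbacks):
        no_ctrl = playbacks[playbacks["call_kind"] != "control"]
        with pytest.raises(ValueError, match="control"):
            preliminary_calltype_model(no_ctrl)


class TestMixedFits:
    def test_zero_re_mixed_agrees_with_fixed(self):
        c = null_community(11, consistency=1.5)
        c.random_intercept_sd = 0.0
        idx = an.true_indices(c)
        pb = an.simulate_playbacks(c, idx, 14, seed=7)
        from alarmnet.models import prepare_playback_table, response_model_spec
        tab = prepare_playback_table(pb, idx, c.body_masses)
        mixed = fit_model(response_model_spec("responded", "binomial"), tab)
        fixed = fit_model(ModelSpec("responded", "binomial",
                                    tuple(DESIGN_TERMS)), tab)
        assert mixed.sigma == pytest.approx(0.0, abs=0.05)
        assert np.allclose(mixed.coefficients["estimate"],
                           fixed.coefficients["estimate"], atol=1e-3)

    def test_six_response_models_fit_and_converge(self, cfg, true_idx, playbacks):
        fits = an.fit_response_models(playbacks, true_idx, cfg.body_masses)
        assert set(fits) == {"responded", "latency_s", "duration_s",
                             "headlift_speed", "n_head_ups", "n_scratches"}
        for name, fit in fits.items():
            assert fit.converged, name
            assert np.isfinite(fit.aicc), name
            assert ((fit.coefficients["p"] >= 0)
                    & (fit.coefficients["p"] <= 1)).all()
        # reduced-n contract: conditional models use responder subsets only
        n_resp = int(playbacks[playbacks["call_kind"] == "heterospecific"]
                     ["responded"].sum())
        assert fits["latency_s"].n == n_resp
        assert fits["duration_s"].n <= n_resp

    def test_standardisation_rescales_linear_coefficients(self, rng):
        x = rng.uniform(1, 5, 400)
        y = np.exp(0.5 + 0.3 * x + rng.normal(0, 0.2, 400))
        data = pd.DataFrame({"y": y, "x": x})
        raw = fit_model(ModelSpec("y", "lognormal", ("x",)), data)
        std, params = standardize_covariates(data, ["x"])
        scaled = fit_model(ModelSpec("y", "lognormal", ("x",)), std)
        mu, sd = params["x"]
        assert scaled.coefficients.loc["x", "estimate"] == pytest.approx(
            raw.coefficients.loc["x", "estimate"] * sd, rel=1e-6)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_control_check([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 1.0

    def test_all_positive_differences_max_statistic(self):
        x = np.arange(1, 11) + 0.5
        res = wilcoxon_control_check(x, np.arange(1, 11).astype(float))
        assert res.V == 55.0                 # n(n+1)/2 for n = 10

    def test_matches_exact_permutation_oracle(self, rng):
        n = 8
        x = rng.uniform(0.1, 3, n)
        y = rng.uniform(0.1, 3, n)
        res = wilcoxon_control_check(x, y)
        d = x - y
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(d))
        v_obs = ranks[d > 0].sum()
        vs = []
        for signs in itertools.product([0, 1], repeat=n):
            vs.append(sum(r for r, s in zip(ranks, signs) if s))
        vs = np.asarray(vs)
        mu = vs.mean()
        p_exact = np.mean(np.abs(vs - mu) >= abs(v_obs - mu) - 1e-9)
        assert res.V == pytest.approx(v_obs)
        assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_control_check([-1.0, 2.0], [0.0, 1.0])
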