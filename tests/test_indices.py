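"""Unit and property tests for the information-content indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alarmnet.indices import (body_size_ratio, call_reliability,
                              caller_consistency, estimate_alarm_propensity,
                              estimate_call_profile, jacobs_transform,
                              scale_unit_interval)
from conftest import random_index_inputs


def loop_consistency(I, eps, A, normalized=True):
    """Brute-force oracle: explicit summation over predators."""
    a = A / A.sum()
    L = pd.DataFrame(index=eps.index, columns=I.columns, dtype=float)
    for i in eps.index:
        for j in I.columns:
            num = sum(I.loc[x, j] * eps.loc[i, x] * a[x] for x in I.index)
            den = sum(eps.loc[i, x] * a[x] for x in I.index)
            L.loc[i, j] = num / den if normalized else num
    return L


def loop_reliability(C, eps):
    V = pd.DataFrame(index=eps.index, columns=C.columns, dtype=float)
    for i in eps.index:
        for j in C.columns:
            V.loc[i, j] = sum(C.loc[x, j] * eps.loc[i, x] for x in C.index)
    return V


class TestJacobsTransform:
    @pytest.mark.parametrize("D,expected", [(-1.0, 0.0), (1.0, 1.0), (0.0, 0.5)])
    def test_linear_map(self, D, expected):
        assert jacobs_transform(D) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            jacobs_transform(1.5)

    def test_pluggable_transform(self):
        sq = jacobs_transform(0.0, transform=lambda d: ((d + 1) / 2) ** 2)
        assert sq == pytest.approx(0.25)


class TestPropensityEstimation:
    def trials(self, rows):
        return pd.DataFrame(
            [{"focal_species": s, "model_kind": "predator", "predator_id": p,
              "alarm_given": a} for s, p, a in rows])

    def test_proportions(self):
        rows = [("sp1", "lion", True)] * 9
        rows += [("sp2", "lion", True)] * 3 + [("sp2", "lion", False)] * 7
        I, n = estimate_alarm_propensity(self.trials(rows))
        assert I.loc["lion", "sp1"] == 1.0
        assert I.loc["lion", "sp2"] == pytest.approx(0.3)
        assert n.loc["lion", "sp2"] == 10

    def test_zero_trial_cell_is_missing_not_zero(self):
        rows = [("sp1", "lion", True), ("sp2", "hyena", False)]
        I, _ = estimate_alarm_propensity(self.trials(rows))
        assert np.isnan(I.loc["hyena", "sp1"])
        assert np.isnan(I.loc["lion", "sp2"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_alarm_propensity(pd.DataFrame())

    def test_estimates_within_binomial_envelope(self, cfg, predator_trials):
        # 9 trials/cell: the exact binomial 99.9% envelope around p with n=9
        I, n = estimate_alarm_propensity(
            predator_trials, species=cfg.species, predators=cfg.predators)
        from scipy.stats import binom
        for x in cfg.predators:
            for j in cfg.vocal_species:
                p = cfg.alarm_propensity.loc[x, j]
                lo, hi = binom.ppf([0.0005, 0.9995], 9, p)
                assert lo / 9 <= I.loc[x, j] <= hi / 9


class TestCallProfile:
    def test_one_hot_caller(self):
        I = pd.DataFrame({"j": [0.8, 0.0, 0.0]}, index=["lion", "hyena", "leopard"])
        C = estimate_call_profile(I)
        assert C.loc["lion", "j"] == 1.0
        assert C["j"].sum() == pytest.approx(1.0)

    def test_equal_rates_uniform(self):
        I = pd.DataFrame({"j": [0.4] * 5}, index=[f"p{i}" for i in range(5)])
        assert np.allclose(estimate_call_profile(I)["j"], 0.2)

    def test_rate_normalisation_corrects_unequal_trial_counts(self):
        # equal underlying rates, 10 vs 20 trials per predator: profiles stay uniform
        rows = [{"focal_species": "j", "model_kind": "predator",
                 "predator_id": "a", "alarm_given": True}] * 10
        rows += [{"focal_species": "j", "model_kind": "predator",
                  "predator_id": "b", "alarm_given": True}] * 20
        I, _ = estimate_alarm_propensity(pd.DataFrame(rows))
        C = estimate_call_profile(I)
        assert np.allclose(C["j"], 0.5)

    def test_silent_caller_column_undefined(self):
        I = pd.DataFrame({"j": [0.5, 0.5], "silent": [0.0, 0.0]},
                         index=["a", "b"])
        C = estimate_call_profile(I)
        assert C["silent"].isna().all()
        assert not C["j"].isna().any()


class TestConsistencyReliability:
    def test_perfect_informant_scores_one(self, rng):
        I, eps, A = random_index_inputs(rng)
        I.loc[:, :] = 1.0
        assert np.allclose(caller_consistency(I, eps, A), 1.0)

    def test_silent_species_scores_zero(self, rng):
        I, eps, A = random_index_inputs(rng)
        I.loc[:, :] = 0.0
        assert np.allclose(caller_consistency(I, eps, A), 0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            I, eps, A = random_index_inputs(rng)
            L = caller_consistency(I, eps, A)
            assert np.allclose(L, loop_consistency(I, eps, A), atol=1e-12)
            Lr = caller_consistency(I, eps, A, normalized=False)
            assert np.allclose(Lr, loop_consistency(I, eps, A, False), atol=1e-12)

    def test_reliability_matches_loop_oracle(self, rng):
        for _ in range(20):
            I, eps, A = random_index_inputs(rng)
            C = estimate_call_profile(I)
            assert np.allclose(call_reliability(C, eps), loop_reliability(C, eps),
                               atol=1e-12)

    def test_one_hot_profile_reads_off_epsilon(self):
        C = pd.DataFrame({"j": [1.0, 0.0]}, index=["a", "b"])
        eps = pd.DataFrame({"a": [0.8], "b": [0.1]}, index=["r"])
        assert call_reliability(C, eps).loc["r", "j"] == pytest.approx(0.8)

    def test_constant_vulnerability_is_convexity_fixed_point(self, rng):
        I, eps, A = random_index_inputs(rng)
        eps.loc[:, :] = 0.37
        C = estimate_call_profile(I)
        assert np.allclose(call_reliability(C, eps), 0.37)

    def test_unnormalised_column_sum_rejected(self):
        C = pd.DataFrame({"j": [0.5, 0.4]}, index=["a", "b"])
        eps = pd.DataFrame({"a": [0.8], "b": [0.1]}, index=["r"])
        with pytest.raises(ValueError):
            call_reliability(C, eps)

    def test_invulnerable_receiver_flagged_undefined(self, rng):
        I, eps, A = random_index_inputs(rng)
        eps.iloc[0, :] = 0.0
        L = caller_consistency(I, eps, A)
        assert L.iloc[0].isna().all()
        assert not L.iloc[1:].isna().any().any()

    def test_predator_label_permutation_invariance(self, rng):
        I, eps, A = random_index_inputs(rng)
        perm = list(rng.permutation(I.index))
        L1 = caller_consistency(I, eps, A)
        L2 = caller_consistency(I.loc[perm], eps[perm], A[perm])
        assert np.allclose(L1, L2, atol=1e-12)
        V1 = call_reliability(estimate_call_profile(I), eps)
        V2 = call_reliability(estimate_call_profile(I.loc[perm]), eps[perm])
        assert np.allclose(V1, V2, atol=1e-12)

    def test_monotone_in_propensity_and_vulnerability(self, rng):
        I, eps, A = random_index_inputs(rng)
        L0 = caller_consistency(I, eps, A)
        I2 = I.copy()
        I2.iloc[1, 1] = min(1.0, I2.iloc[1, 1] + 0.2)
        assert (caller_consistency(I2, eps, A) >= L0 - 1e-12).all().all()
        C = estimate_call_profile(I)
        V0 = call_reliability(C, eps)
        eps2 = eps.copy()
        eps2.iloc[2, 3] = min(1.0, eps2.iloc[2, 3] + 0.2)
        assert (call_reliability(C, eps2) >= V0 - 1e-12).all().all()

    def test_normalised_and_raw_variants_rank_alike(self, rng):
        for _ in range(10):
            I, eps, A = random_index_inputs(rng, n_call=5)
            Ln = caller_consistency(I, eps, A)
            Lr = caller_consistency(I, eps, A, normalized=False)
            for i in eps.index:
                assert (Ln.loc[i].rank() == Lr.loc[i].rank()).all()

    def test_bounds_over_random_configs(self, rng):
        for _ in range(200):
            I, eps, A = random_index_inputs(rng)
            L = caller_consistency(I, eps, A)
            V = call_reliability(estimate_call_profile(I), eps)
            assert ((L >= -1e-12) & (L <= 1 + 1e-12)).all().all()
            assert ((V >= -1e-12) & (V <= 1 + 1e-12)).all().all()


class TestSizeRatioAndScaling:
    @pytest.mark.parametrize("r,c,expected", [
        (100.0, 100.0, 1.0),   # equal masses: both branches give 1
        (100.0, 50.0, 2.0),    # receiver twice as large
        (50.0, 100.0, 0.0),    # receiver half the size: 2 - 2
    ])
    def test_lovich_gibbons_branches(self, r, c, expected):
        assert body_size_ratio(r, c) == pytest.approx(expected)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            body_size_ratio(0.0, 10.0)

    @given(st.floats(0.01, 1000), st.floats(0.01, 1000))
    @settings(max_examples=100, deadline=None)
    def test_continuity_ordering(self, r, c):
        v = body_size_ratio(r, c)
        if r > c:
            assert v >= 1.0
        elif r < c:
            assert v <= 1.0

    def test_unit_scaling(self):
        assert np.allclose(scale_unit_interval([1, 2, 3]), [0, 0.5, 1])
        out = scale_unit_interval([-38.0, -10.0, 2.0])
        assert out[0] == 0.0 and out[-1] == 1.0

    def test_scaling_preserves_order(self, rng):
        v = rng.normal(size=50)
        s = scale_unit_interval(v)
        assert (np.argsort(s) == np.argsort(v)).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            scale_unit_interval([2.0, 2.0, 2.0])
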