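import numpy as np
import pandas as pd
import pytest

from growthmap.bym import (BYMModel, McmcConfig, ModelSpec, car_log_prior,
                           dic, geweke, log_likelihood)
from growthmap.geography import Adjacency
from conftest import make_suburb_data


class TestModelSpec:
    @pytest.mark.parametrize("name,flags", [
        ("null", (False, False, False)), ("random", (False, True, True)),
        ("fixed", (True, False, False)), ("full", (True, True, True))])
    def test_four_nested_models(self, name, flags):
        spec = ModelSpec.from_name(name)
        assert (spec.include_fixed_ses, spec.include_car,
                spec.include_iid) == flags
        assert spec.name == name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_name("bananas")


class TestMcmcConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)


class TestLogLikelihood:
    def test_single_suburb_closed_form(self):
        tab = pd.DataFrame({"cases": [1], "births": [2]})
        assert log_likelihood(tab, np.array([0.0])) == pytest.approx(
            np.log(0.25))

    def test_balanced_data_maximised_at_zero(self):
        tab = pd.DataFrame({"cases": [50], "births": [100]})
        ll0 = log_likelihood(tab, np.array([0.0]))
        for eta in (-0.5, -0.1, 0.1, 0.5):
            assert log_likelihood(tab, np.array([eta])) < ll0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(3)
        n = rng.integers(50, 300, 5)
        r = rng.binomial(n, 0.1)
        eta = rng.normal(-2, 0.5, 5)
        tab = pd.DataFrame({"cases": r, "births": n})
        p = 1 / (1 + np.exp(-eta))
        brute = sum(ri * np.log(pi) + (ni - ri) * np.log(1 - pi)
                    for ri, ni, pi in zip(r, n, p))
        assert log_likelihood(tab, eta) == pytest.approx(brute)


class TestCarLogPrior:
    def test_zero_field_has_zero_energy(self):
        adj = Adjacency(["a", "b"], {"a": ["b"], "b": ["a"]})
        assert car_log_prior(np.zeros(2), adj, 0.5) == 0.0

    def test_two_unit_closed_form(self):
        adj = Adjacency(["a", "b"], {"a": ["b"], "b": ["a"]})
        a, sigma = 0.7, 0.4
        assert car_log_prior(np.array([a, -a]), adj, sigma) == pytest.approx(
            -2 * a ** 2 / sigma ** 2)

    def test_full_conditional_mean_is_neighbour_average(self):
        # the stationary point of the prior in u_i is the neighbour mean
        adj = Adjacency(["a", "b", "c", "d"],
                        {"a": ["b", "c", "d"], "b": ["a"], "c": ["a"],
                         "d": ["a"]})
        u = np.array([0.0, 0.3, -0.1, 0.5])
        sigma, eps = 0.6, 1e-5
        grad = (car_log_prior(u + np.array([eps, 0, 0, 0]), adj, sigma)
                - car_log_prior(u - np.array([eps, 0, 0, 0]), adj, sigma)) \
            / (2 * eps)
        u_star = u.copy()
        u_star[0] = np.mean(u[1:])
        grad_star = (car_log_prior(u_star + np.array([eps, 0, 0, 0]), adj, sigma)
                     - car_log_prior(u_star - np.array([eps, 0, 0, 0]), adj,
                                     sigma)) / (2 * eps)
        assert abs(grad) > 0.1 and abs(grad_star) < 1e-6


class TestGeweke:
    def test_identical_halves_give_zero(self):
        x = np.sin(np.arange(500) / 7.0)
        chain = np.concatenate([x, x])
        assert geweke(chain, first_frac=0.5, last_frac=0.5) == pytest.approx(
            0.0, abs=1e-12)

    def test_trend_is_detected(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(5000) + np.linspace(0, 2, 5000)
        assert abs(geweke(chain)) > 3

    def test_iid_chain_is_calibrated(self):
        rng = np.random.default_rng(1)
        flagged = sum(abs(geweke(rng.standard_normal(5000))) > 3
                      for _ in range(50))
        assert flagged == 0

    def test_short_chain_raises(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50.0))


class TestFitting:
    def test_null_model_tracks_pooled_incidence(self):
        tab, adj = make_suburb_data(8, 8, births=500, seed=50)
        res = BYMModel(tab, adj, "null").fit(
            McmcConfig(iterations=8000, burn_in=2000, thin=5, seed=51))
        pooled = tab["cases"].sum() / tab["births"].sum()
        p = 1 / (1 + np.exp(-res.draws.beta0))
        assert abs(p.mean() - pooled) < 2 * p.std()

    def test_same_seed_gives_identical_draws(self):
        tab, adj = make_suburb_data(6, 6, sigma_u=0.3, sigma_v=0.2, seed=52)
        cfg = McmcConfig(iterations=4000, burn_in=1000, thin=5, seed=53)
        a = BYMModel(tab, adj, "full").fit(cfg)
        b = BYMModel(tab, adj, "full").fit(cfg)
        assert np.array_equal(a.draws.beta0, b.draws.beta0)
        assert np.array_equal(a.draws.u, b.draws.u)
        assert np.array_equal(a.draws.sigma_v, b.draws.sigma_v)

    def test_u_sums_to_zero_in_every_retained_sample(self, small_full_fit):
        _, _, res = small_full_fit
        assert np.abs(res.draws.u.sum(axis=1)).max() < 1e-6

    def test_full_model_recovers_generating_values(self, small_full_fit):
        tab, _, res = small_full_fit
        lo, hi = np.quantile(res.draws.beta1, [0.025, 0.975])
        assert lo < -0.3 < hi
        assert res.mean_probability["ci95"][0] < 0.06

    def test_scales_concentrate_when_truth_is_zero(self):
        tab, adj = make_suburb_data(10, 10, births=400, seed=54)
        res = BYMModel(tab, adj, "full").fit(
            McmcConfig(iterations=12_000, burn_in=4_000, thin=10, seed=55))
        assert np.median(res.draws.sigma_u) < 0.15
        assert np.median(res.draws.sigma_v) < 0.15

    def test_relabelling_units_leaves_population_estimates(self):
        tab, adj = make_suburb_data(6, 6, sigma_u=0.25, sigma_v=0.2,
                                    births=500, seed=56)
        cfg = McmcConfig(iterations=10_000, burn_in=4_000, thin=5, seed=57)
        res_a = BYMModel(tab, adj, "random").fit(cfg)
        perm = np.random.default_rng(58).permutation(len(tab))
        adj_p = Adjacency([adj.ids[k] for k in perm], adj.neighbors)
        res_b = BYMModel(tab, adj_p, "random").fit(cfg)
        # same model, same data, different unit ordering: posterior means of
        # population-level parameters agree within Monte Carlo error
        assert abs(res_a.draws.beta0.mean()
                   - res_b.draws.beta0.mean()) < 0.05
        assert abs(res_a.draws.sigma_u.mean()
                   - res_b.draws.sigma_u.mean()) < 0.08

    def test_missing_ses_column_rejected_for_fixed_model(self):
        tab, adj = make_suburb_data(4, 4, seed=59)
        with pytest.raises(ValueError):
            BYMModel(tab.drop(columns=["ses_std"]), adj, "fixed").fit(
                McmcConfig(iterations=500, burn_in=100, seed=1))

    def test_mismatched_adjacency_rejected(self):
        tab, adj = make_suburb_data(4, 4, seed=60)
        with pytest.raises(ValueError):
            BYMModel(tab.iloc[:-1], adj, "null")

    def test_summary_renders(self, small_full_fit):
        _, _, res = small_full_fit
        text = res.summary()
        assert "DIC" in text and "Geweke" in text and "b1" in text


class TestDic:
    def test_too_few_draws_rejected(self, small_full_fit):
        tab, _, res = small_full_fit
        import dataclasses
        short = dataclasses.replace(
            res.draws, beta0=res.draws.beta0[:50],
            deviance=res.draws.deviance[:50])
        with pytest.raises(ValueError):
            dic(short, tab)

    def test_dic_decomposition_consistent(self, small_full_fit):
        tab, _, res = small_full_fit
        total, pd_ = dic(res.draws, tab)
        assert total == pytest.approx(res.draws.deviance.mean() + pd_)
        assert pd_ > 0
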