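import dataclasses

import numpy as np
import pandas as pd
import pytest

import airhappy as ah
from airhappy.inference import (
    HierarchicalOrdinalRegression,
    McmcConfig,
    PosteriorDraws,
    compute_dic,
    gelman_rubin,
    posterior_summary,
    run_mcmc,
    vpc,
)
from airhappy.model import Dataset, observation_log_probs


def _draws_from_columns(columns: dict, n_chains=2) -> PosteriorDraws:
    """Hand-built PosteriorDraws with a single coefficient structure."""
    n = len(next(iter(columns.values())))
    frames = []
    for c in range(n_chains):
        f = pd.DataFrame(columns)
        f["chain"] = c
        frames.append(f)
    samples = pd.concat(frames, ignore_index=True)
    return PosteriorDraws(
        samples=samples,
        x_names=tuple(c[2:] for c in columns if c.startswith("b_")),
        z_names=tuple(c[2:] for c in columns if c.startswith("g_")),
        city_ids=tuple(c[2:] for c in columns if c.startswith("u_")),
        n_categories=sum(c.startswith("alpha_") for c in columns) + 1,
        config=McmcConfig(n_chains=n_chains, n_iterations=2 * n, burn_in=0, thin=1),
    )


class TestMcmcConfig:
    def test_full_protocol_defaults(self):
        cfg = McmcConfig()
        assert (cfg.n_chains, cfg.n_iterations, cfg.burn_in, cfg.thin) == (3, 50_000, 30_000, 10)

    @pytest.mark.parametrize("kwargs", [
        {"burn_in": 10, "n_iterations": 10},
        {"thin": 0},
        {"n_chains": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            McmcConfig(**kwargs)


class TestRunMcmc:
    def test_seeded_determinism(self, tiny_dataset):
        cfg = McmcConfig(n_chains=2, n_iterations=300, burn_in=100, thin=2, seed=5)
        a = run_mcmc(tiny_dataset, config=cfg)
        b = run_mcmc(tiny_dataset, config=cfg)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        c = run_mcmc(tiny_dataset, config=dataclasses.replace(cfg, seed=6))
        assert not a.samples.equals(c.samples)

    def test_retained_draw_count_and_structure(self, small_fit, tiny_dataset):
        cfg = small_fit.config
        per_chain = -(-(cfg.n_iterations - cfg.burn_in) // cfg.thin)
        assert small_fit.n_draws == cfg.n_chains * per_chain
        assert small_fit.alpha_array().shape[1] == tiny_dataset.J - 1

    def test_threshold_ordering_on_every_draw(self, small_fit):
        assert (np.diff(small_fit.alpha_array(), axis=1) > 0).all()

    def test_sigma_u2_draws_positive(self, small_fit):
        assert (small_fit.pooled("sigma_u2") > 0).all()

    def test_acceptance_rates_in_sane_band(self, small_fit):
        for acc in small_fit.acceptance.values():
            for block in ("alpha", "coef", "u"):
                assert (acc[block] > 0.1).all() and (acc[block] < 0.6).all()

    def test_empty_category_warns_but_runs(self, tiny_survey, model1_spec):
        individuals, cities = tiny_survey
        squeezed = individuals.copy()
        squeezed["happiness"] = squeezed.happiness.clip(lower=2)  # empty category 1
        ds = Dataset.from_frames(squeezed, cities, model1_spec)
        with pytest.warns(UserWarning, match="empty"):
            run_mcmc(ds, config=McmcConfig(n_chains=1, n_iterations=200, burn_in=100, thin=1, seed=0))

    def test_sigma_shrinks_without_heterogeneity(self):
        """Simulated truth with sigma_u2 = 0: the posterior median collapses
        toward zero under the inverse-gamma prior."""
        cfg = ah.default_scenario()
        truth = dataclasses.replace(cfg.true_parameters, sigma_u2=0.0)
        cfg = dataclasses.replace(cfg, true_parameters=truth, seed=77)
        ind, cities = ah.simulate_survey(cfg)
        ds = Dataset.from_frames(ind, cities, ah.default_ladder()["model1"])
        draws = run_mcmc(ds, config=McmcConfig(n_chains=1, n_iterations=1500,
                                               burn_in=700, thin=2, seed=2))
        assert np.median(draws.pooled("sigma_u2")) < 0.05

    def test_posterior_centers_on_independent_mle(self, tiny_scenario):
        """With a flat prior, no simulated between-city heterogeneity and a
        moderate sample, posterior medians agree with the maximum-likelihood
        fit of an independent ordinal-regression implementation within two
        posterior SDs."""
        pytest.importorskip("statsmodels")
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        truth = dataclasses.replace(tiny_scenario.true_parameters, sigma_u2=0.0)
        cfg = dataclasses.replace(tiny_scenario, n_cities=10, city_size_range=(200, 200),
                                  true_parameters=truth, seed=13)
        ind, cities = ah.simulate_survey(cfg)
        ds = Dataset.from_frames(ind, cities, ah.default_ladder()["model1"])
        draws = run_mcmc(ds, config=McmcConfig(n_chains=2, n_iterations=2500,
                                               burn_in=1200, thin=2, seed=3))

        df = ind.merge(cities, on="city_id")
        df["log_income"] = np.log(df.income_rmb)
        res = OrderedModel(df.happiness, df[["log_income", "polluted_days"]],
                           distr="logit").fit(method="bfgs", disp=False)
        for name, mle in [("b_income_rmb", res.params.iloc[0]),
                          ("g_polluted_days", res.params.iloc[1])]:
            v = draws.pooled(name)
            assert abs(np.median(v) - mle) < 2 * v.std()


def test_prior_sensitivity_blocks(tiny_dataset):
    """Alternative hyperpriors of similar vagueness barely move the income
    posterior median."""
    from airhappy.inference import prior_sensitivity
    from airhappy.model import PriorSpec

    cfg = McmcConfig(n_chains=1, n_iterations=800, burn_in=400, thin=2, seed=4)
    out = prior_sensitivity(
        tiny_dataset,
        [PriorSpec(), PriorSpec(ig_shape=0.01, ig_scale=0.01)],
        config=cfg,
    )
    assert out.index.get_level_values("prior").nunique() == 2
    meds = out.xs("b_income_rmb", level="parameter")["median"]
    assert meds.max() - meds.min() < 0.2


class TestPosteriorSummary:
    def test_degenerate_draws(self):
        draws = _draws_from_columns({
            "alpha_1": np.full(10, -1.0), "b_x": np.full(10, 2.5),
            "sigma_u2": np.full(10, 0.3),
        })
        s = posterior_summary(draws)
        assert s.loc["b_x", ["median", "ci_2.5", "ci_97.5"]].tolist() == [2.5, 2.5, 2.5]
        assert s.loc["b_x", "sig"] == "***"  # all-positive draws

    def test_type7_quantiles_on_1_to_100(self):
        draws = _draws_from_columns({
            "alpha_1": np.zeros(100), "b_x": np.arange(1.0, 101.0),
            "sigma_u2": np.ones(100),
        }, n_chains=1)
        s = posterior_summary(draws)
        assert s.loc["b_x", "median"] == pytest.approx(50.5)
        assert s.loc["b_x", "ci_2.5"] == pytest.approx(3.475)
        assert s.loc["b_x", "ci_97.5"] == pytest.approx(97.525)

    def test_star_levels(self):
        rng = np.random.default_rng(1)
        v90 = rng.normal(1.0, 0.55, 4000)  # excludes 0 at 90% but not 99%
        draws = _draws_from_columns({
            "alpha_1": np.zeros(4000), "b_x": v90, "sigma_u2": np.ones(4000),
        }, n_chains=1)
        s = posterior_summary(draws)
        assert s.loc["b_x", "sig"] in {"*", "**"}
        assert s.loc["alpha_1", "sig"] == ""


class TestGelmanRubin:
    def test_identical_chains_near_one(self, small_fit):
        rhat = gelman_rubin(small_fit)
        assert (rhat < 1.3).all()  # short healthy run
        # two literally identical chains
        base = np.sin(np.arange(200.0))
        draws = _draws_from_columns({"alpha_1": base, "b_x": base, "sigma_u2": base**2 + 1})
        assert gelman_rubin(draws)["b_x"] == pytest.approx(1.0, abs=1e-2)

    def test_offset_chains_diverge(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        samples = pd.DataFrame({
            "alpha_1": np.concatenate([a, a + 50.0]),
            "sigma_u2": np.ones(400),
            "chain": np.repeat([0, 1], 200),
        })
        draws = PosteriorDraws(samples=samples, x_names=(), z_names=(), city_ids=(),
                               n_categories=2,
                               config=McmcConfig(n_chains=2, n_iterations=400, burn_in=0, thin=1))
        assert gelman_rubin(draws)["alpha_1"] > 5.0

    def test_hand_computed_two_chain_example(self):
        """Split-R-hat on two length-4 chains matches the textbook
        between/within variance formula evaluated by hand."""
        c1 = np.array([1.0, 2.0, 3.0, 4.0])
        c2 = np.array([2.0, 4.0, 6.0, 8.0])
        samples = pd.DataFrame({
            "alpha_1": np.concatenate([c1, c2]),
            "sigma_u2": np.ones(8),
            "chain": np.repeat([0, 1], 4),
        })
        draws = PosteriorDraws(samples=samples, x_names=(), z_names=(), city_ids=(),
                               n_categories=2,
                               config=McmcConfig(n_chains=2, n_iterations=8, burn_in=0, thin=1))
        # split into 4 half-chains of length 2
        split = np.array([[1, 2], [2, 4], [3, 4], [6, 8]], dtype=float)
        n = 2
        W = split.var(axis=1, ddof=1).mean()
        B = n * split.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(draws)["alpha_1"] == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self, tiny_dataset):
        cfg = McmcConfig(n_chains=1, n_iterations=100, burn_in=40, thin=1, seed=0)
        draws = run_mcmc(tiny_dataset, config=cfg)
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(draws)


class TestDic:
    def test_degenerate_draws_have_zero_pd(self, small_fit, tiny_dataset):
        one = small_fit.samples.iloc[[0]].copy()
        frozen = pd.concat([one] * 20, ignore_index=True)
        draws = dataclasses.replace(small_fit, samples=frozen)
        dic, p_d, dbar = compute_dic(draws, tiny_dataset)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(dbar, abs=1e-8)

    def test_matches_loop_oracle(self, small_fit, tiny_dataset):
        """DIC equals a brute-force recomputation looping over draws and
        respondents."""
        sub = dataclasses.replace(small_fit, samples=small_fit.samples.iloc[:40])
        dic, p_d, dbar = compute_dic(sub, tiny_dataset)

        A, C, U = sub.alpha_array(), sub.coef_array(), sub.u_array()
        ds = tiny_dataset
        devs = []
        for s in range(len(A)):
            total = 0.0
            for i in range(ds.n):
                eta = float(ds.D[i] @ C[s] + U[s][ds.city_index[i]])
                total += float(observation_log_probs(ds.y[i:i + 1], np.array([eta]), A[s])[0])
            devs.append(-2.0 * total)
        dbar_o = np.mean(devs)
        total = 0.0
        Cm, Um, Am = C.mean(0), U.mean(0), A.mean(0)
        for i in range(ds.n):
            eta = float(ds.D[i] @ Cm + Um[ds.city_index[i]])
            total += float(observation_log_probs(ds.y[i:i + 1], np.array([eta]), Am)[0])
        dhat_o = -2.0 * total
        assert dbar == pytest.approx(dbar_o, rel=1e-10)
        assert p_d == pytest.approx(dbar_o - dhat_o, rel=1e-8)
        assert dic == pytest.approx(2 * dbar_o - dhat_o, rel=1e-8)

    def test_mismatched_design_rejected(self, small_fit, tiny_survey):
        individuals, cities = tiny_survey
        other = Dataset.from_frames(individuals, cities, ah.default_ladder()["model2"])
        with pytest.raises(ValueError, match="design"):
            compute_dic(small_fit, other)


class TestVpc:
    @pytest.mark.parametrize("s2,expected", [
        (0.0, 0.0),
        (np.pi**2 / 3, 0.5),
        (0.113, 0.0332),
    ])
    def test_values(self, s2, expected):
        assert vpc(s2) == pytest.approx(expected, abs=5e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vpc(-0.1)


class TestEstimator:
    def test_sklearn_contract(self, tiny_survey):
        individuals, cities = tiny_survey
        est = HierarchicalOrdinalRegression(
            n_iterations=300, burn_in=150, thin=2, n_chains=2, random_state=0,
            transforms={"income_rmb": "log"},
        )
        params = est.get_params()
        assert params["n_iterations"] == 300
        est.set_params(n_iterations=400)
        assert est.n_iterations == 400
        est.set_params(n_iterations=300)

        est.fit(individuals, cities=cities)
        assert est.draws_.n_draws == 2 * 75
        assert est.dic_ > 0
        assert 0 <= est.vpc_ < 1
        probs = est.predict_proba(individuals.head(7), cities=cities)
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0)
        cats = est.predict(individuals.head(7), cities=cities)
        assert set(cats) <= set(range(1, 6))

    def test_unfitted_predict_raises(self):
        est = HierarchicalOrdinalRegression()
        with pytest.raises(AttributeError, match="not fitted"):
            est.predict_proba(pd.DataFrame())

    def test_draws_csv_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "draws.csv"
        small_fit.to_csv(path)
        back = PosteriorDraws.from_csv(path)
        assert back.x_names == small_fit.x_names
        assert back.z_names == small_fit.z_names
        assert back.n_categories == small_fit.n_categories
        np.testing.assert_allclose(back.alpha_array(), small_fit.alpha_array())
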