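import numpy as np
import pytest

import geoadditive as ga
from geoadditive.basis import rw2_penalty
from geoadditive.mcmc import _sample_gaussian_canonical


def test_config_invariants():
    assert ga.MCMCConfig().n_retained == 3000
    with pytest.raises(ValueError):
        ga.MCMCConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        ga.MCMCConfig(thin=0)
    with pytest.raises(ValueError):
        ga.MCMCConfig(augmentation="hmc")
    with pytest.raises(ValueError, match="fixed_variances"):
        ga.MCMCConfig(prior_only=True)


def test_variance_update_is_conjugate_inverse_gamma(rng):
    # matched-moments oracle: IG(a + d/2, b + s/2)
    a, b, d, s = 3.0, 2.0, 8.0, 5.0
    draws = np.array([ga.update_variance(s, d, (a, b), rng) for _ in range(20000)])
    shape, rate = a + d / 2, b + s / 2
    assert draws.mean() == pytest.approx(rate / (shape - 1), rel=0.03)
    direct = rate / rng.gamma(shape, size=20000)
    assert np.quantile(draws, 0.9) == pytest.approx(np.quantile(direct, 0.9), rel=0.05)


def test_variance_update_concentrates_for_large_dimension(rng):
    v = 0.37
    dim = 200000
    draw = ga.update_variance(dim * v, dim, (0.001, 0.001), rng)
    assert draw == pytest.approx(v, rel=0.02)


def test_variance_update_rejects_negative_sum_of_squares(rng):
    with pytest.raises(ValueError):
        ga.update_variance(-1.0, 3, (0.001, 0.001), rng)


def test_centering_moves_level_into_intercept():
    centred, intercept = ga.center_block(np.array([1.0, 1.0, 1.0]), 0.0)
    np.testing.assert_array_equal(centred, 0.0)
    assert intercept == 1.0


def test_centering_preserves_predictor_and_is_idempotent(rng):
    g = rng.normal(size=6)
    idx = rng.integers(0, 6, size=40)
    intercept = 0.7
    eta_before = intercept + g[idx]
    g2, i2 = ga.center_block(g, intercept)
    np.testing.assert_allclose(i2 + g2[idx], eta_before, atol=1e-12)
    g3, i3 = ga.center_block(g2, i2)
    np.testing.assert_allclose(g3, g2, atol=1e-14)
    assert i3 == pytest.approx(i2)


def test_weighted_centering_zeroes_the_weighted_mean(rng):
    theta = rng.normal(size=9)
    w = rng.dirichlet(np.ones(9))
    centred, _ = ga.center_block(theta, 0.0, weights=w)
    assert float(w @ centred) == pytest.approx(0.0, abs=1e-12)


def _quick_fit(df, graph, variant="M1", seed=5, n_iter=300, **kw):
    data = ga.ModelData(df, graph=graph)
    config = ga.MCMCConfig(n_iter=n_iter, burn_in=n_iter // 3, thin=2, seed=seed, **kw)
    return ga.run_mcmc(data, ga.ModelSpec(variant), config)


def test_chain_is_deterministic_given_seed(medium_sim):
    df = medium_sim.data.head(300)
    a = _quick_fit(df, medium_sim.graph, n_iter=120)
    b = _quick_fit(df, medium_sim.graph, n_iter=120)
    for k in a.draws:
        np.testing.assert_array_equal(a.draws[k], b.draws[k])
    c = _quick_fit(df, medium_sim.graph, n_iter=120, seed=6)
    assert not np.array_equal(a.draws["beta"], c.draws["beta"])


def test_fit_invariants_hold(medium_sim):
    fit = _quick_fit(medium_sim.data.head(600), medium_sim.graph, "M6", n_iter=240)
    assert fit.n_retained == fit.config.n_retained
    assert np.isfinite(fit.draws["deviance"]).all()
    for v in ("sigma2_spline", "delta", "tau2"):
        assert (fit.draws[v] > 0).all()
    # g and h recentred every retained iteration
    for blk in ("g", "h"):
        means = fit.draws[blk].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-8)


def test_single_region_spatial_model_rejected(medium_sim):
    df = medium_sim.data[medium_sim.data["region"] == "Dhaka"].head(100)
    g = ga.make_region_graph((["Dhaka"], []))
    data = ga.ModelData(df, graph=g)
    with pytest.raises(ValueError, match="at least two regions"):
        ga.run_mcmc(data, ga.ModelSpec("M3"), ga.MCMCConfig(n_iter=20, burn_in=2))


def test_strong_coefficient_recovered_in_sign_and_size(graph8):
    cfg = ga.GeneratorConfig(
        n_records=1500, seed=31,
        true_linear_effects={"underweight": {"working:Yes": 1.2}},
    )
    sim = ga.simulate_dataset(cfg)
    fit = _quick_fit(sim.data, sim.graph, "M1", n_iter=600)
    s = ga.summarize_effects(fit)
    row = s[(s.category == "underweight") & (s.parameter == "working:Yes")].iloc[0]
    assert row.significant
    assert 0.8 < row["mean"] < 1.6


def test_category_update_order_does_not_change_inference(medium_sim):
    df = medium_sim.data.head(900)
    a = _quick_fit(df, medium_sim.graph, "M1", n_iter=700, seed=9)
    b = _quick_fit(df, medium_sim.graph, "M1", n_iter=700, seed=9,
                   category_order=(1, 0))
    sa = ga.summarize_effects(a)
    sb = ga.summarize_effects(b)
    m = sa.merge(sb, on=["category", "parameter"], suffixes=("_a", "_b"))
    overlap = (m.ci_lower_a <= m.ci_upper_b) & (m.ci_lower_b <= m.ci_upper_a)
    assert overlap.all()


def test_deviance_trace_has_no_trend_after_burn_in(medium_sim):
    fit = _quick_fit(medium_sim.data, medium_sim.graph, "M1", n_iter=900, seed=13)
    dev = fit.draws["deviance"]
    t = np.arange(dev.size, dtype=float)
    slope, intercept = np.polyfit(t, dev, 1)
    resid = dev - (slope * t + intercept)
    se = np.sqrt(resid.var(ddof=2) / ((t - t.mean()) ** 2).sum())
    assert abs(slope) < 3 * se


def test_singular_canonical_sampler_pins_null_space(rng):
    k = rw2_penalty(7)
    draws = np.array(
        [_sample_gaussian_canonical(k, np.zeros(7), rng, singular_ok=True)
         for _ in range(200)]
    )
    ones = np.ones(7) / np.sqrt(7)
    trend = np.arange(7) - 3.0
    trend /= np.linalg.norm(trend)
    np.testing.assert_allclose(draws @ ones, 0.0, atol=1e-10)
    np.testing.assert_allclose(draws @ trend, 0.0, atol=1e-10)
    assert draws.std() > 0


def test_estimation_error_and_bands_shrink_with_sample_size():
    """Posterior RMSE of the linear effects and the width of the smooth
    effect's credible band both decrease as the sample grows."""
    truth = ga.default_true_linear_effects()
    rmse = {}
    band = {}
    for n in (1000, 4000):
        errs = []
        widths = []
        for rep in range(2):
            cfg = ga.GeneratorConfig(
                n_records=n, seed=700 + rep,
                true_linear_effects=truth,
                true_smooth_functions=ga.default_true_smooth_functions(),
            )
            sim = ga.simulate_dataset(cfg)
            data = ga.ModelData(sim.data, graph=sim.graph)
            fit = ga.run_mcmc(
                data, ga.ModelSpec("M2"),
                ga.MCMCConfig(n_iter=1200, burn_in=400, thin=2, seed=800 + rep),
            )
            s = ga.summarize_effects(fit)
            lin = s[(s.block == "linear") & (s.parameter != "intercept")]
            errs.extend(
                (row["mean"] - truth[row.category][row.parameter]) ** 2
                for _, row in lin.iterrows()
            )
            curves = ga.export_nonlinear_effect(fit)
            widths.append(float((curves.ci_upper - curves.ci_lower).mean()))
        rmse[n] = float(np.sqrt(np.mean(errs)))
        band[n] = float(np.mean(widths))
    assert rmse[4000] < rmse[1000]
    assert band[4000] < band[1000]
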