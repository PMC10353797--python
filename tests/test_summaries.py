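import numpy as np
import pandas as pd
import pytest

import geoadditive as ga
from geoadditive.mcmc import PosteriorFit
from geoadditive.model import empty_params
from geoadditive.summaries import DIC_SIMILARITY_THRESHOLD, dic_from_components


def _fake_fit(small_m1_fit, beta_draws):
    """Clone a real fit but replace the beta draws (shape (S, 2, p))."""
    draws = {k: v.copy() for k, v in small_m1_fit.draws.items()}
    draws["beta"] = beta_draws
    return PosteriorFit(
        spec=small_m1_fit.spec,
        config=small_m1_fit.config,
        data=small_m1_fit.data,
        draws=draws,
        categories=small_m1_fit.categories,
    )


def test_dic_is_sum_of_fit_and_complexity(small_m1_fit):
    res = ga.compute_dic(small_m1_fit)
    assert res.dic == pytest.approx(res.mean_deviance + res.effective_parameters, abs=1e-9)


def test_degenerate_chain_has_zero_effective_parameters(small_m1_fit):
    data, spec = small_m1_fit.data, small_m1_fit.spec
    params = empty_params(spec, data)
    params["beta"][:, 0] = (0.3, -0.2)
    const_dev = ga.deviance(data, spec, params)
    s = small_m1_fit.n_retained
    beta = np.broadcast_to(params["beta"], (s,) + params["beta"].shape).copy()
    fit = _fake_fit(small_m1_fit, beta)
    fit.draws["deviance"] = np.full(s, const_dev)
    res = ga.compute_dic(fit)
    assert res.effective_parameters == pytest.approx(0.0, abs=1e-9)
    assert res.dic == pytest.approx(const_dev, abs=1e-9)


def test_effective_parameters_near_free_coefficient_count(small_m1_fit):
    res = ga.compute_dic(small_m1_fit)
    n_free = small_m1_fit.draws["beta"].shape[1] * small_m1_fit.draws["beta"].shape[2]
    assert 0 < res.effective_parameters < 2 * n_free


def test_dic_needs_at_least_two_draws(small_m1_fit):
    crippled = _fake_fit(small_m1_fit, small_m1_fit.draws["beta"][:1])
    crippled.draws["deviance"] = crippled.draws["deviance"][:1]
    with pytest.raises(ValueError, match="retained draws"):
        ga.compute_dic(crippled)


def test_comparison_differences_and_similarity_flags():
    results = [
        dic_from_components("M1", 95.0, 5.0),    # dic 100
        dic_from_components("M2", 100.0, 3.0),   # dic 103
        dic_from_components("M3", 110.0, 10.0),  # dic 120
    ]
    table = ga.compare_models(results, reference="M3")
    assert table.loc[table.model == "M3", "dic_difference"].iloc[0] == 0.0
    assert table.loc[table.model == "M1", "dic_difference"].iloc[0] == pytest.approx(-20.0)
    assert table["similar_to_best"].tolist() == [True, True, False]
    assert DIC_SIMILARITY_THRESHOLD == 5.0


def test_comparison_rejects_duplicates_and_unknown_reference():
    r = [dic_from_components("M1", 10, 1), dic_from_components("M1", 11, 1)]
    with pytest.raises(ValueError, match="duplicate"):
        ga.compare_models(r)
    with pytest.raises(ValueError, match="reference"):
        ga.compare_models([dic_from_components("M1", 10, 1)], reference="M9")


def test_constant_draws_summarize_to_point_interval(small_m1_fit):
    s = small_m1_fit.n_retained
    p = small_m1_fit.draws["beta"].shape[2]
    beta = np.full((s, 2, p), 0.4)
    summary = ga.summarize_effects(_fake_fit(small_m1_fit, beta))
    lin = summary[summary.block == "linear"]
    np.testing.assert_allclose(lin["mean"], 0.4, atol=1e-12)
    np.testing.assert_allclose(lin["ci_lower"], 0.4, atol=1e-12)
    np.testing.assert_allclose(lin["ci_upper"], 0.4, atol=1e-12)
    assert lin["significant"].all()


def test_draws_symmetric_about_zero_are_not_significant(small_m1_fit, rng):
    s = small_m1_fit.n_retained
    p = small_m1_fit.draws["beta"].shape[2]
    half = rng.normal(0.0, 1.0, size=(s // 2, 2, p))
    beta = np.concatenate([half, -half])[:s]
    summary = ga.summarize_effects(_fake_fit(small_m1_fit, beta))
    assert not summary[summary.block == "linear"]["significant"].any()


def test_interval_endpoints_match_normal_quantiles(small_m1_fit, rng):
    draws = rng.standard_normal(10000)
    beta = np.tile(draws[:, None, None], (1, 2, small_m1_fit.draws["beta"].shape[2]))
    fit = _fake_fit(small_m1_fit, beta)
    fit.draws["deviance"] = np.resize(fit.draws["deviance"], 10000)
    for name in ("sigma2_spline", "delta", "tau2"):
        fit.draws.pop(name, None)
    summary = ga.summarize_effects(fit)
    row = summary.iloc[0]
    assert row.ci_lower == pytest.approx(-1.96, abs=0.05)
    assert row.ci_upper == pytest.approx(1.96, abs=0.05)


def test_spatial_export_shape_and_significance_codes(medium_sim):
    data = ga.ModelData(medium_sim.data, graph=medium_sim.graph)
    fit = ga.run_mcmc(
        data, ga.ModelSpec("M3"),
        ga.MCMCConfig(n_iter=300, burn_in=100, thin=2, seed=2),
    )
    table = ga.export_spatial_effects(fit)
    r = medium_sim.graph.n_regions
    assert len(table) == 2 * 2 * r  # two blocks x two categories x regions
    assert set(table["significance"]) <= {"+", "0", "-"}
    sig_pos = table[table.significance == "+"]
    assert (sig_pos["ci_lower"] > 0).all()


def test_spatial_export_requires_spatial_block(small_m1_fit):
    with pytest.raises(ValueError, match="no spatial block"):
        ga.export_spatial_effects(small_m1_fit)


def test_nonlinear_export_band_and_centering(medium_sim):
    data = ga.ModelData(medium_sim.data, graph=medium_sim.graph)
    fit = ga.run_mcmc(
        data, ga.ModelSpec("M2"),
        ga.MCMCConfig(n_iter=400, burn_in=150, thin=2, seed=3),
    )
    curves = ga.export_nonlinear_effect(fit)
    assert (curves["ci_lower"] <= curves["mean"]).all()
    assert (curves["mean"] <= curves["ci_upper"]).all()
    # centering contract: the posterior-mean curve averages to ~0 over the
    # sample ages (design-weighted centering)
    sample_curve = data.b_spline @ fit.draws["theta"].mean(axis=0).T
    assert abs(sample_curve.mean(axis=0)).max() < 1e-6
    with pytest.raises(ValueError, match="outside spline range"):
        ga.export_nonlinear_effect(fit, grid=[10.0])


def test_nonlinear_export_requires_spline(small_m1_fit):
    with pytest.raises(ValueError, match="no smooth age effect"):
        ga.export_nonlinear_effect(small_m1_fit)


def test_few_draws_warns(small_m1_fit):
    crippled = _fake_fit(small_m1_fit, small_m1_fit.draws["beta"][:50])
    for k in list(crippled.draws):
        crippled.draws[k] = crippled.draws[k][:50]
    with pytest.warns(UserWarning, match="retained draws"):
        ga.summarize_effects(crippled)
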