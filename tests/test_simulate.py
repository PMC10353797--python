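import numpy as np
import pytest

import geoadditive as ga


def test_same_seed_gives_byte_identical_datasets():
    cfg = ga.GeneratorConfig(n_records=500, seed=77, structured_truth_delta=0.15)
    a = ga.simulate_dataset(cfg)
    b = ga.simulate_dataset(cfg)
    assert a.data.to_csv(index=False) == b.data.to_csv(index=False)
    for cat in a.truth["structured"]:
        np.testing.assert_array_equal(a.truth["structured"][cat], b.truth["structured"][cat])


def test_different_seeds_differ():
    a = ga.simulate_dataset(ga.GeneratorConfig(n_records=500, seed=1))
    b = ga.simulate_dataset(ga.GeneratorConfig(n_records=500, seed=2))
    assert not a.data.equals(b.data)


def test_null_effects_give_uniform_outcome_frequencies():
    n = 30000
    sim = ga.simulate_dataset(ga.GeneratorConfig(n_records=n, seed=5))
    freqs = sim.data["nutrition_category"].value_counts(normalize=True)
    se = np.sqrt((1 / 3) * (2 / 3) / n)
    for cat in ("underweight", "normal", "overweight_obese"):
        assert abs(freqs[cat] - 1 / 3) < 3 * se


def test_single_logit_coefficient_recovered_from_empirical_log_odds():
    """With one nonzero effect the generator's empirical log-odds invert to it."""
    n = 50000
    beta = 0.64
    cfg = ga.GeneratorConfig(
        n_records=n,
        seed=99,
        true_linear_effects={"overweight_obese": {"wealth:Richest": beta}},
    )
    df = ga.simulate_dataset(cfg).data
    rich = df["wealth"] == "Richest"
    counts = np.array(
        [
            [
                ((df["nutrition_category"] == "overweight_obese") & m).sum(),
                ((df["nutrition_category"] == "normal") & m).sum(),
            ]
            for m in (rich, ~rich)
        ],
        dtype=float,
    )
    log_odds_diff = np.log(counts[0, 0] / counts[0, 1]) - np.log(
        counts[1, 0] / counts[1, 1]
    )
    se = np.sqrt((1.0 / counts).sum())
    assert abs(log_odds_diff - beta) < 3 * se


def test_mean_category_probabilities_match_enumeration_oracle():
    """Empirical frequencies converge to the analytic average of P[y=r]
    computed by brute-force enumeration over the discrete covariate grid."""
    marginals = {
        "wealth": {"Poorest": 0.6, "Richest": 0.4},
        "working": {"No": 0.5, "Yes": 0.5},
    }
    effects = {
        "underweight": {"intercept": -0.4, "wealth:Richest": -0.5},
        "overweight_obese": {"intercept": 0.2, "wealth:Richest": 0.7, "working:Yes": -0.3},
    }
    expected = np.zeros(3)
    for wl, wp in marginals["wealth"].items():
        for kl, kp in marginals["working"].items():
            eta = np.zeros(2)
            for j, cat in enumerate(("underweight", "overweight_obese")):
                eta[j] = effects[cat].get("intercept", 0.0)
                eta[j] += effects[cat].get(f"wealth:{wl}", 0.0)
                eta[j] += effects[cat].get(f"working:{kl}", 0.0)
            expected += wp * kp * ga.multinomial_probs(eta)
    n = 50000
    sim = ga.simulate_dataset(
        ga.GeneratorConfig(
            n_records=n, seed=12, category_marginals=marginals,
            true_linear_effects=effects,
        )
    )
    freqs = sim.data["nutrition_category"].value_counts(normalize=True)
    for p_exp, cat in zip(expected, ("underweight", "overweight_obese", "normal")):
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(freqs[cat] - p_exp) < 3 * se


def test_covariate_marginals_are_respected():
    n = 40000
    sim = ga.simulate_dataset(ga.GeneratorConfig(n_records=n, seed=21, year=2014))
    want = ga.default_table1_marginals(2014)
    got = sim.data["residence"].value_counts(normalize=True)
    for level, p in want["residence"].items():
        assert abs(got[level] - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="n_records"):
        ga.GeneratorConfig(n_records=0).validate()
    with pytest.raises(ValueError, match="age_range"):
        ga.GeneratorConfig(age_range=(10.0, 49.0)).validate()
    with pytest.raises(ValueError, match="probability"):
        ga.GeneratorConfig(
            category_marginals={"wealth": {"Poorest": 0.7, "Richest": 0.2}}
        ).validate()
    with pytest.raises(ValueError, match="one entry per region"):
        ga.GeneratorConfig(
            true_structured_effects={"underweight": [0.1, 0.2]}
        ).validate()


def test_drawn_spatial_truth_is_recorded_and_centred(graph8):
    sim = ga.simulate_dataset(
        ga.GeneratorConfig(n_records=50, seed=4, structured_truth_delta=0.2,
                           unstructured_truth_tau2=0.05)
    )
    side = sim.truth_sidecar()
    assert set(side.columns) == {
        "region", "s_underweight", "s_overweight_obese",
        "u_underweight", "u_overweight_obese",
    }
    for cat in ("underweight", "overweight_obese"):
        assert sim.truth["structured"][cat].mean() == pytest.approx(0.0, abs=1e-10)
        assert len(sim.truth["structured"][cat]) == graph8.n_regions


def test_debug_probabilities_are_valid_and_reflect_truth():
    cfg = ga.GeneratorConfig(
        n_records=200, seed=6,
        true_linear_effects={"underweight": {"intercept": 1.5}},
    )
    df = ga.simulate_dataset(cfg, debug_probs=True).data
    psum = df[["prob_underweight", "prob_overweight_obese", "prob_normal"]].sum(axis=1)
    np.testing.assert_allclose(psum, 1.0, atol=1e-12)
    assert (df["prob_underweight"] > df["prob_normal"]).all()


def test_ages_stay_in_range():
    df = ga.simulate_dataset(ga.GeneratorConfig(n_records=2000, seed=2)).data
    assert df["age"].between(15, 49).all()


def test_published_marginals_match_printed_shares():
    res = ga.default_table1_marginals(2014)["residence"]
    np.testing.assert_allclose(
        list(res.values()), [0.1188, 0.2256, 0.6556], atol=5e-5
    )
    assert list(res) == ["City Corporation", "Other Urban", "Rural"]
    work = ga.default_table1_marginals(2018)["working"]
    np.testing.assert_allclose(list(work.values()), [0.4886, 0.5114], atol=5e-5)
    for year in (2014, 2018):
        for var, probs in ga.default_table1_marginals(year, include_outcome=True).items():
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError, match="unsupported survey year"):
        ga.default_table1_marginals(2016)
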