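import numpy as np
import pandas as pd
import pytest
from greenwalk.glmm import fit_logistic_ri
from greenwalk.outcomes import (
    GeneratingModel,
    MAIN_SAMPLE_MARGINS,
    Table1Margins,
    WALKER_SAMPLE_MARGINS,
    minutes_from_standardized,
    reference_posthoc_walk_model,
    reference_time_model,
    reference_walk_model,
    sigma_u_for_icc,
    simulate_cohort,
    simulate_walk_decision,
    simulate_walk_time,
)


def test_margins_are_valid_probabilities():
    for m in (MAIN_SAMPLE_MARGINS, WALKER_SAMPLE_MARGINS):
        m.validate()
    with pytest.raises(ValueError):
        Table1Margins(age=(0.5, 0.5, 0.2, 0.0), gender=(0.5, 0.5), income=(1, 0, 0, 0)).validate()


def test_cohort_matches_reference_composition(city):
    n = 20000
    cohort = simulate_cohort(city, n, MAIN_SAMPLE_MARGINS, seed=1)
    assert len(cohort) == n
    share_young = (cohort["age_band"] == "5-17").mean()
    share_female = (cohort["gender"] == "female").mean()
    assert share_young == pytest.approx(0.152, abs=0.01)
    assert share_female == pytest.approx(0.519, abs=0.01)


def test_degenerate_margins_give_homogeneous_cohort(city):
    m = Table1Margins(age=(0, 1, 0, 0), gender=(1, 0), income=(0, 0, 0, 1))
    cohort = simulate_cohort(city, 200, m, seed=2)
    assert (cohort["age_band"] == "18-44").all()
    assert (cohort["gender"] == "male").all()
    assert (cohort["income_band"] == "high").all()


def test_walker_margins_skew_female_and_elderly():
    # the walkers' subsample is known to oversample women and the elderly
    assert WALKER_SAMPLE_MARGINS.gender[1] > MAIN_SAMPLE_MARGINS.gender[1]
    assert WALKER_SAMPLE_MARGINS.age[3] > MAIN_SAMPLE_MARGINS.age[3]


def test_null_model_gives_half_walking_rate():
    n = 40000
    design = pd.DataFrame({"z": np.random.default_rng(0).normal(size=n)})
    gm = GeneratingModel(intercept=0.0, coefs={"z": 0.0}, sigma_u=0.0)
    y = simulate_walk_decision(design, np.zeros(n, dtype=int), gm, seed=3)
    assert y.mean() == pytest.approx(0.5, abs=0.01)


def test_no_block_variance_means_binomial_noise_only():
    """With sigma_u = 0 the between-block spread of block rates is what pure
    binomial sampling predicts; with sigma_u large it is far bigger."""
    rng = np.random.default_rng(4)
    n, J, m = 20000, 100, 200
    blocks = np.repeat(np.arange(J), m)
    design = pd.DataFrame({"z": np.zeros(n)})
    rates = lambda y: np.array([y[blocks == j].mean() for j in range(J)])
    y0 = simulate_walk_decision(design, blocks, GeneratingModel(0.0, {"z": 0.0}, sigma_u=0.0), seed=5)
    y1 = simulate_walk_decision(design, blocks, GeneratingModel(0.0, {"z": 0.0}, sigma_u=1.0), seed=5)
    var0 = rates(y0).var(ddof=1)
    binom_var = 0.5 * 0.5 / m
    assert var0 == pytest.approx(binom_var, rel=0.4)
    assert rates(y1).var(ddof=1) > 4 * var0


def test_walk_decision_slope_recovers_generating_odds_ratio():
    rng = np.random.default_rng(6)
    n = 60000
    z = rng.normal(size=n)
    design = pd.DataFrame({"gvi": z})
    gm = GeneratingModel(0.0, {"gvi": float(np.log(1.149))}, sigma_u=0.0)
    y = simulate_walk_decision(design, np.zeros(n, dtype=int), gm, seed=7)
    X = np.column_stack([np.ones(n), z])
    fit = fit_logistic_ri(X, y, np.zeros(n, dtype=int), sigma_fixed=0.0)
    assert np.exp(fit.params.iloc[1]) == pytest.approx(1.149, abs=0.03)


def test_missing_predictor_is_reported():
    design = pd.DataFrame({"a": [0.0, 1.0]})
    gm = GeneratingModel(0.0, {"a": 0.1, "b": 0.2})
    with pytest.raises(ValueError, match="b"):
        simulate_walk_decision(design, [0, 1], gm, seed=0)


def test_walk_time_degenerate_and_scaling():
    n = 5000
    design = pd.DataFrame({"z": np.random.default_rng(8).normal(size=n)})
    blocks = np.zeros(n, dtype=int)
    const = simulate_walk_time(design, blocks, GeneratingModel(0.3, {"z": 0.0}, sigma_b=0.0, sigma_e=0.0), seed=9)
    assert np.allclose(const, 0.3)
    y1 = simulate_walk_time(design, blocks, GeneratingModel(0.0, {"z": 0.0}, sigma_b=0.0, sigma_e=1.0), seed=9)
    y2 = simulate_walk_time(design, blocks, GeneratingModel(0.0, {"z": 0.0}, sigma_b=0.0, sigma_e=2.0), seed=9)
    assert y2.std() == pytest.approx(2 * y1.std(), rel=1e-9)


def test_walk_time_slope_recovers_generating_beta():
    rng = np.random.default_rng(10)
    n = 50000
    z = rng.normal(size=n)
    design = pd.DataFrame({"gvi": z})
    gm = GeneratingModel(0.0, {"gvi": 0.233}, sigma_b=0.0, sigma_e=0.9)
    y = simulate_walk_time(design, np.zeros(n, dtype=int), gm, seed=11)
    slope = np.polyfit(z, y, 1)[0]
    assert slope == pytest.approx(0.233, abs=0.02)


def test_minutes_back_transform_floors_and_counts():
    minutes, n_floored = minutes_from_standardized(np.array([-10.0, 0.0, 1.0]), mean=60, sd=30)
    assert minutes[0] == 1.0 and n_floored == 1
    assert minutes[1] == 60.0 and minutes[2] == 90.0


def test_reference_models_encode_published_effects():
    gm4 = reference_walk_model(400)
    assert np.exp(gm4.coefs["gvi"]) == pytest.approx(1.149)
    assert np.exp(gm4.coefs["female"]) == pytest.approx(1.585)
    gm8 = reference_time_model(800)
    assert gm8.coefs["gvi"] == 0.233
    icc = gm8.sigma_b**2 / (gm8.sigma_b**2 + gm8.sigma_e**2)
    assert icc == pytest.approx(0.160)


def test_posthoc_model_reproduces_stratified_slopes():
    gm = reference_posthoc_walk_model(800)
    female = np.exp(gm.coefs["gvi"] + 0.5 * gm.coefs["gvi_x_gender"])
    male = np.exp(gm.coefs["gvi"] - 0.5 * gm.coefs["gvi_x_gender"])
    assert female == pytest.approx(1.235)
    assert male == pytest.approx(1.181)


def test_sigma_u_for_icc_roundtrip():
    from greenwalk.glmm import LOGISTIC_LATENT_VAR

    s = sigma_u_for_icc(0.079)
    assert s**2 / (s**2 + LOGISTIC_LATENT_VAR) == pytest.approx(0.079)
    with pytest.raises(ValueError):
        sigma_u_for_icc(1.5)


def test_simulation_reproducible_and_seed_sensitive(city):
    cohort = simulate_cohort(city, 500, MAIN_SAMPLE_MARGINS, seed=12)
    design = pd.DataFrame({"z": np.random.default_rng(1).normal(size=500)})
    gm = GeneratingModel(0.0, {"z": 0.3}, sigma_u=0.5)
    y_a = simulate_walk_decision(design, cohort["block_id"], gm, seed=13)
    y_b = simulate_walk_decision(design, cohort["block_id"], gm, seed=13)
    y_c = simulate_walk_decision(design, cohort["block_id"], gm, seed=14)
    assert np.array_equal(y_a, y_b)
    assert not np.array_equal(y_a, y_c)
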