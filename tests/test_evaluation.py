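import numpy as np
import pytest

from franklin.evaluation import (
    classify_extremes,
    compute_fit_metrics,
    decile_dispersion,
    dispersion_decomposition,
    downsampled_ttest,
    percentile_ranks,
    prediction_error_frequencies,
    residual_dispersion_factor,
    simulate_plan_pr_variance,
    structural_dispersion_factor,
    subgroup_evaluate,
)

from oracles import (
    confusion_oracle,
    ks_oracle,
    percentile_error_oracle,
    quantile_oracle,
    spearman_oracle,
)


def test_identity_predictions_are_perfect():
    obs = np.array([100.0, 250.0, 900.0, 40.0, 3000.0])
    m = compute_fit_metrics(obs.copy(), obs)
    assert m.r2_log == pytest.approx(1.0)
    assert m.r2_cost == pytest.approx(1.0)
    assert m.mae_cost == pytest.approx(0.0)
    assert m.spearman_rho == pytest.approx(1.0)
    assert m.ks_log == pytest.approx(0.0)


def test_reversed_predictions_have_spearman_minus_one():
    obs = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    m = compute_fit_metrics(obs[::-1].copy(), obs)
    assert m.spearman_rho == pytest.approx(-1.0)


def test_fit_metrics_validation():
    with pytest.raises(ValueError, match="length"):
        compute_fit_metrics(np.ones(4), np.ones(5))
    with pytest.raises(ValueError, match="at least 3"):
        compute_fit_metrics(np.ones(2), np.ones(2))


def test_spearman_and_ks_match_exhaustive_oracles():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(3, 9)
        # mix of continuous values and deliberate ties
        pred = rng.choice([1.0, 2.0, 3.5, 7.25, 11.0], size=n)
        obs = rng.normal(size=n).round(1)
        if np.all(pred == pred[0]) or np.all(obs == obs[0]):
            continue
        m = compute_fit_metrics(
            pred, np.abs(obs) + 1.0, predicted_log=np.log(pred + 1.0)
        )
        assert m.spearman_rho == pytest.approx(
            spearman_oracle(list(pred), list(np.abs(obs) + 1.0)), abs=1e-12
        )
        assert m.ks_log == pytest.approx(
            ks_oracle(list(np.log(pred + 1.0)), list(np.log(np.abs(obs) + 2.0))),
            abs=1e-12,
        )


def test_perfect_ranking_classifies_tails_perfectly():
    rng = np.random.default_rng(1)
    obs = np.exp(rng.normal(8, 1, 200))
    for tail in ("low", "high"):
        m = classify_extremes(obs * 2.0, obs, q=0.2, tail=tail)
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.precision == 1.0


def test_independent_predictions_have_sensitivity_near_q():
    rng = np.random.default_rng(2)
    obs = np.exp(rng.normal(8, 1, 20_000))
    pred = np.exp(rng.normal(8, 1, 20_000))
    m = classify_extremes(pred, obs, q=0.2, tail="low")
    assert m.sensitivity == pytest.approx(0.2, abs=0.02)


def test_confusion_counts_match_enumeration_on_toys():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = rng.integers(5, 13)
        pred = rng.normal(size=n)
        obs = rng.normal(size=n)
        for tail in ("low", "high"):
            m = classify_extremes(pred, obs, q=0.2, tail=tail)
            o = confusion_oracle(list(pred), list(obs), 0.2, tail)
            assert (m.tp, m.fp, m.fn, m.tn) == (o["tp"], o["fp"], o["fn"], o["tn"])


def test_sensitivity_equals_precision_by_construction():
    rng = np.random.default_rng(4)
    pred = rng.normal(size=500)
    obs = rng.normal(size=500)
    m = classify_extremes(pred, obs, q=0.2, tail="high")
    assert m.sensitivity == pytest.approx(m.precision)


def test_classify_rejects_bad_quantiles():
    with pytest.raises(ValueError, match="q must"):
        classify_extremes(np.ones(10), np.ones(10), q=0.7)
    with pytest.raises(ValueError, match="tail"):
        classify_extremes(np.ones(10), np.ones(10), q=0.2, tail="middle")


def test_error_frequencies_identity_and_monotone():
    rng = np.random.default_rng(5)
    obs = np.exp(rng.normal(8, 1, 300))
    e = prediction_error_frequencies(obs.copy(), obs)
    assert e.overprediction == (0.0, 0.0)
    assert e.underprediction == (0.0, 0.0)

    pred = np.exp(rng.normal(8, 1, 300))
    e2 = prediction_error_frequencies(pred, obs, thresholds=(20.0, 40.0))
    assert e2.overprediction[1] <= e2.overprediction[0]
    assert e2.underprediction[1] <= e2.underprediction[0]
    curve = e2.curve
    assert np.all(np.diff(curve["overprediction"]) <= 1e-12)


def test_error_frequencies_match_enumeration():
    rng = np.random.default_rng(6)
    for _ in range(60):
        n = rng.integers(4, 13)
        pred = rng.choice([1.0, 2.0, 5.0, 9.0], size=n)
        obs = rng.normal(size=n)
        e = prediction_error_frequencies(pred, obs, thresholds=(20.0,))
        over, under = percentile_error_oracle(list(pred), list(obs), 20.0)
        assert e.overprediction[0] == pytest.approx(over)
        assert e.underprediction[0] == pytest.approx(under)


def test_percentile_ranks_average_ties():
    r = percentile_ranks(np.array([1.0, 1.0, 2.0, 3.0]))
    assert r == pytest.approx([37.5, 37.5, 75.0, 100.0])


def test_decile_dispersion_identities():
    rng = np.random.default_rng(7)
    obs = np.full(1000, 500.0)
    d = decile_dispersion(rng.normal(1000, 10, 1000), obs, n_boot=20, seed=0)
    assert np.allclose(d.table["iqr"], 0.0)
    assert np.allclose(d.table["decile_range"], 0.0)

    obs2 = np.exp(rng.normal(8, 1, 1000))
    d2 = decile_dispersion(obs2.copy(), obs2, n_boot=20, seed=0)
    assert np.allclose(d2.table["pr"], 1.0)


def test_decile_iqr_matches_quantile_oracle():
    rng = np.random.default_rng(8)
    pred = np.exp(rng.normal(8, 1, 1000))
    obs = np.exp(rng.normal(8, 1, 1000))
    d = decile_dispersion(pred, obs, n_boot=10, seed=0)
    order = np.argsort(pred, kind="stable")
    for dec, g in enumerate(np.array_split(order, 10)):
        vals = list(obs[g])
        iqr = quantile_oracle(vals, 0.75) - quantile_oracle(vals, 0.25)
        drange = quantile_oracle(vals, 0.90) - quantile_oracle(vals, 0.10)
        assert d.table["iqr"][dec] == pytest.approx(iqr)
        assert d.table["decile_range"][dec] == pytest.approx(drange)
        assert d.table["iqr"][dec] <= d.table["decile_range"][dec]


def test_dispersion_decomposition_closed_forms():
    assert structural_dispersion_factor(0.0) == 1.0
    assert residual_dispersion_factor(1.0, 1.0) == 0.0
    assert residual_dispersion_factor(1.0, 0.0) == pytest.approx(np.e - 1.0)
    # sigma = 0: constant observed costs
    d = dispersion_decomposition(np.full(50, 100.0), r2_log=0.3)
    assert d.structural_factor == 1.0
    assert d.residual_factor == 0.0


def test_dispersion_decomposition_from_sample():
    rng = np.random.default_rng(9)
    obs = np.exp(rng.normal(8, 1.2, 5000))
    d = dispersion_decomposition(obs, r2_log=0.44, offset=0.0)
    assert d.sigma == pytest.approx(1.2, abs=0.05)
    assert d.structural_factor == pytest.approx(np.exp(d.sigma**2 / 2))
    assert d.residual_factor == pytest.approx(np.exp(0.56 * d.sigma**2) - 1)


def test_plan_pr_variance_ratio_tracks_residual_factors():
    out = simulate_plan_pr_variance(
        sigma=1.2, r2_values=(0.15, 0.44), plan_size=500, n_plans=800, seed=0
    )
    r = out["ratios"][(0.15, 0.44)]
    assert r["empirical"] == pytest.approx(r["predicted"], rel=0.25)
    # better model -> smaller PR variance
    assert out["pr_variance"][0.44] < out["pr_variance"][0.15]


def test_plan_pr_variance_scales_inversely_with_plan_size():
    a = simulate_plan_pr_variance(1.0, (0.3,), plan_size=500, n_plans=1500, seed=1)
    b = simulate_plan_pr_variance(1.0, (0.3,), plan_size=1000, n_plans=1500, seed=1)
    ratio = a["pr_variance"][0.3] / b["pr_variance"][0.3]
    assert ratio == pytest.approx(2.0, rel=0.3)


def test_downsampled_ttest_degenerate_and_separating():
    rng = np.random.default_rng(10)
    obs = np.exp(rng.normal(8, 1, 10_000))
    same = downsampled_ttest("spearman", obs * 2, obs * 2, obs, seed=0)
    assert same.p_value == 1.0
    assert same.t_statistic == 0.0

    random_pred = np.exp(rng.normal(8, 1, 10_000))
    sep = downsampled_ttest("spearman", obs * 1.5, random_pred, obs, seed=0)
    assert sep.p_value < 0.001
    again = downsampled_ttest("spearman", obs * 1.5, random_pred, obs, seed=0)
    assert again.p_value == sep.p_value  # seed determinism


def test_downsampled_ttest_validates_cohort_size():
    with pytest.raises(ValueError, match="at least"):
        downsampled_ttest("spearman", np.ones(50), np.ones(50), np.ones(50))


def test_subgroup_table_matches_overall_and_flags_small_levels():
    rng = np.random.default_rng(11)
    obs = np.exp(rng.normal(8, 1, 400))
    pred = obs * np.exp(rng.normal(0, 0.3, 400))
    one_level = subgroup_evaluate(pred, obs, ["all"] * 400)
    overall = compute_fit_metrics(pred, obs)
    assert one_level.loc[0, "r2_log"] == pytest.approx(overall.r2_log)
    assert one_level.loc[0, "share"] == 1.0

    # identical data in two levels -> identical metrics
    labels = ["a"] * 200 + ["b"] * 200
    both = subgroup_evaluate(np.tile(pred[:200], 2), np.tile(obs[:200], 2), labels)
    assert both.loc[0, "spearman_rho"] == pytest.approx(both.loc[1, "spearman_rho"])

    small = subgroup_evaluate(pred, obs, ["big"] * 390 + ["tiny"] * 10)
    assert bool(small.set_index("level").loc["tiny", "below_min_size"]) is True


def test_high_noise_subgroup_has_larger_mae():
    rng = np.random.default_rng(12)
    mu = rng.normal(8, 0.5, 1000)
    sd = np.where(np.arange(1000) < 500, 0.3, 1.5)
    obs = np.exp(mu + rng.normal(0, 1, 1000) * sd)
    pred = np.exp(mu)
    labels = np.where(np.arange(1000) < 500, "low_sigma", "high_sigma")
    table = subgroup_evaluate(pred, obs, labels).set_index("level")
    direct_low = np.mean(np.abs(pred[:500] - obs[:500]))
    assert table.loc["low_sigma", "mae_cost"] == pytest.approx(direct_low)
    assert table.loc["high_sigma", "mae_cost"] > table.loc["low_sigma", "mae_cost"]
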