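import numpy as np
import pandas as pd
import pytest

from patsteps.condition_effects import (
    FitError,
    _marginal_mean_vector,
    contrast_tests,
    fit_zinb,
    marginal_means,
)
from patsteps.synth import DetectionScenario, SyntheticConfig, simulate_dataset


def sim(seed, n_part, profile, sd=0.15, pat="trouser"):
    cfg = SyntheticConfig(
        n_participants=n_part,
        pat_profiles={pat: profile},
        participant_effect_sd=sd,
        true_step_jitter={20: 1.0},
        seed=seed,
    )
    return simulate_dataset(cfg)


def nl(zero_prob, mean_ratio, dispersion=0.25):
    label = ("near_limit" if 0.05 < zero_prob < 0.9
             else "undetectable" if zero_prob >= 0.9 else "detectable")
    cm = "nb"
    return DetectionScenario(label, zero_prob, mean_ratio, dispersion,
                             count_model=cm)


def test_perfect_counts_fall_back_to_plain_nb_with_mean_twenty():
    df = sim(0, 30, {"S-100": DetectionScenario("detectable", 0.0, 1.0, 0.01,
                                                count_model="binomial"),
                     "S-75": DetectionScenario("detectable", 0.0, 1.0, 0.01,
                                               count_model="binomial")},
             sd=0.0)
    fit = fit_zinb(df)
    assert fit.model_kind == "nb"
    assert any("no zero counts" in n for n in fit.notes)
    mm = marginal_means(fit)
    assert np.allclose(mm["marginal_mean"], 20.0, atol=0.5)


def test_half_inflated_condition_has_marginal_mean_ten():
    profile = {"S-100": nl(0.04, 1.0), "S-25": nl(0.5, 1.0)}
    df = sim(1, 250, profile, sd=0.0)
    fit = fit_zinb(df)
    mm = marginal_means(fit).set_index("condition")["marginal_mean"]
    assert mm["S-25"] == pytest.approx(10.0, abs=1.0)
    assert mm["S-100"] == pytest.approx(19.2, abs=1.0)


def test_exposure_enters_with_unit_coefficient():
    profile = {"S-100": nl(0.2, 0.9), "S-40": nl(0.4, 0.7)}
    df = sim(2, 80, profile)
    fit = fit_zinb(df)
    m20 = marginal_means(fit, true_steps=20)["marginal_mean"].to_numpy()
    m40 = marginal_means(fit, true_steps=40)["marginal_mean"].to_numpy()
    assert np.allclose(m40, 2 * m20, rtol=1e-12)


def test_marginal_mean_monotone_in_inflation_probability():
    profile = {"S-100": nl(0.2, 0.9), "S-40": nl(0.4, 0.7)}
    df = sim(3, 60, profile)
    fit = fit_zinb(df)
    params = fit.params.copy()
    base = _marginal_mean_vector(fit, params, 20.0)
    bumped = params.copy()
    bumped[0] += 1.0  # raise every inflation probability
    higher_pi = _marginal_mean_vector(fit, bumped, 20.0)
    assert (higher_pi < base).all()


def test_zinb_agrees_with_plain_nb_when_no_inflation():
    import statsmodels.api as sm

    # dispersion 1.0 produces natural NB zeros without any inflation
    profile = {"S-100": nl(0.0, 0.95, dispersion=1.0),
               "S-40": nl(0.0, 0.85, dispersion=1.0)}
    df = sim(4, 150, profile, sd=0.0)
    assert (df["counted_steps"] == 0).any()
    fit = fit_zinb(df)
    mm = marginal_means(fit).set_index("condition")["marginal_mean"]

    dfc = df.dropna(subset=["counted_steps"])
    x = pd.get_dummies(dfc["condition"], dtype=float)[["S-100", "S-40"]]
    x = np.column_stack([np.ones(len(dfc)), x["S-40"]])
    nb = sm.NegativeBinomialP(
        dfc["counted_steps"].astype(float), x,
        exposure=dfc["true_steps"].astype(float), p=2).fit(disp=0)
    b0, b1 = np.asarray(nb.params)[:2]
    nb_means = 20 * np.exp([b0, b0 + b1])
    assert mm["S-100"] == pytest.approx(nb_means[0], rel=0.05)
    assert mm["S-40"] == pytest.approx(nb_means[1], rel=0.05)


def test_sandwich_variance_exceeds_naive_under_clustering():
    profile = {"S-100": nl(0.2, 1.0), "S-40": nl(0.2, 1.0)}
    ratio = []
    for seed in range(12):
        df = sim(seed, 50, profile, sd=0.45)
        fit = fit_zinb(df)
        mm = marginal_means(fit)
        naive = fit.result.model.fit(start_params=fit.params, method="bfgs",
                                     maxiter=100, disp=0)
        k = len(fit.conditions)
        base = fit._count_offset()
        ratio.append(fit.cov[base, base] / np.asarray(
            naive.cov_params())[base, base])
    assert np.mean(ratio) > 1.0


def test_all_zero_condition_reported_at_boundary():
    profile = {"S-100": nl(0.04, 1.0), "S-75": nl(0.3, 0.8),
               "S-25": nl(1.0, 0.5)}
    df = sim(6, 40, profile)
    fit = fit_zinb(df)
    assert fit.boundary_conditions == ["S-25"]
    assert fit.inflation_mode == "condition"
    assert fit.inflation_probabilities()["S-25"] == 1.0
    mm = marginal_means(fit).set_index("condition")
    assert mm.loc["S-25", "marginal_mean"] == 0.0
    assert mm.loc["S-25", "se"] == 0.0
    assert mm.loc["S-100", "marginal_mean"] == pytest.approx(19.2, abs=1.5)


def test_single_condition_rejected():
    df = sim(7, 10, {"S-100": nl(0.2, 1.0)})
    with pytest.raises(FitError):
        fit_zinb(df)


def test_contrast_tables_cover_step_sizes_and_categories(study_df):
    trouser = study_df[(study_df["pat"] == "trouser")
                       & study_df["counted_steps"].notna()
                       & ~study_df["condition"].isin(["L-75", "L-40"])]
    fit = fit_zinb(trouser)
    contrasts, global_test = contrast_tests(fit)
    labels = set(contrasts["label"])
    assert "S: 100% vs 75%" in labels
    assert "T: 75% vs 40%" in labels
    assert "W vs S (matched step sizes)" in labels
    assert "S: linear step-size trend" in labels
    joint = global_test["joint_tests"]
    assert "S: equality across step sizes" in set(joint["label"])
    assert 0.0 <= global_test["p_value"] <= 1.0
    # strong built-in step-size effect for the trouser sensor
    assert global_test["p_value"] < 1e-6


def test_large_generator_gap_is_detected_as_crutch_effect(study_df):
    trouser = study_df[(study_df["pat"] == "trouser")
                       & study_df["counted_steps"].notna()
                       & ~study_df["condition"].isin(["L-75", "L-40"])]
    fit = fit_zinb(trouser)
    contrasts, _ = contrast_tests(fit)
    row = contrasts[contrasts["label"] == "W vs S (matched step sizes)"]
    assert row["estimate"].iloc[0] < 0  # crutches lower the counts
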