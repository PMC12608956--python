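import warnings

import numpy as np
import pandas as pd
import pytest

from patsteps.icc import (
    anova_variance_components,
    fit_condition_icc,
    inter_hcp_icc,
    intra_hcp_icc,
)
from patsteps.preprocess import CleaningReport, RatioDataset
from patsteps.protocol import ANALYSIS_CODES

from _oracles import balanced_anova_components


def balanced_data(rng, g=12, n=2, sigma_c=0.3, sigma_r=0.3):
    b = rng.normal(0, sigma_c, g)
    y = (b[:, None] + rng.normal(0, sigma_r, (g, n))).ravel()
    groups = np.repeat(np.arange(g), n)
    return y, groups


@pytest.mark.parametrize("seed", range(8))
def test_reml_matches_closed_form_on_balanced_data(seed):
    """For balanced one-way data the REML optimum is the ANOVA estimator."""
    rng = np.random.default_rng(seed)
    y, groups = balanced_data(rng, g=12, n=2)
    res = fit_condition_icc(y, groups)
    sc2, sr2 = balanced_anova_components(y, 12, 2)
    if sc2 > 1e-4:  # interior solution: estimators coincide
        assert res.sigma_condition**2 == pytest.approx(sc2, abs=1e-6)
        assert res.sigma_residual**2 == pytest.approx(sr2, abs=1e-6)
        assert res.icc == pytest.approx(sc2 / (sc2 + sr2), abs=1e-6)
    else:  # boundary: REML truncates to zero as well
        assert res.sigma_condition**2 == pytest.approx(0.0, abs=1e-6)


def test_package_anova_matches_oracle_formula():
    rng = np.random.default_rng(10)
    y, groups = balanced_data(rng, g=8, n=4)
    sc2, sr2 = anova_variance_components(y, groups)
    osc2, osr2 = balanced_anova_components(y, 8, 4)
    assert sc2 == pytest.approx(osc2, abs=1e-12)
    assert sr2 == pytest.approx(osr2, abs=1e-12)


def test_reml_matches_statsmodels_mixedlm_on_unbalanced_data():
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(2)
    sizes = [2, 3, 5, 2, 4, 6, 3, 2]
    b = rng.normal(0, 0.4, len(sizes))
    rows = []
    for i, (s, bi) in enumerate(zip(sizes, b)):
        for _ in range(s):
            rows.append((f"g{i}", bi + rng.normal(0, 0.3)))
    df = pd.DataFrame(rows, columns=["g", "y"])

    res = fit_condition_icc(df["y"].to_numpy(), df["g"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lmm = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
    sc2_sm = float(lmm.cov_re.iloc[0, 0])
    sr2_sm = float(lmm.scale)
    assert res.sigma_condition**2 == pytest.approx(sc2_sm, abs=1e-4)
    assert res.sigma_residual**2 == pytest.approx(sr2_sm, abs=1e-4)


def test_between_dominated_variance_gives_icc_near_one():
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
    groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    res = fit_condition_icc(y, groups)
    assert res.icc is not None and res.icc >= 0.95
    assert not res.suppressed


def test_identical_values_suppressed():
    res = fit_condition_icc(np.full(8, 0.7), np.repeat(["a", "b", "c", "d"], 2))
    assert res.suppressed
    assert res.icc is None or res.sigma_condition == 0.0


def test_small_between_group_sd_triggers_suppression_rule():
    rng = np.random.default_rng(4)
    b = rng.normal(0, 0.02, 12)  # well below the 0.1 reporting threshold
    y = (b[:, None] + rng.normal(0, 0.3, (12, 4))).ravel()
    res = fit_condition_icc(y, np.repeat(np.arange(12), 4))
    assert res.suppressed
    assert "below" in res.reason


@pytest.mark.parametrize("shift,scale", [(0.7, 1.0), (0.0, 3.0), (1.2, 0.5)])
def test_icc_invariant_to_affine_rescaling(shift, scale):
    rng = np.random.default_rng(5)
    y, groups = balanced_data(rng, g=10, n=3)
    base = fit_condition_icc(y, groups)
    moved = fit_condition_icc(y * scale + shift, groups)
    assert moved.icc == pytest.approx(base.icc, abs=1e-5)


def test_parameter_recovery_at_equal_components():
    rng = np.random.default_rng(6)
    estimates = []
    for _ in range(200):
        y, groups = balanced_data(rng, g=12, n=4, sigma_c=0.3, sigma_r=0.3)
        estimates.append(fit_condition_icc(y, groups).icc)
    assert abs(np.mean(estimates) - 0.5) < 0.1


# ---------------------------------------------------------------------------
# pairing designs


def make_dataset(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "round", "condition",
                                     "pat", "ratio"])
    return RatioDataset(table=df, provenance="synthetic",
                        report=CleaningReport())


def spread_rows(parts, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for part in parts:
        for rnd in (1, 2):
            for i, code in enumerate(ANALYSIS_CODES):
                rows.append((part, rnd, code, "trouser",
                             i / 11 + noise * rng.normal()))
    return rows


def test_perfect_test_retest_icc_near_one():
    data = make_dataset(spread_rows([1], noise=0.01))
    res = intra_hcp_icc(data, 1, "trouser")
    assert res.icc > 0.95
    assert not res.suppressed


def test_intra_icc_matches_balanced_hand_computation(study_data):
    part = study_data.participants(pat="trouser")[2]
    res = intra_hcp_icc(study_data, part, "trouser")
    t = study_data.ratios(participant=part, pat="trouser")
    both = t.pivot_table(index="condition", columns="round", values="ratio")
    both = both.dropna()
    y = np.column_stack([both[1], both[2]]).ravel()
    sc2, sr2 = balanced_anova_components(y, len(both), 2)
    if sc2 > 1e-4 and res.icc is not None:
        assert res.icc == pytest.approx(sc2 / (sc2 + sr2), abs=1e-5)


def test_intra_icc_undefined_without_second_round():
    rows = [r for r in spread_rows([1]) if r[1] == 1]
    data = make_dataset(rows)
    res = intra_hcp_icc(data, 1, "trouser")
    assert res.suppressed and res.icc is None


def test_identical_participants_inter_icc_near_one():
    data = make_dataset(spread_rows([1, 2, 3], noise=0.01))
    res, breakdown = inter_hcp_icc(data, "trouser")
    assert res.icc > 0.9
    assert len(breakdown) == 3 * 4  # C(3,2)=3 pairs x 4 round combos


def test_inter_icc_combination_counts():
    data = make_dataset(spread_rows(range(1, 14), noise=0.05))
    res, breakdown = inter_hcp_icc(data, "trouser")
    assert len(breakdown) == 78 * 4


def test_unstructured_participants_suppressed_or_near_zero():
    rng = np.random.default_rng(9)
    rows = []
    for part in (1, 2, 3, 4):
        for rnd in (1, 2):
            for code in ANALYSIS_CODES:
                rows.append((part, rnd, code, "trouser",
                             float(rng.uniform(0, 1))))
    data = make_dataset(rows)
    res, _ = inter_hcp_icc(data, "trouser")
    assert res.suppressed or res.icc < 0.3


def test_pooled_inter_icc_variant_runs(study_data):
    res, _ = inter_hcp_icc(study_data, "trouser", pool=True)
    assert res.method.startswith("pooled")
    assert res.icc is None or 0.0 <= res.icc <= 1.0
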