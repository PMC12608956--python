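import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patsteps.agreement import (
    Band,
    RatioPair,
    WEIGHT_TABLE,
    agreement_rate,
    band_of,
    inter_hcp_kappa,
    intra_hcp_kappa,
    intra_hcp_pairs,
    landis_koch_label,
    pair_weight,
    weighted_kappa,
)
from patsteps.preprocess import CleaningReport, RatioDataset
from patsteps.protocol import ANALYSIS_CODES

from _oracles import brute_agreement_rate, clause_weight, random_ratios

ratios = st.one_of(
    st.floats(min_value=0.0, max_value=1.6, allow_nan=False),
    st.integers(min_value=0, max_value=32).map(lambda k: k / 20),
    st.sampled_from([0.0, 0.2, 0.5, 0.8, 1.0]),
)


def make_dataset(rows):
    """rows: (participant, round, condition, pat, ratio)."""
    df = pd.DataFrame(rows, columns=["participant_id", "round", "condition",
                                     "pat", "ratio"])
    return RatioDataset(table=df, provenance="synthetic",
                        report=CleaningReport())


@pytest.mark.parametrize("ratio,band", [
    (0.0, Band.low), (0.19, Band.low),
    (0.2, Band.mid_low), (0.49, Band.mid_low),
    (0.5, Band.mid_high), (0.8, Band.mid_high),
    (0.81, Band.high), (0.95, Band.high), (1.55, Band.high),
])
def test_band_boundaries(ratio, band):
    assert band_of(ratio) is band


def test_negative_ratio_rejected():
    with pytest.raises(ValueError):
        band_of(-0.01)


@pytest.mark.parametrize("a,b,w", [
    (0.95, 0.05, 0.0),   # clear detection vs clear failure
    (0.65, 0.10, 0.5),   # mid-high vs failure
    (0.30, 0.95, 0.5),   # mid-low vs clear detection
    (0.3, 0.7, 1.0),     # both in the middle
    (0.9, 0.6, 1.0),     # detection with mid-high support
    (0.1, 0.3, 1.0),     # failure with mid-low support
])
def test_pair_weight_clauses(a, b, w):
    assert pair_weight(a, b) == w
    assert pair_weight(b, a) == w


@given(ratios, ratios)
@settings(deadline=None, derandomize=True, max_examples=300)
def test_pair_weight_matches_clause_oracle_and_is_symmetric(a, b):
    w = pair_weight(a, b)
    assert w == clause_weight(a, b)
    assert w == pair_weight(b, a)
    assert w in (0.0, 0.5, 1.0)


@given(ratios)
@settings(deadline=None, derandomize=True, max_examples=100)
def test_identical_ratios_fully_agree(x):
    assert pair_weight(x, x) == 1.0


def test_weight_table_enumeration():
    reps = {Band.low: 0.1, Band.mid_low: 0.3, Band.mid_high: 0.6,
            Band.high: 0.9}
    for ba, bb in itertools.product(Band, Band):
        assert WEIGHT_TABLE[ba, bb] == clause_weight(reps[ba], reps[bb])
        assert WEIGHT_TABLE[ba, bb] == WEIGHT_TABLE[bb, ba]


def test_agreement_rate_examples():
    same = [RatioPair(0.95, 0.95), RatioPair(0.1, 0.1)]
    assert agreement_rate(same) == 1.0
    mixed = [RatioPair(0.95, 0.05), RatioPair(0.95, 0.95)]
    assert agreement_rate(mixed) == 0.5
    with pytest.raises(ValueError):
        agreement_rate([])


def test_agreement_rate_equals_bruteforce_loop():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(1, 40))
        pairs = [RatioPair(a, b) for a, b in
                 zip(random_ratios(rng, n), random_ratios(rng, n))]
        assert agreement_rate(pairs) == pytest.approx(
            brute_agreement_rate(pairs), abs=1e-12)


def test_perfect_two_band_agreement_has_kappa_one():
    pairs = [RatioPair(0.05, 0.06)] * 5 + [RatioPair(0.95, 0.97)] * 5
    res = weighted_kappa(pairs)
    assert res.observed_agreement == 1.0
    assert res.chance_agreement < 1.0
    assert res.kappa == pytest.approx(1.0)
    assert not res.suppressed


def test_kappa_suppressed_when_all_ratios_high():
    pairs = [RatioPair(0.6, 0.9), RatioPair(0.95, 0.7), RatioPair(0.55, 0.85)]
    res = weighted_kappa(pairs)
    assert res.suppressed
    assert "0.5" in res.reason
    assert res.kappa is None


def test_kappa_undefined_for_degenerate_marginals():
    # variation present (not all above 0.5) but a single band pairing
    pairs = [RatioPair(0.05, 0.1)] * 4
    res = weighted_kappa(pairs)
    assert res.suppressed
    assert res.kappa is None
    assert "chance" in res.reason


def test_chance_marginal_policies_differ_for_asymmetric_members():
    pairs = [RatioPair(0.05, 0.95)] * 3 + [RatioPair(0.95, 0.95)] * 6 \
        + [RatioPair(0.05, 0.05)] * 1
    pair_pol = weighted_kappa(pairs, chance_marginals="pair")
    pooled = weighted_kappa(pairs, chance_marginals="pooled")
    assert pair_pol.observed_agreement == pooled.observed_agreement
    assert pair_pol.chance_agreement != pytest.approx(pooled.chance_agreement)
    with pytest.raises(ValueError):
        weighted_kappa(pairs, chance_marginals="upside-down")


def test_independent_members_have_near_zero_kappa():
    rng = np.random.default_rng(0)
    a = random_ratios(rng, 4000)
    b = random_ratios(rng, 4000)
    res = weighted_kappa([RatioPair(x, y) for x, y in zip(a, b)])
    assert abs(res.kappa) < 0.05


@pytest.mark.parametrize("kappa,label", [
    (-0.2, "poor"), (0.0, "poor"), (0.1, "slight"), (0.2, "slight"),
    (0.38, "fair"), (0.45, "moderate"), (0.62, "substantial"),
    (0.8, "substantial"), (0.95, "almost perfect"), (1.0, "almost perfect"),
])
def test_landis_koch_labels(kappa, label):
    assert landis_koch_label(kappa) == label


def complete_two_rater_rows(ratio_fn):
    rows = []
    for part in (1, 2):
        for rnd in (1, 2):
            for i, code in enumerate(ANALYSIS_CODES):
                rows.append((part, rnd, code, "trouser",
                             ratio_fn(part, rnd, i)))
    return rows


def test_intra_pairs_complete_participant():
    data = make_dataset(complete_two_rater_rows(lambda p, r, i: i / 12))
    pairs = intra_hcp_pairs(data, 1, "trouser")
    assert len(pairs) == 12
    conds = {p.condition for p in pairs}
    assert conds == set(ANALYSIS_CODES)


def test_intra_pairs_empty_when_round_missing():
    rows = [r for r in complete_two_rater_rows(lambda p, r, i: i / 12)
            if not (r[0] == 1 and r[1] == 1)]
    data = make_dataset(rows)
    assert intra_hcp_pairs(data, 1, "trouser") == []
    res = intra_hcp_kappa(data, 1, "trouser")
    assert res.suppressed and res.n_pairs == 0


def test_intra_pair_count_matches_bruteforce_join(study_data):
    for part in study_data.participants(pat="trouser"):
        pairs = intra_hcp_pairs(study_data, part, "trouser")
        t = study_data.ratios(participant=part, pat="trouser")
        joined = t[t["round"] == 1].merge(t[t["round"] == 2], on="condition")
        assert len(pairs) == len(joined)


def test_identical_participants_give_inter_kappa_one():
    # same ratios everywhere, spanning low and high bands
    data = make_dataset(complete_two_rater_rows(
        lambda p, r, i: 0.05 if i < 6 else 0.95))
    res, breakdown = inter_hcp_kappa(data, "trouser")
    assert res.kappa == pytest.approx(1.0)
    assert len(breakdown) == 4  # one participant pair, four round combos


def test_inter_kappa_combination_counts():
    rows = []
    rng = np.random.default_rng(1)
    for part in range(1, 14):  # 13 usable participants
        for rnd in (1, 2):
            for code in ANALYSIS_CODES:
                rows.append((part, rnd, code, "wrist",
                             float(rng.uniform(0, 1.2))))
    data = make_dataset(rows)
    res, breakdown = inter_hcp_kappa(data, "wrist")
    assert len(breakdown) == 78 * 4  # C(13,2) participant pairs x round combos
    res_cross, bd_cross = inter_hcp_kappa(data, "wrist", round_combos="cross")
    assert len(bd_cross) == 78 * 2


def test_independent_participants_give_near_zero_mean_kappa():
    rng = np.random.default_rng(3)
    rows = []
    for part in range(1, 41):
        for rnd in (1, 2):
            for code in ANALYSIS_CODES:
                rows.append((part, rnd, code, "wrist",
                             float(random_ratios(rng, 1)[0])))
    data = make_dataset(rows)
    res, _ = inter_hcp_kappa(data, "wrist")
    assert abs(res.kappa) < 0.1
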