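import numpy as np
import pandas as pd
import pytest

from capstew.stats import (
    DEFAULT_BINARIZATION_RULES,
    BinarizationRule,
    TwoByTwo,
    binarize,
    median_difference,
    modified_poisson,
    paf,
    pearson_chisq,
    proportion_difference,
    risk_ratio_2x2,
    spline_logistic_curve,
    two_by_two,
    wilcoxon_ranksum,
)


# ---------------------------------------------------------------------------
# 2x2 risk ratios


def test_risk_ratio_symmetric_table_is_unity():
    est = risk_ratio_2x2(TwoByTwo(10, 10, 10, 10))
    assert est.rr == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


def test_katz_ci_contains_point_and_widens_with_smaller_counts():
    big = risk_ratio_2x2(TwoByTwo(40, 60, 20, 80))
    small = risk_ratio_2x2(TwoByTwo(4, 6, 2, 8))
    for est in (big, small):
        assert est.ci_low <= est.rr <= est.ci_high
    assert small.ci_high / small.ci_low > big.ci_high / big.ci_low


def test_zero_event_arm_uses_continuity_correction():
    est = risk_ratio_2x2(TwoByTwo(0, 10, 5, 5))
    assert est.continuity_corrected
    assert est.rr > 0


def test_two_by_two_from_vectors():
    t = two_by_two([1, 1, 0, 0], [1, 0, 1, 0])
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


# ---------------------------------------------------------------------------
# chi-squared / rank-sum


def test_chisq_flat_table_is_zero():
    stat, p = pearson_chisq(TwoByTwo(10, 10, 10, 10))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chisq_matches_direct_formula_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(25):
        a, b, c, d = rng.integers(1, 60, size=4)
        t = TwoByTwo(int(a), int(b), int(c), int(d))
        stat, _ = pearson_chisq(t)
        obs = t.as_array()
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, rel=1e-12)


def test_degenerate_margin_rejected():
    with pytest.raises(ValueError):
        pearson_chisq(TwoByTwo(0, 0, 5, 5))


def test_ranksum_identical_samples_uninformative():
    with pytest.warns(UserWarning):
        _, p = wilcoxon_ranksum([2.0, 2.0, 2.0], [2.0, 2.0])
    assert p == 1.0


def test_ranksum_exact_small_sample():
    """Fully separated ranks, n = 3 + 3: exact two-sided p = 2/20 = 0.1."""
    w, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
    assert w == pytest.approx(6.0)  # ranks 1+2+3
    assert p == pytest.approx(0.1)


def test_ranksum_detects_shift_in_large_samples():
    rng = np.random.default_rng(7)
    hits = 0
    for _ in range(40):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.5, 1, 200)
        _, p = wilcoxon_ranksum(x, y)
        hits += p < 0.01
    assert hits >= 38  # power well above 95%


# ---------------------------------------------------------------------------
# binarization


def test_crp_rule_splits_at_100():
    table = pd.DataFrame({"crp_max_mg_L": [167.0, 62.0, 100.0, np.nan]})
    out, report = binarize(table, DEFAULT_BINARIZATION_RULES)
    assert out["crp_max_mg_L"].tolist()[:3] == [1, 0, 0]  # cutoff itself -> 0
    assert pd.isna(out["crp_max_mg_L"].iloc[3])
    assert report.loc[report["variable"] == "crp_max_mg_L", "cutoff"].item() == 100.0


def test_at_least_direction_keeps_boundary():
    table = pd.DataFrame({"sofa": [2, 1]})
    out, _ = binarize(table, DEFAULT_BINARIZATION_RULES)
    assert out["sofa"].tolist() == [1, 0]


def test_median_rule_on_even_sample():
    table = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
    out, report = binarize(table, rules=(), median_for=["v"])
    assert out["v"].tolist() == [0, 0, 1, 1]
    row = report.iloc[0]
    assert row["cutoff"] == 2.5 and row["provenance"] == "median"


def test_median_rule_on_constant_variable_errors():
    table = pd.DataFrame({"v": [3.0, 3.0, 3.0]})
    with pytest.raises(ValueError, match="v"):
        binarize(table, rules=(), median_for=["v"])


# ---------------------------------------------------------------------------
# modified Poisson


def _saturated_layout(t: TwoByTwo):
    y = np.r_[np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
    x = np.r_[np.ones(t.a + t.b), np.zeros(t.c + t.d)]
    return y, pd.DataFrame({"exposure": x})


@pytest.mark.parametrize("t", [TwoByTwo(15, 30, 82, 352), TwoByTwo(6, 4, 91, 378),
                               TwoByTwo(25, 25, 10, 40)])
def test_saturated_model_identity(t):
    y, X = _saturated_layout(t)
    fit = modified_poisson(y, X)
    direct = risk_ratio_2x2(t).rr
    assert fit.estimates["exposure"].rr == pytest.approx(direct, rel=1e-9)


def test_rank_deficient_design_rejected():
    y = np.array([0, 1, 0, 1.0])
    X = pd.DataFrame({"a": [1, 1, 0, 0], "b": [2, 2, 0, 0]})
    with pytest.raises(ValueError):
        modified_poisson(y, X)


def test_non_binary_outcome_rejected():
    with pytest.raises(ValueError):
        modified_poisson(np.array([0, 2, 1.0]), pd.DataFrame({"a": [1, 0, 1]}))


def test_robust_se_close_to_binomial_truth():
    """On a large saturated layout the sandwich SE approaches the Katz SE."""
    t = TwoByTwo(400, 600, 300, 700)
    y, X = _saturated_layout(t)
    fit = modified_poisson(y, X)
    katz = risk_ratio_2x2(t)
    assert fit.estimates["exposure"].se_log == pytest.approx(katz.se_log, rel=0.02)


# ---------------------------------------------------------------------------
# PAF


def test_paf_null_effect_is_zero():
    assert paf(1.0, 0.7).paf == pytest.approx(0.0)


def test_paf_case_load_formula():
    assert paf(2.0, 0.5).paf == pytest.approx(0.25)


def test_protective_exposure_gives_negative_paf():
    est = paf(0.5, 0.3)
    assert est.paf < 0 and est.protective


def test_paf_bootstrap_is_seed_reproducible():
    def source(rng):
        return float(rng.uniform(1.5, 2.5)), float(rng.uniform(0.3, 0.6))

    a = paf(2.0, 0.5, resample_source=source, n_boot=300, seed=5)
    b = paf(2.0, 0.5, resample_source=source, n_boot=300, seed=5)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low < a.paf < a.ci_high


# ---------------------------------------------------------------------------
# spline logistic curves


def test_spline_on_null_data_stays_near_constant_probability():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 200, 400)
    y = rng.random(400) < 0.4
    curve = spline_logistic_curve(x, y.astype(int), df=4)
    mean = y.mean()
    assert np.all(curve.ci_low <= mean + 0.12)
    assert np.all(curve.ci_high >= mean - 0.12)
    assert not curve.quasi_separation


def test_spline_recovers_step_increase():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 200, 1500)
    p = np.where(x > 100, 0.8, 0.2)
    y = (rng.random(1500) < p).astype(int)
    curve = spline_logistic_curve(x, y, df=4, grid=np.linspace(50, 150, 21))
    assert curve.probability[0] < 0.45 < curve.probability[-1]
    assert np.all(np.diff(curve.probability) > -0.02)  # rises through the step


def test_spline_input_contracts():
    x = np.linspace(0, 1, 60)
    y = (x > 0.5).astype(int)
    with pytest.raises(ValueError):
        spline_logistic_curve(x[:20], y[:20], df=4)
    with pytest.raises(ValueError):
        spline_logistic_curve(x, y, df=1)
    with pytest.raises(ValueError):
        spline_logistic_curve(np.repeat([0.0, 1.0, 2.0], 20), y, df=5)


# ---------------------------------------------------------------------------
# medians and proportions


def test_median_difference_recovers_pure_shift():
    rng = np.random.default_rng(3)
    y = rng.normal(10, 2, 300)
    x = y + 3.0
    res = median_difference(x, y, n_boot=500, seed=9)
    assert res["difference"] == pytest.approx(3.0)
    assert res["ci_low"] < 3.0 < res["ci_high"]
    assert res["p_value"] < 0.01


def test_median_difference_is_bit_reproducible():
    rng = np.random.default_rng(4)
    x, y = rng.normal(0, 1, 80), rng.normal(1, 1, 90)
    a = median_difference(x, y, n_boot=300, seed=11)
    b = median_difference(x, y, n_boot=300, seed=11)
    assert a == b


def test_median_difference_requires_enough_bootstraps():
    with pytest.raises(ValueError):
        median_difference([1.0, 2.0], [3.0], n_boot=50)


def test_proportion_difference_hand_computation():
    res = proportion_difference((50, 100), (25, 100))
    se = np.sqrt(0.5 * 0.5 / 100 + 0.25 * 0.75 / 100)
    assert res["difference"] == pytest.approx(0.25)
    assert res["ci_low"] == pytest.approx(0.25 - 1.959963984540054 * se)
    assert res["ci_high"] == pytest.approx(0.25 + 1.959963984540054 * se)


def test_equal_proportions_give_zero_difference():
    assert proportion_difference((30, 60), (15, 30))["difference"] == pytest.approx(0.0)
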