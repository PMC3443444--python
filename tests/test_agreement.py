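"""Bland-Altman, ICC, Pearson and paired-t statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from octgraft import (MeasurementSeries, agreement_table, bland_altman,
                      icc_two_way, paired_t, pearson_r)
from octgraft.errors import DegenerateDataError, ParameterError


def series(a, b, la="A", lb="B"):
    return MeasurementSeries(np.asarray(a, float), np.asarray(b, float), la, lb)


# ---------------------------------------------------------------------------
# Bland-Altman

def test_identical_arms_have_zero_limits():
    s = series([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    rep = bland_altman(s)
    assert rep.bias == 0.0 and rep.sd_diff == 0.0
    assert rep.loa_lower == 0.0 and rep.loa_upper == 0.0


def test_hand_computed_simple_differences():
    s = series([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])  # differences -1, 0, 1
    rep = bland_altman(s)
    assert rep.bias == pytest.approx(0.0)
    assert rep.sd_diff == pytest.approx(1.0)
    assert rep.loa_lower == pytest.approx(-1.96)
    assert rep.loa_upper == pytest.approx(1.96)
    tq = stats.t.ppf(0.975, 2)
    assert rep.bias_ci[1] == pytest.approx(tq / np.sqrt(3))
    assert rep.loa_upper_ci[0] == pytest.approx(1.96 - tq * np.sqrt(3 / 3))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e5, 1e5), min_size=3, max_size=40),
       st.integers(0, 2**31 - 1))
def test_loa_symmetry_and_swap_mirror(a_vals, seed):
    """loa_lower + loa_upper == 2*bias always, and swapping the arms
    mirrors every Bland-Altman quantity."""
    rng = np.random.default_rng(seed)
    a = np.array(a_vals)
    b = a + rng.normal(0, 10, a.size)
    s = series(a, b)
    rep = bland_altman(s)
    assert rep.loa_lower + rep.loa_upper == pytest.approx(2 * rep.bias, abs=1e-6)
    mir = bland_altman(s.swapped())
    assert mir.bias == pytest.approx(-rep.bias, abs=1e-9)
    assert mir.loa_lower == pytest.approx(-rep.loa_upper, abs=1e-9)
    assert mir.loa_upper == pytest.approx(-rep.loa_lower, abs=1e-9)


def test_small_samples_rejected():
    with pytest.raises(ParameterError):
        series([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# ICC

def anova_icc_a1_oracle(a, b):
    """Brute-force two-way ANOVA mean squares -> ICC(A,1)."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True)
            + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_identical_arms_is_one():
    s = series([1.0, 5.0, 9.0, 2.0], [1.0, 5.0, 9.0, 2.0])
    icc, ci = icc_two_way(s)
    assert icc == pytest.approx(1.0)
    assert ci == (1.0, 1.0)


def test_icc_offset_penalised_under_absolute_agreement():
    a = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    s = series(a, a + 8.0)
    icc_abs, _ = icc_two_way(s, kind="absolute")
    icc_con, _ = icc_two_way(s, kind="consistency")
    assert icc_abs < 1.0
    assert icc_con == pytest.approx(1.0)


def test_icc_matches_anova_oracle_on_toy_table():
    a = [166.0, 150.0, 178.0, 190.0, 161.0, 172.0]
    b = [160.0, 148.0, 185.0, 200.0, 165.0, 170.0]
    icc, _ = icc_two_way(series(a, b))
    assert icc == pytest.approx(anova_icc_a1_oracle(np.array(a), np.array(b)),
                                rel=1e-12)


def test_icc_matches_pingouin():
    """Independent cross-check of point estimate and CI against a
    published implementation."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd
    rng = np.random.default_rng(11)
    truth = rng.uniform(1e5, 2e5, 30)
    a = truth + rng.normal(0, 8e3, 30)
    b = truth + rng.normal(0, 8e3, 30)
    icc, ci = icc_two_way(series(a, b))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(30), 2),
        "rater": np.tile(["A", "B"], 30),
        "score": np.column_stack([a, b]).ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
    row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
    assert icc == pytest.approx(row["ICC"], abs=1e-9)
    ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
    lo, hi = row[ci_col]
    assert ci[0] == pytest.approx(lo, abs=0.006)  # pingouin rounds its CI
    assert ci[1] == pytest.approx(hi, abs=0.006)


def test_icc_degenerate_data_rejected():
    s = series([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    with pytest.raises(DegenerateDataError):
        icc_two_way(s)


# ---------------------------------------------------------------------------
# Pearson r and paired t

def test_perfect_correlation_under_offset():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(series(a, a + 5.0)) == pytest.approx(1.0)


def test_zero_variance_correlation_undefined():
    with pytest.raises(DegenerateDataError):
        pearson_r(series([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_paired_t_zero_mean_differences():
    t, p = paired_t(series([0.0, 1.0, 2.0], [1.0, 1.0, 1.0]))
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_paired_t_matches_textbook_arithmetic():
    a = np.array([12.0, 15.0, 11.0, 16.0, 14.0])
    b = np.array([10.0, 14.0, 12.0, 13.0, 11.0])
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    p_hand = 2 * stats.t.sf(abs(t_hand), 4)
    t, p = paired_t(series(a, b))
    assert t == pytest.approx(t_hand, rel=1e-12)
    assert p == pytest.approx(p_hand, rel=1e-12)
    # agrees with scipy's paired test
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_identical_series_t_is_zero():
    t, p = paired_t(series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
    assert (t, p) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# table assembly and parameter recovery

def test_agreement_table_degenerate_row_flagged(tmp_path):
    a = [1.0, 2.0, 3.0, 4.0]
    tab = agreement_table([series(a, a, "M1", "M2")])
    row = tab.iloc[0]
    assert bool(row["degenerate"])
    assert np.isnan(row["p_value"])
    assert row["r"] == pytest.approx(1.0)
    assert row["icc"] == pytest.approx(1.0)
    assert row["loa_upper"] == 0.0 and row["loa_lower"] == 0.0
    # CSV round-trip preserves the numbers
    import pandas as pd
    p = tmp_path / "tab.csv"
    tab.to_csv(p, index=False)
    back = pd.read_csv(p)
    assert back["bias"].iloc[0] == row["bias"]
    assert back["icc"].iloc[0] == pytest.approx(row["icc"])


def test_simulated_observers_recover_bias_and_spread():
    """Two observers reading the same objects with independent N(0, σ)
    noise: bias ~ 0 within 3σ/sqrt(n) and sd_diff ~ σ√2 within 10%."""
    rng = np.random.default_rng(42)
    n, sigma = 200, 5000.0
    truth = rng.uniform(1e5, 2e5, n)
    s = series(truth + rng.normal(0, sigma, n), truth + rng.normal(0, sigma, n))
    rep = bland_altman(s)
    assert abs(rep.bias) < 3 * sigma / np.sqrt(n)
    assert rep.sd_diff == pytest.approx(sigma * np.sqrt(2), rel=0.10)


def test_icc_tends_to_one_as_noise_vanishes():
    rng = np.random.default_rng(5)
    truth = rng.uniform(1e5, 2e5, 100)
    for sigma, floor in [(2e4, 0.2), (2e3, 0.9), (2.0, 0.999999)]:
        s = series(truth + rng.normal(0, sigma, 100),
                   truth + rng.normal(0, sigma, 100))
        icc, _ = icc_two_way(s)
        assert icc > floor
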