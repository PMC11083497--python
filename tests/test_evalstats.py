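"""Agreement statistics against independent oracles and hand calculations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aortaquant.errors import InputError
from aortaquant.evalstats import (DiagnosticCounts, PairedMeasurements,
                                  agreement_stats, bland_altman, clopper_pearson,
                                  diagnostic_metrics, error_summary, icc_2_1,
                                  icc_band, paired_nonparametrics,
                                  wilcoxon_exact_p)


# -- ICC --------------------------------------------------------------------

def test_icc_perfect_agreement():
    icc, band, _ = icc_2_1(PairedMeasurements([1, 2, 3], [1, 2, 3]))
    assert icc == pytest.approx(1.0) and band == "excellent"


def test_icc_constant_offset_hand_anova():
    # pairs (1,2),(2,3),(3,4): MSR=2, MSC=1.5, MSE=0 -> ICC = 2/3
    icc, band, _ = icc_2_1(PairedMeasurements(auto=[2, 3, 4], manual=[1, 2, 3]))
    assert icc == pytest.approx(2.0 / 3.0)
    assert band == "moderate"


def test_icc_independent_series_near_zero():
    rng = np.random.default_rng(0)
    icc, _, _ = icc_2_1(PairedMeasurements(rng.normal(size=200),
                                           rng.normal(size=200)))
    assert abs(icc) < 0.15


def test_icc_degenerate_zero_variance_flagged():
    icc, _, flags = icc_2_1(PairedMeasurements([5.0, 5, 5], [5.0, 5, 5]))
    assert icc == 1.0 and flags


def test_icc_matches_pingouin_on_random_tables():
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    rng = np.random.default_rng(3)
    for _ in range(8):
        a = rng.normal(40, 5, size=5)
        b = a + rng.normal(0, 2, size=5) + 0.5
        df = pd.DataFrame({"t": list(range(5)) * 2, "r": ["m"] * 5 + ["a"] * 5,
                           "y": np.concatenate([a, b])})
        ref = pg.intraclass_corr(df, "t", "r", "y")
        ref = float(ref[ref["Type"] == "ICC(A,1)"]["ICC"].iloc[0])
        ours, _, _ = icc_2_1(PairedMeasurements(b, a))
        assert ours == pytest.approx(ref, abs=1e-10)


def test_icc_bands():
    assert icc_band(0.3) == "poor"
    assert icc_band(0.6) == "moderate"
    assert icc_band(0.8) == "good"
    assert icc_band(0.95) == "excellent"


# -- Bland-Altman ------------------------------------------------------------

def test_bland_altman_constant_difference():
    bias, lo, hi = bland_altman(PairedMeasurements([2, 3, 4], [1, 2, 3]))
    assert (bias, lo, hi) == (1.0, 1.0, 1.0)


def test_bland_altman_parameter_recovery():
    """Recover a bias/LoA pattern like the published overall contrast row."""
    bias_true = -1.3
    sigma = (7.2 - (-1.3)) / 1.96   # LoA half-width 8.5 mm -> sigma
    rng = np.random.default_rng(12)
    manual = rng.normal(42, 6, size=10_000)
    auto = manual + rng.normal(bias_true, sigma, size=10_000)
    bias, lo, hi = bland_altman(PairedMeasurements(auto, manual))
    assert bias == pytest.approx(-1.3, abs=0.2)
    assert lo == pytest.approx(-9.8, abs=0.2)
    assert hi == pytest.approx(7.2, abs=0.2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 27))
def test_bland_altman_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a, m = rng.normal(size=6), rng.normal(size=6)
    b1, l1, h1 = bland_altman(PairedMeasurements(a, m))
    b2, l2, h2 = bland_altman(PairedMeasurements(m, a))
    assert b2 == pytest.approx(-b1)
    assert l2 == pytest.approx(-h1) and h2 == pytest.approx(-l1)


def test_loa_cover_95_percent_of_normal_differences():
    rng = np.random.default_rng(5)
    manual = rng.normal(40, 5, size=100_000)
    auto = manual + rng.normal(1.0, 2.0, size=100_000)
    p = PairedMeasurements(auto, manual)
    _, lo, hi = bland_altman(p)
    frac = np.mean((p.diff >= lo) & (p.diff <= hi))
    assert 0.94 <= frac <= 0.96


# -- Wilcoxon / Spearman -----------------------------------------------------

def test_wilcoxon_six_positive_differences_exact():
    wp, rho, _ = paired_nonparametrics(
        PairedMeasurements([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6]))
    assert wp == pytest.approx(2 / 64)
    assert rho == pytest.approx(1.0)


def test_wilcoxon_antisymmetric_pattern_null():
    wp, _, _ = paired_nonparametrics(
        PairedMeasurements([1, -1, 2, -2], [0, 0, 0, 0]))
    assert wp == pytest.approx(1.0)


def test_wilcoxon_all_zero_differences_flagged():
    wp, _, flags = paired_nonparametrics(PairedMeasurements([1, 2, 3], [1, 2, 3]))
    assert wp == 1.0 and any("zero" in f for f in flags)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(-5, 5).filter(lambda x: x != 0),
                min_size=2, max_size=12))
def test_wilcoxon_exact_matches_full_enumeration(diffs):
    d = np.asarray(diffs, dtype=float)
    ours = wilcoxon_exact_p(d)
    ranks = sps.rankdata(np.abs(d))
    mean = ranks.sum() / 2.0
    w0 = ranks[d > 0].sum()
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s > 0)
                   for signs in itertools.product([1, -1], repeat=len(d))])
    brute = np.mean(np.abs(ws - mean) >= abs(w0 - mean) - 1e-9)
    assert ours == pytest.approx(brute, abs=1e-12)


# -- Error summaries ---------------------------------------------------------

def test_error_summary_hand_counts():
    p = PairedMeasurements([0, 2, 4], [1, 2, 3])   # diffs -1, 0, +1
    abs_med, _, sys_med, _, _, _ = error_summary(p)
    assert sys_med == 0.0
    assert abs_med == 1.0


def test_error_summary_sign_property():
    p = PairedMeasurements([2, 3, 4], [1, 2, 3])
    _, _, sys_med, _, _, _ = error_summary(p)
    assert sys_med > 0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 27), st.integers(3, 15))
def test_abs_median_dominates_sys_median(seed, n):
    rng = np.random.default_rng(seed)
    p = PairedMeasurements(rng.normal(size=n), rng.normal(size=n))
    abs_med, _, sys_med, _, _, _ = error_summary(p)
    assert abs(sys_med) <= abs_med + 1e-12


def test_ks_normality_detects_gross_nonnormality():
    rng = np.random.default_rng(2)
    normal = PairedMeasurements(rng.normal(0, 1, 500) + 40, np.full(500, 40.0))
    bimodal = PairedMeasurements(np.concatenate([rng.normal(-5, 0.1, 250),
                                                 rng.normal(5, 0.1, 250)]) + 40,
                                 np.full(500, 40.0))
    assert error_summary(normal)[4] > 0.05
    assert error_summary(bimodal)[4] < 0.01


# -- Diagnostic metrics ------------------------------------------------------

def test_clopper_pearson_sensitivity_37_of_42():
    lo, hi = clopper_pearson(37, 42)
    assert round(100 * lo, 1) == 74.4
    assert round(100 * hi, 1) == 96.0


def test_clopper_pearson_boundaries():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0


def test_clopper_pearson_coverage():
    """Empirical coverage >= nominal over seeded binomial replications."""
    n, p_true, reps = 42, 0.881, 10_000
    rng = np.random.default_rng(9)
    los, his = np.array([clopper_pearson(k, n) for k in range(n + 1)]).T
    ks = rng.binomial(n, p_true, size=reps)
    covered = (los[ks] <= p_true) & (p_true <= his[ks])
    assert covered.mean() >= 0.95


def test_diagnostic_metrics_perfect_detector():
    m = diagnostic_metrics(DiagnosticCounts(tp=10, fp=0, tn=12, fn=0))
    assert m.accuracy == 1.0
    assert m.accuracy_ci[1] == 1.0


def test_diagnostic_metrics_zero_denominator_flagged():
    m = diagnostic_metrics(DiagnosticCounts(tp=0, fp=0, tn=5, fn=0))
    assert m.sensitivity is None and m.flags


def test_ci_contains_point_estimate():
    m = diagnostic_metrics(DiagnosticCounts(tp=37, fn=5, tn=44, fp=2))
    for val, ci in [(m.sensitivity, m.sensitivity_ci),
                    (m.specificity, m.specificity_ci),
                    (m.accuracy, m.accuracy_ci)]:
        assert ci[0] <= val <= ci[1]


# -- plumbing ----------------------------------------------------------------

def test_paired_measurements_validation():
    with pytest.raises(InputError):
        PairedMeasurements([1, 2], [1, 2])          # < 3 pairs
    with pytest.raises(InputError):
        PairedMeasurements([1, 2, np.nan], [1, 2, 3])


def test_agreement_stats_bundle_consistency():
    rng = np.random.default_rng(1)
    m = rng.normal(40, 5, 50)
    a = m + rng.normal(0.5, 1.5, 50)
    s = agreement_stats(PairedMeasurements(a, m))
    assert s.loa_low <= s.bias <= s.loa_high
    assert s.icc <= 1.0
    assert 0 <= s.wilcoxon_p <= 1
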