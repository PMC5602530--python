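"""Hypothesis-test battery against hand values and independent oracles
(brute-force enumeration, scipy.stats, statsmodels)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from pdrkit.cohort import CohortSpec, cohort_to_dataframe, make_cohort
from pdrkit.stats import (
    analyze_cohort,
    exact_u_counts,
    fisher_exact_2x2,
    fit_logistic,
    kruskal_wallis,
    mann_whitney_u,
    pearson_chi2_2x2,
    pearson_correlation,
)
from pdrkit.volumes import ParameterError, SchemaError


# ------------------------------------------------------------- chi-squared

def test_chi2_gender_table_reproduces_printed_value():
    res = pearson_chi2_2x2([[34, 20], [22, 7]])
    assert res.statistic == pytest.approx(1.430, abs=5e-4)
    assert res.p_value == pytest.approx(0.232, abs=5e-4)
    assert res.df == 1


def test_chi2_hand_values_and_errors():
    assert pearson_chi2_2x2([[10, 10], [10, 10]]).statistic == 0.0
    assert pearson_chi2_2x2([[10, 10], [10, 10]]).p_value == 1.0
    assert pearson_chi2_2x2([[5, 0], [0, 5]]).statistic == pytest.approx(10.0)
    with pytest.raises(ParameterError):
        pearson_chi2_2x2([[0, 0], [3, 4]])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=40), min_size=4, max_size=4))
def test_chi2_invariant_under_transpose_and_swaps(cells):
    a, b, c, d = cells
    base = pearson_chi2_2x2([[a, b], [c, d]]).statistic
    for variant in ([[a, c], [b, d]], [[c, d], [a, b]], [[b, a], [d, c]]):
        assert pearson_chi2_2x2(variant).statistic == pytest.approx(base)


def test_chi2_matches_scipy_uncorrected():
    table = [[34, 20], [22, 7]]
    got = pearson_chi2_2x2(table)
    want = ss.chi2_contingency(np.array(table), correction=False)
    assert got.statistic == pytest.approx(want.statistic)
    assert got.p_value == pytest.approx(want.pvalue)


# ------------------------------------------------------------- Fisher exact

def _fisher_bruteforce(table):
    """Independent oracle: exact-integer hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    total = sum(v for v in probs.values() if v <= p_obs)
    return total / denom


def test_fisher_reproduces_printed_removal_and_location_pvalues():
    assert fisher_exact_2x2([[4, 52], [0, 27]]).p_value == pytest.approx(0.299, abs=5e-4)
    assert fisher_exact_2x2([[0, 56], [2, 25]]).p_value == pytest.approx(0.103, abs=5e-4)


def test_fisher_small_tables():
    assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)
    assert fisher_exact_2x2([[0, 5], [0, 5]]).p_value == 1.0  # degenerate margin


def test_fisher_equals_bruteforce_on_sampled_tables():
    rng = np.random.default_rng(4)
    for _ in range(200):
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            continue
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            _fisher_bruteforce(t.tolist()), abs=1e-12)


# ------------------------------------------------------------- Mann-Whitney

def _mwu_bruteforce(x, y):
    """Enumerate all rank assignments (no ties) for the exact two-sided p."""
    n1, n2 = len(x), len(y)
    ranks = ss.rankdata(np.concatenate([x, y]))
    u1_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min = min(u1_obs, n1 * n2 - u1_obs)
    total = 0
    hits = 0
    all_ranks = list(range(1, n1 + n2 + 1))
    for combo in itertools.combinations(all_ranks, n1):
        u1 = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if u1 <= u_min or u1 >= n1 * n2 - u_min:
            hits += 1
    return min(u1_obs, n1 * n2 - u1_obs), hits / total


def test_mwu_symmetric_samples():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.statistic == 4.5  # n1*n2/2


def test_mwu_exact_enumeration_example():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3)
    assert res.method == "mann_whitney_exact"


def test_mwu_exact_matches_bruteforce_small_samples():
    rng = np.random.default_rng(7)
    for n1 in range(2, 7):
        for n2 in range(2, 7):
            x = rng.permutation(100)[:n1 + n2].astype(float)
            u_want, p_want = _mwu_bruteforce(x[:n1], x[n1:])
            res = mann_whitney_u(x[:n1], x[n1:])
            assert res.statistic == pytest.approx(u_want)
            assert res.p_value == pytest.approx(p_want, abs=1e-12)


def test_mwu_counts_sum_to_binomial():
    counts = exact_u_counts(4, 5)
    assert counts.sum() == math.comb(9, 4)
    assert np.array_equal(counts, counts[::-1])  # symmetric distribution


def test_mwu_normal_approximation_close_to_scipy():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.4, 1, 35)
    res = mann_whitney_u(x, y)
    want = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(want.pvalue, rel=1e-6)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_mwu_shift_invariance(shift):
    x = [1.0, 5.0, 9.0]
    y = [2.0, 3.0, 11.0, 12.0]
    a = mann_whitney_u(x, y)
    b = mann_whitney_u([v + shift for v in x], [v + shift for v in y])
    assert a.statistic == b.statistic and a.p_value == b.p_value


def test_mwu_empty_sample_errors():
    with pytest.raises(ParameterError):
        mann_whitney_u([], [1.0])


# ------------------------------------------------------------- Kruskal-Wallis

def test_kruskal_wallis_values_and_invariances():
    assert kruskal_wallis([[1, 1], [1, 1], [1, 1]]).p_value == 1.0
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(4.571, abs=5e-4)
    assert res.df == 2
    perm = kruskal_wallis([[5, 6], [1, 2], [3, 4]])
    assert perm.statistic == pytest.approx(res.statistic)
    with pytest.raises(ParameterError):
        kruskal_wallis([[1, 2]])


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(13)
    groups = [rng.integers(0, 8, size=n).astype(float) for n in (9, 12, 7)]
    res = kruskal_wallis(groups)
    want = ss.kruskal(*groups)
    assert res.statistic == pytest.approx(want.statistic)
    assert res.p_value == pytest.approx(want.pvalue)


# ------------------------------------------------------------- correlation

def test_pearson_correlation_hand_values():
    assert pearson_correlation([1, 2, 3], [3, 5, 7]).statistic == pytest.approx(1.0)
    assert pearson_correlation([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)
    res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
    assert res.statistic == pytest.approx(0.8)
    want = ss.pearsonr([1, 2, 3, 4], [1, 3, 2, 4])
    assert res.p_value == pytest.approx(want.pvalue)
    with pytest.raises(ParameterError):
        pearson_correlation([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------- logistic

def test_logistic_intercept_only_closed_form():
    X = np.zeros((4, 0))
    fit = fit_logistic(X, [1, 1, 1, 0], feature_names=[])
    assert fit.coefficients["intercept"] == pytest.approx(math.log(3.0), abs=1e-6)


def test_logistic_single_binary_covariate_closed_form():
    x = np.array([1.0] * 15 + [0.0] * 15)
    y = np.array([1] * 10 + [0] * 5 + [1] * 4 + [0] * 11)
    fit = fit_logistic(x[:, None], y, feature_names=["exposed"])
    assert fit.coefficients["exposed"] == pytest.approx(math.log(5.5), abs=1e-6)
    assert fit.converged


def test_logistic_affine_reparameterization():
    rng = np.random.default_rng(3)
    age = rng.uniform(40, 90, 120)
    p = 1 / (1 + np.exp(-(-4.0 + 0.06 * age)))
    y = (rng.random(120) < p).astype(float)
    f1 = fit_logistic(age[:, None], y, feature_names=["age"])
    f2 = fit_logistic((age / 10.0)[:, None], y, feature_names=["age10"])
    assert f2.coefficients["age10"] == pytest.approx(
        10 * f1.coefficients["age"], rel=1e-4)
    assert f2.log_likelihood == pytest.approx(f1.log_likelihood, abs=1e-6)


def test_logistic_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 3))
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.0])
    y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y, feature_names=["a", "b", "c"])
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    got = [fit.coefficients[k] for k in ("intercept", "a", "b", "c")]
    assert np.allclose(got, sm_fit.params, atol=1e-6)
    got_se = [fit.std_errors[k] for k in ("intercept", "a", "b", "c")]
    assert np.allclose(got_se, sm_fit.bse, atol=1e-5)


def test_logistic_separation_is_flagged():
    x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.5, 1.5])
    y = (x > 0.4).astype(float)
    with pytest.warns(RuntimeWarning):
        fit = fit_logistic(x[:, None], y, feature_names=["x"])
    assert not fit.converged


def test_logistic_parameter_recovery_on_synthetic_cohorts():
    """Mean estimates over 20 seeds of n=500 within 10% of the truth."""
    truth = np.array([-1.0, 0.9, -0.6])
    estimates = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X = rng.normal(size=(500, 2))
        eta = truth[0] + X @ truth[1:]
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y, feature_names=["a", "b"])
        estimates.append([fit.coefficients["intercept"],
                          fit.coefficients["a"], fit.coefficients["b"]])
    mean_est = np.mean(estimates, axis=0)
    assert np.all(np.abs(mean_est - truth) <= 0.1 * np.abs(truth))


# ------------------------------------------------------------- cohort report

def _engineered_gender_cohort():
    """Cohort whose gender x PDR cross-tab is [[34, 20], [22, 7]]."""
    records = make_cohort(CohortSpec(n_patients=83), seed=1)
    df = cohort_to_dataframe(records)
    cells = [("M", True, 34), ("M", False, 20), ("F", True, 22), ("F", False, 7)]
    i = 0
    for gender, pdr, count in cells:
        for _ in range(count):
            df.loc[i, "gender"] = gender
            df.loc[i, "pdr_positive"] = pdr
            if not pdr:
                df.loc[i, "pdr_volume_cc"] = 0.0
            elif df.loc[i, "pdr_volume_cc"] == 0.0:
                df.loc[i, "pdr_volume_cc"] = 1.0
            i += 1
    return df


def test_analyze_cohort_reproduces_gender_chi2():
    df = _engineered_gender_cohort()
    report = analyze_cohort(df)
    test = report["variables"]["gender"]["test"]
    assert test["statistic"] == pytest.approx(1.430, abs=5e-4)
    assert test["p_value"] == pytest.approx(0.232, abs=5e-4)


def test_analyze_cohort_errors():
    with pytest.raises(SchemaError):
        analyze_cohort([])
    df = cohort_to_dataframe(make_cohort(CohortSpec(n_patients=20), seed=2))
    with pytest.raises(SchemaError, match="age"):
        analyze_cohort(df.drop(columns=["age"]))


def test_analyze_cohort_deterministic_bytes():
    import json

    df = cohort_to_dataframe(make_cohort(CohortSpec(), seed=6))
    a = json.dumps(analyze_cohort(df), sort_keys=True)
    b = json.dumps(analyze_cohort(df.copy()), sort_keys=True)
    assert a == b


def test_analyze_cohort_report_structure():
    df = cohort_to_dataframe(make_cohort(CohortSpec(n_patients=200), seed=8))
    report = analyze_cohort(df)
    assert report["n"] == 200
    model = report["logistic_model"]
    assert model is not None
    for name in ("male", "age_per_10y", "deep_location", "time_from_so_h",
                 "nihss_admission", "log_iph_volume"):
        assert name in model["odds_ratios"]
        lo, hi = model["wald_ci_95"][name]
        assert lo <= model["odds_ratios"][name] <= hi
    corr = report["variables"]["pdr_vs_iph_volume"]["test"]
    assert corr["statistic"] > 0  # positive rim-vs-clot volume coupling
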