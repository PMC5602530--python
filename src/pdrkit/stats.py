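"""Cohort statistics: the hypothesis-test battery and the multivariate
logistic model used for PDR-positive vs PDR-negative comparisons.

Everything is implemented directly (Pearson chi-squared without
continuity correction, two-sided Fisher exact with point-probability
ordering, Mann-Whitney U with exact small-sample enumeration, tie- and
continuity-corrected normal approximation otherwise, Kruskal-Wallis with
tie correction, product-moment correlation with the t-based p-value, and
maximum-likelihood logistic regression by iteratively reweighted least
squares with Wald intervals).  scipy supplies only the reference
distribution functions (chi2 / normal / t tail areas, hypergeometric
point probabilities).

The conventions are the ones that reproduce the printed contingency
statistics of the hyperacute-hemorrhage series this pipeline targets:
an uncorrected chi-squared (a Yates-corrected one would not give 1.430
on the gender table) and point-probability-ordered Fisher p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom, norm, rankdata
from scipy.stats import t as t_dist

from .volumes import ParameterError, SchemaError

ALPHA = 0.05  # two-sided significance threshold, no multiplicity correction


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ParameterError("contingency counts must be non-negative")
    return t


def pearson_chi2_rxc(table) -> TestResult:
    """Uncorrected Pearson chi-squared on an r x c contingency table."""
    t = _as_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if (rows == 0).any() or (cols == 0).any() or n == 0:
        raise ParameterError("chi-squared requires positive margins")
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(statistic=stat, df=df,
                      p_value=float(chi2_dist.sf(stat, df)),
                      method="pearson_chi2")


def pearson_chi2_2x2(table) -> TestResult:
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ParameterError("expected a 2x2 table")
    return pearson_chi2_rxc(t)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test with point-probability ordering.

    With margins fixed, the p-value is the sum of hypergeometric point
    probabilities of every table whose probability does not exceed that
    of the observed table (within a small relative tolerance).
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ParameterError("expected a 2x2 table")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        raise ParameterError("empty table")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = float(hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return TestResult(statistic=float(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]),
                      df=None, p_value=min(p, 1.0), method="fisher_exact")


def exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of tie-free rank assignments yielding each U1 value.

    Recurrence over the largest remaining rank: with i sample-1 and j
    sample-2 items, c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u) -- the
    largest item either belongs to sample 1 (beating all j sample-2
    items, so U1 gains j) or to sample 2 (U1 unchanged).  Equivalent to
    enumerating all C(n1+n2, n1) assignments.
    """
    size = n1 * n2 + 1
    cols = [np.zeros(size) for _ in range(n2 + 1)]   # i = 0 row
    for j in range(n2 + 1):
        cols[j][0] = 1.0
    for _i in range(1, n1 + 1):
        new = [np.zeros(size) for _ in range(n2 + 1)]
        new[0][0] = 1.0
        for j in range(1, n2 + 1):
            shifted = np.zeros(size)
            shifted[j:] = cols[j][:size - j]
            new[j] = shifted + new[j - 1]
        cols = new
    return cols[n2]


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U; reports U = min(U1, U2).

    Exact two-sided p by enumeration of rank assignments when the smaller
    sample has at most ``exact_max_n`` observations and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and min(n1, n2) <= exact_max_n:
        counts = exact_u_counts(n1, n2)
        total = counts.sum()
        k = int(round(u_min))
        p = (counts[:k + 1].sum() + counts[n1 * n2 - k:].sum()) / total
        return TestResult(statistic=float(u_min), df=None,
                          p_value=float(min(p, 1.0)), method="mann_whitney_exact")

    n = n1 + n2
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(statistic=float(u_min), df=None, p_value=1.0,
                          method="mann_whitney_normal")
    z = (u_min - n1 * n2 / 2.0 + 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return TestResult(statistic=float(u_min), df=None, p_value=p,
                      method="mann_whitney_normal")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-squared p on k-1 df."""
    groups = [np.asarray(g, np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need at least two non-empty groups")
    combined = np.concatenate(groups)
    n = combined.size
    ranks = rankdata(combined)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size].sum()
        h += r * r / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - float((tie_counts ** 3 - tie_counts).sum()) / (n ** 3 - n)
    if correction <= 0:   # all values identical
        return TestResult(statistic=0.0, df=len(groups) - 1, p_value=1.0,
                          method="kruskal_wallis")
    h /= correction
    df = len(groups) - 1
    return TestResult(statistic=float(h), df=df,
                      p_value=float(chi2_dist.sf(h, df)),
                      method="kruskal_wallis")


def pearson_correlation(x, y) -> TestResult:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired samples with n >= 3")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = math.sqrt(float(xm @ xm))
    sy = math.sqrt(float(ym @ ym))
    if sx == 0.0 or sy == 0.0:
        raise ParameterError("zero-variance sample")
    r = float(xm @ ym) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return TestResult(statistic=r, df=None, p_value=min(p, 1.0),
                      method="pearson_correlation")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% intervals.

    ``odds_ratios`` are exp(coefficient); the clinical source this
    pipeline mirrors labels these "HR", but no time-to-event model is
    involved.
    """

    feature_names: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    wald_ci_95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    converged: bool
    n_iterations: int
    log_likelihood: float
    std_errors: dict[str, float] = field(default_factory=dict)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically safe sum of y*eta - log(1 + exp(eta))
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_logistic(design, outcome, feature_names=None, add_intercept: bool = True,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Converges when the log-likelihood improves by less than ``tol``.
    Perfect separation never converges in finite coefficients; the fit is
    then flagged ``converged=False`` and the last iterate is reported
    with a warning.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(np.float64)
    else:
        X = np.asarray(design, np.float64)
        if X.ndim == 1:
            X = X[:, None]
        names = list(feature_names) if feature_names is not None else \
            [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcome, np.float64).ravel()
    if y.size != X.shape[0]:
        raise ParameterError("design and outcome lengths differ")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ParameterError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ParameterError("outcome must contain both classes")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    if X.shape[0] <= X.shape[1]:
        raise ParameterError("need more observations than coefficients")

    beta = np.zeros(X.shape[1])
    ll = _log_likelihood(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        xtwx = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(xtwx, grad, rcond=None)[0]
        # step-halving keeps the likelihood monotone
        new_ll = _log_likelihood(X @ (beta + step), y)
        halves = 0
        while new_ll < ll and halves < 30:
            step *= 0.5
            new_ll = _log_likelihood(X @ (beta + step), y)
            halves += 1
        beta = beta + step
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged or float(np.max(np.abs(beta))) > 30.0:
        converged = False
        warnings.warn("logistic fit did not converge (possible separation); "
                      "coefficients reported with Wald quantities unreliable",
                      RuntimeWarning, stacklevel=2)
        ll = _log_likelihood(X @ beta, y)

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(xtwx)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zcrit = float(norm.ppf(0.975))
    zs = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(zs))

    with np.errstate(over="ignore"):
        ors = np.exp(beta)
        ci_lo = np.exp(beta - zcrit * se)
        ci_hi = np.exp(beta + zcrit * se)
    return LogisticFit(
        feature_names=names,
        coefficients={n: float(b) for n, b in zip(names, beta)},
        odds_ratios={n: float(v) for n, v in zip(names, ors)},
        wald_ci_95={n: (float(lo), float(hi))
                    for n, lo, hi in zip(names, ci_lo, ci_hi)},
        p_values={n: float(pv) for n, pv in zip(names, pvals)},
        converged=converged,
        n_iterations=it,
        log_likelihood=float(ll),
        std_errors={n: float(s) for n, s in zip(names, se)},
    )


# ---------------------------------------------------------------------------
# cohort-level dispatch

_REQUIRED = ["age", "gender", "location", "time_from_so_bin", "onset_hours",
             "iph_volume_cc", "pdr_volume_cc", "pdr_positive",
             "nihss_admission", "nihss_discharge", "removal", "death"]

_CONTINUOUS_MWU = [("age", "age"), ("iph_volume_cc", "iph_volume_cc"),
                   ("nihss_admission", "nihss_admission"),
                   ("nihss_discharge", "nihss_discharge")]


def _median_iqr(v: np.ndarray) -> dict:
    if v.size == 0:
        return {"median": math.nan, "p25": math.nan, "p75": math.nan, "n": 0}
    p25, med, p75 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "p25": float(p25), "p75": float(p75),
            "n": int(v.size)}


def _tr(res: TestResult) -> dict:
    return {"statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "method": res.method, "significant": bool(res.p_value < ALPHA)}


def analyze_cohort(cohort, time_bins=None) -> dict:
    """Baseline-table comparison of PDR+ vs PDR- plus the multivariate model.

    ``cohort`` is a DataFrame or a list of PatientRecord.  The report maps
    each variable to per-group summaries and the appropriate named test
    (Mann-Whitney for continuous variables, chi-squared for gender and the
    onset-time bins, Fisher exact for location, removal and mortality,
    Kruskal-Wallis for rim size across onset bins, product-moment
    correlation for IPH vs rim volume) and fits the logistic model of PDR
    positivity on gender, age per 10-year interval, deep-vs-lobar
    location, onset-to-MRI time in hours, admission NIHSS and log IPH
    volume.  Deterministic given the cohort.
    """
    from .cohort import TIME_BINS, cohort_to_dataframe

    if not isinstance(cohort, pd.DataFrame):
        if len(cohort) == 0:
            raise SchemaError("empty cohort")
        cohort = cohort_to_dataframe(cohort)
    if cohort.shape[0] == 0:
        raise SchemaError("empty cohort")
    missing = [c for c in _REQUIRED if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    bins = tuple(time_bins) if time_bins is not None else TIME_BINS

    df = cohort
    pos = df[df["pdr_positive"].astype(bool)]
    neg = df[~df["pdr_positive"].astype(bool)]

    report: dict = {"n": int(df.shape[0]), "n_pdr_positive": int(pos.shape[0]),
                    "n_pdr_negative": int(neg.shape[0]),
                    "pdr_prevalence": float(pos.shape[0] / df.shape[0]),
                    "variables": {}}

    for col, name in _CONTINUOUS_MWU:
        entry = {"pdr_positive": _median_iqr(pos[col].to_numpy(float)),
                 "pdr_negative": _median_iqr(neg[col].to_numpy(float))}
        if len(pos) and len(neg):
            entry["test"] = _tr(mann_whitney_u(pos[col], neg[col]))
        report["variables"][name] = entry

    def crosstab(mask_series) -> np.ndarray:
        m = mask_series.astype(bool)
        p = df["pdr_positive"].astype(bool)
        return np.array([[int((m & p).sum()), int((m & ~p).sum())],
                         [int((~m & p).sum()), int((~m & ~p).sum())]])

    gender_tab = crosstab(df["gender"] == "M")
    report["variables"]["gender"] = {
        "table": gender_tab.tolist(),
        "test": _tr(pearson_chi2_2x2(gender_tab))
        if gender_tab.sum(axis=1).all() and gender_tab.sum(axis=0).all() else None,
    }

    supra_tab = crosstab(df["location"] != "infratentorial")
    report["variables"]["location_supra_vs_infra"] = {
        "table": supra_tab.tolist(), "test": _tr(fisher_exact_2x2(supra_tab))}
    for col in ("removal", "death"):
        tab = crosstab(df[col])
        report["variables"][col] = {"table": tab.tolist(),
                                    "test": _tr(fisher_exact_2x2(tab))}

    time_counts = np.array(
        [[int((pos["time_from_so_bin"] == b).sum()) for b in bins],
         [int((neg["time_from_so_bin"] == b).sum()) for b in bins]]).T
    keep = time_counts.sum(axis=1) > 0
    entry = {"table": time_counts.tolist()}
    if keep.sum() >= 2 and (time_counts.sum(axis=0) > 0).all():
        entry["test"] = _tr(pearson_chi2_rxc(time_counts[keep]))
    report["variables"]["time_from_so_bin"] = entry

    groups = [pos.loc[pos["time_from_so_bin"] == b, "pdr_volume_cc"].to_numpy(float)
              for b in bins]
    groups = [g for g in groups if g.size > 0]
    if len(groups) >= 2:
        report["variables"]["pdr_volume_by_time"] = {"test": _tr(kruskal_wallis(groups))}
    if len(pos) >= 3 and pos["iph_volume_cc"].nunique() > 1 \
            and pos["pdr_volume_cc"].nunique() > 1:
        report["variables"]["pdr_vs_iph_volume"] = {
            "test": _tr(pearson_correlation(pos["iph_volume_cc"],
                                            pos["pdr_volume_cc"]))}

    # multivariate model: supratentorial cases only (location enters as
    # deep vs lobar, matching the source model)
    sup = df[df["location"] != "infratentorial"]
    model = None
    if sup["pdr_positive"].astype(bool).nunique() == 2:
        design = pd.DataFrame({
            "male": (sup["gender"] == "M").astype(float),
            "age_per_10y": sup["age"].astype(float) / 10.0,
            "deep_location": (sup["location"] == "deep").astype(float),
            "time_from_so_h": sup["onset_hours"].astype(float),
            "nihss_admission": sup["nihss_admission"].astype(float),
            "log_iph_volume": np.log(sup["iph_volume_cc"].astype(float)),
        })
        fit = fit_logistic(design, sup["pdr_positive"].astype(float))
        model = {
            "n": int(sup.shape[0]),
            "converged": fit.converged,
            "coefficients": fit.coefficients,
            "odds_ratios": fit.odds_ratios,
            "odds_ratio_label": "OR (reported as HR in source)",
            "wald_ci_95": {k: list(v) for k, v in fit.wald_ci_95.items()},
            "p_values": fit.p_values,
        }
    report["logistic_model"] = model
    return report
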