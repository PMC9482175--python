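"""Statistical battery: association tests with the chi-square/Fisher
selection rule, log-density comparisons and correlations, Kaplan-Meier,
log-rank and Cox proportional-hazards regression.

Conventions (all tests two-sided, alpha = 0.05, no multiplicity
correction):

* Pearson chi-square carries the Yates continuity correction on 2x2
  tables and is uncorrected on larger tables;
* Fisher's exact test is chosen whenever any expected cell count is
  below 5; for tables larger than 2x2 the exact p is computed by full
  enumeration over tables with fixed margins (Monte-Carlo fallback for
  large supports);
* density log transforms use log(x + 1), guarding zero densities;
* Cox ties are handled with the Efron approximation by default
  (Breslow available), maximised by Newton-Raphson with Wald CIs.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .types import CoxFit, SurvivalRecord, TestResult

__all__ = [
    "chi_square_test", "fisher_exact_test", "select_association_test",
    "expected_counts", "log_offset_transform", "paired_t_test",
    "pearson_log_correlation", "two_sample_t_test", "kruskal_wallis",
    "kaplan_meier", "median_follow_up", "log_rank_test", "cox_fit",
    "run_association_battery",
]


# ---------------------------------------------------------------- tables

def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("contingency table must be a 2-D array of counts")
    return t


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def chi_square_test(table) -> TestResult:
    """Pearson chi-square; Yates-corrected for 2x2, uncorrected otherwise.

    Degenerate tables (a zero row/column margin) return p = 1 with a flag
    rather than raising.
    """
    t = _as_table(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    correction = t.shape == (2, 2)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin: chi-square degenerate, p = 1", stacklevel=2)
        df = (t.shape[0] - 1) * (t.shape[1] - 1)
        return TestResult("chi_square", 0.0, 1.0, degrees_of_freedom=df,
                          continuity_correction=correction, flags=("zero_margin",))
    stat, p, df, _ = sps.chi2_contingency(t, correction=correction)
    return TestResult("chi_square", float(stat), float(p),
                      degrees_of_freedom=float(df),
                      continuity_correction=correction)


def _log_table_prob(t: np.ndarray, lgr: np.ndarray, lgc: np.ndarray,
                    lgn: float) -> float:
    # P(T) = prod(r_i!) prod(c_j!) / (N! prod(t_ij!))
    return float(lgr.sum() + lgc.sum() - lgn - gammaln(t + 1).sum())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i, remaining_cols):
        if i == r - 1:
            table[i] = remaining_cols
            yield table
            return
        def fill_row(j, left, rem):
            if j == c - 1:
                if left <= rem[j]:
                    table[i, j] = left
                    yield True
                return
            lo = max(0, left - int(rem[j + 1:].sum()))
            hi = min(left, rem[j])
            for v in range(lo, hi + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v, rem)
        for _ in fill_row(0, int(row_sums[i]), remaining_cols):
            yield from fill(i + 1, remaining_cols - table[i])

    yield from fill(0, np.asarray(col_sums, dtype=np.int64).copy())


def fisher_exact_test(table, max_enumeration: int = 2_000_000,
                      mc_samples: int = 200_000, seed: int = 0) -> TestResult:
    """Fisher's exact test; two-sided by summation of table probabilities
    not exceeding that of the observed table.

    2x2 tables go through the hypergeometric distribution.  Larger tables
    are handled by full enumeration over the fixed-margin support; if the
    support is too large, a Monte-Carlo estimate over Patefield-sampled
    tables is returned (flagged, with the simulation standard error).
    """
    t = _as_table(table).astype(np.int64)
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult("fisher_exact", float("nan"), float(min(p, 1.0)))

    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return TestResult("fisher_exact", float("nan"), 1.0, flags=("zero_margin",))
    lgr = gammaln(row_sums + 1)
    lgc = gammaln(col_sums + 1)
    lgn = float(gammaln(t.sum() + 1))
    logp_obs = _log_table_prob(t, lgr, lgc, lgn)

    # support size bound: product over free cells of (margin + 1)
    bound = 1
    for rs in row_sums[:-1]:
        for cs in col_sums[:-1]:
            bound *= min(rs, cs) + 1
            if bound > max_enumeration:
                break
        if bound > max_enumeration:
            break

    if bound <= max_enumeration:
        p = 0.0
        for cand in _enumerate_tables(row_sums, col_sums):
            lp = _log_table_prob(cand, lgr, lgc, lgn)
            if lp <= logp_obs + 1e-9:
                p += math.exp(lp)
        return TestResult("fisher_exact", float("nan"), float(min(p, 1.0)))

    rng = np.random.default_rng(seed)
    dist = sps.random_table(row_sums, col_sums)
    samples = dist.rvs(mc_samples, random_state=rng)
    lps = np.array([_log_table_prob(s, lgr, lgc, lgn) for s in samples])
    hits = lps <= logp_obs + 1e-9
    p = float(hits.mean())
    se = float(hits.std(ddof=1) / np.sqrt(mc_samples))
    warnings.warn(f"Fisher support too large; Monte-Carlo p (se {se:.2e})",
                  stacklevel=2)
    return TestResult("fisher_exact_mc", float("nan"), p,
                      flags=(f"mc_se={se:.3e}",))


def select_association_test(table) -> TestResult:
    """Chi-square unless any expected cell count is below 5, then Fisher.

    The choice is recorded in the result's ``method``.
    """
    t = _as_table(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("degenerate table: need at least 2 rows and 2 columns")
    if np.any(expected_counts(t) < 5):
        return fisher_exact_test(t)
    return chi_square_test(t)


# ------------------------------------------------------- scale comparisons

def log_offset_transform(density) -> np.ndarray:
    """Natural log of (density + 1); densities must be non-negative."""
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("densities must be non-negative")
    return np.log(d + 1.0)


def paired_t_test(values_close, values_distant) -> TestResult:
    """Paired t-test on (already log-transformed) density pairs."""
    a = np.asarray(values_close, dtype=float)
    b = np.asarray(values_distant, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return TestResult("paired_t", 0.0, 1.0, degrees_of_freedom=a.size - 1)
        return TestResult("paired_t", float("inf"), 0.0,
                          degrees_of_freedom=a.size - 1,
                          flags=("zero_variance_nonzero_mean",))
    stat, p = sps.ttest_rel(a, b)
    return TestResult("paired_t", float(stat), float(p),
                      degrees_of_freedom=a.size - 1)


def pearson_log_correlation(densities_a, densities_b) -> tuple[float, float]:
    """Pearson correlation of log(x + 1) values; two-sided p."""
    a = log_offset_transform(densities_a)
    b = log_offset_transform(densities_b)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def two_sample_t_test(group_a, group_b, equal_var: bool = True) -> TestResult:
    """Student t-test (pooled variance by default), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    stat = 0.0 if np.isnan(stat) else float(stat)
    p = 1.0 if np.isnan(p) else float(p)
    return TestResult("t_test", stat, p, degrees_of_freedom=a.size + b.size - 2)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square approximation."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0,
                          degrees_of_freedom=len(groups) - 1,
                          flags=("all_identical",))
    stat, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      degrees_of_freedom=len(groups) - 1)


# ------------------------------------------------------------- survival

def _records_to_arrays(records: list[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def kaplan_meier(records: list[SurvivalRecord]):
    """Product-limit survival estimator (lifelines fitter)."""
    if not records:
        raise ValueError("no survival records")
    from lifelines import KaplanMeierFitter

    t, e = _records_to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return kmf


def median_follow_up(records: list[SurvivalRecord]) -> float:
    """Median follow-up by reverse Kaplan-Meier (censor/event swapped)."""
    from lifelines import KaplanMeierFitter

    t, e = _records_to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=1 - e)
    return float(kmf.median_survival_time_)


def log_rank_test(records: list[SurvivalRecord], groups) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df, two-sided)."""
    from lifelines.statistics import logrank_test as ll_logrank

    t, e = _records_to_arrays(records)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank here compares exactly two groups")
    if e.sum() == 0:
        warnings.warn("no events: log-rank undefined", stacklevel=2)
        return TestResult("log_rank", float("nan"), float("nan"),
                          flags=("no_events",))
    m = g == labels[0]
    res = ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return TestResult("log_rank", float(res.test_statistic), float(res.p_value),
                      degrees_of_freedom=1.0)


def _cox_loglik(beta, times, events, X, ties_method):
    """Negative log partial likelihood with gradient and Hessian."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    times, events, X = times[order], events[order], X[order]
    n, k = X.shape
    eta = X @ beta
    theta = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))

    # running risk-set accumulators (times decreasing => risk set grows)
    s0 = 0.0
    s1 = np.zeros(k)
    s2 = np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        for idx in range(i, j):
            s0 += theta[idx]
            s1 += theta[idx] * X[idx]
            s2 += theta[idx] * np.outer(X[idx], X[idx])
        ev = [idx for idx in range(i, j) if events[idx] == 1]
        d = len(ev)
        if d:
            xd = X[ev]
            td = theta[ev]
            loglik += eta[ev].sum()
            if ties_method == "breslow":
                for _ in range(d):
                    loglik -= math.log(s0)
                    grad -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
                grad += xd.sum(axis=0)
            else:  # efron
                t0 = td.sum()
                t1 = (td[:, None] * xd).sum(axis=0)
                t2 = np.einsum("i,ij,ik->jk", td, xd, xd)
                for ell in range(d):
                    f = ell / d
                    z0 = s0 - f * t0
                    z1 = s1 - f * t1
                    z2 = s2 - f * t2
                    loglik -= math.log(z0)
                    grad -= z1 / z0
                    hess -= z2 / z0 - np.outer(z1, z1) / z0 ** 2
                grad += xd.sum(axis=0)
        i = j
    return loglik, grad, hess


def cox_fit(
    records: list[SurvivalRecord],
    covariates: list[str] | tuple[str, ...],
    ties_method: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Covariate values are taken from each record's ``covariates`` mapping.
    Ties are handled by the Efron approximation (default) or Breslow.
    Confidence intervals and p-values are Wald-based.  Monotone likelihood
    (complete separation) and non-convergence are flagged, not raised.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError("ties_method must be 'efron' or 'breslow'")
    if not records:
        raise ValueError("no survival records")
    times, events = _records_to_arrays(records)
    X = np.array([[float(r.covariates[c]) for c in covariates] for r in records])
    n, k = X.shape
    n_events = int(events.sum())
    flags = []
    if n_events == 0:
        raise ValueError("no events: Cox model undefined")

    # centre covariates for numerical stability (does not change beta)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean

    beta = np.zeros(k)
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        loglik, grad, hess = _cox_loglik(beta, times, events, Xc, ties_method)
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        # step-halving if the likelihood would decrease
        alpha = 1.0
        for _ in range(20):
            cand = beta + alpha * step
            ll_new, _, _ = _cox_loglik(cand, times, events, Xc, ties_method)
            if ll_new >= loglik - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if np.max(np.abs(alpha * step)) < tol:
            converged = True
            loglik, grad, hess = _cox_loglik(beta, times, events, Xc, ties_method)
            break
    if not converged:
        flags.append("no_convergence")
    if np.any(np.abs(beta) > 15):
        flags.append("monotone_likelihood")

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        flags.append("singular_information")

    return CoxFit(
        covariates=tuple(covariates), coef=beta, se=se,
        log_likelihood=float(loglik), ties_method=ties_method,
        converged=converged, n=n, n_events=n_events, flags=tuple(flags))


# ------------------------------------------------------- battery

#: how each clinicopathological variable is compared across marker groups
DEFAULT_VARIABLE_TYPES = {
    "age": "scale_parametric",
    "tbc_percent_expanding": "scale_nonparametric",
    "gender": "categorical",
    "tnm_stage": "categorical",
    "pT": "categorical",
    "pN": "categorical",
    "venous_invasion": "categorical",
    "postop_chemo": "categorical",
}


def run_association_battery(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    variable_types: dict | None = None,
    group_columns: tuple = ("CD8_group", "GZMB_group", "CD68_group"),
) -> pd.DataFrame:
    """Cross every clinicopathological variable with every marker group.

    Categorical variables go through the chi-square/Fisher selection rule
    on the crosstab; parametric scale variables through a two-sample
    t-test; non-parametric scale variables through Kruskal-Wallis.
    Complete cases per test; per-test n is reported.  Variables with a
    single observed level are skipped with a warning.
    """
    variable_types = variable_types or DEFAULT_VARIABLE_TYPES
    merged = scores.merge(clinical, on="patient_id", how="inner")
    rows = []
    for gcol in group_columns:
        if gcol not in merged.columns:
            continue
        for var, vtype in variable_types.items():
            if var not in merged.columns:
                continue
            sub = merged[[gcol, var]].dropna()
            if sub.empty or sub[gcol].nunique() < 2:
                continue
            if vtype == "categorical":
                if sub[var].nunique() < 2:
                    warnings.warn(f"{var}: single level, skipped", stacklevel=2)
                    continue
                tab = pd.crosstab(sub[var], sub[gcol])
                res = select_association_test(tab.to_numpy())
            else:
                groups = [g[var].to_numpy(dtype=float)
                          for _, g in sub.groupby(gcol, sort=True)]
                if vtype == "scale_parametric":
                    res = two_sample_t_test(groups[0], groups[1])
                else:
                    res = kruskal_wallis(*groups)
            rows.append({
                "marker_group": gcol, "variable": var, "method": res.method,
                "statistic": res.statistic, "p_value": res.p_value,
                "n": int(len(sub)),
            })
    return pd.DataFrame(rows)
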