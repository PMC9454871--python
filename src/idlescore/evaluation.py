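"""Survival-analysis evaluation of risk scores.

Implements the prediction-accuracy toolkit used on the LOOCV risk scores:
Kaplan-Meier estimation, time-dependent (cumulative-case / dynamic-control)
sensitivity, specificity and AUC with inverse-probability-of-censoring
weighting (IPCW, censoring distribution by reverse Kaplan-Meier), bootstrap
AUC standard deviations, Bayes-rule time-dependent PPV/NPV, the
HR-maximising high-risk cutoff, multivariate Cox regression (Breslow ties),
and two-group cohort comparison tables (Welch t-test / Fisher exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_estimate(time, event):
    """Kaplan-Meier product-limit estimate of survival.

    Returns a fitted ``lifelines.KaplanMeierFitter``; evaluate with
    ``km_survival_at(km, t)`` (right-continuous step function).
    """
    from lifelines import KaplanMeierFitter

    time, event = _check_survival(time, event)
    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    return km

def km_survival_at(km, t) -> float:
    return float(km.predict(float(t)))


def censoring_survival(time, event):
    """Reverse Kaplan-Meier estimate G of the censoring distribution."""
    from lifelines import KaplanMeierFitter

    time, event = _check_survival(time, event)
    g = KaplanMeierFitter()
    g.fit(time, event_observed=1 - event)
    return g


def _censoring_left(time, event, at) -> np.ndarray:
    """Left limits G(t-) of the reverse Kaplan-Meier censoring survival.

    Vectorised product-limit over censoring times (event == 0); equivalent
    to fitting a Kaplan-Meier to the censoring indicator and evaluating just
    below each requested time.
    """
    time = np.asarray(time, dtype=float)
    cens_times = np.sort(time[np.asarray(event) == 0])
    if cens_times.size == 0:
        return np.ones(len(np.atleast_1d(at)))
    tc, dc = np.unique(cens_times, return_counts=True)
    n_at_risk = time.size - np.searchsorted(np.sort(time), tc, side="left")
    factors = 1.0 - dc / n_at_risk
    g_steps = np.concatenate(([1.0], np.cumprod(factors)))
    idx = np.searchsorted(tc, np.atleast_1d(np.asarray(at, dtype=float)),
                          side="left")
    return g_steps[idx]


def td_confusion(scores, time, event, t, cutoff):
    """IPCW time-dependent sensitivity and specificity at one cutoff.

    Cases are patients with an observed event by ``t`` (weighted 1/G(T-));
    controls are patients still at risk beyond ``t`` (uniform weights, so
    the IPCW factors cancel).  A test is positive when score > cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _check_survival(time, event)
    case = (event == 1) & (time <= t)
    ctrl = time > t
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError(f"no cases or no controls at t={t}")
    w = np.zeros_like(scores)
    gl = _censoring_left(time, event, time)
    w[case] = 1.0 / np.maximum(gl[case], 1e-12)
    pos = scores > cutoff
    sens = float(w[case & pos].sum() / w[case].sum())
    spec = float((ctrl & ~pos).sum() / ctrl.sum())
    return sens, spec


def td_auc_point(scores, time, event, t) -> float:
    """IPCW cumulative/dynamic time-dependent AUC at horizon ``t``.

    Concordance of (case, control) pairs with case weights 1/G(T-); with no
    censoring this reduces exactly to the empirical AUC for event-by-t
    labels.  Ties in score count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _check_survival(time, event)
    case = (event == 1) & (time <= t)
    ctrl = time > t
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError(f"no comparable case/control pairs at t={t}")
    w = 1.0 / np.maximum(_censoring_left(time, event, time[case]), 1e-12)
    sc, st = scores[case], scores[ctrl]
    gt = (sc[:, None] > st[None, :]).sum(axis=1)
    eq = (sc[:, None] == st[None, :]).sum(axis=1)
    conc = np.sum(w * (gt + 0.5 * eq))
    return float(conc / (w.sum() * st.size))


@dataclass(frozen=True)
class TdAUC:
    t: float
    auc: float
    sd: float
    n_boot: int


def td_auc(scores, time, event, t, n_boot: int = 500, seed: int = 0) -> TdAUC:
    """Time-dependent AUC with a patient-level bootstrap standard deviation.

    The SD is the standard deviation of the IPCW AUC over ``n_boot``
    resamples of patients; degenerate resamples (no cases or no controls)
    are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _check_survival(time, event)
    point = td_auc_point(scores, time, event, t)
    rng = np.random.default_rng(seed)
    n = scores.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(td_auc_point(scores[idx], time[idx], event[idx], t))
        except ValueError:
            continue
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return TdAUC(float(t), point, sd, n_boot)


def td_ppv_npv(scores, time, event, t, sensitivity_grid) -> pd.DataFrame:
    """Bayes-rule time-dependent PPV/NPV along a target-sensitivity grid.

    PPV(t) = sensitivity(t) * (1 - S(t)) / P(test positive) and
    NPV(t) = specificity(t) * S(t) / P(test negative), with S(t) the
    Kaplan-Meier progression-free survival.  For each target sensitivity the
    cutoff maximising specificity subject to sensitivity >= target is used
    (ties resolved toward higher sensitivity); unreachable targets are
    reported as non-evaluable rows.
    """
    grid = np.asarray(sensitivity_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sensitivity grid")
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("target sensitivities must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    time, event = _check_survival(time, event)
    s_t = km_survival_at(km_estimate(time, event), t)
    cuts = np.unique(scores)
    cand = np.concatenate(([-np.inf], cuts))
    table = []
    sens_spec = [td_confusion(scores, time, event, t, c) for c in cand]
    for target in grid:
        best = None
        for c, (sens, spec) in zip(cand, sens_spec):
            if sens < target:
                continue
            if best is None or (spec, sens) > (best[2], best[1]):
                best = (c, sens, spec)
        if best is None:
            table.append({"target_sensitivity": target, "evaluable": False,
                          "cutoff": np.nan, "sensitivity": np.nan,
                          "specificity": np.nan, "ppv": np.nan, "npv": np.nan})
            continue
        c, sens, spec = best
        p_pos = float(np.mean(scores > c))
        p_neg = 1.0 - p_pos
        ppv = sens * (1.0 - s_t) / p_pos if p_pos > 0 else np.nan
        npv = spec * s_t / p_neg if p_neg > 0 else np.nan
        table.append({"target_sensitivity": target, "evaluable": True,
                      "cutoff": c, "sensitivity": sens, "specificity": spec,
                      "ppv": ppv, "npv": npv})
    return pd.DataFrame(table)


def _phreg_fit(X: np.ndarray, time, event, names):
    """Cox partial-likelihood fit with Breslow tie handling."""
    import statsmodels.api as sm

    model = sm.PHReg(np.asarray(time, dtype=float), X,
                     status=np.asarray(event, dtype=int), ties="breslow")
    try:
        fit = model.fit(disp=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"Cox model failed (separation/collinearity?): {exc}") from exc
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise ValueError("Cox model failed to converge (separation/collinearity?)")
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "covariate": names,
        "coef": fit.params,
        "hr": np.exp(fit.params),
        "ci_low": np.exp(fit.params - z * fit.bse),
        "ci_high": np.exp(fit.params + z * fit.bse),
        "p": 2 * stats.norm.sf(np.abs(fit.params / fit.bse)),
    }).reset_index(drop=True)


def _cox_binary(group, time, event):
    tab = _phreg_fit(np.asarray(group, dtype=float)[:, None], time, event, ["g"])
    r = tab.iloc[0]
    return float(r["hr"]), float(r["ci_low"]), float(r["ci_high"]), float(r["p"])


def optimal_cutoff_hr(scores, time, event, quantile_range=(0.10, 0.90),
                      step: float = 0.01, min_group: int = 10) -> dict:
    """High/low-risk cutoff maximising the univariate Cox hazard ratio.

    Cutoffs are scanned over the score quantiles in ``quantile_range`` (1%
    steps); partitions leaving fewer than ``min_group`` patients on either
    side are skipped; ties go to the smaller cutoff.  Also reports the
    logrank p of the chosen partition.
    """
    from lifelines.statistics import logrank_test

    scores = np.asarray(scores, dtype=float)
    time, event = _check_survival(time, event)
    if np.unique(scores).size < 2:
        raise ValueError("degenerate input: constant scores")
    qs = np.arange(quantile_range[0], quantile_range[1] + 1e-9, step)
    best = None
    seen = set()
    for q in qs:
        c = float(np.quantile(scores, q))
        key = float(np.round(c, 12))
        if key in seen:
            continue
        seen.add(key)
        g = scores > c
        if g.sum() < min_group or (~g).sum() < min_group:
            continue
        if event[g].sum() == 0 or event[~g].sum() == 0:
            continue
        try:
            hr, lo, hi, p = _cox_binary(g, time, event)
        except Exception:
            continue
        if best is None or hr > best["hr"]:
            best = {"cutoff": c, "hr": hr, "ci_low": lo, "ci_high": hi, "cox_p": p}
    if best is None:
        raise ValueError("no admissible cutoff (groups too small or no events)")
    g = scores > best["cutoff"]
    lr = logrank_test(time[g], time[~g], event[g], event[~g])
    best["logrank_p"] = float(lr.p_value)
    return best


def cox_multivariate(data: pd.DataFrame, duration_col: str = "time",
                     event_col: str = "event", covariates=None) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Breslow ties).

    Returns a table with one row per covariate: HR, Wald 95% CI and p.
    """
    cols = list(covariates) if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)]
    df = data[cols + [duration_col, event_col]].astype(float)
    if int(df[event_col].sum()) < len(cols):
        raise ValueError("fewer events than covariates")
    if np.linalg.matrix_rank(df[cols].to_numpy()) < len(cols):
        raise ValueError("design matrix is rank deficient (collinearity)")
    return _phreg_fit(df[cols].to_numpy(), df[duration_col], df[event_col], cols)


def fisher_or_chi2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table; chi-square for larger."""
    table = np.asarray(table)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def cohort_summary(patients: pd.DataFrame, outcomes: pd.DataFrame,
                   variables=None) -> pd.DataFrame:
    """Two-group comparison of baseline variables by progression status.

    Continuous variables: group mean +/- SD and a two-sided Welch t-test.
    Categorical variables: counts and a two-sided Fisher exact test (2x2) or
    chi-square test (larger tables).
    """
    merged = patients.merge(outcomes[["patient_id", "event"]], on="patient_id")
    grp1 = merged[merged["event"] == 1]
    grp0 = merged[merged["event"] == 0]
    if len(grp1) == 0 or len(grp0) == 0:
        raise ValueError("both progression groups must be non-empty")
    if variables is None:
        variables = [c for c in patients.columns if c != "patient_id"]
    rows = []
    for var in variables:
        col = merged[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2 \
                and not pd.api.types.is_bool_dtype(col):
            p = float(stats.ttest_ind(grp1[var], grp0[var], equal_var=False).pvalue)
            rows.append({
                "variable": var, "type": "continuous",
                "progression": f"{grp1[var].mean():.1f} ± {grp1[var].std():.1f}",
                "no_progression": f"{grp0[var].mean():.1f} ± {grp0[var].std():.1f}",
                "p": p})
        else:
            tab = pd.crosstab(merged[var], merged["event"])
            if tab.shape[0] < 2:
                p = np.nan
            else:
                p = fisher_or_chi2(tab.to_numpy())
            rows.append({
                "variable": var, "type": "categorical",
                "progression": " / ".join(f"{k}:{v}" for k, v in
                                          grp1[var].value_counts().sort_index().items()),
                "no_progression": " / ".join(f"{k}:{v}" for k, v in
                                             grp0[var].value_counts().sort_index().items()),
                "p": p})
    return pd.DataFrame(rows)
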