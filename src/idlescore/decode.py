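"""Decoding the fitted network: what drives the risk score.

After refitting the network on the full cohort, input features are ranked by
how often the hidden layers select them (surviving magnitude pruning,
counted across both layers through chained nonzero paths).  The most
selected variables are dichotomised at their HR-maximising thresholds and
tested by logrank against progression, local recurrence, and distant
metastasis.  Input variables and hidden-layer activations are screened
univariately against progression status (Welch t-test for continuous
variables, chi-square for discrete ones, Fisher exact when expected counts
are small), the top 25 are standardized to z-scores (population SD) for
heatmap export, and single-platform ablation scores are compared with the
integrated score through time-dependent ROC analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ct.registry import FEATURE_NAMES as CT_FEATURE_NAMES
from .evaluation import optimal_cutoff_hr, td_auc
from .model import IDLEResults, event_by_horizon_labels
from .tissue import TISSUE_COLUMNS

ENDPOINTS = ("progression", "local_recurrence", "distant_metastasis")


def platform_tag(feature: str) -> str:
    if feature in CT_FEATURE_NAMES:
        return "CT"
    if feature in TISSUE_COLUMNS:
        return "tissue"
    return "clinical"


def _median_split_logrank_p(values, time, event) -> float:
    from lifelines.statistics import logrank_test

    v = np.asarray(values, dtype=float)
    g = v > np.median(v)
    if g.sum() == 0 or (~g).sum() == 0:
        return 1.0
    return float(logrank_test(time[g], time[~g], event[g], event[~g]).p_value)


def refit_full_and_rank(results: IDLEResults, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Selection-frequency feature ranking of a full-cohort fit.

    Rank 1 is the most frequently selected input variable; ties are broken
    by the univariate median-split logrank p, then by name.
    """
    counts = results.trace.selection_counts
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    X = results.model.X
    tie_p = {f: _median_split_logrank_p(X[f], time, event) if counts[f] > 0 else 1.0
             for f in counts.index}
    rank_df = pd.DataFrame({
        "feature": counts.index,
        "selection_count": counts.to_numpy(),
        "logrank_p": [tie_p[f] for f in counts.index],
        "platform": [platform_tag(f) for f in counts.index],
    })
    rank_df = rank_df.sort_values(
        by=["selection_count", "logrank_p", "feature"],
        ascending=[False, True, True]).reset_index(drop=True)
    rank_df["rank"] = np.arange(1, len(rank_df) + 1)
    return rank_df


def endpoint_survival(outcomes: pd.DataFrame, endpoint: str):
    """(time, event) for one endpoint; competing causes are censored."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    if endpoint == "progression":
        return time, event
    cause = outcomes["cause"].astype(str).to_numpy()
    return time, ((event == 1) & (cause == endpoint)).astype(int)


def dichotomize_max_hr(values, outcomes: pd.DataFrame,
                       endpoint: str = "progression", min_group: int = 10) -> dict:
    """HR-maximising dichotomisation of one feature for one endpoint."""
    time, event = endpoint_survival(outcomes, endpoint)
    if event.sum() == 0:
        raise ValueError(f"no {endpoint} events to test against")
    out = optimal_cutoff_hr(np.asarray(values, dtype=float), time, event,
                            min_group=min_group)
    out["endpoint"] = endpoint
    return out


def _screen_p(values: np.ndarray, labels: np.ndarray) -> tuple[float, str]:
    v = np.asarray(values, dtype=float)
    uniq = np.unique(v)
    if uniq.size < 2:
        return np.nan, "constant"
    if uniq.size <= 5 and np.allclose(uniq, np.round(uniq)):
        tab = pd.crosstab(v, labels).to_numpy()
        expected = stats.contingency.expected_freq(tab)
        if expected.min() < 5 and tab.shape == (2, 2):
            return float(stats.fisher_exact(tab)[1]), "fisher"
        return float(stats.chi2_contingency(tab, correction=False)[1]), "chi2"
    return float(stats.ttest_ind(v[labels == 1], v[labels == 0],
                                 equal_var=False).pvalue), "welch_t"


def hidden_layer_table(results: IDLEResults) -> pd.DataFrame:
    """Named hidden-layer activations (both layers) for every patient."""
    A1, H2 = results.hidden_activations(results.model.X)
    cols = {f"h1_{i+1:03d}": A1[:, i] for i in range(A1.shape[1])}
    cols.update({f"h2_{i+1:03d}": H2[:, i] for i in range(H2.shape[1])})
    return pd.DataFrame(cols, index=results.model.X.index)


def univariate_screen(X: pd.DataFrame, labels, top: int = 25) -> pd.DataFrame:
    """Per-variable association with progression status.

    Welch t-test for continuous variables, chi-square (Fisher exact when a
    2x2 table has small expected counts) for discrete ones; returns all
    variables sorted by ascending p with the top ``top`` flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes are required")
    rows = []
    for c in X.columns:
        p, test = _screen_p(X[c].to_numpy(), labels)
        rows.append({"variable": c, "p": p, "test": test})
    out = pd.DataFrame(rows).sort_values(by=["p", "variable"],
                                         na_position="last").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top
    return out


def zscore_heatmap_matrix(X: pd.DataFrame, variables=None) -> pd.DataFrame:
    """z-score matrix (variables x patients) for heatmap export.

    z = (value - mean over all patients) / population SD, applied per
    variable; constant variables are dropped with a warning.
    """
    cols = list(variables) if variables is not None else list(X.columns)
    rows = {}
    for c in cols:
        v = X[c].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"dropping constant variable {c!r} from z-score matrix",
                          stacklevel=2)
            continue
        rows[c] = (v - v.mean()) / sd
    if not rows:
        raise ValueError("all requested variables are constant")
    return pd.DataFrame(rows, index=X.index).T


def synergy_report(scores_by_platform: dict, outcomes: pd.DataFrame,
                   horizons=(5.0, 10.0), n_boot: int = 200, seed: int = 0):
    """Compare integrated vs single-platform LOOCV scores.

    Returns ``(table, synergy_flag)``: one row per platform per horizon with
    AUC(t) +/- bootstrap SD, and a flag that is True when the integrated
    score beats both ablations at every horizon.
    """
    required = {"integrated", "ldct_only", "tissue_only"}
    if set(scores_by_platform) != required:
        raise ValueError(f"need scores for platforms {sorted(required)}")
    n = len(outcomes)
    for k, v in scores_by_platform.items():
        if len(v) != n:
            raise ValueError(f"platform {k!r} scores do not match the cohort")
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    rows = []
    for t in horizons:
        for plat in ("integrated", "ldct_only", "tissue_only"):
            a = td_auc(np.asarray(scores_by_platform[plat], dtype=float),
                       time, event, t, n_boot=n_boot, seed=seed)
            rows.append({"t": t, "platform": plat, "auc": a.auc, "auc_sd": a.sd})
    table = pd.DataFrame(rows)
    flag = True
    for t in horizons:
        sub = table[table["t"] == t].set_index("platform")["auc"]
        if not (sub["integrated"] > sub["ldct_only"]
                and sub["integrated"] > sub["tissue_only"]):
            flag = False
    return table, flag
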