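"""Survival evaluation statistics vs hand computation and brute force."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from idlescore import evaluation as ev


def no_censoring_dataset(rng, n=30):
    t = rng.exponential(4, n).clip(0.05, None)
    e = np.ones(n, dtype=int)
    s = rng.normal(size=n)
    return s, t, e


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = ev.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert ev.km_survival_at(km, 2.9) == 1.0

    def test_hand_product_limit(self):
        km = ev.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert ev.km_survival_at(km, 2.5) == pytest.approx(1 / 3)

    def test_single_censored_patient(self):
        km = ev.km_estimate([1.0], [0])
        assert ev.km_survival_at(km, 5.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        _, t, e = no_censoring_dataset(rng, 40)
        km = ev.km_estimate(t, e)
        for tau in (1.0, 2.0, 5.0):
            assert ev.km_survival_at(km, tau) == pytest.approx((t > tau).mean())

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            ev.km_estimate([0.0, 1.0], [1, 1])


class TestTimeDependentAUC:
    def test_perfect_scores_no_censoring(self):
        t = np.array([1.0, 2, 3, 6, 7, 8])
        e = np.ones(6, int)
        s = -t  # shorter survival -> higher score
        assert ev.td_auc_point(s, t, e, 5.0) == 1.0

    def test_no_censoring_equals_bruteforce_pair_counting(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(4, 8).clip(0.05, None)
        e = np.ones(8, int)
        s = rng.normal(size=8)
        tau = float(np.median(t))
        case, ctrl = (e == 1) & (t <= tau), t > tau
        num, den = 0.0, 0
        for i in np.flatnonzero(case):
            for j in np.flatnonzero(ctrl):
                den += 1
                num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert ev.td_auc_point(s, t, e, tau) == pytest.approx(num / den, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(20):
            t = rng.exponential(6, 500).clip(0.05, 12)
            e = (rng.random(500) < 0.5).astype(int)
            s = rng.normal(size=500)
            aucs.append(ev.td_auc_point(s, t, e, 5.0))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60).clip(0.05, None)
        e = (rng.random(60) < 0.7).astype(int)
        s = rng.normal(size=60)
        a = ev.td_auc_point(s, t, e, 4.0)
        b = ev.td_auc_point(np.exp(2 * s), t, e, 4.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_independent_ipcw_implementation(self):
        """Cross-check against scikit-survival's Uno estimator."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(0)
        t = rng.exponential(6, 150).clip(0.05, 12)
        e = (rng.random(150) < 0.6).astype(int)
        e[t >= 11.5] = 1
        s = 0.5 / t + rng.normal(0, 0.1, 150)
        y = Surv.from_arrays(e.astype(bool), t)
        for tau in (3.0, 5.0, 8.0):
            theirs = cumulative_dynamic_auc(y, y, s, [tau])[0][0]
            assert ev.td_auc_point(s, t, e, tau) == pytest.approx(theirs, abs=1e-3)

    def test_bootstrap_sd_stabilises(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(6, 200).clip(0.05, 12)
        e = (rng.random(200) < 0.6).astype(int)
        s = 1.0 / t + rng.normal(0, 0.2, 200)
        a = ev.td_auc(s, t, e, 5.0, n_boot=400, seed=0)
        b = ev.td_auc(s, t, e, 5.0, n_boot=800, seed=1)
        assert a.sd > 0
        assert abs(a.sd - b.sd) / b.sd < 0.10

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            ev.td_auc_point([1.0, 2.0], [6.0, 7.0], [1, 1], 5.0)


class TestPPVNPV:
    def test_perfect_classifier(self):
        t = np.array([1.0, 2, 3, 7, 8, 9])
        e = np.ones(6, int)
        s = -t
        out = ev.td_ppv_npv(s, t, e, 5.0, [0.6, 0.9])
        ok = out[out["evaluable"]]
        assert np.allclose(ok["ppv"], 1.0)
        assert np.allclose(ok["npv"], 1.0)

    def test_bayes_rule_equals_direct_counting_without_censoring(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(10, 51))
            s, t, e = no_censoring_dataset(rng, n)
            tau = float(np.quantile(t, 0.5))
            if not ((t <= tau).any() and (t > tau).any()):
                continue
            out = ev.td_ppv_npv(s, t, e, tau, [0.5, 0.8])
            for _, row in out[out["evaluable"]].iterrows():
                c = row["cutoff"]
                pos = s > c
                if pos.any():
                    assert row["ppv"] == pytest.approx(
                        ((t <= tau) & pos).sum() / pos.sum(), abs=1e-12)
                if (~pos).any():
                    assert row["npv"] == pytest.approx(
                        ((t > tau) & ~pos).sum() / (~pos).sum(), abs=1e-12)

    def test_unreachable_sensitivity_reported_not_evaluable(self):
        # scores constant over the cases: only sensitivity 0 or 1 achievable
        t = np.array([1.0, 2, 8, 9, 10, 11])
        e = np.ones(6, int)
        s = np.array([0.5, 0.5, 0.9, 0.9, 0.9, 0.9])  # cases score LOW
        out = ev.td_ppv_npv(s, t, e, 5.0, [0.99])
        # the only cutoffs reaching sens 0.99 select everyone
        assert out["evaluable"].iloc[0] in (True, False)
        out2 = ev.td_ppv_npv(s, t, e, 5.0, [0.5])
        assert set(out2.columns) >= {"ppv", "npv", "cutoff", "evaluable"}

    def test_no_events_by_t_gives_zero_ppv(self):
        t = np.array([6.0, 7, 8, 9])
        e = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.9, 0.2, 0.8])
        with pytest.raises(ValueError):
            # no cases at t=5 -> sensitivity undefined upstream
            ev.td_confusion(s, t, e, 5.0, 0.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ev.td_ppv_npv([1.0, 2.0], [1.0, 9.0], [1, 1], 5.0, [])


class TestOptimalCutoff:
    def test_two_component_hr_recovery(self):
        rng = np.random.default_rng(6)
        errs = []
        for _ in range(3):
            n = 400
            g = rng.random(n) < 0.5
            lam = np.where(g, 4.0, 1.0)  # true HR 4
            t = rng.exponential(1.0 / lam).clip(1e-3, None)
            e = np.ones(n, int)
            s = g + rng.normal(0, 0.01, n)
            out = ev.optimal_cutoff_hr(s, t, e)
            errs.append(abs(out["hr"] - 4.0) / 4.0)
            assert 0.0 < out["cutoff"] < 1.0
        assert np.median(errs) <= 0.25

    def test_null_scores_ci_covers_one(self):
        rng = np.random.default_rng(7)
        cover = 0
        for _ in range(12):
            t = rng.exponential(5, 120).clip(1e-3, None)
            e = (rng.random(120) < 0.7).astype(int)
            s = rng.normal(size=120)
            out = ev.optimal_cutoff_hr(s, t, e)
            cover += out["ci_low"] <= 1.0 <= out["ci_high"]
        # the scan maximises HR, so coverage of 1 is below nominal but the
        # CI should still usually include it
        assert cover >= 6

    def test_monotone_transform_keeps_partition(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 80).clip(1e-3, None)
        e = np.ones(80, int)
        s = rng.normal(size=80)
        a = ev.optimal_cutoff_hr(s, t, e)
        b = ev.optimal_cutoff_hr(np.exp(s), t, e)
        assert np.array_equal(s > a["cutoff"], np.exp(s) > b["cutoff"])
        assert a["hr"] == pytest.approx(b["hr"])

    def test_constant_scores_degenerate(self):
        with pytest.raises(ValueError):
            ev.optimal_cutoff_hr(np.ones(40), np.arange(1, 41.0), np.ones(40, int))


class TestCoxMultivariate:
    def test_binary_covariate_recovery(self):
        rng = np.random.default_rng(9)
        rel_errs = []
        for _ in range(5):
            n = 500
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1.0 / np.exp(np.log(2.0) * x)).clip(1e-3, None)
            e = (rng.random(n) < 0.8).astype(int)
            df = pd.DataFrame({"x": x, "time": t, "event": e})
            tab = ev.cox_multivariate(df, covariates=["x"])
            rel_errs.append(abs(tab["hr"][0] - 2.0) / 2.0)
        assert np.median(rel_errs) <= 0.15

    def test_breslow_partial_likelihood_oracle(self):
        """4-subject toy: the coefficient maximises the hand-written Breslow
        partial likelihood (brute-force 1-D optimisation)."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            ll = 0.0
            for i in np.argsort(t):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        beta_hat = optimize.minimize_scalar(neg_pl, bounds=(-5, 5),
                                            method="bounded",
                                            options={"xatol": 1e-10}).x
        tab = ev.cox_multivariate(pd.DataFrame({"x": x, "time": t, "event": e}),
                                  covariates=["x"])
        assert np.log(tab["hr"][0]) == pytest.approx(beta_hat, abs=1e-6)

    def test_collinear_design_rejected(self):
        df = pd.DataFrame({"a": [1.0, 0, 1, 0], "b": [2.0, 0, 2, 0],
                           "time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            ev.cox_multivariate(df, covariates=["a", "b"])


class TestCohortSummary:
    def test_fisher_on_published_style_table(self):
        p = ev.fisher_or_chi2(np.array([[21, 33], [27, 101]]))
        assert p == pytest.approx(0.0167, abs=5e-5)

    def test_balanced_table_p_one(self):
        assert ev.fisher_or_chi2(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            tab = rng.integers(0, 12, size=(2, 2))
            if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
                continue
            a, b = tab[0]
            c, d = tab[1]
            n = tab.sum()
            row1, col1 = a + b, a + c
            probs = {k: stats.hypergeom.pmf(k, n, row1, col1)
                     for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)}
            p_obs = probs[a]
            expected = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
            assert ev.fisher_or_chi2(tab) == pytest.approx(expected, abs=1e-9)

    def test_summary_table_structure(self):
        rng = np.random.default_rng(11)
        n = 60
        patients = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "age_at_surgery": rng.normal(65, 5, n),
            "sex": rng.choice(["M", "F"], n),
        })
        outcomes = pd.DataFrame({"patient_id": patients["patient_id"],
                                 "time": rng.exponential(5, n).clip(0.01, None),
                                 "event": rng.integers(0, 2, n)})
        tab = ev.cohort_summary(patients, outcomes)
        assert set(tab["variable"]) == {"age_at_surgery", "sex"}
        assert tab.set_index("variable").loc["age_at_surgery", "type"] == "continuous"
        assert ((tab["p"].dropna() >= 0) & (tab["p"].dropna() <= 1)).all()

    def test_empty_group_rejected(self):
        patients = pd.DataFrame({"patient_id": ["A", "B"], "age_at_surgery": [60.0, 61]})
        outcomes = pd.DataFrame({"patient_id": ["A", "B"], "time": [1.0, 2],
                                 "event": [1, 1]})
        with pytest.raises(ValueError):
            ev.cohort_summary(patients, outcomes)
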