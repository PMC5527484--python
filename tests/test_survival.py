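"""Censoring, Kaplan-Meier/log-rank and Cox proportional-hazards checks."""
import numpy as np
import pandas as pd
import pytest

from melsubtypes.survival import (apply_censoring, cox_fit, km_logrank,
                                  subtype_survival_analysis, survival_frame)


def surv_df(times, events, groups=None, **extra):
    df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(times))],
                       "time": times, "event": events})
    if groups is not None:
        df["group"] = groups
    for k, v in extra.items():
        df[k] = v
    return df


class TestCensoring:
    def test_event_beyond_horizon_recoded(self):
        out = apply_censoring(surv_df([72.0, 12.0], [1, 1]), horizon=60)
        assert out.loc[0, "time"] == 60 and out.loc[0, "event"] == 0
        assert out.loc[1, "time"] == 12 and out.loc[1, "event"] == 1

    def test_all_censored_unchanged(self):
        df = surv_df([10.0, 20.0], [0, 0])
        out = apply_censoring(df, horizon=60)
        pd.testing.assert_series_equal(out["time"], df["time"])
        assert out["event"].sum() == 0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_censoring(surv_df([-1.0], [1]))


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        base = surv_df([5, 8, 12, 20, 30, 44.0], [1, 0, 1, 1, 0, 1])
        both = pd.concat([base.assign(group="A"), base.assign(group="B")],
                         ignore_index=True)
        res = km_logrank(both)
        assert res.statistic == pytest.approx(0, abs=1e-9)
        assert res.pvalue == pytest.approx(1, abs=1e-9)

    def test_two_group_statistic_matches_hand_computation(self):
        """Six-subject toy: log-rank O-E/V recomputed from first principles."""
        times = np.array([6, 7, 10, 15, 19, 25], dtype=float)
        events = np.array([1, 0, 1, 1, 0, 1])
        groups = np.array(["A", "A", "B", "A", "B", "B"])
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n, n_a = at_risk.sum(), (at_risk & (groups == "A")).sum()
            d = int(((times == t) & (events == 1)).sum())
            d_a = int(((times == t) & (events == 1) & (groups == "A")).sum())
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected = o_minus_e ** 2 / var
        res = km_logrank(surv_df(times, events, groups))
        assert res.statistic == pytest.approx(expected, rel=1e-9)
        assert res.df == 1

    def test_km_equals_empirical_without_censoring(self, rng):
        times = rng.exponential(10, 40)
        res = km_logrank(surv_df(times, np.ones(40, int), ["A"] * 40))
        curve = res.curves["A"]
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()
        for t in (2.0, 8.0, 15.0):
            emp = (times > t).mean()
            km_at = curve.loc[curve["timeline"] <= t, "survival"].iloc[-1]
            assert km_at == pytest.approx(emp, abs=1e-12)

    def test_single_group_no_test(self):
        res = km_logrank(surv_df([1, 2, 3.0], [1, 1, 0], ["A"] * 3))
        assert res.statistic is None and "A" in res.curves

    def test_logrank_equals_cox_score_test(self, rng):
        """With continuous times the 2-group log-rank chi-square equals the
        Cox score statistic at beta=0 (computed from first principles)."""
        n = 120
        x = np.repeat([0, 1], n // 2)
        times = rng.exponential(np.where(x == 1, 6, 10))
        events = (rng.random(n) < 0.8).astype(int)
        order = np.argsort(times)
        t, e, xv = times[order], events[order], x[order].astype(float)
        u = 0.0
        v = 0.0
        for i in range(n):
            if e[i]:
                risk = slice(i, n)
                xbar = xv[risk].mean()
                u += xv[i] - xbar
                v += ((xv[risk] - xbar) ** 2).sum() / (n - i)
        score_chi2 = u ** 2 / v
        res = km_logrank(surv_df(times, events, x.astype(str)))
        assert res.statistic == pytest.approx(score_chi2, rel=1e-6)

    def test_power_under_planted_hazard_ratio(self, rng):
        reps, hits = 100, 0
        for _ in range(reps):
            t0 = rng.exponential(50, 500)
            t1 = rng.exponential(25, 500)
            cens = rng.uniform(0, 60, 1000)
            times = np.minimum(np.concatenate([t0, t1]), cens)
            events = (np.concatenate([t0, t1]) <= cens).astype(int)
            res = km_logrank(surv_df(times, events,
                                     ["A"] * 500 + ["B"] * 500))
            hits += res.pvalue < 0.01
        assert hits >= 95


class TestCoxFit:
    def _two_arm(self, rng, n, hr):
        x = rng.random(n) < 0.5
        times = rng.exponential(1 / (0.02 * np.where(x, hr, 1.0)))
        cens = rng.uniform(0, 80, n)
        return surv_df(np.minimum(times, cens), (times <= cens).astype(int),
                       subtype=np.where(x, "NF1", "BRAF"))

    def test_parameter_recovery(self, rng):
        df = self._two_arm(rng, 5000, 2.0)
        fit = cox_fit(df, ["subtype"])
        assert 1.8 <= fit.hr("subtype_NF1") <= 2.2
        lo, hi = fit.ci("subtype_NF1")
        assert lo <= fit.hr("subtype_NF1") <= hi

    def test_null_after_permutation(self, rng):
        reps, hits = 100, 0
        for _ in range(reps):
            df = self._two_arm(rng, 300, 2.0)
            df["subtype"] = rng.permutation(df["subtype"].to_numpy())
            fit = cox_fit(df, ["subtype"])
            hits += fit.summary.loc["subtype_NF1", "p"] > 0.05
        assert hits >= 93

    def test_time_unit_invariance(self, rng):
        df = self._two_arm(rng, 400, 1.8)
        hr_months = cox_fit(df, ["subtype"]).hr("subtype_NF1")
        df_days = df.assign(time=df["time"] * 30.44)
        hr_days = cox_fit(df_days, ["subtype"]).hr("subtype_NF1")
        assert hr_months == pytest.approx(hr_days, abs=1e-6)

    def test_constant_covariate_dropped(self, rng):
        df = self._two_arm(rng, 200, 1.5)
        df["age"] = 50.0
        fit = cox_fit(df, ["subtype", "age"])
        assert "age" not in fit.summary.index

    def test_too_few_events_raises(self):
        df = surv_df([1, 2, 3, 4.0], [0, 0, 0, 0],
                     subtype=["BRAF", "NF1", "BRAF", "NF1"])
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["subtype"])


class TestSubtypeSurvivalAnalysis:
    def test_full_report_structure(self, cohort870, classified870):
        bundle, _ = cohort870
        calls, _ = classified870
        report = subtype_survival_analysis(calls, bundle.clinical)
        assert set(report["stratum"]) >= {"all", "metastases", "primaries"}
        un = report[(report["stratum"] == "all") & (report["endpoint"] == "OS")
                    & (report["model"] == "unadjusted")
                    & (report["term"] == "subtype_NF1")]
        assert len(un) == 1 and un.iloc[0]["hr"] > 1
        adj = report[(report["stratum"] == "all") & (report["endpoint"] == "OS")
                     & (report["model"] == "adjusted")
                     & (report["term"] == "subtype_NF1")]
        # covariates independent of survival: adjusted HR within unadjusted CI
        assert un.iloc[0]["ci_lower"] <= adj.iloc[0]["hr"] <= un.iloc[0]["ci_upper"]

    def test_low_event_group_flagged(self):
        rng = np.random.default_rng(5)
        n = 120
        calls = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "subtype": ["BRAF"] * 100 + ["NF1"] * 20,
        })
        times = rng.exponential(40, n)
        clinical = pd.DataFrame({
            "sample_id": calls["sample_id"],
            "os_time": np.minimum(times, 59.0),
            "os_event": [1 if (t < 59 and i < 100) else 0
                         for i, t in enumerate(times)],
            "dss_event": 0, "age": 60.0, "gender": "male",
            "tumor_type": "metastasis", "treated": np.nan,
        })
        report = subtype_survival_analysis(calls, clinical, strata=("all",))
        flagged = report[report.get("note") == "not_estimable_low_events"]
        assert any(flagged["term"] == "subtype_NF1")

    def test_missing_followup_excluded(self, classified870, cohort870):
        bundle, _ = cohort870
        calls, _ = classified870
        clinical = bundle.clinical.copy()
        clinical.loc[clinical.index[:25], "os_time"] = np.nan
        surv = survival_frame(clinical, "OS")
        assert len(surv) == len(clinical) - 25
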