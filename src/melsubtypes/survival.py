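"""Survival contrasts between genomic subtypes.

Overall survival (OS, death from any cause) and disease-specific survival
(DSS, death from melanoma; other deaths censored at the death time) are
measured in months from specimen removal and censored at five years before
testing.  Contrasts are Kaplan-Meier curves with k-group log-rank tests and
Cox proportional-hazards fits (Efron tie handling, BRAF as the reference
subtype), optionally adjusted for age, gender and tumor type.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .subtypes import BRAF, EXCLUDED, NF1, RAS, TRIPLE_WT

log = logging.getLogger(__name__)

DEFAULT_HORIZON = 60.0   # months
ENDPOINTS = ("OS", "DSS")
SUBTYPE_ORDER = [BRAF, RAS, NF1, TRIPLE_WT]


def apply_censoring(inputs: pd.DataFrame, horizon: float = DEFAULT_HORIZON,
                    time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Administratively censor at ``horizon`` months: later events become
    censored observations at the horizon."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if (inputs[time_col] < 0).any():
        bad = inputs.index[inputs[time_col] < 0].tolist()
        raise ValueError(f"negative follow-up times at rows {bad[:5]}")
    out = inputs.copy()
    late = out[time_col] > horizon
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = horizon
    out[event_col] = out[event_col].astype(int)
    return out


def survival_frame(clinical: pd.DataFrame, endpoint: str = "OS") -> pd.DataFrame:
    """Extract (sample_id, time, event) for an endpoint.

    DSS censors deaths from other causes at the death time.  Samples
    without follow-up (missing time or event) are dropped.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    event = clinical["os_event"] if endpoint == "OS" else clinical["dss_event"]
    df = pd.DataFrame({
        "sample_id": clinical["sample_id"],
        "time": pd.to_numeric(clinical["os_time"], errors="coerce"),
        "event": pd.to_numeric(event, errors="coerce"),
    })
    n_missing = int(df[["time", "event"]].isna().any(axis=1).sum())
    if n_missing:
        log.info("%d samples without usable %s follow-up excluded", n_missing, endpoint)
    return df.dropna(subset=["time", "event"]).reset_index(drop=True)


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]   # group -> (timeline, survival)
    statistic: float | None           # k-group log-rank chi-square, k-1 df
    pvalue: float | None
    df: int | None


def km_logrank(inputs: pd.DataFrame, grouping: pd.Series | None = None,
               group_col: str = "group") -> KMResult:
    """Product-limit curves per group plus the k-group log-rank test.

    ``inputs`` needs ``time``/``event`` columns and either a ``group``
    column or an external ``grouping`` indexed by sample_id.
    """
    df = inputs.copy()
    if grouping is not None:
        df[group_col] = df["sample_id"].map(grouping)
        df = df.dropna(subset=[group_col])
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in df.groupby(group_col):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = pd.DataFrame({
            "timeline": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
        })
    groups = df[group_col].unique()
    if len(groups) < 2 or df["event"].sum() == 0:
        log.warning("log-rank test skipped (single group or no events)")
        return KMResult(curves, None, None, None)
    res = multivariate_logrank_test(df["time"], df[group_col], df["event"])
    return KMResult(curves, float(res.test_statistic), float(res.p_value),
                    int(len(groups) - 1))


@dataclass
class CoxFit:
    summary: pd.DataFrame   # per-covariate hazard_ratio, ci_lower, ci_upper, p
    lr_pvalue: float        # global likelihood-ratio p
    n: int
    events: int

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hazard_ratio"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _dummies(df: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Design columns; subtype becomes dummies against the BRAF reference."""
    X = pd.DataFrame(index=df.index)
    dropped = []
    for cov in covariates:
        if cov == "subtype":
            levels = [s for s in SUBTYPE_ORDER if s in set(df["subtype"])]
            for s in levels:
                if s != BRAF:
                    X[f"subtype_{s}"] = (df["subtype"] == s).astype(float)
        elif cov == "gender":
            X["male"] = (df["gender"] == "male").astype(float)
        elif cov == "tumor_type":
            X["metastasis"] = (df["tumor_type"] == "metastasis").astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov], errors="coerce")
    for col in list(X.columns):
        if X[col].nunique(dropna=True) < 2:
            log.warning("constant covariate %s dropped from Cox model", col)
            X = X.drop(columns=col)
            dropped.append(col)
    return X, dropped


def cox_fit(inputs: pd.DataFrame, covariates: list[str] | None = None) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    ``inputs`` needs ``time``/``event`` plus the covariate columns;
    ``subtype`` enters as dummies against BRAF.  Wald CIs and p per
    covariate; the global p is the likelihood-ratio test.
    """
    covariates = covariates or ["subtype"]
    X, _ = _dummies(inputs, covariates)
    df = pd.concat([inputs[["time", "event"]].reset_index(drop=True),
                    X.reset_index(drop=True)], axis=1).dropna()
    events = int(df["event"].sum())
    if events < X.shape[1]:
        raise ValueError(f"too few events ({events}) for {X.shape[1]} covariates")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")   # lifelines default: Efron ties
    s = cph.summary
    summary = pd.DataFrame({
        "hazard_ratio": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    return CoxFit(summary, float(cph.log_likelihood_ratio_test().p_value),
                  n=len(df), events=events)


STRATA = ("all", "metastases", "primaries", "treated", "untreated")
ADJUSTMENT = ["subtype", "age", "gender", "tumor_type"]


def _stratum_mask(clinical: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=clinical.index)
    if stratum == "metastases":
        return clinical["tumor_type"] == "metastasis"
    if stratum == "primaries":
        return clinical["tumor_type"] == "primary"
    if stratum == "treated":
        return clinical["treated"] == 1
    if stratum == "untreated":
        return clinical["treated"] == 0
    raise ValueError(f"unknown stratum {stratum!r}")


def subtype_survival_analysis(calls: pd.DataFrame, clinical: pd.DataFrame,
                              horizon: float = DEFAULT_HORIZON,
                              strata=STRATA) -> pd.DataFrame:
    """Subtype survival report over strata x endpoints x adjustment.

    For each stratum (all / metastases / primaries / treated / untreated)
    and endpoint (OS / DSS), runs the log-rank test plus unadjusted and
    covariate-adjusted Cox contrasts against BRAF.  Subtype levels with at
    most one event are flagged not estimable and left out of the fit; empty
    or event-free strata are reported as not estimable.
    """
    merged = calls.merge(clinical, on="sample_id", how="inner")
    merged = merged[merged["subtype"] != EXCLUDED]
    rows: list[dict] = []
    for stratum in strata:
        sub = merged[_stratum_mask(merged, stratum)]
        for endpoint in ENDPOINTS:
            surv = survival_frame(sub, endpoint)
            surv = surv.merge(sub[["sample_id", "subtype", "age", "gender",
                                   "tumor_type"]], on="sample_id")
            if surv.empty or surv["event"].sum() == 0:
                rows.append({"stratum": stratum, "endpoint": endpoint,
                             "model": "none", "term": "", "note": "not_estimable"})
                continue
            surv = apply_censoring(surv, horizon)
            ev_per_subtype = surv.groupby("subtype")["event"].sum()
            weak = ev_per_subtype[ev_per_subtype <= 1].index.tolist()
            for s in weak:
                rows.append({"stratum": stratum, "endpoint": endpoint,
                             "model": "unadjusted", "term": f"subtype_{s}",
                             "note": "not_estimable_low_events"})
            fit_df = surv[~surv["subtype"].isin(weak)]
            if fit_df["subtype"].nunique() < 2 or fit_df["event"].sum() == 0:
                rows.append({"stratum": stratum, "endpoint": endpoint,
                             "model": "none", "term": "", "note": "not_estimable"})
                continue
            lr = km_logrank(fit_df.assign(group=fit_df["subtype"]))
            rows.append({"stratum": stratum, "endpoint": endpoint,
                         "model": "logrank", "term": "global",
                         "statistic": lr.statistic, "p": lr.pvalue,
                         "n": len(fit_df), "events": int(fit_df["event"].sum())})
            for model, covs in (("unadjusted", ["subtype"]),
                                ("adjusted", ADJUSTMENT)):
                try:
                    fit = cox_fit(fit_df, covs)
                except ValueError as exc:
                    rows.append({"stratum": stratum, "endpoint": endpoint,
                                 "model": model, "term": "", "note": str(exc)})
                    continue
                for term, r in fit.summary.iterrows():
                    rows.append({"stratum": stratum, "endpoint": endpoint,
                                 "model": model, "term": term,
                                 "hr": float(r["hazard_ratio"]),
                                 "ci_lower": float(r["ci_lower"]),
                                 "ci_upper": float(r["ci_upper"]),
                                 "p": float(r["p"]), "n": fit.n,
                                 "events": fit.events})
    return pd.DataFrame(rows)
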