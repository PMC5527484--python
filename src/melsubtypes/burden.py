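"""Per-sample mutational load and its association with clinical strata.

*Total load* counts single-nucleotide variants of every class (noncoding,
synonymous and nonsynonymous) over the shared gene panel; focal indels are
excluded from it but do count toward the *nonsynonymous load*.  Loads are
compared between strata with rank tests (Wilcoxon rank-sum for two groups,
Kruskal-Wallis beyond), and categorical clinical covariates are tested
against subtype with Fisher's exact test (Monte-Carlo beyond 2x2), age
with one-way ANOVA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort_io import CohortBundle, NONSYNONYMOUS_CLASSES
from .subtypes import EXCLUDED

log = logging.getLogger(__name__)

AGE_BINS = ["<=40", "41-60", "61-80", ">=81"]


def categorize_age(age: pd.Series) -> pd.Series:
    """Age-at-diagnosis categories used for burden comparisons."""
    bins = pd.cut(age, bins=[-np.inf, 40, 60, 80, np.inf], labels=AGE_BINS)
    return bins.astype(object).where(age.notna(), None)


def compute_loads(bundle: CohortBundle) -> pd.DataFrame:
    """Per-sample total (SNV-only) and nonsynonymous loads.

    Samples absent from the mutation table are absent from the result
    (harmonization already dropped mutation-free samples).
    """
    m = bundle.mutations
    snv = (m["ref"].str.len().eq(1) & m["alt"].str.len().eq(1)
           & m["ref"].isin(list("ACGT")) & m["alt"].isin(list("ACGT")))
    nonsyn = m["variant_class"].isin(NONSYNONYMOUS_CLASSES)
    loads = (
        pd.DataFrame({"sample_id": m["sample_id"], "snv": snv, "nonsyn": nonsyn})
        .groupby("sample_id", sort=True)
        .sum()
        .rename(columns={"snv": "total_load", "nonsyn": "nonsyn_load"})
        .reset_index()
    )
    loads[["total_load", "nonsyn_load"]] = loads[["total_load", "nonsyn_load"]].astype(int)
    return loads


@dataclass
class LoadComparison:
    test: str                 # "wilcoxon_ranksum" or "kruskal_wallis"
    statistic: float
    pvalue: float
    groups: pd.DataFrame      # group, n, median, min, max
    excluded_groups: list[str]


def compare_loads(loads: pd.DataFrame, grouping: Mapping[str, str] | pd.Series,
                  value: str = "total_load") -> LoadComparison:
    """Rank-test a load column across >= 2 groups of samples.

    Two groups -> Wilcoxon rank-sum; more -> Kruskal-Wallis.  Groups with
    fewer than two samples are excluded with a warning.
    """
    if not isinstance(grouping, pd.Series):
        grouping = pd.Series(grouping)
    df = loads.set_index("sample_id")
    df = df.join(grouping.rename("group"), how="inner").dropna(subset=["group"])
    sizes = df.groupby("group").size()
    excluded = sorted(sizes[sizes < 2].index)
    if excluded:
        log.warning("groups excluded from load comparison (<2 samples): %s", excluded)
        df = df[~df["group"].isin(excluded)]
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two nonempty groups")
    vectors = [df.loc[df["group"] == g, value].to_numpy(float) for g in labels]
    if len(labels) == 2:
        stat, p = stats.ranksums(vectors[0], vectors[1])
        test = "wilcoxon_ranksum"
    else:
        stat, p = stats.kruskal(*vectors)
        test = "kruskal_wallis"
    summary = pd.DataFrame({
        "group": labels,
        "n": [len(v) for v in vectors],
        "median": [float(np.median(v)) for v in vectors],
        "min": [float(v.min()) for v in vectors],
        "max": [float(v.max()) for v in vectors],
    })
    return LoadComparison(test, float(stat), float(p), summary, excluded)


# --------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# --------------------------------------------------------------------------

def _log_table_prob(tables: np.ndarray) -> np.ndarray:
    """Log probability of contingency table(s) under fixed margins
    (multivariate hypergeometric null).  Accepts one r x c table or a
    stacked (k, r, c) array."""
    t = np.asarray(tables)
    single = t.ndim == 2
    if single:
        t = t[None]
    n = t.sum(axis=(1, 2))
    out = (gammaln(t.sum(axis=2) + 1).sum(axis=1)
           + gammaln(t.sum(axis=1) + 1).sum(axis=1)
           - gammaln(n + 1)
           - gammaln(t + 1).sum(axis=(1, 2)))
    return out[0] if single else out


def fisher_exact_rxc(table: np.ndarray, rng: np.random.Generator | None = None,
                     n_draws: int = 100_000) -> float:
    """Fisher's exact p for an r x c table.

    2x2 tables use the exact two-sided test; larger tables use a
    Monte-Carlo estimate (probability ordering, ``n_draws`` tables with
    fixed margins via Patefield sampling).
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    if rng is None:
        rng = np.random.default_rng(0)
    obs = _log_table_prob(table)
    sampled = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = sampled.rvs(n_draws, method="patefield", random_state=rng)
    logp = _log_table_prob(draws)
    hits = int((logp <= obs + 1e-9).sum())
    return (hits + 1) / (n_draws + 1)


@dataclass
class Association:
    covariate: str
    test: str
    statistic: float
    pvalue: float
    table: pd.DataFrame | None   # counts (and percentages) per subtype


def clinical_association_table(calls: pd.DataFrame, clinical: pd.DataFrame,
                               rng: np.random.Generator | None = None,
                               n_draws: int = 100_000) -> list[Association]:
    """Clinical covariates versus genomic subtype.

    Categorical covariates (tumor_type, origin, gender) are tested with
    Fisher's exact test over non-missing cells; age with one-way ANOVA.
    EXCLUDED samples are dropped before testing.
    """
    df = calls.merge(clinical, on="sample_id", how="inner")
    df = df[df["subtype"] != EXCLUDED]
    subtype_levels = sorted(df["subtype"].unique())
    if len(subtype_levels) < 2:
        log.warning("only one subtype present; no association tests run")
        return []
    out: list[Association] = []
    for cov in ("tumor_type", "origin", "gender"):
        sub = df[df[cov].notna() & (df[cov] != "missing")]
        if sub.empty or sub[cov].nunique() < 2:
            log.warning("covariate %s all-missing or constant; omitted", cov)
            continue
        counts = pd.crosstab(sub[cov], sub["subtype"])
        pct = counts.div(counts.sum(axis=0), axis=1).mul(100).round(1)
        display = counts.astype(str) + " (" + pct.astype(str) + ")"
        p = fisher_exact_rxc(counts.to_numpy(), rng=rng, n_draws=n_draws)
        out.append(Association(cov, "fisher_exact", float("nan"), p, display))
    age = df[df["age"].notna()]
    if not age.empty and age["subtype"].nunique() >= 2:
        groups = [g["age"].to_numpy(float) for _, g in age.groupby("subtype")]
        f, p = stats.f_oneway(*groups)
        means = age.groupby("subtype")["age"].mean().round(1).to_frame("mean_age")
        out.append(Association("age", "one_way_anova", float(f), float(p), means))
    return out
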