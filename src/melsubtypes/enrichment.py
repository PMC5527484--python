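"""Burden-adjusted differential mutation screening across genomic subtypes.

The NF1 subtype carries several-fold more mutations than the others, so a
naive per-gene Fisher test calls most of the panel "NF1-enriched".  The
screen here fits, per gene, a logistic regression of the gene's
nonsynonymous-mutation indicator on genomic subtype (BRAF as reference)
plus the sample's total mutational load, and reports Wald p-values for the
subtype contrasts with Benjamini-Hochberg adjustment per contrast.  Genes
that separate perfectly fall back to a Firth-penalized (Jeffreys-prior)
fit rather than being dropped.

Also here: the twelve-driver-pathway screen (same adjusted model on
per-sample pathway indicators) and a Fisher mutual-exclusivity test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortBundle, NONSYNONYMOUS_CLASSES
from .subtypes import BRAF, EXCLUDED, NF1, RAS, TRIPLE_WT

log = logging.getLogger(__name__)

#: Subtype-defining genes, never screened themselves.
SUBTYPE_GENES = frozenset({"BRAF", "NRAS", "KRAS", "HRAS", "NF1"})
CONTRASTS = (RAS, NF1, TRIPLE_WT)
DEFAULT_MIN_FREQ = 5 / 870


def load_pathways() -> pd.DataFrame:
    """Packaged twelve-pathway driver-gene table (long format: pathway,
    process, gene).  Gene sets are pairwise disjoint."""
    with resources.files("melsubtypes.data").joinpath("driver_pathways.tsv").open() as fh:
        wide = pd.read_csv(fh, sep="\t")
    rows = []
    for r in wide.itertuples(index=False):
        for gene in r.genes.split(","):
            rows.append({"pathway": r.pathway, "process": r.process, "gene": gene})
    long = pd.DataFrame(rows)
    if long["gene"].duplicated().any():
        raise ValueError("pathway gene sets must be pairwise disjoint")
    return long


# --------------------------------------------------------------------------
# Firth-penalized logistic regression (separation fallback)
# --------------------------------------------------------------------------

def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray, bool]:
    """Jeffreys-prior penalized logistic fit.

    Returns (coefficients, standard errors, converged).  The penalty keeps
    estimates finite under complete separation; Wald inference uses the
    penalized information matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # dampen wild steps early in the iteration
        norm = np.abs(step).max()
        if norm > 5:
            step *= 5 / norm
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (p * (1 - p))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, converged


def _fit_gene(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Plain ML logistic fit, Firth fallback on separation/non-convergence.

    Returns (coef, se, used_firth)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            se = res.bse
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(se)) \
                    and np.abs(res.params).max() < 15:
                return np.asarray(res.params), np.asarray(se), False
        except Exception:
            pass
    beta, se, _ = firth_logistic(X, y)
    return beta, se, True


# --------------------------------------------------------------------------
# Screens
# --------------------------------------------------------------------------

def _design(calls: pd.DataFrame, loads: pd.DataFrame, log_load: bool
            ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = calls.merge(loads, on="sample_id", how="inner")
    df = df[df["subtype"] != EXCLUDED].reset_index(drop=True)
    load = df["total_load"].to_numpy(float)
    if log_load:
        load = np.log1p(load)
    cols = [np.ones(len(df))]
    names = ["const"]
    for s in CONTRASTS:
        cols.append((df["subtype"] == s).to_numpy(float))
        names.append(s)
    cols.append(load)
    names.append("total_load")
    return df, np.column_stack(cols), names


def _mutation_matrix(bundle: CohortBundle, samples: pd.Series) -> pd.DataFrame:
    """sample x gene indicator of any nonsynonymous mutation."""
    m = bundle.mutations
    m = m[m["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    mat = (m.assign(v=1)
            .pivot_table(index="sample_id", columns="gene", values="v",
                         aggfunc="max", fill_value=0))
    return mat.reindex(samples, fill_value=0).astype(int)


def _screen(indicators: pd.DataFrame, X: np.ndarray, names: list[str],
            subtype: pd.Series, min_freq: float) -> pd.DataFrame:
    results = []
    freq_groups = {s: (subtype == s).to_numpy() for s in [BRAF, *CONTRASTS]}
    for feature in indicators.columns:
        y = indicators[feature].to_numpy(float)
        frac = y.mean()
        if frac < min_freq or frac > 1 - 1e-12:
            continue
        coef, se, used_firth = _fit_gene(X, y)
        for s in CONTRASTS:
            j = names.index(s)
            z = coef[j] / se[j] if se[j] > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            results.append({
                "gene": feature, "contrast": s,
                "coef": float(coef[j]), "se": float(se[j]), "p": float(p),
                "firth": used_firth,
                **{f"freq_{g}": float(y[mask].mean()) if mask.any() else np.nan
                   for g, mask in freq_groups.items()},
            })
    table = pd.DataFrame(results)
    if table.empty:
        return table
    table["q"] = np.nan
    for s in CONTRASTS:
        mask = (table["contrast"] == s) & table["p"].notna()
        if mask.any():
            table.loc[mask, "q"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    return table.sort_values(["contrast", "q", "p"]).reset_index(drop=True)


def gene_logistic_screen(bundle: CohortBundle, calls: pd.DataFrame,
                         loads: pd.DataFrame, min_freq: float = DEFAULT_MIN_FREQ,
                         genes: list[str] | None = None,
                         log_load: bool = False) -> pd.DataFrame:
    """Per-gene burden-adjusted logistic screen.

    For each gene (excluding the subtype-defining genes and genes mutated
    in fewer than ``min_freq`` of samples), fits
    ``mutated ~ subtype + total_load`` and reports per-contrast
    coefficients (log-odds vs BRAF), Wald p, BH q per contrast, and
    per-subtype mutation frequencies.
    """
    df, X, names = _design(calls, loads, log_load)
    mat = _mutation_matrix(bundle, df["sample_id"])
    candidates = [g for g in (genes or mat.columns) if g not in SUBTYPE_GENES]
    mat = mat[[g for g in candidates if g in mat.columns]]
    return _screen(mat, X, names, df["subtype"], min_freq)


def pathway_indicator(bundle: CohortBundle, samples: pd.Series,
                      pathways: pd.DataFrame) -> pd.DataFrame:
    """sample x pathway indicator: any nonsynonymous mutation in a member
    gene present in the bundle's gene universe."""
    mat = _mutation_matrix(bundle, samples)
    out = {}
    for pw, grp in pathways.groupby("pathway", sort=False):
        members = [g for g in grp["gene"] if g in bundle.gene_universe]
        if not members:
            out[pw] = pd.Series(np.nan, index=mat.index)
            continue
        present = [g for g in members if g in mat.columns]
        out[pw] = mat[present].max(axis=1) if present else pd.Series(0, index=mat.index)
    return pd.DataFrame(out)


def pathway_screen(bundle: CohortBundle, calls: pd.DataFrame, loads: pd.DataFrame,
                   pathways: pd.DataFrame | None = None,
                   min_freq: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway prevalences plus the burden-adjusted logistic contrasts.

    Returns (prevalence table, association table).  A pathway with no
    member gene in the universe gets a missing prevalence.
    """
    if pathways is None:
        pathways = load_pathways()
    df, X, names = _design(calls, loads, log_load=False)
    ind = pathway_indicator(bundle, df["sample_id"], pathways)
    prevalence = pd.DataFrame({
        "pathway": ind.columns,
        "prevalence": [float(ind[c].mean()) if ind[c].notna().all() else np.nan
                       for c in ind.columns],
    })
    testable = ind[[c for c in ind.columns if ind[c].notna().all()]].astype(int)
    assoc = _screen(testable, X, names, df["subtype"], min_freq)
    if not assoc.empty:
        assoc = assoc.rename(columns={"gene": "pathway"})
    return prevalence, assoc


def mutual_exclusivity_test(indicator_a: pd.Series, indicator_b: pd.Series
                            ) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 co-occurrence table of two per-sample
    indicators; odds ratio < 1 means exclusivity."""
    a = indicator_a.astype(bool)
    b = indicator_b.astype(bool).reindex(a.index)
    table = np.array([
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("mutual exclusivity test with an empty margin; p = 1")
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table)
    return float(odds), float(p)
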