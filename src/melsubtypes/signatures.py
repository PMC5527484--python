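"""96-context mutation spectra and non-negative signature refitting.

Each single-nucleotide variant is binned into one of 96 classes: the six
pyrimidine-strand substitutions (C>A, C>G, C>T, T>A, T>C, T>G) crossed
with the 16 flanking-base contexts.  Variants reported on the purine
strand are reverse-complemented first.  Per-sample spectra are then
decomposed against a reference signature matrix (rows = signatures,
columns = the 96 classes, rows summing to 1) by iterated non-negative
least squares: fit, discard signatures whose weight falls below a
threshold (default 6%), refit, until the active set is stable.  Samples
with fewer than ``min_mutations`` (default 50) contributing SNVs are
excluded from fitting for lack of statistical power.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .cohort_io import CohortBundle, is_snv
from .subtypes import EXCLUDED

log = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 class labels, substitution-major, flanking contexts alphabetical:
#: "A[C>A]A", "A[C>A]C", ... "T[T>G]T".
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

UV_SIGNATURE = "Signature.7"


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def class_index(ref: str, alt: str, context3: str) -> int:
    """96-class index of an SNV given its 3-base reference context.

    Purine-reference variants are folded onto the pyrimidine strand.
    Raises ValueError when the context middle base does not match ref.
    """
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(f"context {context3!r} does not center on ref {ref!r}")
    if ref in ("A", "G"):
        ref, alt, context3 = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context3)
    label = f"{context3[0]}[{ref}>{alt}]{context3[2]}"
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValueError(f"not a valid substitution class: {label}") from None


@dataclass
class SpectrumCounts:
    sample_id: str
    counts: np.ndarray          # length 96, CONTEXT_LABELS order
    skipped: int                # SNVs without a resolvable context

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def spectrum_from_mutations(records: pd.DataFrame) -> SpectrumCounts:
    """Bin one sample's SNV records into a 96-context spectrum.

    Indels and records without a usable 3-base context are skipped and
    counted in ``skipped``.
    """
    sids = records["sample_id"].unique()
    sample_id = sids[0] if len(sids) else ""
    counts = np.zeros(96, dtype=int)
    skipped = 0
    for ref, alt, ctx in zip(records["ref"], records["alt"],
                             records["context3"].fillna("")):
        if not is_snv(ref, alt):
            continue
        try:
            counts[class_index(ref, alt, ctx)] += 1
        except ValueError:
            skipped += 1
            log.debug("skipping SNV %s>%s with context %r", ref, alt, ctx)
    return SpectrumCounts(sample_id, counts, skipped)


@dataclass
class ExposureWeights:
    sample_id: str
    weights: dict[str, float]   # signature name -> fraction, all >= discard threshold
    residual: float             # unassigned fraction, sum(weights) + residual = 1
    sse: float                  # squared reconstruction error on the fraction scale


def load_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a reference signature matrix: TSV with a ``signature`` name
    column plus the 96 context columns; rows are normalized to sum to 1."""
    df = pd.read_csv(path, sep="\t")
    if "signature" not in df.columns:
        raise ValueError("signature matrix needs a 'signature' column")
    df = df.set_index("signature")
    missing = [c for c in CONTEXT_LABELS if c not in df.columns]
    if missing:
        raise ValueError(f"signature matrix missing context columns, e.g. {missing[:3]}")
    df = df[list(CONTEXT_LABELS)].astype(float)
    df = df.div(df.sum(axis=1), axis=0)
    return df


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("signature").reset_index().to_csv(path, sep="\t", index=False)


def fit_exposures(spectrum: SpectrumCounts, signatures: pd.DataFrame,
                  min_mutations: int = 50, discard_below: float = 0.06
                  ) -> ExposureWeights | None:
    """Refit one spectrum against the reference signatures.

    Returns None for samples below the mutation-count gate.  The spectrum
    is normalized to fractions and decomposed by NNLS; signatures whose
    normalized weight falls below ``discard_below`` are zeroed and the
    remainder refitted until the active set is stable.
    """
    if spectrum.total == 0:
        raise ValueError("all-zero spectrum cannot be fitted")
    if spectrum.total < min_mutations:
        return None
    target = spectrum.counts / spectrum.total
    S = signatures.to_numpy().T          # 96 x k
    names = list(signatures.index)
    active = np.ones(S.shape[1], dtype=bool)
    w_full = np.zeros(S.shape[1])
    for _ in range(S.shape[1]):
        w, _rnorm = nnls(S[:, active], target)
        w_full[:] = 0.0
        w_full[active] = w
        total = w_full.sum()
        if total <= 0:
            break
        drop = active & (w_full / total < discard_below) & (w_full > 0)
        small_zero = active & (w_full == 0)
        if not drop.any() and not small_zero.any():
            break
        active &= ~(drop | small_zero)
        if not active.any():
            break
    total = w_full.sum()
    if total > 1.0:
        w_full = w_full / total
    resid_frac = 1.0 - w_full.sum()
    recon = S @ w_full
    sse = float(((recon - target) ** 2).sum())
    weights = {names[i]: float(w_full[i]) for i in range(len(names)) if w_full[i] > 0}
    return ExposureWeights(spectrum.sample_id, weights, float(resid_frac), sse)


@dataclass
class SignatureComparison:
    signature: str
    test: str
    statistic: float
    pvalue: float
    medians: pd.Series          # subtype -> median weight


def cohort_signature_table(bundle: CohortBundle, calls: pd.DataFrame,
                           signatures: pd.DataFrame, min_mutations: int = 50,
                           discard_below: float = 0.06,
                           compare: str = UV_SIGNATURE
                           ) -> tuple[pd.DataFrame, SignatureComparison | None]:
    """Fit exposures for every eligible sample and compare the UV-signature
    weight across subtypes with a Kruskal-Wallis test.

    Returns (per-sample exposure table with one column per signature plus
    ``residual``/``sse``/``n_mutations``, comparison or None when fewer
    than two subtypes have fitted samples).
    """
    rows = []
    for sid, records in bundle.mutations.groupby("sample_id", sort=True):
        spec = spectrum_from_mutations(records)
        if spec.total == 0:
            continue
        exp = fit_exposures(spec, signatures, min_mutations, discard_below)
        if exp is None:
            continue
        row = {"sample_id": sid, "n_mutations": spec.total,
               "residual": exp.residual, "sse": exp.sse}
        for name in signatures.index:
            row[name] = exp.weights.get(name, 0.0)
        rows.append(row)
    exposures = pd.DataFrame(rows)
    if exposures.empty:
        log.warning("no samples passed the %d-mutation gate", min_mutations)
        return exposures, None

    merged = exposures.merge(calls[["sample_id", "subtype"]], on="sample_id")
    merged = merged[merged["subtype"] != EXCLUDED]
    groups = {s: g[compare].to_numpy(float)
              for s, g in merged.groupby("subtype") if len(g) >= 2}
    if len(groups) < 2:
        log.warning("fewer than two subtypes with fitted samples; comparison skipped")
        return exposures, None
    stat, p = stats.kruskal(*groups.values())
    medians = pd.Series({s: float(np.median(v)) for s, v in groups.items()})
    return exposures, SignatureComparison(compare, "kruskal_wallis",
                                          float(stat), float(p), medians)
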