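"""Reading, writing and harmonization of somatic-mutation and clinical tables.

Mutation catalogs arrive as MAF-like tab-separated tables (one row per
somatic variant per tumor).  This module normalizes the variant-class
vocabulary onto a small fixed enum, joins several source cohorts into one
analysis-ready :class:`CohortBundle` restricted to the genes shared by all
cohorts, and screens for cross-cohort duplicate samples by mutation-key
overlap.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Variant-class vocabulary
# --------------------------------------------------------------------------

MISSENSE = "missense"
NONSENSE = "nonsense"
NONSTOP = "nonstop"
FRAMESHIFT_INDEL = "frameshift_indel"
INFRAME_INDEL = "inframe_indel"
SPLICE_SITE = "splice_site"
SYNONYMOUS = "synonymous"
NONCODING = "noncoding"

VARIANT_CLASSES = frozenset({
    MISSENSE, NONSENSE, NONSTOP, FRAMESHIFT_INDEL, INFRAME_INDEL,
    SPLICE_SITE, SYNONYMOUS, NONCODING,
})

#: Protein-altering classes: missense, nonsense, nonstop, focal indels
#: (frameshift and in-frame) and splice-site variants.
NONSYNONYMOUS_CLASSES = frozenset({
    MISSENSE, NONSENSE, NONSTOP, FRAMESHIFT_INDEL, INFRAME_INDEL, SPLICE_SITE,
})

INDEL_CLASSES = frozenset({FRAMESHIFT_INDEL, INFRAME_INDEL})

#: Synonym table mapping MAF ``Variant_Classification`` strings onto the
#: internal enum.  Anything absent from this table is treated as noncoding
#: (and logged), which is where MAF consequence classes such as Intron,
#: 3'UTR, IGR or RNA belong for burden accounting.
MAF_CLASS_SYNONYMS: dict[str, str] = {
    "Missense_Mutation": MISSENSE,
    "Nonsense_Mutation": NONSENSE,
    "Nonstop_Mutation": NONSTOP,
    "Frame_Shift_Del": FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": FRAMESHIFT_INDEL,
    "In_Frame_Del": INFRAME_INDEL,
    "In_Frame_Ins": INFRAME_INDEL,
    "Splice_Site": SPLICE_SITE,
    "Silent": SYNONYMOUS,
    "Synonymous": SYNONYMOUS,
    # already-normalized names map to themselves
    **{c: c for c in VARIANT_CLASSES},
}

MUTATION_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "variant_class", "protein_change", "context3", "cohort",
]

CLINICAL_COLUMNS = [
    "sample_id", "age", "gender", "tumor_type", "origin",
    "os_time", "os_event", "dss_event", "treated", "cohort",
]

MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_class",
    "Protein_Change": "protein_change",
}

DNA_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


def is_snv(ref: str, alt: str) -> bool:
    """True for a single-nucleotide substitution (both alleles one base)."""
    return len(ref) == 1 and len(alt) == 1 and ref in DNA_BASES and alt in DNA_BASES


# --------------------------------------------------------------------------
# Bundle container
# --------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Analysis-ready cohort: mutation rows, clinical rows, gene universe.

    ``mutations`` has the :data:`MUTATION_COLUMNS` layout, ``clinical``
    the :data:`CLINICAL_COLUMNS` layout (plus an ``in_mutation_data`` flag
    after harmonization).  ``gene_universe`` is the set of HUGO symbols the
    mutation table is restricted to.
    """

    mutations: pd.DataFrame
    clinical: pd.DataFrame
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_universe:
            self.gene_universe = set(self.mutations["gene"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.mutations["sample_id"].unique())

    def validate(self) -> None:
        m = self.mutations
        if (m["pos"] < 1).any():
            raise ValueError("mutation positions must be 1-based (pos >= 1)")
        bad = set(m["variant_class"]) - VARIANT_CLASSES
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")
        outside = set(m["gene"]) - self.gene_universe
        if outside:
            raise ValueError(f"mutations outside gene_universe: {sorted(outside)[:5]}")
        dup = self.clinical["sample_id"].duplicated()
        if dup.any():
            raise ValueError("clinical table has duplicated sample_ids")
        ctx = m["context3"].fillna("")
        has_ctx = ctx != ""
        if has_ctx.any():
            snv = m["ref"].str.len().eq(1) & m["alt"].str.len().eq(1)
            bad_len = has_ctx & (ctx.str.len() != 3)
            if bad_len.any():
                raise ValueError("context3 must be empty or length 3")
            mism = has_ctx & snv & (ctx.str[1] != m["ref"])
            if mism.any():
                raise ValueError("context3 middle base must equal ref for SNVs")


@dataclass
class HarmonizeReport:
    """What harmonization dropped or flagged, per the row-conservation rule."""

    gene_universe_size: int
    input_mutation_rows: int
    dropped_mutation_rows: int
    dropped_samples: list[str]
    clinical_without_mutations: list[str]

    @property
    def retained_mutation_rows(self) -> int:
        return self.input_mutation_rows - self.dropped_mutation_rows


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def normalize_variant_classes(raw: pd.Series) -> pd.Series:
    """Map raw variant-class strings onto the enum; unmapped -> noncoding."""
    mapped = raw.map(MAF_CLASS_SYNONYMS)
    unmapped = mapped.isna()
    if unmapped.any():
        log.warning(
            "%d rows with unmappable variant classes %s treated as noncoding",
            int(unmapped.sum()), sorted(raw[unmapped].unique())[:10],
        )
        mapped = mapped.fillna(NONCODING)
    return mapped


def read_mutation_table(path: str | Path, dialect: str = "maf",
                        cohort: str | None = None) -> pd.DataFrame:
    """Read a mutation table in the ``maf`` or ``simple_tsv`` dialect.

    Returns a DataFrame with the :data:`MUTATION_COLUMNS` layout.  ``cohort``
    overrides / supplies the source-study label.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "maf":
        required = [c for c in MAF_COLUMN_MAP if c != "Protein_Change"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required MAF column(s) {missing}")
        df = df.rename(columns=MAF_COLUMN_MAP)
    elif dialect == "simple_tsv":
        required = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in ("protein_change", "context3", "cohort"):
        if col not in df.columns:
            df[col] = ""
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna()
    if bad.any():
        # +2 -> 1-based line number counting the header line
        lineno = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: unparseable position at line {lineno}")
    df["pos"] = pos.astype(int)
    df["variant_class"] = normalize_variant_classes(df["variant_class"])
    if cohort is not None:
        df["cohort"] = cohort
    df["chrom"] = df["chrom"].astype(str)
    return df[MUTATION_COLUMNS].copy()


def read_clinical_table(path: str | Path, cohort: str | None = None) -> pd.DataFrame:
    """Read a clinical annotation table (simple_tsv dialect)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column(s) ['sample_id']")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    for col in ("age", "os_time"):
        df[col] = pd.to_numeric(df[col].replace("", None), errors="coerce")
    for col in ("os_event", "dss_event", "treated"):
        df[col] = pd.to_numeric(df[col].replace("", None), errors="coerce")
    for col in ("gender", "tumor_type", "origin"):
        df[col] = df[col].replace("", "missing")
    if cohort is not None:
        df["cohort"] = cohort
    if (df["os_time"].dropna() < 0).any():
        raise FormatError(f"{path}: negative follow-up time")
    dss1 = df["dss_event"] == 1
    if (dss1 & (df["os_event"] != 1)).any():
        raise FormatError(f"{path}: dss_event=1 requires os_event=1")
    return df[CLINICAL_COLUMNS].copy()


def write_mutation_table(df: pd.DataFrame, path: str | Path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c in CLINICAL_COLUMNS or c == "in_mutation_data"]
    df[cols].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Harmonization & duplicate screening
# --------------------------------------------------------------------------

def harmonize(bundles: Sequence[CohortBundle]) -> tuple[CohortBundle, HarmonizeReport]:
    """Join cohorts on the shared-gene intersection.

    The gene universe of the result is the intersection of the inputs'
    universes; mutation rows outside it are dropped, samples left with zero
    mutation rows are dropped and reported, and clinical records with no
    mutation row are retained but flagged (``in_mutation_data = False``).
    """
    if not bundles:
        raise ValueError("harmonize requires at least one bundle")
    universe: set[str] = set(bundles[0].gene_universe)
    for b in bundles[1:]:
        universe &= b.gene_universe
    if not universe:
        raise ValueError("empty shared-gene intersection across cohorts")

    mutations = pd.concat([b.mutations for b in bundles], ignore_index=True)
    clinical = pd.concat([b.clinical for b in bundles], ignore_index=True)
    n_in = len(mutations)
    keep = mutations["gene"].isin(universe)
    dropped_rows = int((~keep).sum())
    samples_before = set(mutations["sample_id"])
    mutations = mutations[keep].reset_index(drop=True)
    samples_after = set(mutations["sample_id"])
    dropped_samples = sorted(samples_before - samples_after)
    if dropped_samples:
        log.warning("%d sample(s) left without somatic mutations over the "
                    "shared genes and dropped: %s", len(dropped_samples),
                    dropped_samples[:10])

    clinical = clinical.copy()
    clinical["in_mutation_data"] = clinical["sample_id"].isin(samples_after)
    report = HarmonizeReport(
        gene_universe_size=len(universe),
        input_mutation_rows=n_in,
        dropped_mutation_rows=dropped_rows,
        dropped_samples=dropped_samples,
        clinical_without_mutations=sorted(
            clinical.loc[~clinical["in_mutation_data"], "sample_id"]),
    )
    return CohortBundle(mutations, clinical, universe), report


def mutation_keys(bundle: CohortBundle) -> dict[str, frozenset]:
    """Per-sample sets of (gene, chrom, pos, alt) mutation keys.

    ref and variant class are deliberately excluded so that cohorts annotated
    by different pipelines still collide on shared events.
    """
    m = bundle.mutations
    keys: dict[str, set] = {}
    for sid, gene, chrom, pos, alt in zip(
            m["sample_id"], m["gene"], m["chrom"], m["pos"], m["alt"]):
        keys.setdefault(sid, set()).add((gene, chrom, pos, alt))
    return {s: frozenset(v) for s, v in keys.items()}


@dataclass(frozen=True)
class DuplicatePair:
    sample_a: str
    sample_b: str
    agreement: float


def find_duplicates(bundle: CohortBundle, threshold: float = 0.3) -> list[DuplicatePair]:
    """Flag cross-cohort sample pairs sharing > ``threshold`` of mutations.

    Agreement is |keys(A) ∩ keys(B)| / min(|keys(A)|, |keys(B)|); pairs are
    returned sorted by decreasing agreement.  Only pairs from different
    source cohorts are compared (duplicates within one study are that
    study's own problem).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    keys = mutation_keys(bundle)
    cohort_of = dict(zip(bundle.mutations["sample_id"], bundle.mutations["cohort"]))
    samples = sorted(keys)
    empty = [s for s in samples if not keys[s]]
    for s in empty:
        log.warning("sample %s has no mutation keys; excluded from pairing", s)
    samples = [s for s in samples if keys[s]]

    # invert: key -> samples, so only pairs that share at least one key are touched
    by_key: dict[tuple, list[str]] = {}
    for s in samples:
        for k in keys[s]:
            by_key.setdefault(k, []).append(s)
    candidate_pairs: set[tuple[str, str]] = set()
    for shared in by_key.values():
        for a, b in itertools.combinations(sorted(shared), 2):
            if cohort_of.get(a) != cohort_of.get(b):
                candidate_pairs.add((a, b))

    out = []
    for a, b in candidate_pairs:
        inter = len(keys[a] & keys[b])
        agreement = inter / min(len(keys[a]), len(keys[b]))
        if agreement > threshold:
            out.append(DuplicatePair(a, b, agreement))
    out.sort(key=lambda p: (-p.agreement, p.sample_a, p.sample_b))
    return out
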