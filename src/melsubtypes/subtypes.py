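"""MAPK genomic subtyping of melanoma samples.

Samples are assigned to one of four genomic subtypes from their somatic
mutation records:

* **BRAF** — a hotspot mutation whose affected residue span touches V600
  or K601 of BRAF;
* **RAS** — a hotspot mutation at Q61, G12 or G13 of NRAS, KRAS or HRAS;
* **NF1** — any nonsynonymous NF1 mutation (without a BRAF/RAS hotspot);
* **TRIPLE_WT** — none of the above.

Samples co-mutated for NF1 and a BRAF or RAS hotspot go to the hotspot
subtype (the NF1 evidence is kept as a flag); samples with both BRAF and
RAS hotspots are EXCLUDED from downstream contrasts.  BRAF P-loop
mutations (codons 466-471) and recurrent KIT/GNA11/GNAQ mutations are
recorded as informational flags only.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_io import CohortBundle, NONSYNONYMOUS_CLASSES

log = logging.getLogger(__name__)

BRAF = "BRAF"
RAS = "RAS"
NF1 = "NF1"
TRIPLE_WT = "TRIPLE_WT"
EXCLUDED = "EXCLUDED"
SUBTYPES = (BRAF, RAS, NF1, TRIPLE_WT, EXCLUDED)

RAS_GENES = frozenset({"NRAS", "KRAS", "HRAS"})
BRAF_HOTSPOT_CODONS = frozenset({600, 601})
BRAF_PLOOP_CODONS = frozenset(range(466, 472))
RAS_HOTSPOT_CODONS = frozenset({12, 13, 61})
NF1_LOF_CLASSES = frozenset({"nonsense", "frameshift_indel", "splice_site"})

#: Recurrent activating mutations in the rarer MAPK genes, annotated as an
#: informational flag on triple-wild-type samples.
RECURRENT_KIT_GNA = {
    "KIT": {"p.K642E", "p.V559A", "p.N822K", "p.L576P", "p.W557R", "p.N822I"},
    "GNA11": {"p.Q209L", "p.Q209H", "p.R183C"},
    "GNAQ": {"p.Q209P", "p.Q209L", "p.R183Q", "p.R183*"},
}

_PROTEIN_RE = re.compile(
    r"^p\.\(?"
    r"(?P<ref>[A-Z*])(?:[a-z]{2})?"      # first residue, 1- or 3-letter
    r"(?P<start>\d+)"
    r"(?:_(?:[A-Z*])(?:[a-z]{2})?(?P<end>\d+))?"  # optional span end
)


@dataclass(frozen=True)
class ProteinPos:
    """First affected residue of an HGVS-p change, with its codon span."""

    ref_aa: str
    start: int
    end: int

    def span_intersects(self, codons: frozenset[int]) -> bool:
        return any(self.start <= c <= self.end for c in codons)


def parse_protein_pos(protein_change: str) -> Optional[ProteinPos]:
    """Extract (reference residue, codon span) from an HGVS-p string.

    Handles ``p.V600E``, ``p.Q61*``, ``p.V600_K601delinsE``, ``p.K583fs``
    and 3-letter forms like ``p.Val600Glu``; empty or unparseable strings
    return None.
    """
    if not protein_change:
        return None
    m = _PROTEIN_RE.match(protein_change.strip())
    if m is None:
        log.debug("unparseable protein change %r", protein_change)
        return None
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    return ProteinPos(m.group("ref"), start, max(start, end))


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    braf_hotspot: bool
    braf_ploop: bool
    ras_hotspot: bool
    nf1_nonsyn: bool
    nf1_lof: bool
    twt_kit_gna_recurrent: bool = False


def _nonsyn_in(records: pd.DataFrame, genes) -> pd.DataFrame:
    mask = records["gene"].isin(genes) & records["variant_class"].isin(NONSYNONYMOUS_CLASSES)
    return records[mask]


def _any_codon_hit(records: pd.DataFrame, codons: frozenset[int]) -> bool:
    for pc in records["protein_change"]:
        pos = parse_protein_pos(pc)
        if pos is not None and pos.span_intersects(codons):
            return True
    return False


def is_braf_hotspot(records: pd.DataFrame) -> bool:
    """Any nonsynonymous BRAF record whose codon span touches 600/601."""
    return _any_codon_hit(_nonsyn_in(records, [BRAF]), BRAF_HOTSPOT_CODONS)


def is_braf_ploop(records: pd.DataFrame) -> bool:
    return _any_codon_hit(_nonsyn_in(records, [BRAF]), BRAF_PLOOP_CODONS)


def is_ras_hotspot(records: pd.DataFrame) -> bool:
    """Any nonsynonymous N/K/HRAS record at codon 12, 13 or 61."""
    return _any_codon_hit(_nonsyn_in(records, RAS_GENES), RAS_HOTSPOT_CODONS)


def classify_sample(records: pd.DataFrame) -> SubtypeCall:
    """Assign one sample's subtype with the precedence
    EXCLUDED (BRAF and RAS hotspots) > BRAF > RAS > NF1 > TRIPLE_WT."""
    sids = records["sample_id"].unique()
    if len(sids) > 1:
        raise ValueError("classify_sample expects records from a single sample")
    sample_id = sids[0] if len(sids) else ""

    braf = is_braf_hotspot(records)
    ploop = is_braf_ploop(records)
    ras = is_ras_hotspot(records)
    nf1_records = _nonsyn_in(records, [NF1])
    nf1_nonsyn = len(nf1_records) > 0
    nf1_lof = bool(nf1_records["variant_class"].isin(NF1_LOF_CLASSES).any())

    if braf and ras:
        subtype = EXCLUDED
    elif braf:
        subtype = BRAF
    elif ras:
        subtype = RAS
    elif nf1_nonsyn:
        subtype = NF1
    else:
        subtype = TRIPLE_WT

    recurrent = False
    if subtype == TRIPLE_WT:
        for gene, changes in RECURRENT_KIT_GNA.items():
            sub = _nonsyn_in(records, [gene])
            if sub["protein_change"].isin(changes).any():
                recurrent = True
                break

    return SubtypeCall(sample_id, subtype, braf, ploop, ras,
                       nf1_nonsyn, nf1_lof, recurrent)


CALL_COLUMNS = ["sample_id", "subtype", "braf_hotspot", "braf_ploop",
                "ras_hotspot", "nf1_nonsyn", "nf1_lof", "twt_kit_gna_recurrent"]


def _span_hits(protein: pd.Series, codons: frozenset[int]) -> pd.Series:
    """Vectorized span-vs-codon-set test with a parse cache per unique string."""
    cache = {
        pc: (pos.span_intersects(codons) if (pos := parse_protein_pos(pc)) else False)
        for pc in protein.unique()
    }
    return protein.map(cache)


def classify_cohort(bundle: CohortBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample with at least one mutation record.

    Vectorized but decision-identical to per-sample :func:`classify_sample`
    (asserted by the test suite).  Returns (per-sample call table, subtype
    count/fraction summary).
    """
    m = bundle.mutations
    samples = pd.Index(sorted(m["sample_id"].unique()), name="sample_id")
    nonsyn = m[m["variant_class"].isin(NONSYNONYMOUS_CLASSES)]

    def per_sample_any(mask: pd.Series) -> pd.Series:
        hit = nonsyn.loc[mask, "sample_id"].unique()
        return pd.Series(samples.isin(hit), index=samples)

    braf_rows = nonsyn["gene"] == BRAF
    ras_rows = nonsyn["gene"].isin(RAS_GENES)
    braf = per_sample_any(braf_rows & _span_hits(nonsyn["protein_change"].where(braf_rows, ""), BRAF_HOTSPOT_CODONS))
    ploop = per_sample_any(braf_rows & _span_hits(nonsyn["protein_change"].where(braf_rows, ""), BRAF_PLOOP_CODONS))
    ras = per_sample_any(ras_rows & _span_hits(nonsyn["protein_change"].where(ras_rows, ""), RAS_HOTSPOT_CODONS))
    nf1_rows = nonsyn["gene"] == NF1
    nf1_nonsyn = per_sample_any(nf1_rows)
    nf1_lof = per_sample_any(nf1_rows & nonsyn["variant_class"].isin(NF1_LOF_CLASSES))

    subtype = np.select(
        [braf & ras, braf, ras, nf1_nonsyn],
        [EXCLUDED, BRAF, RAS, NF1],
        default=TRIPLE_WT,
    )
    recurrent_rows = pd.Series(False, index=nonsyn.index)
    for gene, changes in RECURRENT_KIT_GNA.items():
        recurrent_rows |= (nonsyn["gene"] == gene) & nonsyn["protein_change"].isin(changes)
    recurrent = per_sample_any(recurrent_rows) & (subtype == TRIPLE_WT)

    table = pd.DataFrame({
        "sample_id": samples,
        "subtype": subtype,
        "braf_hotspot": braf.to_numpy(),
        "braf_ploop": ploop.to_numpy(),
        "ras_hotspot": ras.to_numpy(),
        "nf1_nonsyn": nf1_nonsyn.to_numpy(),
        "nf1_lof": nf1_lof.to_numpy(),
        "twt_kit_gna_recurrent": recurrent.to_numpy(),
    }).reset_index(drop=True)
    if table.empty:
        table = pd.DataFrame(columns=CALL_COLUMNS)
    counts = table["subtype"].value_counts().reindex(SUBTYPES, fill_value=0)
    summary = pd.DataFrame({
        "subtype": counts.index,
        "n": counts.to_numpy(),
    })
    summary["fraction"] = summary["n"] / max(len(table), 1)
    return table, summary


def subtype_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Convenience: subtype -> n over a call table."""
    return {s: int((calls["subtype"] == s).sum()) for s in SUBTYPES}
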