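"""Post-call somatic filtering of tumor/normal candidate variant calls.

Calls are accepted when the matched-normal site is adequately covered
(>= 8x), the tumor site is adequately covered (>= 6x), at least four reads
support the alternate allele, those reads make up at least 10% of the tumor
reads, and the matched normal shows at most 3% alternate reads.  All five
thresholds are configurable and all inequalities are inclusive.  A failing
call carries *every* violated criterion, not just the first.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

# criterion labels used in decisions and rejection reports
R_NORMAL_DEPTH = "normal_depth"
R_TUMOR_DEPTH = "tumor_depth"
R_MIN_MUTANT_READS = "min_mutant_reads"
R_TUMOR_VAF = "tumor_vaf"
R_NORMAL_VAF = "normal_vaf"
R_NO_COVERAGE = "no_coverage"

ALL_REASONS = (R_NORMAL_DEPTH, R_TUMOR_DEPTH, R_MIN_MUTANT_READS,
               R_TUMOR_VAF, R_NORMAL_VAF, R_NO_COVERAGE)

CALL_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt",
                "tumor_depth", "tumor_alt_reads", "normal_depth", "normal_alt_reads"]


@dataclass(frozen=True)
class FilterConfig:
    """Somatic-filter thresholds (defaults: the deep-sequencing screen)."""

    min_normal_depth: int = 8
    min_tumor_depth: int = 6
    min_mutant_reads: int = 4
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.03


@dataclass(frozen=True)
class CandidateCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt_reads: int
    normal_depth: int
    normal_alt_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_alt_reads <= self.tumor_depth):
            raise ValueError("tumor_alt_reads must lie in [0, tumor_depth]")
        if not (0 <= self.normal_alt_reads <= self.normal_depth):
            raise ValueError("normal_alt_reads must lie in [0, normal_depth]")


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: frozenset[str]


def filter_call(call: CandidateCall, config: FilterConfig = FilterConfig()) -> FilterDecision:
    """Apply every threshold to one call; FAIL carries all violated criteria."""
    reasons: set[str] = set()
    if call.normal_depth < config.min_normal_depth:
        reasons.add(R_NORMAL_DEPTH)
    if call.tumor_depth < config.min_tumor_depth:
        reasons.add(R_TUMOR_DEPTH)
    if call.tumor_alt_reads < config.min_mutant_reads:
        reasons.add(R_MIN_MUTANT_READS)
    if call.tumor_depth == 0:
        reasons.add(R_NO_COVERAGE)
    elif call.tumor_alt_reads / call.tumor_depth < config.min_tumor_vaf:
        reasons.add(R_TUMOR_VAF)
    if call.normal_depth > 0:
        if call.normal_alt_reads / call.normal_depth > config.max_normal_vaf:
            reasons.add(R_NORMAL_VAF)
    return FilterDecision(passed=not reasons, reasons=frozenset(reasons))


def filter_table(calls: pd.DataFrame, config: FilterConfig = FilterConfig()
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition a candidate-call table into passing keys and a rejection report.

    Returns (passing rows with the site-key columns, counts of failures per
    criterion).  Decisions are vectorized but identical to per-call
    :func:`filter_call`.
    """
    if calls.empty:
        return calls.reindex(columns=CALL_COLUMNS[:5]).copy(), {}
    td = calls["tumor_depth"].to_numpy()
    ta = calls["tumor_alt_reads"].to_numpy()
    nd = calls["normal_depth"].to_numpy()
    na = calls["normal_alt_reads"].to_numpy()

    v_nd = nd < config.min_normal_depth
    v_td = td < config.min_tumor_depth
    v_alt = ta < config.min_mutant_reads
    no_cov = td == 0
    # avoid division by zero; VAF criteria only evaluated where depth > 0
    v_tvaf = (~no_cov) & (ta < config.min_tumor_vaf * td)
    v_nvaf = (nd > 0) & (na > config.max_normal_vaf * nd)

    any_fail = v_nd | v_td | v_alt | no_cov | v_tvaf | v_nvaf
    report = {
        R_NORMAL_DEPTH: int(v_nd.sum()),
        R_TUMOR_DEPTH: int(v_td.sum()),
        R_MIN_MUTANT_READS: int(v_alt.sum()),
        R_TUMOR_VAF: int(v_tvaf.sum()),
        R_NORMAL_VAF: int(v_nvaf.sum()),
        R_NO_COVERAGE: int(no_cov.sum()),
    }
    report = {k: v for k, v in report.items() if v}
    passing = calls.loc[~any_fail, ["sample_id", "chrom", "pos", "ref", "alt"]]
    return passing.reset_index(drop=True), report


def decisions_from_table(calls: pd.DataFrame, config: FilterConfig = FilterConfig()
                         ) -> list[FilterDecision]:
    """Per-row :func:`filter_call` decisions (the slow reference path)."""
    out = []
    for row in calls.itertuples(index=False):
        call = CandidateCall(str(row.sample_id), str(row.chrom), int(row.pos),
                             str(row.ref), str(row.alt),
                             int(row.tumor_depth), int(row.tumor_alt_reads),
                             int(row.normal_depth), int(row.normal_alt_reads))
        out.append(filter_call(call, config))
    return out
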