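"""End-to-end orchestration: harmonize -> (filter) -> classify -> burden ->
enrichment -> signatures -> survival, with TSV outputs per stage and one
machine-readable run summary.  Identical config + seed gives an identical
summary."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import clinical_association_table, compare_loads, compute_loads
from .cohort_io import (CohortBundle, find_duplicates, harmonize,
                        read_clinical_table, read_mutation_table,
                        write_clinical_table, write_mutation_table)
from .enrichment import gene_logistic_screen, pathway_screen
from .signatures import cohort_signature_table, load_signature_matrix, UV_SIGNATURE
from .simulate import GeneratorConfig, generate_cohort, synthetic_signature_matrix
from .somatic_filter import FilterConfig, filter_table
from .subtypes import classify_cohort
from .survival import subtype_survival_analysis

log = logging.getLogger(__name__)

ALL_STAGES = ("harmonize", "filter", "classify", "burden", "enrich",
              "signatures", "survival")


@dataclass
class RunConfig:
    """One pipeline run: either real input tables or a simulate block."""

    output_dir: Path
    seed: int = 1
    mutation_tables: list[dict] = field(default_factory=list)   # path/dialect/cohort
    clinical_tables: list[dict] = field(default_factory=list)
    candidate_calls: Path | None = None
    signature_matrix: Path | None = None
    simulate: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    dedup_threshold: float = 0.3
    min_mutations: int = 50
    fdr_level: float = 0.05
    censoring_horizon: float = 60.0
    min_freq: float = 5 / 870

    def __post_init__(self) -> None:
        has_inputs = bool(self.mutation_tables)
        if has_inputs == (self.simulate is not None):
            raise ValueError("config needs exactly one of input tables or a "
                             "simulate block")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fc = FilterConfig(**raw.pop("filter", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(filter_config=fc, stages=stages, **raw)

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["output_dir"] = str(self.output_dir)
        d["candidate_calls"] = str(self.candidate_calls) if self.candidate_calls else None
        d["signature_matrix"] = str(self.signature_matrix) if self.signature_matrix else None
        d["filter_config"] = self.filter_config.__dict__
        d["stages"] = list(self.stages)
        d["version"] = __version__
        return d


def _load_inputs(config: RunConfig) -> CohortBundle:
    if config.simulate is not None:
        gen = GeneratorConfig(**{**config.simulate, "seed": config.seed})
        return generate_cohort(gen)
    bundles = []
    clin_by_cohort: dict[str, pd.DataFrame] = {}
    for spec in config.clinical_tables:
        label = spec.get("cohort", Path(spec["path"]).stem)
        clin_by_cohort[label] = read_clinical_table(spec["path"], cohort=label)
    for spec in config.mutation_tables:
        label = spec.get("cohort", Path(spec["path"]).stem)
        mut = read_mutation_table(spec["path"], dialect=spec.get("dialect", "maf"),
                                  cohort=label)
        clin = clin_by_cohort.get(
            label, pd.DataFrame({"sample_id": mut["sample_id"].unique()})
            .pipe(lambda d: d.reindex(columns=["sample_id"])))
        if "cohort" not in clin.columns:
            clin["cohort"] = label
        bundles.append(CohortBundle(mut, clin))
    merged, _ = harmonize(bundles)
    return merged


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages in order; write per-stage TSVs plus
    ``run_summary.json`` under ``output_dir``; return the summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": config.echo(), "stages": {}}
    stage = "load"
    try:
        bundle = _load_inputs(config)

        if "harmonize" in config.stages:
            stage = "harmonize"
            merged, report = harmonize([bundle])
            dupes = find_duplicates(merged, config.dedup_threshold)
            write_mutation_table(merged.mutations, out / "mutations.tsv")
            write_clinical_table(merged.clinical, out / "clinical.tsv")
            summary["stages"]["harmonize"] = {
                "n_samples": len(merged.sample_ids),
                "gene_universe": report.gene_universe_size,
                "dropped_samples": report.dropped_samples,
                "duplicate_pairs": [[d.sample_a, d.sample_b, round(d.agreement, 4)]
                                    for d in dupes],
            }
            bundle = merged

        if "filter" in config.stages and config.candidate_calls is not None:
            stage = "filter"
            calls_df = pd.read_csv(config.candidate_calls, sep="\t")
            passing, report = filter_table(calls_df, config.filter_config)
            passing.to_csv(out / "filter_passing.tsv", sep="\t", index=False)
            summary["stages"]["filter"] = {
                "n_calls": len(calls_df), "n_pass": len(passing),
                "rejections": report,
            }

        stage = "classify"
        calls, subtype_summary = classify_cohort(bundle)
        calls.to_csv(out / "subtypes.tsv", sep="\t", index=False)
        summary["stages"]["classify"] = {
            "counts": dict(zip(subtype_summary["subtype"],
                               subtype_summary["n"].astype(int))),
        }

        loads = compute_loads(bundle)
        if "burden" in config.stages:
            stage = "burden"
            loads.to_csv(out / "loads.tsv", sep="\t", index=False)
            grouping = calls.set_index("sample_id")["subtype"]
            grouping = grouping[grouping != "EXCLUDED"]
            cmp_res = compare_loads(loads, grouping)
            assoc = clinical_association_table(
                calls, bundle.clinical, rng=np.random.default_rng(config.seed))
            summary["stages"]["burden"] = {
                "test": cmp_res.test, "p": cmp_res.pvalue,
                "medians": dict(zip(cmp_res.groups["group"],
                                    cmp_res.groups["median"])),
                "clinical_associations": {a.covariate: a.pvalue for a in assoc},
            }

        if "enrich" in config.stages:
            stage = "enrich"
            screen = gene_logistic_screen(bundle, calls, loads,
                                          min_freq=config.min_freq)
            screen.to_csv(out / "gene_screen.tsv", sep="\t", index=False)
            prevalence, pw_assoc = pathway_screen(bundle, calls, loads)
            prevalence.to_csv(out / "pathway_prevalence.tsv", sep="\t", index=False)
            pw_assoc.to_csv(out / "pathway_screen.tsv", sep="\t", index=False)
            top = (screen[(screen["contrast"] == "NF1")
                          & (screen["q"] < config.fdr_level)
                          & (screen["coef"] > 0)]
                   .nsmallest(10, "q")["gene"].tolist()) if not screen.empty else []
            summary["stages"]["enrich"] = {
                "n_genes_tested": int(screen["gene"].nunique()) if not screen.empty else 0,
                "top_nf1_enriched": top,
                "pathway_prevalence": {r.pathway: (None if pd.isna(r.prevalence)
                                                   else round(float(r.prevalence), 4))
                                       for r in prevalence.itertuples()},
            }

        if "signatures" in config.stages:
            stage = "signatures"
            if config.signature_matrix is not None:
                matrix = load_signature_matrix(config.signature_matrix)
            else:
                matrix = synthetic_signature_matrix()
            exposures, comparison = cohort_signature_table(
                bundle, calls, matrix, min_mutations=config.min_mutations)
            exposures.to_csv(out / "exposures.tsv", sep="\t", index=False)
            summary["stages"]["signatures"] = {
                "n_fitted": len(exposures),
                "uv_medians": (comparison.medians.round(4).to_dict()
                               if comparison else None),
                "kruskal_p": comparison.pvalue if comparison else None,
            }

        if "survival" in config.stages:
            stage = "survival"
            report = subtype_survival_analysis(
                calls, bundle.clinical, horizon=config.censoring_horizon)
            report.to_csv(out / "survival.tsv", sep="\t", index=False)
            hr_rows = report[(report.get("model") == "unadjusted")
                             & report.get("hr").notna()] if not report.empty else report
            summary["stages"]["survival"] = {
                "hr_table": [
                    {k: (round(v, 4) if isinstance(v, float) else v)
                     for k, v in r.items() if pd.notna(v)}
                    for r in hr_rows.to_dict("records")
                ],
            }
    except Exception as exc:
        summary["failed_stage"] = stage
        with open(out / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
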