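# melsubtypes

Genomic subtyping and mutational-landscape analysis of melanoma cohorts.

Cutaneous melanoma is dominated by constitutive MAPK-pathway activation,
and tumors fall into four genomic subtypes defined by their driver
mutations: **BRAF** (hotspot at V600/K601), **RAS** (NRAS/KRAS/HRAS hotspot
at Q61/G12/G13), **NF1** (any nonsynonymous mutation in the RAS-GAP *NF1*),
and **triple-wild-type** (none of the above). The subtypes differ in
mutational burden, UV-signature exposure, co-mutated genes, patient
demographics and survival — the NF1 subtype in particular carries a
several-fold higher mutation load and a roughly doubled death hazard.

`melsubtypes` turns that analysis into a tested, reusable pipeline for
MAF-like somatic mutation catalogs compiled across studies:

* **cohort_io** — read MAF / simple-TSV mutation and clinical tables,
  normalize variant-class vocabulary, intersect cohorts on shared genes,
  flag cross-cohort duplicate samples by mutation-key agreement.
* **somatic_filter** — tumor/normal post-call filter (normal ≥ 8×, tumor
  ≥ 6×, ≥ 4 mutant reads, tumor VAF ≥ 10 %, normal VAF ≤ 3 %; all
  configurable, failures carry every violated criterion).
* **subtypes** — hotspot-codon classifier with the precedence
  EXCLUDED (BRAF ∧ RAS) > BRAF > RAS > NF1 > triple-WT, plus P-loop,
  NF1-loss-of-function and KIT/GNAQ/GNA11 evidence flags.
* **burden** — total (SNV) and nonsynonymous loads, rank-test
  comparisons, Fisher/ANOVA clinical association tables.
* **enrichment** — per-gene logistic screen of mutation status on
  subtype + total load (Firth fallback under separation, BH FDR per
  contrast), the twelve-driver-pathway screen, mutual-exclusivity tests.
* **signatures** — 96-trinucleotide-context spectra and iterated-NNLS
  refitting of exposures against a reference signature matrix
  (≥ 50-mutation gate, 6 % discard threshold).
* **survival** — Kaplan–Meier/log-rank and Cox proportional-hazards
  contrasts (Efron ties, BRAF reference, 5-year censoring, OS and DSS).
* **simulate** — a synthetic cohort generator that reproduces the study
  conditions (subtype mix, load distributions, hotspot drivers, planted
  enriched genes, UV-skewed spectra, survival model) so every stage is
  validated against known ground truth.

## Worked example

```python
from melsubtypes import GeneratorConfig, generate_cohort, classify_cohort
from melsubtypes.burden import compute_loads, compare_loads
from melsubtypes.survival import apply_censoring, cox_fit, survival_frame

bundle = generate_cohort(GeneratorConfig(n_samples=870, seed=1))
calls, summary = classify_cohort(bundle)
print(summary.to_string(index=False))

loads = compute_loads(bundle)
grouping = calls.set_index("sample_id")["subtype"]
res = compare_loads(loads, grouping[grouping != "EXCLUDED"])
print(res.groups.to_string(index=False))
print(f"{res.test}: p = {res.pvalue:.3g}")

surv = survival_frame(bundle.clinical, "OS").merge(
    calls[["sample_id", "subtype"]], on="sample_id")
fit = cox_fit(apply_censoring(surv, 60.0), ["subtype"])
print(fit.summary.round(3).to_string())
```

prints

```
  subtype   n  fraction
     BRAF 419  0.481609
      RAS 238  0.273563
      NF1  90  0.103448
TRIPLE_WT 123  0.141379
 EXCLUDED   0  0.000000
    group   n  median  min    max
     BRAF 419    70.0  5.0 2436.0
      NF1  90   248.0 16.0 5075.0
      RAS 238    95.0  8.0 1187.0
TRIPLE_WT 123    18.0  2.0  215.0
kruskal_wallis: p = 7.18e-54
                   hazard_ratio  ci_lower  ci_upper      p
subtype_RAS               1.073     0.836     1.378  0.580
subtype_NF1               1.855     1.358     2.535  0.000
subtype_TRIPLE_WT         0.875     0.628     1.221  0.433
```

The classifier recovers the configured subtype mix (46/30/9/14 %), the
per-subtype load medians sit near their targets (69/95/246/19.5 SNVs),
and the unadjusted Cox contrast estimates the generator's NF1-vs-BRAF
hazard ratio of 2 with BRAF as reference; RAS and triple-WT, generated
with no excess hazard, stay near 1.

A command-line interface mirrors the stages
(`melsubtypes simulate | filter | harmonize | classify | burden | enrich |
signatures | survival | run-all`); `run-all --config cfg.yaml` executes
the whole pipeline and writes per-stage TSVs plus a machine-readable
`run_summary.json` that is bit-identical under a fixed config and seed.

## Documentation

`docs/methods.md` describes the statistical model behind each stage, the
synthetic-data generator's assumptions and calibration, numerical choices
and known limitations.
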