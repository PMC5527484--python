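# Methods

## Cohort harmonization

Mutation catalogs from different studies rarely cover the same genes
(targeted panels versus whole exomes), so all analyses run over the
intersection of the cohorts' gene universes. Mutation rows outside the
intersection are dropped with full row accounting; samples left with zero
rows are removed and reported, and clinical records without mutation data
are retained but flagged so downstream modules can exclude them
explicitly rather than silently.

Duplicate samples across studies are screened by mutation-key agreement:
keys are (gene, chromosome, position, alt allele) — the reference allele
and variant class are deliberately excluded because annotation pipelines
disagree on them more often than on the event itself — and agreement is
the shared-key count divided by the smaller sample's key count, which
stays well-behaved when a panel-sequenced sample is compared with an
exome. Pairs above the threshold (default 0.3) are reported, sorted by
agreement; which member to remove is a curation decision left to the
caller.

## Somatic filter

The post-call tumor/normal filter requires normal depth ≥ 8×, tumor depth
≥ 6×, ≥ 4 alternate reads forming ≥ 10 % of tumor reads, and ≤ 3 %
alternate reads in the matched normal. All inequalities are inclusive
("minimum"/"at least"/"at maximum" read literally), every threshold is a
`FilterConfig` field, and a failing call reports *all* violated criteria
so rejection tallies are interpretable. The variant allele fraction is
computed from the supplied read counts; no re-estimation, strand-bias or
mapping-quality logic is applied — those belong to the upstream caller.
A zero-depth tumor site fails with a dedicated `no_coverage` reason
instead of a division error.

## Subtype classification

Hotspots are matched on protein coordinates parsed from HGVS-p strings
(compiled cohorts are annotated at protein level, and the subtype
definitions are residue-based): BRAF when the affected codon span touches
600 or 601, RAS (NRAS/KRAS/HRAS) at codons 12, 13 or 61. Multi-residue
events count when their span intersects the hotspot set, so
`p.V600_K601delinsE` is a BRAF hotspot. The NF1 criterion is any
nonsynonymous mutation (missense, nonsense, nonstop, focal indel, splice
site). Precedence: samples carrying both BRAF and RAS hotspots are
EXCLUDED from contrasts; otherwise BRAF > RAS > NF1 > triple-wild-type,
i.e. NF1 co-mutation never overrides a hotspot but is retained as a flag,
as is NF1 loss-of-function (nonsense/frameshift/splice — a reporting
convention, not part of assignment), BRAF P-loop status (codons 466–471)
and recurrent KIT/GNA11/GNAQ mutations on triple-WT samples. The
vectorized cohort classifier is kept decision-identical to the
per-sample reference implementation by test.

## Mutational burden

Total load counts single-nucleotide variants of every class (noncoding,
synonymous, nonsynonymous) per sample; focal indels are excluded from the
total but included in the nonsynonymous load. This asymmetry is
intentional: the total-load definition is an SNV count, while the
nonsynonymous class set explicitly includes indels. Group comparisons use
Wilcoxon rank-sum (two groups) or Kruskal–Wallis (more), reporting
per-group medians and ranges; groups under two samples are excluded with
a warning. Clinical covariates are tested against subtype with Fisher's
exact test — exact for 2×2, Monte-Carlo (Patefield sampling of
fixed-margin tables, probability ordering, default 10⁵ draws with a
seeded generator) for larger tables where exact enumeration is
infeasible — and age with one-way ANOVA. Age categories for burden
comparisons are ≤ 40, 41–60, 61–80, ≥ 81 years.

## Burden-adjusted enrichment

Because the NF1 subtype carries several-fold more mutations, naive
per-gene tests call most of the panel NF1-enriched. The screen fits, per
gene, `mutated ~ subtype + total_load` (logistic; BRAF reference;
untransformed load by default, with a log1p option) and reports Wald
p-values per subtype contrast with Benjamini–Hochberg adjustment computed
separately within each contrast. The subtype-defining genes (BRAF,
NRAS, KRAS, HRAS, NF1) are never screened, and genes below a minimum
frequency (default 5/870 ≈ 0.6 %) are skipped. Complete or quasi-complete
separation — common for rare genes in small subtypes — triggers a
Firth-penalized (Jeffreys-prior) refit with Wald inference from the
penalized information matrix; separated genes are flagged, never dropped.

The pathway screen applies the same adjusted model to per-sample pathway
indicators (any nonsynonymous mutation in a member gene present in the
gene universe) over twelve driver pathways grouped into three cellular
processes. The packaged table transcribes the published unique-pathway
gene sets verbatim, including legacy symbols; the printed gene column
contains 63 symbols. Mutual exclusivity (e.g. BRAF vs RAS hotspots) is a
Fisher 2×2 test where an odds ratio below 1 indicates exclusivity.

## Mutational signatures

SNVs are binned into the standard 96 classes — six pyrimidine-strand
substitutions × 16 flanking contexts, substitution-major with contexts
alphabetical — after folding purine-reference records onto the pyrimidine
strand; records whose context middle base contradicts the reference
allele are skipped and counted. Exposure refitting normalizes the
spectrum to fractions and solves non-negative least squares against a
row-normalized reference matrix, iteratively zeroing signatures whose
weight falls below 6 % of the total and refitting until the active set is
stable; weights plus an unassigned residual sum to one. Samples with
fewer than 50 contributing mutations are excluded for lack of power. The
reference matrix is an explicit input file so the signature-set version
is never implicit; the package bundles only a *synthetic* demonstration
matrix (UV-like, CpG-deamination-like, alkylation-like and Dirichlet
signatures) for testing and simulation. No exome trinucleotide-frequency
renormalization is applied by default; a per-context scaling hook
accepts one. Subtype comparison reports the Kruskal–Wallis test on the
UV-signature weight with per-subtype medians.

## Survival

Overall survival counts death from any cause; disease-specific survival
counts melanoma death, censoring other deaths at the death time (the
standard DSS convention). Times run in months from specimen removal and
are administratively censored at five years before testing — curves and
tests both use the censored data. Contrasts use Kaplan–Meier curves with
the k-group log-rank test and Cox proportional-hazards fits (lifelines,
Efron tie handling, Wald CIs, likelihood-ratio global p) against the BRAF
reference, unadjusted and adjusted for age, gender and tumor type.
Subgroup reports cover all samples, metastases, primaries, treated and
untreated strata for both endpoints; a subtype level with at most one
event in a stratum is flagged not estimable and excluded from that fit,
and constant covariates are dropped with a warning. Co-occurrence
contrasts (e.g. RAS ∧ NF1 versus RAS alone) are produced by relabeling
through the generic grouping argument rather than a separate code path.

## Synthetic cohort generator

The generator emulates the compiled-cohort study conditions so every
stage runs against known ground truth:

* subtype proportions 404/260/80/122 over 866 (≈ 46/30/9/14 %);
* per-subtype total loads log-normal with medians 69 (BRAF), 95 (RAS),
  246 (NF1), 19.5 (triple-WT) and dispersion σ = 0.95, chosen so an
  870-sample cohort spans roughly 1–3500 mutations;
* defining drivers sampled from named hotspot variants (V600E, V600K,
  K601E, a V600_K601 delins to exercise span parsing; Q61R/K/L, G12D,
  G13D over NRAS/KRAS/HRAS; NF1 events 63 % loss-of-function split over
  nonsense/frameshift/splice) plus NF1 co-mutation in 4.5 % of BRAF and
  9.6 % of RAS samples and recurrent KIT/GNA11/GNAQ mutations in 12 % of
  triple-WT samples;
* planted enriched genes (PTPN11, RASA2, RASSF2) drawn from
  logit P(mutated) = −3.0 + 0.005·load + log OR·[subtype], so the
  configured odds ratio (default 4 in NF1) is exactly the
  burden-adjusted log-odds the screen estimates;
* background SNVs scattered uniformly over the remaining panel (1461
  genes) with codons kept clear of hotspot residues, so background can
  never fake a driver; NF1 and planted genes are excluded from scatter
  to keep their mutation status under explicit control;
* 96-context classes drawn per subtype from signature mixtures over the
  synthetic matrix (UV weight 0.85 NF1, 0.70 RAS, 0.55 BRAF, 0.45
  triple-WT), with half the records reported on the purine strand to
  exercise strand folding;
* age means 56/64/72/66 (σ = 14), male fractions 0.60/0.62/0.73/0.55,
  metastasis fractions 0.80/0.89/0.80/0.76 per subtype;
* survival exponential with baseline hazard 0.012/month, per-subtype
  log-hazards (NF1 = log 2, others 0), 85 % of deaths melanoma-specific,
  uniform administrative censoring over 0–96 months.

Identical seeds give byte-identical tables. The generator deliberately
omits realistic genomic coordinates, linkage between mutations, germline
variation and copy number; passing tests therefore demonstrate the
statistical machinery, not robustness to real-world annotation noise.
Context generation bypasses FASTA lookup by construction, so the
context-from-genome path is exercised only through the context-validation
logic.

## Problem sizes and validation design

Replicate-based properties run at the sizes stated with them: subtype
partition and the NF1 consistency identity at n = 2000; filter
truth-label recovery on 500 generated calls; two-signature 50/50 mixture
recovery (mean absolute weight error < 0.05) over 20 replicates of 1000
mutations; planted-gene recovery and null FDR control over 50 replicates
of n = 900 **load-matched** cohorts (equal load medians), which isolates
the screen's recovery property from subtype–load collinearity — under the
default confounded load model the same experiment yields ≈ 88 % per-gene
recovery because the NF1 indicator and total load are strongly
correlated, which the enrichment tests document on a single default
cohort; and Cox CI coverage of the generator's NF1 log-hazard over 50
replicates of n = 900.

## Known limitations

* Hotspot matching is protein-coordinate-based; genomic-coordinate
  matching, copy-number NF1 loss and BRAF fusions are out of scope.
* The r×c Fisher p is Monte-Carlo, hence seed-dependent in its last
  digits; 2×2 tables are exact.
* The logistic screen's untransformed-load adjustment is an
  approximation when the true per-gene hit probability is concave in
  load (as uniform scatter implies); residual lack of fit can leak into
  subtype coefficients for extreme-load samples.
* The survival module fits proportional hazards without time-varying
  effects or competing-risks machinery; DSS treats other-cause death as
  independent censoring.
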