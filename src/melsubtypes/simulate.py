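"""Synthetic melanoma-cohort generator.

Generates mutation and clinical tables with the statistical structure the
downstream analyses assume, so the whole pipeline can run and be validated
without access to patient data.  The defaults encode the study conditions
of a compiled four-study melanoma cohort:

* subtype composition BRAF/RAS/NF1/triple-wild-type = 46/30/9/14%;
* per-subtype total mutational load log-normal with medians 69/95/246/19.5;
* hotspot drivers placed as named protein changes (V600E, K601E, Q61R, ...);
* NF1 co-mutation in a fraction of BRAF (4.5%) and RAS (9.6%) samples,
  63% of NF1 events loss-of-function;
* planted NF1-enriched genes (PTPN11, RASA2, RASSF2, odds ratio 4);
* UV-dominated 96-context spectra, strongest in the NF1 subtype;
* subtype-skewed age (means 56/64/72/66) and male fraction
  (0.60/0.62/0.73/0.55);
* exponential survival with an NF1-vs-BRAF log-hazard of log 2.

The reference signature matrix used for context generation is synthetic
(see :func:`synthetic_signature_matrix`); it mimics the *shape* of a UV /
CpG-deamination / alkylation signature set but is not any published
catalog.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import CLINICAL_COLUMNS, MUTATION_COLUMNS, CohortBundle
from .signatures import BASES, COMPLEMENT, SUBSTITUTIONS, revcomp
from .somatic_filter import CALL_COLUMNS, FilterConfig
from .subtypes import BRAF, NF1, RAS, TRIPLE_WT

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BRAF_DRIVERS = (("p.V600E", 0.75), ("p.V600K", 0.10), ("p.K601E", 0.10),
                ("p.V600_K601delinsE", 0.05))
RAS_DRIVERS = (("p.Q61R", 0.45), ("p.Q61K", 0.25), ("p.Q61L", 0.17),
               ("p.G12D", 0.09), ("p.G13D", 0.04))
RAS_GENE_WEIGHTS = (("NRAS", 0.93), ("KRAS", 0.04), ("HRAS", 0.03))
TWT_RECURRENT = (("KIT", "p.K642E"), ("KIT", "p.V559A"),
                 ("GNA11", "p.Q209L"), ("GNAQ", "p.Q209P"))

SUBTYPE_LIST = [BRAF, RAS, NF1, TRIPLE_WT]


# --------------------------------------------------------------------------
# Synthetic reference signatures
# --------------------------------------------------------------------------

def synthetic_signature_matrix(n_signatures: int = 30, seed: int = 97) -> pd.DataFrame:
    """A synthetic 30-signature x 96-context reference matrix.

    Signature.7 is UV-like (C>T at dipyrimidines, i.e. a pyrimidine 5'
    neighbor), Signature.1 is CpG-deamination-like (C>T at NpCpG),
    Signature.11 is alkylation-like (broad C>T), Signature.5 is flat;
    the rest are sparse Dirichlet draws.  Deterministic given ``seed``.
    This is a stand-in catalog for testing, not any published signature set.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for k in range(1, n_signatures + 1):
        name = f"Signature.{k}"
        w = rng.dirichlet(np.full(96, 0.08))
        if k == 7:
            w = np.full(96, 1e-4)
            for i5, five in enumerate(BASES):
                for i3, three in enumerate(BASES):
                    idx = 2 * 16 + i5 * 4 + i3       # C>T block
                    if five in ("C", "T"):
                        w[idx] = 1.0 + 0.25 * rng.random()
        elif k == 1:
            w = np.full(96, 5e-3)
            for i5 in range(4):
                idx = 2 * 16 + i5 * 4 + 2            # C>T at _CG
                w[idx] = 1.0
        elif k == 11:
            w = np.full(96, 1e-3)
            w[2 * 16:3 * 16] = 1.0 + rng.random(16)  # all C>T contexts
        elif k == 5:
            w = np.full(96, 1.0) + 0.2 * rng.random(96)
        rows[name] = w / w.sum()
    from .signatures import CONTEXT_LABELS
    return pd.DataFrame(rows, index=list(CONTEXT_LABELS)).T.rename_axis("signature")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def _default_mixtures() -> dict[str, dict[str, float]]:
    return {
        BRAF: {"Signature.7": 0.55, "Signature.1": 0.25, "Signature.5": 0.20},
        RAS: {"Signature.7": 0.70, "Signature.1": 0.15, "Signature.5": 0.15},
        NF1: {"Signature.7": 0.85, "Signature.1": 0.08, "Signature.5": 0.07},
        TRIPLE_WT: {"Signature.7": 0.45, "Signature.1": 0.25, "Signature.5": 0.30},
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_samples: int = 870
    seed: int = 1
    # exact compiled-cohort composition (404/260/80/122 of 866 classified
    # samples); rounds to the reported 46/30/9/14%
    subtype_proportions: dict[str, float] = field(default_factory=lambda: {
        BRAF: 404 / 866, RAS: 260 / 866, NF1: 80 / 866, TRIPLE_WT: 122 / 866})
    load_medians: dict[str, float] = field(default_factory=lambda: {
        BRAF: 69.0, RAS: 95.0, NF1: 246.0, TRIPLE_WT: 19.5})
    load_sigma: float = 0.95            # log-normal dispersion of total load
    panel_size: int = 1461
    nf1_comutation_rate: dict[str, float] = field(default_factory=lambda: {
        BRAF: 0.045, RAS: 0.096})
    nf1_lof_fraction: float = 0.63
    twt_recurrent_rate: float = 0.12    # KIT/GNA11/GNAQ recurrent in triple-wt
    planted_genes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "PTPN11": {NF1: 4.0}, "RASA2": {NF1: 4.0}, "RASSF2": {NF1: 4.0}})
    # planted-gene model: logit P(mutated) = intercept + slope*load + log(OR);
    # the subtype odds ratio is therefore exactly the burden-adjusted
    # log-odds the enrichment screen estimates
    planted_logit_intercept: float = -3.0
    planted_logit_load_slope: float = 0.005
    signature_mixtures: dict[str, dict[str, float]] = field(
        default_factory=_default_mixtures)
    age_means: dict[str, float] = field(default_factory=lambda: {
        BRAF: 56.0, RAS: 64.0, NF1: 72.0, TRIPLE_WT: 66.0})
    age_sd: float = 14.0
    male_fraction: dict[str, float] = field(default_factory=lambda: {
        BRAF: 0.60, RAS: 0.62, NF1: 0.73, TRIPLE_WT: 0.55})
    metastasis_fraction: dict[str, float] = field(default_factory=lambda: {
        BRAF: 0.80, RAS: 0.89, NF1: 0.80, TRIPLE_WT: 0.76})
    baseline_hazard: float = 0.012      # deaths per month, BRAF reference
    log_hazards: dict[str, float] = field(default_factory=lambda: {
        BRAF: 0.0, RAS: 0.0, NF1: float(np.log(2.0)), TRIPLE_WT: 0.0})
    melanoma_death_fraction: float = 0.85
    censoring_window: float = 96.0      # months, uniform administrative censoring
    treated_fraction: float = 0.30
    cohort_label: str = "synthetic"

    def validate(self) -> None:
        props = np.array([self.subtype_proportions[s] for s in SUBTYPE_LIST])
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("subtype proportions must sum to 1")
        if (props < 0).any():
            raise ValueError("subtype proportions must be non-negative")
        if any(m <= 0 for m in self.load_medians.values()):
            raise ValueError("load medians must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


def default_gene_panel(size: int = 1461) -> list[str]:
    """Driver + pathway + planted genes padded with filler symbols."""
    from .enrichment import load_pathways
    core = ["BRAF", "NRAS", "KRAS", "HRAS", "NF1", "KIT", "GNA11", "GNAQ",
            "PTPN11", "RASA2", "RASSF2", "TP53", "CDKN2A", "PTEN", "CTNNB1"]
    genes = list(dict.fromkeys(core + list(load_pathways()["gene"])))
    fillers = (f"GENE{i:04d}" for i in range(1, size + 1))
    while len(genes) < size:
        g = next(fillers)
        if g not in genes:
            genes.append(g)
    return genes[:size]


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _strand_tables() -> tuple[np.ndarray, ...]:
    """Per-class (ref, alt, context) lookup tables for both strands."""
    ref_p, alt_p, ctx_p, ref_m, alt_m, ctx_m = ([] for _ in range(6))
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                ref, alt = sub[0], sub[2]
                ctx = five + ref + three
                ref_p.append(ref); alt_p.append(alt); ctx_p.append(ctx)
                ref_m.append(COMPLEMENT[ref]); alt_m.append(COMPLEMENT[alt])
                ctx_m.append(revcomp(ctx))
    return tuple(np.array(x, dtype=object)
                 for x in (ref_p, alt_p, ctx_p, ref_m, alt_m, ctx_m))


_REF_P, _ALT_P, _CTX_P, _REF_M, _ALT_M, _CTX_M = _strand_tables()


def _class_to_snv(rng: np.random.Generator, class_idx: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map 96-class indices to (ref, alt, context3), randomly reporting half
    of them on the purine strand to exercise strand folding downstream."""
    flip = rng.random(len(class_idx)) < 0.5
    ref = np.where(flip, _REF_M[class_idx], _REF_P[class_idx])
    alt = np.where(flip, _ALT_M[class_idx], _ALT_P[class_idx])
    ctx = np.where(flip, _CTX_M[class_idx], _CTX_P[class_idx])
    return ref, alt, ctx


def _draw_contexts(rng: np.random.Generator, subtypes: np.ndarray,
                   counts_per_sample: np.ndarray, mixtures, matrix: pd.DataFrame
                   ) -> np.ndarray:
    """One 96-class index per mutation, drawn from each sample's subtype
    signature mixture."""
    total = int(counts_per_sample.sum())
    out = np.empty(total, dtype=int)
    owner_subtype = np.repeat(subtypes, counts_per_sample)
    sig_rows = {name: matrix.loc[name].to_numpy() for name in matrix.index}
    for s in SUBTYPE_LIST:
        mask = owner_subtype == s
        n = int(mask.sum())
        if n == 0:
            continue
        mix = mixtures[s]
        names = list(mix)
        which = rng.choice(len(names), size=n, p=np.array([mix[k] for k in names]))
        block = np.empty(n, dtype=int)
        for j, name in enumerate(names):
            m2 = which == j
            if m2.any():
                block[m2] = rng.choice(96, size=int(m2.sum()), p=sig_rows[name])
        out[mask] = block
    return out


def _nf1_mutation(rng: np.random.Generator, lof_fraction: float) -> tuple[str, str]:
    """(variant_class, protein_change) for one NF1 nonsynonymous event."""
    if rng.random() < lof_fraction:
        kind = rng.choice(["nonsense", "frameshift_indel", "splice_site"],
                          p=[0.5, 0.35, 0.15])
        if kind == "nonsense":
            return "nonsense", f"p.R{rng.integers(100, 2800)}*"
        if kind == "frameshift_indel":
            return "frameshift_indel", f"p.K{rng.integers(100, 2800)}fs"
        return "splice_site", ""
    codon = rng.integers(100, 2800)
    a1, a2 = rng.choice(list(AMINO_ACIDS), size=2)
    return "missense", f"p.{a1}{codon}{a2}"


def _weighted_pick(rng: np.random.Generator, pairs) -> str:
    items = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return items[rng.choice(len(items), p=probs / probs.sum())]


def generate_cohort(config: GeneratorConfig | None = None, return_truth: bool = False):
    """Generate a harmonizable synthetic cohort.

    Returns a :class:`CohortBundle`; with ``return_truth=True`` also a
    per-sample truth table (true subtype, NF1 co-mutation, planted-gene
    indicators) that downstream analyses never see.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    panel = default_gene_panel(config.panel_size)
    matrix = synthetic_signature_matrix()

    if n == 0:
        empty_m = pd.DataFrame(columns=MUTATION_COLUMNS)
        empty_c = pd.DataFrame(columns=CLINICAL_COLUMNS)
        bundle = CohortBundle(empty_m, empty_c, set(panel))
        return (bundle, pd.DataFrame()) if return_truth else bundle

    props = np.array([config.subtype_proportions[s] for s in SUBTYPE_LIST])
    subtype_idx = rng.choice(4, size=n, p=props)
    subtypes = np.array(SUBTYPE_LIST)[subtype_idx]
    sample_ids = np.array([f"S{i+1:05d}" for i in range(n)])

    medians = np.array([config.load_medians[s] for s in SUBTYPE_LIST])
    loads = np.maximum(1, np.round(rng.lognormal(
        mean=np.log(medians[subtype_idx]), sigma=config.load_sigma)).astype(int))

    # ---- driver and co-mutation events (per-sample python loop; row lists)
    drv_rows: list[tuple] = []   # (sample_idx, gene, variant_class, protein_change)
    nf1_comut = np.zeros(n, dtype=bool)
    for i in range(n):
        s = subtypes[i]
        if s == BRAF:
            pc = _weighted_pick(rng, BRAF_DRIVERS)
            vc = "inframe_indel" if "delins" in pc else "missense"
            drv_rows.append((i, "BRAF", vc, pc))
        elif s == RAS:
            gene = _weighted_pick(rng, RAS_GENE_WEIGHTS)
            drv_rows.append((i, gene, "missense", _weighted_pick(rng, RAS_DRIVERS)))
        elif s == NF1:
            vc, pc = _nf1_mutation(rng, config.nf1_lof_fraction)
            drv_rows.append((i, "NF1", vc, pc))
        else:  # triple-wild-type
            if rng.random() < config.twt_recurrent_rate:
                gene, pc = TWT_RECURRENT[rng.integers(len(TWT_RECURRENT))]
                drv_rows.append((i, gene, "missense", pc))
        if s in config.nf1_comutation_rate and rng.random() < config.nf1_comutation_rate[s]:
            nf1_comut[i] = True
            vc, pc = _nf1_mutation(rng, config.nf1_lof_fraction)
            drv_rows.append((i, "NF1", vc, pc))

    # ---- planted enriched genes: odds proportional to load, boosted per subtype
    planted_hits: dict[str, np.ndarray] = {}
    for gene, or_by_subtype in config.planted_genes.items():
        logit = (config.planted_logit_intercept
                 + config.planted_logit_load_slope * loads.astype(float))
        for s, ratio in or_by_subtype.items():
            logit = np.where(subtypes == s, logit + np.log(ratio), logit)
        p = 1.0 / (1.0 + np.exp(-logit))
        hit = rng.random(n) < p
        planted_hits[gene] = hit
        for i in np.flatnonzero(hit):
            codon = rng.integers(100, 460)
            drv_rows.append((int(i), gene, "missense", f"p.L{codon}P"))

    # ---- background SNVs scattered over the panel
    is_driver_snv = np.array([vc not in ("frameshift_indel", "inframe_indel")
                              for _, _, vc, _ in drv_rows], dtype=bool) \
        if drv_rows else np.array([], dtype=bool)
    snv_per_sample = np.bincount(
        [r[0] for k, r in enumerate(drv_rows) if is_driver_snv[k]], minlength=n) \
        if drv_rows else np.zeros(n, dtype=int)
    bg_counts = np.maximum(loads - snv_per_sample, 0)
    total_bg = int(bg_counts.sum())

    # NF1 and planted genes are excluded from background scatter so their
    # mutation status stays under explicit control
    excluded_bg = {"NF1", *config.planted_genes}
    pool = [g for g in panel if g not in excluded_bg]
    bg_gene = rng.choice(len(pool), size=total_bg)
    bg_class = rng.choice(
        ["noncoding", "synonymous", "missense", "nonsense", "splice_site"],
        size=total_bg, p=[0.40, 0.15, 0.40, 0.03, 0.02])
    # codons kept clear of the BRAF (600/601, 466-471) and RAS (12/13/61)
    # hotspot residues so background never fakes a driver
    bg_codon = rng.integers(100, 460, size=total_bg)

    # ---- assemble mutation table
    drv_sample = np.array([r[0] for r in drv_rows], dtype=int)
    all_sample_idx = np.concatenate([drv_sample, np.repeat(np.arange(n), bg_counts)]) \
        if drv_rows else np.repeat(np.arange(n), bg_counts)
    genes = np.concatenate([np.array([r[1] for r in drv_rows], dtype=object),
                            np.array(pool, dtype=object)[bg_gene]]) \
        if drv_rows else np.array(pool, dtype=object)[bg_gene]
    classes = np.concatenate([np.array([r[2] for r in drv_rows], dtype=object),
                              bg_class.astype(object)]) \
        if drv_rows else bg_class.astype(object)
    protein = np.concatenate([np.array([r[3] for r in drv_rows], dtype=object),
                              np.where(bg_class == "missense",
                                       np.char.add(np.char.add("p.L", bg_codon.astype(str)), "P"),
                                       np.where(bg_class == "nonsense",
                                                np.char.add(np.char.add("p.R", bg_codon.astype(str)), "*"),
                                                "")).astype(object)]) \
        if drv_rows else np.full(total_bg, "", dtype=object)

    m = len(all_sample_idx)
    is_indel = np.isin(classes, ["frameshift_indel", "inframe_indel"])
    snv_count_per_sample = np.bincount(all_sample_idx[~is_indel], minlength=n)
    class_idx = _draw_contexts(rng, subtypes, snv_count_per_sample,
                               config.signature_mixtures, matrix)
    ref = np.full(m, "", dtype=object)
    alt = np.full(m, "", dtype=object)
    ctx = np.full(m, "", dtype=object)
    if class_idx.size:
        # _draw_contexts orders by sample; reorder rows to match
        order = np.argsort(all_sample_idx[~is_indel], kind="stable")
        r_, a_, c_ = _class_to_snv(rng, class_idx)
        snv_positions = np.flatnonzero(~is_indel)[order]
        ref[snv_positions] = r_
        alt[snv_positions] = a_
        ctx[snv_positions] = c_
    ref[is_indel] = "TA"
    alt[is_indel] = "T"

    mutations = pd.DataFrame({
        "sample_id": sample_ids[all_sample_idx],
        "gene": genes,
        "chrom": rng.integers(1, 23, size=m).astype(str),
        "pos": rng.integers(1, 200_000_000, size=m),
        "ref": ref,
        "alt": alt,
        "variant_class": classes,
        "protein_change": protein,
        "context3": ctx,
        "cohort": config.cohort_label,
    })[MUTATION_COLUMNS]
    mutations = mutations.sort_values(["sample_id", "gene", "pos"],
                                      kind="stable").reset_index(drop=True)

    # ---- clinical covariates and survival
    age = np.clip(rng.normal([config.age_means[s] for s in subtypes],
                             config.age_sd), 20, 95).round(1)
    male = rng.random(n) < np.array([config.male_fraction[s] for s in subtypes])
    metas = rng.random(n) < np.array([config.metastasis_fraction[s] for s in subtypes])
    origin = rng.choice(["cutaneous", "unknown_primary", "non_sun_induced",
                         "other", "missing"], size=n,
                        p=[0.83, 0.05, 0.02, 0.005, 0.095])
    treated = rng.choice([1.0, 0.0, np.nan], size=n,
                         p=[config.treated_fraction,
                            1 - config.treated_fraction - 0.15, 0.15])

    hazard = config.baseline_hazard * np.exp(
        np.array([config.log_hazards[s] for s in subtypes]))
    t_death = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0, config.censoring_window, size=n)
    os_time = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    melanoma_cause = rng.random(n) < config.melanoma_death_fraction
    dss_event = (os_event == 1) & melanoma_cause

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "gender": np.where(male, "male", "female"),
        "tumor_type": np.where(metas, "metastasis", "primary"),
        "origin": origin,
        "os_time": np.round(os_time, 2),
        "os_event": os_event,
        "dss_event": dss_event.astype(int),
        "treated": treated,
        "cohort": config.cohort_label,
    })[CLINICAL_COLUMNS]

    bundle = CohortBundle(mutations, clinical, set(panel))
    if not return_truth:
        return bundle
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "true_subtype": subtypes,
        "nf1_comutation": nf1_comut,
        "total_load": loads,
        **{f"planted_{g}": planted_hits[g] for g in planted_hits},
    })
    return bundle, truth


# --------------------------------------------------------------------------
# Candidate-call generation for filter validation
# --------------------------------------------------------------------------

def generate_candidate_calls(n_samples: int = 20, per_sample: int = 10,
                             violation_rate: float = 0.3, seed: int = 1,
                             config: FilterConfig = FilterConfig()
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate tumor/normal calls with known truth labels.

    A ``violation_rate`` fraction of calls violates exactly one somatic
    filter criterion (chosen uniformly among the five); the rest pass all
    criteria.  Returns (call table, truth table with ``expected_pass`` and
    ``expected_reasons``).
    """
    if per_sample < 1:
        raise ValueError("per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    kinds = ["normal_depth", "tumor_depth", "min_mutant_reads",
             "tumor_vaf", "normal_vaf"]
    for i in range(n_samples):
        sid = f"C{i+1:04d}"
        for j in range(per_sample):
            td = int(rng.integers(60, 200))
            ta = max(int(rng.binomial(td, 0.35)),
                     config.min_mutant_reads,
                     int(np.ceil(config.min_tumor_vaf * td)))
            nd = int(rng.integers(30, 100))
            na = 0
            reasons: set[str] = set()
            if rng.random() < violation_rate:
                kind = kinds[int(rng.integers(len(kinds)))]
                if kind == "normal_depth":
                    nd = int(rng.integers(0, config.min_normal_depth))
                    na = 0
                elif kind == "tumor_depth":
                    td = int(config.min_tumor_depth - 1)
                    ta = min(td, config.min_mutant_reads)  # 5x/4 alt: only depth fails
                elif kind == "min_mutant_reads":
                    td = 20
                    ta = int(config.min_mutant_reads - 1)  # 3/20 = 15% VAF, depth fine
                elif kind == "tumor_vaf":
                    td = 100
                    ta = 5                                  # 5% < 10%, >= 4 reads
                elif kind == "normal_vaf":
                    na = max(int(np.ceil(config.max_normal_vaf * nd)) + 1, 2)
                reasons.add(kind)
            rows.append({"sample_id": sid, "chrom": str(rng.integers(1, 23)),
                         "pos": int(rng.integers(1, 200_000_000)),
                         "ref": "C", "alt": "T",
                         "tumor_depth": td, "tumor_alt_reads": ta,
                         "normal_depth": nd, "normal_alt_reads": na})
            truth.append({"sample_id": sid, "expected_pass": not reasons,
                          "expected_reasons": ",".join(sorted(reasons))})
    calls = pd.DataFrame(rows)[CALL_COLUMNS]
    return calls, pd.DataFrame(truth)
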