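import numpy as np
import pandas as pd
import pytest

from melsubtypes.cohort_io import CohortBundle, MUTATION_COLUMNS
from melsubtypes.simulate import GeneratorConfig, generate_cohort


def make_mutations(rows: list[dict]) -> pd.DataFrame:
    """Build a mutation table from sparse row dicts (sane defaults)."""
    defaults = {"sample_id": "S1", "gene": "GENE1", "chrom": "1", "pos": 100,
                "ref": "C", "alt": "T", "variant_class": "missense",
                "protein_change": "", "context3": "", "cohort": "test"}
    df = pd.DataFrame([{**defaults, **r} for r in rows],
                      columns=MUTATION_COLUMNS)
    return df[MUTATION_COLUMNS]


def make_bundle(rows: list[dict], clinical: pd.DataFrame | None = None,
                universe: set[str] | None = None) -> CohortBundle:
    mutations = make_mutations(rows)
    if clinical is None:
        clinical = pd.DataFrame({"sample_id": mutations["sample_id"].unique()})
    return CohortBundle(mutations, clinical, universe or set())


@pytest.fixture(scope="session")
def cohort870():
    """One synthetic cohort at the default study conditions, with truth."""
    bundle, truth = generate_cohort(GeneratorConfig(n_samples=870, seed=11),
                                    return_truth=True)
    return bundle, truth


@pytest.fixture(scope="session")
def classified870(cohort870):
    from melsubtypes.subtypes import classify_cohort
    bundle, truth = cohort870
    calls, summary = classify_cohort(bundle)
    return calls, summary


@pytest.fixture(scope="session")
def loads870(cohort870):
    from melsubtypes.burden import compute_loads
    bundle, _ = cohort870
    return compute_loads(bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
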