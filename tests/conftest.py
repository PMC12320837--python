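import numpy as np
import pandas as pd
import pytest

from ugityper.config import AnalysisConfig
from ugityper.core_tables import FeatureTable, RelAbundanceTable
from ugityper.synthetic import SyntheticSpec, generate_cohort, generate_controls


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def small_counts() -> FeatureTable:
    data = pd.DataFrame(
        {
            "s1": [10, 0, 5],
            "s2": [2, 8, 5],
            "s3": [1, 1, 1],
        },
        index=["taxA", "taxB", "taxC"],
    )
    return FeatureTable(data)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    spec = SyntheticSpec(seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_with_controls():
    spec = SyntheticSpec(seed=17, n_subjects=10, locations=("saliva", "duodenum"), n_low_biomass=4)
    table, meta, truth = generate_cohort(spec)
    ctrl, cmeta = generate_controls(spec, 3)
    full = FeatureTable(table.data.join(ctrl.data))
    allmeta = pd.concat([meta, cmeta], ignore_index=True)
    return full, allmeta, truth


def random_rel_table(rng: np.random.Generator, n_taxa=6, n_samples=8) -> RelAbundanceTable:
    x = rng.dirichlet(np.full(n_taxa, 0.8), size=n_samples).T
    return RelAbundanceTable(
        pd.DataFrame(
            x,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
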