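import numpy as np
import pandas as pd
import pytest

from oralmicro.cohort import CohortSpec, ConditionSpec, generate_cohort
from oralmicro.io import CountTable


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples with genus/phylum lineage."""
    counts = pd.DataFrame(
        [[5, 0], [3, 4], [2, 6]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2"],
    )
    tax = pd.DataFrame(
        {
            "genus": ["Prevotella", "Prevotella", "Streptococcus"],
            "phylum": ["Bacteroidetes", "Bacteroidetes", "Firmicutes"],
        },
        index=counts.index,
    )
    return CountTable(counts, tax)


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(20, 10)),
        index=[f"t{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(10)],
    )
    return CountTable(counts)


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-sample cohort with a smoking effect and family units."""
    spec = CohortSpec(
        n_samples=250,
        n_taxa=30,
        reads_per_sample=3000,
        seed=7,
        age_bin_weights=(3, 1, 1, 1, 1, 1),
        condition_specs=[
            ConditionSpec("smoking", 0.25, 1.0, 0.8),
            ConditionSpec("cystic_fibrosis", 0.06, 1.5),
        ],
        family_effect_sd=1.0,
        family_fraction=0.4,
        missing_fraction=0.03,
    )
    return generate_cohort(spec)
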