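import numpy as np
import pandas as pd
import pytest

from enterochron.io import CountTable
from enterochron.simulate import CohortConfig, generate_design, generate_bacterial_counts


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(
        sample_ids=["S1", "S2", "S3"],
        taxon_ids=["A", "B", "C", "D"],
        counts=np.array(
            [
                [10, 10, 10, 10],
                [40, 0, 0, 0],
                [5, 15, 20, 60],
            ]
        ),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (design, counts, truth)."""
    cfg = CohortConfig(seed=0)
    design = generate_design(cfg)
    counts, truth = generate_bacterial_counts(design, cfg)
    return cfg, design, counts, truth


@pytest.fixture
def small_cohort_config():
    """A reduced cohort for fast end-to-end tests."""
    return dict(
        n_pigs=6,
        cohort_sizes=(2, 4),
        microbiome_subset_size=4,
        n_bacterial_taxa=60,
        n_fungal_taxa=40,
        library_size_model={
            3: (3.3, 0.1),
            **{a: (3.6, 0.1) for a in (6, 10, 12, 22, 32, 49, 50, 53)},
        },
    )


@pytest.fixture
def long_metadata() -> pd.DataFrame:
    rows = []
    for pig in ["P1", "P2"]:
        for age in (3, 6, 10):
            rows.append(
                {
                    "sample_id": f"{pig}_w{age:02d}",
                    "pig_id": pig,
                    "cohort": 1 if pig == "P1" else 2,
                    "age_weeks": float(age),
                }
            )
    return pd.DataFrame(rows)
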