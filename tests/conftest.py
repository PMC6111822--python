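import numpy as np
import pandas as pd
import pytest

from revmap import (
    CohortSimConfig, ExpressionCohort, GeneSignature, RefSimConfig,
    simulate_cohort, simulate_reference_library,
)


@pytest.fixture(scope="session")
def toy_profile():
    """Three-gene signed-rank profile used by the worked scoring examples."""
    return {"g1": 3, "g2": -2, "g3": 1}


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 4-sample, 3-gene cohort with survival annotations."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 4.0, 7.0],
            "S2": [2.0, 3.0, 8.0],
            "S3": [3.0, 2.0, 9.0],
            "S4": [4.0, 1.0, 6.0],
        },
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
    )
    clinical = pd.DataFrame(
        {"time_months": [12.0, 30.0, 8.0, 45.0], "event": [1, 0, 1, 1]},
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return ExpressionCohort(values, clinical)


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized simulated cohort shared by recovery tests."""
    return simulate_cohort(
        CohortSimConfig(n_samples=200, n_genes=300, block_coupling=0.7, seed=11)
    )


@pytest.fixture(scope="session")
def planted_library():
    """Library of 40 drugs with 3 strong planted reversers (G=500, m=16)."""
    signature = GeneSignature.from_genes([f"X{i:03d}" for i in range(16)])
    universe = [f"X{i:03d}" for i in range(500)]
    cfg = RefSimConfig(
        n_drugs=40,
        gene_universe=universe,
        planted_reversers=["drug0003", "drug0011", "drug0025"],
        reversal_strength=3.0,
        n_replicates_range=(2, 5),
        seed=19,
    )
    refset, truth = simulate_reference_library(cfg, signature)
    return refset, truth, signature
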