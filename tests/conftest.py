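import numpy as np
import pytest

from metaboqtl.genotypes import simulate_genotypes
from metaboqtl.pedigree import (
    household_matrix,
    kinship_from_pedigree,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact related cohort (~200 descendants) for association tests."""
    ped = simulate_pedigree(6, 3, mean_children=2.8, seed=42)
    K = kinship_from_pedigree(ped)
    ids = ped.descendant_ids
    return {
        "ped": ped,
        "ids": ids,
        "K": K.subset(ids),
        "K_full": K,
        "H": household_matrix(ped, ids),
    }


@pytest.fixture(scope="session")
def unrelated_cohort():
    """300 unrelated founders (kinship = identity/2) for OLS comparisons."""
    ped = simulate_pedigree(150, 1, mean_children=0.0, seed=7)
    K = kinship_from_pedigree(ped)
    rng = np.random.default_rng(7)
    n = ped.n
    X = np.column_stack([np.ones(n), rng.normal(50, 10, n), rng.integers(0, 2, n)])
    y = X @ np.array([2.0, 0.01, -0.3]) + rng.standard_normal(n)
    spec = [(float(m), f"b{j}") for j, m in enumerate(rng.uniform(0.1, 0.5, 10))]
    G = simulate_genotypes(ped, spec, seed=8)
    return {"ped": ped, "K": K, "X": X, "y": y, "G": G}
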