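import numpy as np
import pandas as pd
import pytest

from sspatk import (
    MetaboliteMatrix,
    PathwayCollection,
    SyntheticSpec,
    generate_base_matrix,
    generate_pathway_collection,
    make_toy_fixture,
)


@pytest.fixture(scope="session")
def toy():
    """6x6 deterministic matrix, 3 two-member pathways, binary labels."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def small_base():
    """Small standardized block-correlated matrix for fast simulations."""
    spec = SyntheticSpec(
        n_samples=60, n_metabolites=40, block_size_range=(4, 8),
        block_rho=0.3, seed=42,
    )
    return generate_base_matrix(spec)


@pytest.fixture(scope="session")
def small_collection(small_base):
    return generate_pathway_collection(
        8, (2, 5), small_base.metabolite_ids, "disjoint", seed=7
    )


def random_matrix(n, m, seed, standardized=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    if standardized:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    data = pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(m)],
    )
    prov = ["log2", "standardized"] if standardized else []
    return MetaboliteMatrix(data=data, provenance=prov)


def single_pathway(members):
    return PathwayCollection.from_dict({"P": list(members)})
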