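"""Synthetic metabolomics matrices and pathway collections.

The generator emulates the statistical shape of a post-processed
untargeted MS dataset: standardized log-scale metabolite columns with
block correlation structure (metabolites within a biochemical module
co-vary; modules are roughly independent).  Defaults mirror a typical
plasma metabolomics study: 260 samples x 335 metabolites, correlation
blocks of 5-20 metabolites at within-block correlation 0.3.

Pathway collections come in two flavours: fully disjoint ("non
redundant") sets, and a shared-pool model in which pathways re-draw a
controlled fraction of their members from metabolites already used by
earlier pathways, producing a spread of pairwise overlap coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway_io import PathwayCollection
from .preprocessing import MetaboliteMatrix

__all__ = [
    "SyntheticSpec",
    "generate_base_matrix",
    "generate_pathway_collection",
    "make_toy_fixture",
]


@dataclass
class SyntheticSpec:
    """Parameters of the base-matrix generator.

    ``block_size_range`` and ``block_rho`` control the block-diagonal
    correlation model (equicorrelated within a block, independent
    between blocks).  ``missing_rate`` > 0 and ``raw_scale=True`` yield a
    raw-scale log-normal matrix with missing cells for preprocessing
    tests; the default is a ready-to-score standardized log-scale
    matrix.
    """

    n_samples: int = 260
    n_metabolites: int = 335
    block_size_range: tuple[int, int] = (5, 20)
    block_rho: float = 0.3
    raw_scale: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.block_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid block size range")


def _block_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.block_size_range
    sizes: list[int] = []
    remaining = spec.n_metabolites
    while remaining > 0:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    return sizes


def generate_base_matrix(spec: SyntheticSpec) -> MetaboliteMatrix:
    """Draw a base matrix with block-correlated Gaussian columns.

    Within a block of size b the correlation matrix is equicorrelated
    with off-diagonal ``block_rho`` (realised as a shared Gaussian
    factor), which is positive semi-definite for any rho in [0, 1).
    Columns are standardized (ddof=1) and two placeholder groups A/B are
    assigned to the first/second half of the samples; the benchmark
    permutes them anyway.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_metabolites
    rho = spec.block_rho
    X = np.empty((n, m))
    j = 0
    for size in _block_sizes(spec, rng):
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, size))
        X[:, j : j + size] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
        j += size
    metabolite_ids = [f"CHEBI:{10000 + k}" for k in range(m)]
    sample_ids = [f"S{k:03d}" for k in range(n)]
    half = n // 2
    groups = pd.Series(
        ["A"] * half + ["B"] * (n - half), index=sample_ids, name="group"
    )
    if spec.raw_scale:
        raw = np.exp2(X * 0.5 + 10.0)  # plausible raw MS intensity scale
        if spec.missing_rate > 0:
            mask = rng.random((n, m)) < spec.missing_rate
            # keep at least one observed value per column
            for col in np.flatnonzero(mask.all(axis=0)):
                mask[rng.integers(n), col] = False
            raw[mask] = np.nan
        data = pd.DataFrame(raw, index=sample_ids, columns=metabolite_ids)
        return MetaboliteMatrix(data=data, groups=groups, provenance=[])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    data = pd.DataFrame(X, index=sample_ids, columns=metabolite_ids)
    return MetaboliteMatrix(
        data=data, groups=groups, provenance=["log2", "standardized"]
    )


def generate_pathway_collection(
    n_pathways: int,
    size_range: tuple[int, int],
    metabolite_universe: list[str],
    overlap_model: str = "disjoint",
    reuse_rate: float = 0.5,
    seed: int = 0,
) -> PathwayCollection:
    """Generate a pathway collection over a metabolite universe.

    ``overlap_model="disjoint"`` assigns every pathway fresh metabolites
    (pairwise overlap coefficient 0 for all pairs; requires the universe
    to be large enough).  ``overlap_model="shared-pool"`` draws a
    ``reuse_rate`` fraction of each pathway's members from metabolites
    already used by earlier pathways, yielding a controlled spread of
    pairwise overlaps; reuse 0 is equivalent to disjoint until the
    universe is exhausted.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    universe = list(metabolite_universe)
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_pathways)]
    sets: dict[str, frozenset[str]] = {}
    if overlap_model == "disjoint":
        if sum(sizes) > len(universe):
            raise ValueError(
                f"disjoint collection needs {sum(sizes)} metabolites but the "
                f"universe has {len(universe)}"
            )
        perm = rng.permutation(len(universe))
        j = 0
        for k, size in enumerate(sizes):
            sets[f"SP{k:04d}"] = frozenset(universe[i] for i in perm[j : j + size])
            j += size
    elif overlap_model == "shared-pool":
        if not 0 <= reuse_rate <= 1:
            raise ValueError("reuse_rate must be in [0, 1]")
        if hi > len(universe):
            raise ValueError("pathway size exceeds universe size")
        unused = list(universe)
        rng.shuffle(unused)
        used: list[str] = []
        for k, size in enumerate(sizes):
            n_reused = min(int(round(reuse_rate * size)), len(used))
            chosen: set[str] = set()
            if n_reused:
                picks = rng.choice(len(used), size=n_reused, replace=False)
                chosen.update(used[i] for i in picks)
            while len(chosen) < size and unused:
                chosen.add(unused.pop())
            while len(chosen) < size:  # universe exhausted: draw from used pool
                pick = used[int(rng.integers(len(used)))]
                chosen.add(pick)
            sets[f"SP{k:04d}"] = frozenset(chosen)
            for mid in sets[f"SP{k:04d}"]:
                if mid not in used:
                    used.append(mid)
    else:
        raise ValueError(f"unknown overlap model {overlap_model!r}")
    return PathwayCollection.from_dict(sets, source="synthetic")


def make_toy_fixture() -> tuple[MetaboliteMatrix, PathwayCollection, pd.Series]:
    """Fixed 6-sample x 6-metabolite instance with 3 two-member pathways.

    Values are small integers standardized column-wise, so pathway
    z-scores can be verified by hand.  Byte-stable across runs.
    """
    raw = np.array(
        [
            [1.0, 2.0, 5.0, 1.0, 3.0, 2.0],
            [2.0, 4.0, 4.0, 2.0, 1.0, 5.0],
            [3.0, 6.0, 3.0, 3.0, 4.0, 3.0],
            [4.0, 8.0, 2.0, 5.0, 2.0, 9.0],
            [5.0, 10.0, 1.0, 8.0, 6.0, 11.0],
            [6.0, 12.0, 6.0, 13.0, 5.0, 14.0],
        ]
    )
    Z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    metabolite_ids = [f"CHEBI:{j}" for j in range(1, 7)]
    sample_ids = [f"T{j}" for j in range(1, 7)]
    data = pd.DataFrame(Z, index=sample_ids, columns=metabolite_ids)
    labels = pd.Series(
        ["A", "A", "A", "B", "B", "B"], index=sample_ids, name="group"
    )
    matrix = MetaboliteMatrix(
        data=data, groups=labels, provenance=["log2", "standardized"]
    )
    collection = PathwayCollection.from_dict(
        {
            "TOY1": ["CHEBI:1", "CHEBI:2"],
            "TOY2": ["CHEBI:3", "CHEBI:4"],
            "TOY3": ["CHEBI:5", "CHEBI:6"],
        },
        source="synthetic",
    )
    return matrix, collection, labels
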