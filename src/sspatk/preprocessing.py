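"""Metabolite abundance container and the standard post-processing chain.

Untargeted MS metabolomics matrices typically arrive with missing values
and sample-to-sample dilution effects.  The pipeline implemented here is
the common one for such data: iterative-SVD imputation of missing
intensities, probabilistic quotient normalisation (PQN) against the
median spectrum, log2 transformation, and per-metabolite standardisation
to mean 0 / sd 1.  Each step is callable on its own; :func:`preprocess`
runs them in that fixed order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteMatrix",
    "impute_iterative_svd",
    "pqn_normalize",
    "log2_standardize",
    "preprocess",
    "read_matrix",
    "write_matrix",
]


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance table with optional group labels.

    Parameters
    ----------
    data:
        DataFrame with unique sample ids as the index and unique
        metabolite identifiers (e.g. ``CHEBI:...``) as columns.
    groups:
        Optional per-sample categorical labels (e.g. disease / control),
        indexed like ``data``.
    provenance:
        Ordered record of the transforms already applied.  The strings
        ``"log2"`` and ``"standardized"`` are recognised by downstream
        steps to avoid double transformation.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = self.data.index.difference(self.groups.index)
            if len(missing):
                raise ValueError(
                    f"group labels missing for samples: {list(missing)[:5]}"
                )
            self.groups = self.groups.loc[self.data.index]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, step: str | None = None) -> "MetaboliteMatrix":
        """Return a copy carrying new values and an extended provenance."""
        prov = list(self.provenance) + ([step] if step else [])
        return MetaboliteMatrix(data=data, groups=self.groups, provenance=prov)

    def copy(self) -> "MetaboliteMatrix":
        return replace(self, data=self.data.copy(), provenance=list(self.provenance))


def read_matrix(
    path,
    sep: str | None = None,
    labels_path=None,
    provenance: list[str] | None = None,
) -> MetaboliteMatrix:
    """Read a samples x metabolites table (first column sample id, header row
    metabolite ids).  Empty cells and ``NA`` are treated as missing.  An
    optional two-column labels file (sample id, group) supplies groups."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    data = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    groups = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=sep, index_col=0).iloc[:, 0]
        groups = lab
    return MetaboliteMatrix(data=data, groups=groups, provenance=provenance or [])


def write_matrix(matrix: MetaboliteMatrix, path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep)


def impute_iterative_svd(
    matrix: MetaboliteMatrix,
    rank: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> MetaboliteMatrix:
    """Fill missing entries with an iterative low-rank SVD reconstruction.

    Missing cells are initialised with column means; each iteration
    computes the rank-``rank`` truncated SVD of the completed matrix and
    overwrites the missing cells with the reconstruction, until the
    relative Frobenius change of the imputed entries drops below ``tol``.
    Observed entries are never altered.

    ``rank`` defaults to ``min(10, min(n, m) - 1)``.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, m = X.shape
    if rank is None:
        rank = min(10, min(n, m) - 1)
    if not 1 <= rank < min(n, m):
        raise ValueError(f"rank must be in [1, {min(n, m) - 1}], got {rank}")
    mask = np.isnan(X)
    if not mask.any():
        return matrix.with_data(matrix.data.copy(), "imputed")
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        bad = [matrix.metabolite_ids[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"columns with no observed value: {bad}")

    col_means = np.nanmean(X, axis=0)
    filled = np.where(mask, col_means, X)
    converged = False
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new_imputed = recon[mask]
        change = np.linalg.norm(new_imputed - filled[mask])
        denom = max(np.linalg.norm(new_imputed), np.finfo(float).tiny)
        filled[mask] = new_imputed
        if change / denom < tol:
            converged = True
            break
    step = "imputed" if converged else "imputed(non-converged)"
    if not converged:
        warnings.warn("iterative SVD imputation did not converge", RuntimeWarning)
    out = pd.DataFrame(filled, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_data(out, step)


def pqn_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Probabilistic quotient normalisation against the median spectrum.

    The reference spectrum is the per-metabolite median over samples;
    each sample is divided by the median over metabolites of its
    value/reference quotients.  Requires strictly positive raw-scale
    values (apply before the log transform).
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before PQN")
    if (X <= 0).any():
        raise ValueError(
            "non-positive values; PQN must be applied to raw-scale data "
            "before any log transform"
        )
    reference = np.median(X, axis=0)
    quotients = np.median(X / reference, axis=1)
    out = pd.DataFrame(
        X / quotients[:, None], index=matrix.data.index, columns=matrix.data.columns
    )
    return matrix.with_data(out, "pqn")


def log2_standardize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """log2-transform then standardise each metabolite to mean 0, sd 1.

    The sample standard deviation (ddof=1) is used.  If provenance
    already marks the matrix as log2 scale the log step is skipped.
    """
    X = matrix.data.to_numpy(dtype=float)
    steps = []
    if "log2" not in matrix.provenance:
        if (X <= 0).any():
            raise ValueError("non-positive values cannot be log2 transformed")
        X = np.log2(X)
        steps.append("log2")
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [matrix.metabolite_ids[j] for j in np.flatnonzero(zero_var)]
        raise ValueError(f"zero-variance metabolites: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    out = pd.DataFrame(Z, index=matrix.data.index, columns=matrix.data.columns)
    result = matrix.with_data(out)
    result.provenance += steps + ["standardized"]
    return result


def preprocess(
    matrix: MetaboliteMatrix,
    rank: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> MetaboliteMatrix:
    """Full chain: impute -> PQN -> log2 -> standardise."""
    out = impute_iterative_svd(matrix, rank=rank, max_iter=max_iter, tol=tol)
    out = pqn_normalize(out)
    return log2_standardize(out)
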