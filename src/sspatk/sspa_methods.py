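"""Single-sample pathway scoring.

Six scorers share one contract: (post-processed samples x metabolites
matrix, coverage-filtered pathway collection) -> samples x pathways
score matrix.

* ``score_zscore``   - normalised z-score sum over pathway members.
* ``score_svd``      - PLAGE: leading sample-side singular vector of the
  pathway submatrix.
* ``score_ssgsea``   - integrated Kolmogorov-Smirnov-like random walk
  over each sample's abundance-ranked metabolite list.
* ``score_gsva``     - kernel-CDF transformed ranks followed by a
  max-deviation KS random walk.
* ``score_ssclustpa`` - projection onto the unit vector between two
  k-means centroids of the pathway submatrix.
* ``score_kpca``     - first principal component of an RBF-kernel PCA of
  the pathway submatrix.

SVD, ssClustPA and kPCA scores carry an arbitrary sign; the
``mean-correlation`` sign policy flips each column so it correlates
non-negatively with the per-sample mean of the pathway submatrix,
making output deterministic without claiming directional meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import ndtr
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .pathway_io import PathwayCollection
from .preprocessing import MetaboliteMatrix

__all__ = [
    "PathwayScoreMatrix",
    "score_zscore",
    "score_svd",
    "score_ssgsea",
    "score_gsva",
    "score_ssclustpa",
    "score_kpca",
    "SCORERS",
]


@dataclass
class PathwayScoreMatrix:
    """Samples x pathways score matrix with method provenance."""

    scores: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.columns)


def _pathway_columns(
    matrix: MetaboliteMatrix, collection: PathwayCollection
) -> dict[str, np.ndarray]:
    """Column index arrays of each pathway's measured members, in a
    deterministic (matrix column) order."""
    col_index = {m: j for j, m in enumerate(matrix.metabolite_ids)}
    out: dict[str, np.ndarray] = {}
    for pid in collection:
        members = collection.members(pid)
        missing = members - col_index.keys()
        if missing:
            raise ValueError(
                f"pathway {pid!r} has members absent from the matrix "
                f"(run filter_by_coverage first): {sorted(missing)[:5]}"
            )
        out[pid] = np.array(sorted(col_index[m] for m in members), dtype=int)
    return out


def _fix_signs(scores: np.ndarray, X: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    """mean-correlation sign policy: flip each score column so that its
    covariance with the per-sample mean of its pathway submatrix is >= 0."""
    for k, idx in enumerate(cols):
        ref = X[:, idx].mean(axis=1)
        cov = np.dot(scores[:, k] - scores[:, k].mean(), ref - ref.mean())
        if cov < 0:
            scores[:, k] = -scores[:, k]
    return scores


def _result(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    scores: np.ndarray,
    method: str,
    **params,
) -> PathwayScoreMatrix:
    if not np.isfinite(scores).all():
        raise ValueError(f"{method} produced non-finite scores")
    df = pd.DataFrame(
        scores, index=matrix.data.index, columns=collection.pathway_ids
    )
    return PathwayScoreMatrix(scores=df, method=method, params=params)


def score_zscore(
    matrix: MetaboliteMatrix, collection: PathwayCollection
) -> PathwayScoreMatrix:
    """Normalised z-score: score(i, k) = sum_{j in p_k} z_ij / sqrt(M_k).

    Expects a per-metabolite standardized matrix; for independent
    standardized members the scores are again approximately standard
    normal.
    """
    if "standardized" not in matrix.provenance:
        warnings.warn(
            "z-score pathway scoring expects a standardized matrix; "
            "provenance does not record standardisation",
            RuntimeWarning,
        )
    X = matrix.data.to_numpy(dtype=float)
    cols = _pathway_columns(matrix, collection)
    member = np.zeros((X.shape[1], len(cols)))
    for k, idx in enumerate(cols.values()):
        member[idx, k] = 1.0 / np.sqrt(len(idx))
    return _result(matrix, collection, X @ member, "zscore")


def score_svd(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    sign_policy: str = "mean-correlation",
) -> PathwayScoreMatrix:
    """PLAGE-style scores: the unit-norm left singular vector of the
    pathway submatrix Z_k associated with its largest singular value."""
    X = matrix.data.to_numpy(dtype=float)
    cols = _pathway_columns(matrix, collection)
    n = X.shape[0]
    scores = np.empty((n, len(cols)))
    for k, idx in enumerate(cols.values()):
        Z = X[:, idx]
        if not Z.any():
            pid = list(cols)[k]
            raise ValueError(f"pathway {pid!r} submatrix is all zeros")
        # small-side eigendecomposition: M_k << n in practice
        G = Z.T @ Z
        w, v = eigh(G, subset_by_index=[G.shape[0] - 1, G.shape[0] - 1])
        if w[0] <= 0:
            pid = list(cols)[k]
            raise ValueError(f"pathway {pid!r} submatrix is degenerate")
        scores[:, k] = (Z @ v[:, 0]) / np.sqrt(w[0])
    if sign_policy == "mean-correlation":
        scores = _fix_signs(scores, X, list(cols.values()))
    return _result(matrix, collection, scores, "svd", sign_policy=sign_policy)


def _descending_order_and_ranks(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample stable descending order and descending rank values
    (top abundance -> rank m; ties share their average rank)."""
    order = np.argsort(-X, axis=1, kind="stable")
    m = X.shape[1]
    ranks = m + 1 - rankdata(X, axis=1, method="average")  # 1 = top
    rank_values = m + 1 - ranks  # m = top
    return order, rank_values


def _ks_walk(
    ordered_weight: np.ndarray,
    ordered_inset: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Weighted KS-like random walk for every sample at once.

    ``ordered_weight``: n x m in-set weights at each ranked position;
    ``ordered_inset``: n x m boolean in-set indicator at each position.
    ``mode``: ``"integrated"`` sums the running deviation over all steps
    (ssGSEA lineage); ``"max-diff"`` returns max positive deviation +
    min negative deviation (GSVA lineage).
    """
    w_in = np.where(ordered_inset, ordered_weight, 0.0)
    total_in = w_in.sum(axis=1, keepdims=True)
    if (total_in == 0).any():
        raise ValueError("pathway with zero total in-set weight")
    cum_in = np.cumsum(w_in, axis=1) / total_in
    n_out = (~ordered_inset).sum(axis=1, keepdims=True)
    cum_out = np.cumsum(~ordered_inset, axis=1) / n_out
    v = cum_in - cum_out
    if mode == "integrated":
        return v.sum(axis=1)
    if mode == "max-diff":
        return np.maximum(v, 0).max(axis=1) + np.minimum(v, 0).min(axis=1)
    if mode == "max-abs":
        imax = np.abs(v).argmax(axis=1)
        return v[np.arange(v.shape[0]), imax]
    raise ValueError(f"unknown walk mode {mode!r}")


def score_ssgsea(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    weight_alpha: float = 0.25,
    normalize: bool = False,
) -> PathwayScoreMatrix:
    """ssGSEA: per sample, metabolites are ranked by abundance and the
    enrichment score is the *integrated* running sum of the weighted
    in-set ECDF (weights = rank^weight_alpha) minus the unweighted
    out-set ECDF.  Optional normalisation divides the whole score matrix
    by its (max - min)."""
    X = matrix.data.to_numpy(dtype=float)
    n, m = X.shape
    cols = _pathway_columns(matrix, collection)
    for pid, idx in cols.items():
        if len(idx) >= m:
            raise ValueError(f"pathway {pid!r} covers every metabolite")
    order, rank_values = _descending_order_and_ranks(X)
    rows = np.arange(n)[:, None]
    ordered_weight = (rank_values[rows, order]) ** weight_alpha
    scores = np.empty((n, len(cols)))
    inset = np.zeros(m, dtype=bool)
    for k, idx in enumerate(cols.values()):
        inset[:] = False
        inset[idx] = True
        scores[:, k] = _ks_walk(ordered_weight, inset[order], "integrated")
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return _result(
        matrix, collection, scores, "ssgsea",
        weight_alpha=weight_alpha, normalize=normalize,
    )


def _kernel_cdf(X: np.ndarray) -> np.ndarray:
    """Per-metabolite Gaussian kernel CDF estimate across samples,
    bandwidth = sample sd / 4."""
    n, m = X.shape
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance metabolite: kernel bandwidth is 0")
    h = sd / 4.0
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        out[:, j] = ndtr((col[:, None] - col[None, :]) / h[j]).mean(axis=1)
    return out


def score_gsva(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    tau: float = 1.0,
    es_mode: str = "max-diff",
) -> PathwayScoreMatrix:
    """GSVA: (1) Gaussian-kernel CDF estimate per metabolite across
    samples; (2) per sample, rank the CDF statistics across metabolites
    and form the symmetric rank statistic |m/2 - rank|; (3) KS-like walk
    down the ranked list with in-set weights |r|^tau, enrichment score
    per ``es_mode`` (default max positive deviation + min negative
    deviation)."""
    X = matrix.data.to_numpy(dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("GSVA kernel CDF needs at least 3 samples")
    cols = _pathway_columns(matrix, collection)
    kcdf = _kernel_cdf(X)
    order = np.argsort(-kcdf, axis=1, kind="stable")
    # ordinal ranks (ties broken by stable column order) so the symmetric
    # statistic cannot vanish for a whole metabolite set
    ranks = np.empty_like(kcdf)
    np.put_along_axis(ranks, order, np.arange(1, m + 1, dtype=float)[None, :], axis=1)
    sym = np.abs(m / 2.0 - ranks)
    rows = np.arange(n)[:, None]
    ordered_weight = sym[rows, order] ** tau
    scores = np.empty((n, len(cols)))
    inset = np.zeros(m, dtype=bool)
    for k, idx in enumerate(cols.values()):
        inset[:] = False
        inset[idx] = True
        scores[:, k] = _ks_walk(ordered_weight, inset[order], es_mode)
    return _result(matrix, collection, scores, "gsva", tau=tau, es_mode=es_mode)


def score_ssclustpa(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    seed: int = 0,
    restarts: int = 10,
    sign_policy: str = "mean-correlation",
) -> PathwayScoreMatrix:
    """ssClustPA: per pathway, 2-cluster k-means on the pathway
    submatrix Z_k; scores are the projection A_k = Z_k u onto the unit
    vector u between the two centroids."""
    X = matrix.data.to_numpy(dtype=float)
    cols = _pathway_columns(matrix, collection)
    n = X.shape[0]
    if n < 2:
        raise ValueError("k-means with k=2 needs at least 2 samples")
    scores = np.empty((n, len(cols)))
    seeds = np.random.SeedSequence(seed).generate_state(len(cols)) % (2**31)
    for k, idx in enumerate(cols.values()):
        Z = X[:, idx]
        km = KMeans(
            n_clusters=2,
            n_init=restarts,
            random_state=int(seeds[k]),
            tol=1e-6,
        ).fit(Z)
        c1, c2 = km.cluster_centers_
        delta = c1 - c2
        norm = np.linalg.norm(delta)
        if norm == 0:
            pid = list(cols)[k]
            raise ValueError(f"pathway {pid!r}: coincident k-means centroids")
        scores[:, k] = Z @ (delta / norm)
    if sign_policy == "mean-correlation":
        scores = _fix_signs(scores, X, list(cols.values()))
    return _result(
        matrix, collection, scores, "ssclustpa",
        seed=seed, restarts=restarts, sign_policy=sign_policy,
    )


def score_kpca(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    gamma: float | None = None,
    sign_policy: str = "mean-correlation",
) -> PathwayScoreMatrix:
    """Kernel PCA with an RBF kernel per pathway submatrix; the first
    principal component scores (leading centered-kernel eigenvector
    scaled by the square root of its eigenvalue) are the pathway scores.

    ``gamma`` defaults to 1/n with n the number of samples.
    """
    X = matrix.data.to_numpy(dtype=float)
    n = X.shape[0]
    if gamma is None:
        gamma = 1.0 / n
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    cols = _pathway_columns(matrix, collection)
    scores = np.empty((n, len(cols)))
    for k, idx in enumerate(cols.values()):
        Z = X[:, idx]
        sq = (Z * Z).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
        np.maximum(d2, 0, out=d2)
        K = np.exp(-gamma * d2)
        # double-centering
        row_means = K.mean(axis=1)
        K -= row_means[:, None]
        K -= K.mean(axis=0)[None, :]
        w, v = eigh(K, subset_by_index=[n - 1, n - 1], check_finite=False)
        if w[0] <= 0:
            pid = list(cols)[k]
            raise ValueError(f"pathway {pid!r}: non-positive leading eigenvalue")
        scores[:, k] = v[:, 0] * np.sqrt(w[0])
    if sign_policy == "mean-correlation":
        scores = _fix_signs(scores, X, list(cols.values()))
    return _result(
        matrix, collection, scores, "kpca", gamma=gamma, sign_policy=sign_policy
    )


def _seeded(fn):
    def wrapper(matrix, collection, seed=0):
        return fn(matrix, collection)

    return wrapper


#: Uniform access to the six scorers: fn(matrix, collection, seed) -> scores.
SCORERS = {
    "zscore": _seeded(score_zscore),
    "svd": _seeded(score_svd),
    "ssgsea": _seeded(score_ssgsea),
    "gsva": _seeded(score_gsva),
    "ssclustpa": lambda matrix, collection, seed=0: score_ssclustpa(
        matrix, collection, seed=seed
    ),
    "kpca": _seeded(score_kpca),
}
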