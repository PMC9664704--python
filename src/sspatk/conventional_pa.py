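"""Conventional pathway analysis comparators: ORA and permutation GSEA.

ORA applies a one-sided Fisher's exact test to the 2x2 membership table
of differentially abundant metabolites per pathway; GSEA computes the
classic weighted Kolmogorov-Smirnov running-sum enrichment score on a
t-statistic-ranked metabolite list with a sample-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathway_io import PathwayCollection
from .preprocessing import MetaboliteMatrix

__all__ = [
    "EnrichmentResultTable",
    "differential_metabolites",
    "ora",
    "gsea",
]


@dataclass
class EnrichmentResultTable:
    """Per-pathway enrichment results.

    ``table`` has columns ``statistic``, ``p_value``, ``q_value`` indexed
    by pathway id; ``n_tested`` is the number of pathways that received a
    p-value (ORA only tests pathways with at least one differentially
    abundant member, so this can be smaller than the collection).
    """

    table: pd.DataFrame
    method: str
    n_tested: int

    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    def q_values(self) -> pd.Series:
        return self.table["q_value"]


def _two_group_arrays(
    matrix: MetaboliteMatrix, labels: pd.Series | None = None
) -> tuple[np.ndarray, np.ndarray]:
    labels = matrix.groups if labels is None else pd.Series(labels).loc[matrix.data.index]
    if labels is None:
        raise ValueError("no group labels provided")
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    X = matrix.data.to_numpy(dtype=float)
    mask = (labels == levels[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return X[mask], X[~mask]


def differential_metabolites(
    matrix: MetaboliteMatrix,
    labels: pd.Series | None = None,
    q_threshold: float = 0.05,
) -> tuple[frozenset[str], pd.DataFrame]:
    """Per-metabolite two-sided t-tests with BH correction.

    Returns the set of metabolites with q <= ``q_threshold`` and the full
    statistics table (t, p, q per metabolite).
    """
    A, B = _two_group_arrays(matrix, labels)
    t, p = stats.ttest_ind(A, B, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"t": t, "p_value": p, "q_value": q}, index=matrix.data.columns
    )
    da = frozenset(table.index[table["q_value"] <= q_threshold])
    return da, table


def ora(
    da_set: frozenset[str] | set[str],
    collection: PathwayCollection,
    background: frozenset[str] | set[str],
) -> EnrichmentResultTable:
    """Over-representation analysis via one-sided Fisher's exact tests.

    Only pathways containing at least one differentially abundant (DA)
    metabolite are tested; BH correction is applied over those.  The
    background is conventionally the set of measured metabolites
    annotated to at least one pathway.
    """
    background = frozenset(background)
    da_set = frozenset(da_set) & background
    if not background:
        raise ValueError("empty background set")
    rows = []
    for pid in collection:
        members = collection.members(pid) & background
        hits = members & da_set
        if not hits:
            continue
        a = len(hits)
        b = len(members) - a
        c = len(da_set) - a
        d = len(background) - len(da_set) - b
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((pid, odds, p))
    if not rows:
        table = pd.DataFrame(columns=["statistic", "p_value", "q_value"])
        return EnrichmentResultTable(table=table, method="ora", n_tested=0)
    table = pd.DataFrame(
        rows, columns=["pathway_id", "statistic", "p_value"]
    ).set_index("pathway_id")
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return EnrichmentResultTable(table=table, method="ora", n_tested=len(table))


def _ranking_tstat(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Equal-variance t statistic per column for mask vs ~mask."""
    nA, nB = mask.sum(), (~mask).sum()
    A, B = X[mask], X[~mask]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    vA, vB = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    denom = np.sqrt(sp2 * (1 / nA + 1 / nB))
    denom = np.where(denom == 0, np.finfo(float).tiny, denom)
    return (mA - mB) / denom


def _gsea_es(
    stats_vec: np.ndarray, inset: np.ndarray, weight: float
) -> float:
    """Max-deviation weighted KS enrichment score for one pathway.

    Metabolites are ordered by decreasing ranking statistic; the in-set
    increment at each step is |stat|^weight (normalised), the out-set
    increment 1/(m - M_k).  Returns the signed maximum deviation.
    """
    order = np.argsort(-stats_vec, kind="stable")
    inset_o = inset[order]
    w = np.abs(stats_vec[order]) ** weight
    w_in = np.where(inset_o, w, 0.0)
    total = w_in.sum()
    if total == 0:
        return 0.0
    v = np.cumsum(w_in) / total - np.cumsum(~inset_o) / (~inset_o).sum()
    return float(v[np.argmax(np.abs(v))])


def gsea(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    labels: pd.Series | None = None,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResultTable:
    """Conventional two-group GSEA with a sample-permutation null.

    Metabolites are ranked by the signed equal-variance t statistic; the
    enrichment score is the maximum deviation of the weighted KS running
    sum; the p-value is the plus-one-corrected fraction of label
    permutations whose |ES| reaches the observed |ES|.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", RuntimeWarning)
    labels = matrix.groups if labels is None else pd.Series(labels).loc[matrix.data.index]
    if labels is None:
        raise ValueError("no group labels provided")
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    X = matrix.data.to_numpy(dtype=float)
    mask = (labels == levels[0]).to_numpy()
    m = X.shape[1]
    col_index = {c: j for j, c in enumerate(matrix.data.columns)}
    insets = {}
    for pid in collection:
        vec = np.zeros(m, dtype=bool)
        vec[[col_index[c] for c in collection.members(pid) if c in col_index]] = True
        if vec.any() and not vec.all():
            insets[pid] = vec

    obs_stats = _ranking_tstat(X, mask)
    obs_es = {pid: _gsea_es(obs_stats, v, weight) for pid, v in insets.items()}

    rng = np.random.default_rng(seed)
    exceed = dict.fromkeys(insets, 0)
    for _ in range(n_perm):
        perm_mask = rng.permutation(mask)
        perm_stats = _ranking_tstat(X, perm_mask)
        for pid, vec in insets.items():
            es = _gsea_es(perm_stats, vec, weight)
            if abs(es) >= abs(obs_es[pid]):
                exceed[pid] += 1
    rows = [
        (pid, obs_es[pid], (exceed[pid] + 1) / (n_perm + 1)) for pid in insets
    ]
    table = pd.DataFrame(
        rows, columns=["pathway_id", "statistic", "p_value"]
    ).set_index("pathway_id")
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return EnrichmentResultTable(table=table, method="gsea", n_tested=len(table))
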