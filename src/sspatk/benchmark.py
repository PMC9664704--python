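"""Semi-synthetic permute-and-spike benchmarking engine.

The design: group labels are randomly permuted (erasing any real
signal), k pathways are chosen as "enriched", and a constant effect
alpha is added on the log2 scale to the (optionally subsampled) member
metabolites of those pathways in one group only.  Each scoring method
is then run on the spiked matrix, per-pathway two-sample t-tests and
BH correction give q-values, and pathways are classified TP/FP/TN/FN
against an overlap-coefficient truth model: a pathway counts as truly
positive if it is one of the enriched pathways or overlaps their pooled
metabolite set with overlap coefficient >= theta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .conventional_pa import differential_metabolites, gsea, ora
from .pathway_io import PathwayCollection, filter_by_coverage, overlap_coefficient
from .preprocessing import MetaboliteMatrix
from .sspa_methods import SCORERS, PathwayScoreMatrix

__all__ = [
    "SpikeDesign",
    "ConfusionRecord",
    "Metrics",
    "BenchmarkResult",
    "simulate_dataset",
    "reduce_coverage",
    "pathway_ttests",
    "bh_adjust",
    "classify_outcomes",
    "compute_metrics",
    "normalized_ranks",
    "run_benchmark",
    "pairwise_method_tests",
]


@dataclass
class SpikeDesign:
    """One realisation of the permute-and-spike simulation."""

    permuted_labels: pd.Series
    enriched: tuple[str, ...]
    spiked_group: str
    spiked_metabolites: frozenset[str]
    m_k: frozenset[str]
    alpha: float
    signal_fraction: float
    rng_seed: int | None = None

    @property
    def enriched_set(self) -> frozenset[str]:
        return frozenset(self.enriched)


@dataclass(frozen=True)
class ConfusionRecord:
    pathway_id: str
    p_value: float
    q_value: float
    oc: float
    outcome: str  # TP / FP / TN / FN
    theta: float

    @property
    def is_positive_class(self) -> bool:
        return self.outcome in ("TP", "FN")


class Metrics(NamedTuple):
    recall: float
    precision: float
    auc: float
    precision_defined: bool = True
    auc_defined: bool = True


def simulate_dataset(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    alpha: float,
    k: int = 3,
    signal_fraction: float = 100.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[MetaboliteMatrix, SpikeDesign]:
    """Permute group labels and spike the enriched pathways' metabolites.

    ``alpha`` is added on the log2 scale to a random ``signal_fraction``
    percent of the enriched pathways' measured members, for samples in
    the (permuted) second group only; the first group and all other
    entries are untouched.
    """
    rng = np.random.default_rng(rng)
    if matrix.groups is None:
        raise ValueError("matrix has no group labels to permute")
    levels = sorted(pd.unique(matrix.groups))
    if len(levels) != 2:
        raise ValueError("permute-and-spike needs exactly two groups")
    if k > len(collection):
        raise ValueError(f"k={k} exceeds collection size {len(collection)}")
    if not 0 <= signal_fraction <= 100:
        raise ValueError("signal_fraction must be a percentage in [0, 100]")

    permuted = pd.Series(
        rng.permutation(matrix.groups.to_numpy()),
        index=matrix.data.index,
        name="group",
    )
    pids = collection.pathway_ids
    enriched = tuple(pids[i] for i in rng.choice(len(pids), size=k, replace=False))
    m_k = frozenset().union(*(collection.members(p) for p in enriched))
    m_k_sorted = sorted(m_k)
    n_spiked = int(round(signal_fraction / 100.0 * len(m_k_sorted)))
    spiked = frozenset(
        m_k_sorted[i]
        for i in rng.choice(len(m_k_sorted), size=n_spiked, replace=False)
    )

    data = matrix.data.copy()
    if alpha != 0 and spiked:
        rows = (permuted == levels[1]).to_numpy()
        cols = [c for c in data.columns if c in spiked]
        data.loc[rows, cols] += alpha
    Y = MetaboliteMatrix(
        data=data, groups=permuted, provenance=list(matrix.provenance)
    )
    design = SpikeDesign(
        permuted_labels=permuted,
        enriched=enriched,
        spiked_group=levels[1],
        spiked_metabolites=spiked,
        m_k=m_k,
        alpha=alpha,
        signal_fraction=signal_fraction,
    )
    return Y, design


def reduce_coverage(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    pathway_id: str,
    relative_coverage: float,
    rng: np.random.Generator | int | None = None,
) -> MetaboliteMatrix:
    """Delete a random subset of one pathway's measured metabolite columns
    so that ``round(relative_coverage/100 * coverage)`` remain.  Deleted
    columns vanish from the matrix globally (and hence from every other
    pathway's measured set)."""
    rng = np.random.default_rng(rng)
    measured = [m for m in collection.members(pathway_id) if m in matrix.data.columns]
    keep = int(round(relative_coverage / 100.0 * len(measured)))
    if keep < 2:
        raise ValueError(
            f"reducing {pathway_id!r} to {keep} member(s); at least 2 required"
        )
    if keep >= len(measured):
        return matrix.with_data(matrix.data.copy())
    measured = sorted(measured)
    drop_idx = rng.choice(len(measured), size=len(measured) - keep, replace=False)
    drop = [measured[i] for i in drop_idx]
    return matrix.with_data(matrix.data.drop(columns=drop))


def pathway_ttests(
    scores: PathwayScoreMatrix,
    labels: pd.Series,
    equal_var: bool = True,
) -> pd.Series:
    """Two-sided independent two-sample t-test per pathway score column.

    Degenerate columns (zero variance in both groups with equal means)
    get p = 1 by convention.
    """
    labels = pd.Series(labels).loc[scores.scores.index]
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    mask = (labels == levels[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    X = scores.scores.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(X[mask], X[~mask], axis=0, equal_var=equal_var)
    if np.isnan(p).any():
        warnings.warn(
            "constant score column(s): p set to 1 by convention", RuntimeWarning
        )
        p = np.nan_to_num(p, nan=1.0)
    return pd.Series(p, index=scores.scores.columns, name="p_value")


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_outcomes(
    q: pd.Series,
    design: SpikeDesign,
    collection: PathwayCollection,
    theta: float,
    p: pd.Series | None = None,
    q_threshold: float = 0.05,
) -> list[ConfusionRecord]:
    """Assign each scored pathway a TP/FP/TN/FN outcome.

    A pathway is in the positive class if it is one of the enriched
    pathways or its measured member set has overlap coefficient >=
    ``theta`` with the pooled spiked-pathway metabolite set M_k;
    significance is q <= ``q_threshold``.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    records = []
    enriched = design.enriched_set
    for pid, q_val in q.items():
        if pid not in collection:
            raise ValueError(f"scored pathway {pid!r} absent from collection")
        oc = overlap_coefficient(design.m_k, collection.members(pid))
        positive = pid in enriched or oc >= theta
        significant = q_val <= q_threshold
        outcome = ("TP" if positive else "FP") if significant else (
            "FN" if positive else "TN"
        )
        records.append(
            ConfusionRecord(
                pathway_id=pid,
                p_value=float(p[pid]) if p is not None else float("nan"),
                q_value=float(q_val),
                oc=oc,
                outcome=outcome,
                theta=theta,
            )
        )
    return records


def compute_metrics(records: list[ConfusionRecord]) -> Metrics:
    """Recall, precision and ROC AUC from a set of confusion records.

    Precision with zero predicted positives is recorded as 0 with
    ``precision_defined=False``.  AUC uses the positive-class labels and
    -log10(p) as scores (midrank tie handling); with a single class it
    is NaN with ``auc_defined=False``.
    """
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for r in records:
        counts[r.outcome] += 1
    tp, fp, fn = counts["TP"], counts["FP"], counts["FN"]
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    labels = np.array([r.is_positive_class for r in records], dtype=int)
    pvals = np.clip(np.array([r.p_value for r in records]), 1e-300, 1.0)
    if np.isnan(pvals).any():
        raise ValueError("AUC requires p-values on every record")
    auc_defined = 0 < labels.sum() < len(labels)
    auc = (
        float(roc_auc_score(labels, -np.log10(pvals)))
        if auc_defined
        else float("nan")
    )
    return Metrics(recall, precision, auc, precision_defined, auc_defined)


def normalized_ranks(
    p: pd.Series,
    design: SpikeDesign,
    n_tested: int | None = None,
) -> float:
    """Mean normalized ascending-p rank of the enriched pathways.

    Ties take midranks; an enriched pathway missing from ``p`` (e.g.
    untested by ORA) is assigned the worst rank ``n_tested``.
    """
    if n_tested is None:
        n_tested = len(p)
    if n_tested < len(design.enriched):
        raise ValueError("n_tested smaller than the number of enriched pathways")
    ranks = pd.Series(stats.rankdata(p.to_numpy(), method="average"), index=p.index)
    vals = []
    for pid in design.enriched:
        if pid in ranks.index:
            vals.append(ranks[pid] / n_tested)
        else:
            warnings.warn(
                f"enriched pathway {pid!r} untested; assigned worst rank",
                RuntimeWarning,
            )
            vals.append(1.0)
    return float(np.mean(vals))


@dataclass
class BenchmarkResult:
    """Long-format per-iteration benchmark records plus run parameters.

    ``records`` columns: method, parameter, condition, iteration,
    recall, precision, auc, norm_rank, failed.
    """

    records: pd.DataFrame
    parameter: str
    theta: float
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and SEM of each metric per (method, condition).

        Undefined (NaN) AUC iterations are excluded from the AUC
        aggregate; failed iterations are excluded entirely.
        """
        ok = self.records[~self.records["failed"]]
        grouped = ok.groupby(["method", "condition"])[
            ["recall", "precision", "auc", "norm_rank", "reject_rate"]
        ]
        out = grouped.agg(["mean", "sem"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()


def _restandardize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    X = matrix.data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance metabolite after spiking")
    Z = (X - X.mean(axis=0)) / sd
    out = matrix.with_data(
        pd.DataFrame(Z, index=matrix.data.index, columns=matrix.data.columns)
    )
    if "standardized" not in out.provenance:
        out.provenance.append("standardized")
    return out


def _method_pvalues(
    method: str,
    Y: MetaboliteMatrix,
    collection: PathwayCollection,
    scorer_seed: int,
    gsea_n_perm: int,
    gsea_seed: int,
) -> tuple[pd.Series, pd.Series, int]:
    """Run one method on a simulated matrix; return (p, q, n_tested).

    ssPA methods score then t-test every coverage-filtered pathway; ORA
    and GSEA produce pathway p-values directly.  Pathways a method does
    not test are assigned q = 1 (never significant).
    """
    if method in SCORERS:
        scores = SCORERS[method](Y, collection, seed=scorer_seed)
        p = pathway_ttests(scores, Y.groups)
        q = pd.Series(bh_adjust(p), index=p.index)
        return p, q, len(p)
    if method == "ora":
        background = frozenset(Y.metabolite_ids) & collection.all_members()
        da, _ = differential_metabolites(Y)
        result = ora(da, collection, background)
        p = result.p_values()
        q = result.q_values()
        full_q = pd.Series(1.0, index=collection.pathway_ids)
        full_q.loc[q.index] = q
        return p, full_q, max(result.n_tested, 1)
    if method == "gsea":
        result = gsea(Y, collection, n_perm=gsea_n_perm, seed=gsea_seed)
        return result.p_values(), result.q_values(), result.n_tested
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    methods: list[str],
    grid: dict[str, list[float]],
    iterations: int = 200,
    theta: float = 0.5,
    k: int = 3,
    seed: int = 0,
    restandardize: bool = True,
    coverage_pathway: str | None = None,
    coverage_alpha: float = 1.0,
    gsea_n_perm: int = 250,
) -> BenchmarkResult:
    """Full permute-and-spike benchmark loop.

    ``grid`` maps one condition parameter name to its values: ``alpha``
    (effect size, signal fraction 100%), ``signal_fraction`` (percent
    spiked at alpha = 1), or ``relative_coverage`` (percent of
    ``coverage_pathway``'s members retained, that pathway enriched at
    ``coverage_alpha``).  Every method sees the identical spike design
    within an iteration (paired comparison), and per-iteration RNG
    streams are split from the master seed so reruns are bit-identical.
    """
    if len(grid) != 1:
        raise ValueError("grid must specify exactly one condition parameter")
    parameter, values = next(iter(grid.items()))
    if parameter not in ("alpha", "signal_fraction", "relative_coverage"):
        raise ValueError(f"unknown grid parameter {parameter!r}")
    if parameter == "relative_coverage" and coverage_pathway is None:
        raise ValueError("relative_coverage grid requires coverage_pathway")

    master = np.random.SeedSequence(seed)
    children = master.spawn(len(values) * iterations)
    rows = []
    for ci, value in enumerate(values):
        for it in range(iterations):
            child = children[ci * iterations + it]
            rng = np.random.default_rng(child)
            scorer_seed, gsea_seed = (
                int(x) for x in child.generate_state(2) % (2**31)
            )
            if parameter == "alpha":
                work_matrix, work_collection = matrix, collection
                Y, design = simulate_dataset(
                    work_matrix, work_collection, alpha=value, k=k, rng=rng
                )
            elif parameter == "signal_fraction":
                work_matrix, work_collection = matrix, collection
                Y, design = simulate_dataset(
                    work_matrix, work_collection, alpha=1.0, k=k,
                    signal_fraction=value, rng=rng,
                )
            else:  # relative_coverage
                reduced = reduce_coverage(
                    matrix, collection, coverage_pathway, value, rng
                )
                work_collection, _ = filter_by_coverage(collection, reduced)
                work_matrix = reduced
                Y, design = _simulate_fixed(
                    work_matrix, work_collection, coverage_pathway,
                    coverage_alpha, rng,
                )
            if restandardize and design.alpha != 0:
                Y = _restandardize(Y)
            for method in methods:
                try:
                    p, q, n_tested = _method_pvalues(
                        method, Y, work_collection, scorer_seed,
                        gsea_n_perm, gsea_seed,
                    )
                    full_p = pd.Series(1.0, index=work_collection.pathway_ids)
                    full_p.loc[p.index] = p
                    full_q = q.reindex(work_collection.pathway_ids, fill_value=1.0)
                    records = classify_outcomes(
                        full_q, design, work_collection, theta, p=full_p,
                    )
                    metrics = compute_metrics(records)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        nr = normalized_ranks(p, design, n_tested)
                    reject = float((p.to_numpy() <= 0.05).mean())
                    rows.append(
                        (method, parameter, value, it, metrics.recall,
                         metrics.precision, metrics.auc, nr, reject, False, "")
                    )
                except Exception as exc:  # record failure, keep running
                    rows.append(
                        (method, parameter, value, it, np.nan, np.nan,
                         np.nan, np.nan, np.nan, True, f"{type(exc).__name__}: {exc}")
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "method", "parameter", "condition", "iteration", "recall",
            "precision", "auc", "norm_rank", "reject_rate", "failed",
            "reason",
        ],
    )
    return BenchmarkResult(
        records=records,
        parameter=parameter,
        theta=theta,
        params={
            "iterations": iterations, "k": k, "seed": seed,
            "restandardize": restandardize, "methods": list(methods),
        },
    )


def _simulate_fixed(
    matrix: MetaboliteMatrix,
    collection: PathwayCollection,
    pathway_id: str,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[MetaboliteMatrix, SpikeDesign]:
    """Spike one fixed pathway (coverage-reduction simulations)."""
    levels = sorted(pd.unique(matrix.groups))
    permuted = pd.Series(
        rng.permutation(matrix.groups.to_numpy()),
        index=matrix.data.index,
        name="group",
    )
    m_k = frozenset(collection.members(pathway_id))
    data = matrix.data.copy()
    rows = (permuted == levels[1]).to_numpy()
    data.loc[rows, sorted(m_k)] += alpha
    Y = MetaboliteMatrix(data=data, groups=permuted, provenance=list(matrix.provenance))
    design = SpikeDesign(
        permuted_labels=permuted,
        enriched=(pathway_id,),
        spiked_group=levels[1],
        spiked_metabolites=m_k,
        m_k=m_k,
        alpha=alpha,
        signal_fraction=100.0,
    )
    return Y, design


def pairwise_method_tests(
    results: BenchmarkResult,
    metric: str,
    condition: float,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests between every pair of methods on
    per-iteration metric values at one condition, Bonferroni corrected
    over the number of pairs."""
    ok = results.records[
        (~results.records["failed"])
        & (results.records["condition"] == condition)
    ]
    methods = sorted(ok["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    pairs = list(combinations(methods, 2))
    rows = []
    for a, b in pairs:
        xa = ok.loc[ok["method"] == a, metric].dropna()
        xb = ok.loc[ok["method"] == b, metric].dropna()
        if len(xa) < 10 or len(xb) < 10:
            raise ValueError("need at least 10 iterations per method")
        allvals = np.concatenate([xa.to_numpy(), xb.to_numpy()])
        if np.all(allvals == allvals[0]):
            u, p = math.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append((a, b, u, p))
    table = pd.DataFrame(rows, columns=["method_a", "method_b", "U", "p_value"])
    table["p_bonferroni"] = np.minimum(table["p_value"] * len(pairs), 1.0)
    return table
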