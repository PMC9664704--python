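"""Permute-and-spike engine, truth model, and performance metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from sspatk import (
    ConfusionRecord,
    SpikeDesign,
    bh_adjust,
    classify_outcomes,
    compute_metrics,
    normalized_ranks,
    pairwise_method_tests,
    pathway_ttests,
    reduce_coverage,
    run_benchmark,
    simulate_dataset,
)
from sspatk.sspa_methods import PathwayScoreMatrix


def _design(enriched=("P1",), m_k=("a", "b"), theta_labels=None):
    return SpikeDesign(
        permuted_labels=pd.Series(dtype=object),
        enriched=tuple(enriched),
        spiked_group="B",
        spiked_metabolites=frozenset(m_k),
        m_k=frozenset(m_k),
        alpha=1.0,
        signal_fraction=100.0,
    )


class TestSimulateDataset:
    def test_alpha_zero_is_bitwise_identity(self, small_base, small_collection):
        Y, design = simulate_dataset(small_base, small_collection, alpha=0.0, rng=0)
        assert np.array_equal(Y.data.to_numpy(), small_base.data.to_numpy())
        assert design.alpha == 0.0

    def test_control_group_rows_unchanged(self, small_base, small_collection):
        Y, design = simulate_dataset(small_base, small_collection, alpha=0.7, rng=1)
        ctrl = (design.permuted_labels != design.spiked_group).to_numpy()
        assert np.array_equal(
            Y.data.to_numpy()[ctrl], small_base.data.to_numpy()[ctrl]
        )

    def test_alpha_one_gives_fold_change_two(self, small_base, small_collection):
        """A +1 spike on the log2 scale is exactly a raw-scale fold change
        of 2 between the group means of every spiked metabolite."""
        Y, design = simulate_dataset(small_base, small_collection, alpha=1.0, rng=2)
        spiked_mask = (design.permuted_labels == design.spiked_group).to_numpy()
        for met in sorted(design.spiked_metabolites):
            diff = (
                Y.data.loc[spiked_mask, met].mean()
                - Y.data.loc[~spiked_mask, met].mean()
                - (
                    small_base.data.loc[spiked_mask, met].mean()
                    - small_base.data.loc[~spiked_mask, met].mean()
                )
            )
            assert 2.0 ** diff == pytest.approx(2.0)

    def test_signal_fraction_controls_spiked_count(self, small_base, small_collection):
        Y, design = simulate_dataset(
            small_base, small_collection, alpha=1.0, signal_fraction=50.0, rng=3
        )
        assert len(design.spiked_metabolites) == round(0.5 * len(design.m_k))

    def test_k_too_large_rejected(self, small_base, small_collection):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_dataset(small_base, small_collection, alpha=1.0, k=100, rng=0)


class TestReduceCoverage:
    def test_full_coverage_unchanged(self, small_base, small_collection):
        pid = small_collection.pathway_ids[0]
        out = reduce_coverage(small_base, small_collection, pid, 100.0, rng=0)
        assert out.data.shape == small_base.data.shape

    def test_rounding(self, small_base):
        from sspatk import PathwayCollection

        members = small_base.metabolite_ids[:10]
        coll = PathwayCollection.from_dict({"big": members})
        out = reduce_coverage(small_base, coll, "big", 20.0, rng=1)
        remaining = [m for m in members if m in out.data.columns]
        assert len(remaining) == 2

    def test_below_two_members_rejected(self, small_base, small_collection):
        pid = min(
            small_collection.pathway_ids,
            key=lambda p: len(small_collection.members(p)),
        )
        with pytest.raises(ValueError, match="at least 2"):
            reduce_coverage(small_base, small_collection, pid, 10.0, rng=0)


class TestPathwayTTests:
    def _scores(self, X, labels):
        df = pd.DataFrame(
            X, index=[f"s{i}" for i in range(X.shape[0])],
            columns=[f"P{j}" for j in range(X.shape[1])],
        )
        return (
            PathwayScoreMatrix(scores=df, method="test"),
            pd.Series(labels, index=df.index),
        )

    def test_duplicate_groups_give_p_one(self):
        block = np.random.default_rng(0).standard_normal((5, 3))
        scores, labels = self._scores(
            np.vstack([block, block]), ["A"] * 5 + ["B"] * 5
        )
        p = pathway_ttests(scores, labels)
        assert np.allclose(p, 1.0)

    def test_separated_means_tiny_p(self):
        rng = np.random.default_rng(1)
        X = np.concatenate(
            [rng.normal(-5, 1, (50, 1)), rng.normal(5, 1, (50, 1))]
        )
        scores, labels = self._scores(X, ["A"] * 50 + ["B"] * 50)
        assert pathway_ttests(scores, labels).iloc[0] < 1e-10

    def test_constant_column_p_one_with_warning(self):
        X = np.ones((8, 1))
        scores, labels = self._scores(X, ["A"] * 4 + ["B"] * 4)
        with pytest.warns(RuntimeWarning, match="constant"):
            p = pathway_ttests(scores, labels)
        assert p.iloc[0] == 1.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_order_preserving(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = bh_adjust(p)
        # q is a monotone non-decreasing function of p (ties allowed)
        assert np.all(np.diff(q[np.argsort(p)]) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassifyOutcomes:
    def _collection(self):
        from sspatk import PathwayCollection

        return PathwayCollection.from_dict(
            {
                "P1": ["a", "b"],          # enriched
                "P2": ["a", "c", "d", "e", "f", "g"],  # oc 1/2... depends
                "P3": ["x", "y"],          # disjoint
            }
        )

    def test_enriched_significant_is_tp(self):
        coll = self._collection()
        design = _design(enriched=("P1",), m_k=("a", "b"))
        q = pd.Series({"P1": 0.01, "P2": 0.5, "P3": 0.9})
        records = {r.pathway_id: r for r in
                   classify_outcomes(q, design, coll, theta=0.5)}
        assert records["P1"].outcome == "TP"

    def test_low_overlap_significant_is_fp(self):
        coll = self._collection()
        design = _design(enriched=("P1",), m_k=("a", "b"))
        q = pd.Series({"P1": 0.01, "P2": 0.01, "P3": 0.9})
        records = {r.pathway_id: r for r in
                   classify_outcomes(q, design, coll, theta=0.5)}
        # OC(m_k, P2) = |{a}| / min(2, 6) = 0.5 -> positive at theta 0.5?
        assert records["P2"].oc == pytest.approx(0.5)
        records = {r.pathway_id: r for r in
                   classify_outcomes(q, design, coll, theta=0.6)}
        assert records["P2"].outcome == "FP"

    def test_high_overlap_nonsignificant_is_fn(self):
        coll = self._collection()
        design = _design(enriched=("P1",), m_k=("a", "b"))
        q = pd.Series({"P1": 0.01, "P2": 0.2, "P3": 0.9})
        records = {r.pathway_id: r for r in
                   classify_outcomes(q, design, coll, theta=0.5)}
        assert records["P2"].outcome == "FN"  # oc 0.5 >= theta, q > 0.05
        assert records["P3"].outcome == "TN"

    @pytest.mark.parametrize("theta", [0.25, 0.5])
    def test_partition_complete(self, theta, small_base, small_collection):
        rng = np.random.default_rng(3)
        q = pd.Series(
            rng.random(len(small_collection)),
            index=small_collection.pathway_ids,
        )
        design = _design(
            enriched=tuple(small_collection.pathway_ids[:2]),
            m_k=sorted(
                small_collection.members(small_collection.pathway_ids[0])
                | small_collection.members(small_collection.pathway_ids[1])
            ),
        )
        records = classify_outcomes(q, design, small_collection, theta)
        assert len(records) == len(small_collection)
        counts = pd.Series([r.outcome for r in records]).value_counts()
        assert counts.sum() == len(small_collection)

    def test_lower_theta_never_shrinks_positive_class(self, small_collection):
        rng = np.random.default_rng(4)
        q = pd.Series(
            rng.random(len(small_collection)),
            index=small_collection.pathway_ids,
        )
        design = _design(
            enriched=(small_collection.pathway_ids[0],),
            m_k=sorted(small_collection.members(small_collection.pathway_ids[0])),
        )
        pos = {}
        for theta in (0.75, 0.5, 0.25):
            records = classify_outcomes(q, design, small_collection, theta)
            pos[theta] = sum(r.is_positive_class for r in records)
        assert pos[0.25] >= pos[0.5] >= pos[0.75]


class TestComputeMetrics:
    def _records(self, spec):
        return [
            ConfusionRecord("P%d" % i, p, q, oc, outcome, 0.5)
            for i, (p, q, oc, outcome) in enumerate(spec)
        ]

    def test_perfect_detection(self):
        records = self._records(
            [(1e-6, 1e-5, 1.0, "TP"), (0.9, 0.95, 0.0, "TN"),
             (0.8, 0.9, 0.0, "TN")]
        )
        m = compute_metrics(records)
        assert (m.recall, m.precision, m.auc) == (1.0, 1.0, 1.0)

    def test_zero_predictions_flagged(self):
        records = self._records(
            [(0.9, 0.9, 1.0, "FN"), (0.8, 0.85, 0.0, "TN")]
        )
        m = compute_metrics(records)
        assert m.precision == 0.0 and not m.precision_defined

    def test_auc_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 15
            p = rng.random(n)
            positive = rng.random(n) < 0.4
            if positive.all() or not positive.any():
                continue
            spec = []
            for i in range(n):
                sig = p[i] <= 0.05
                outcome = ("TP" if positive[i] else "FP") if sig else (
                    "FN" if positive[i] else "TN")
                spec.append((p[i], p[i], float(positive[i]), outcome))
            m = compute_metrics(self._records(spec))
            # brute-force pairwise comparison with midrank ties
            score = -np.log10(p)
            wins = ties = 0
            for i in np.flatnonzero(positive):
                for j in np.flatnonzero(~positive):
                    wins += score[i] > score[j]
                    ties += score[i] == score[j]
            expected = (wins + 0.5 * ties) / (positive.sum() * (~positive).sum())
            assert m.auc == pytest.approx(expected, abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(6)
        aucs = []
        for _ in range(300):
            p = rng.random(20)
            labels = np.zeros(20, dtype=int)
            labels[:5] = 1
            aucs.append(roc_auc_score(labels, -np.log10(p)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestNormalizedRanks:
    def test_top_ranks(self):
        p = pd.Series(
            np.linspace(0.001, 0.9, 255), index=[f"P{i}" for i in range(255)]
        )
        design = _design(enriched=("P0", "P1", "P2"))
        assert normalized_ranks(p, design) == pytest.approx(2 / 255)

    def test_all_ties_give_half(self):
        p = pd.Series(0.5, index=[f"P{i}" for i in range(99)])
        design = _design(enriched=("P0", "P1", "P2"))
        assert normalized_ranks(p, design) == pytest.approx(50 / 99)

    def test_untested_enriched_gets_worst_rank(self):
        p = pd.Series({"P1": 0.01, "P2": 0.5})
        design = _design(enriched=("P1", "P9"))
        with pytest.warns(RuntimeWarning, match="untested"):
            val = normalized_ranks(p, design, n_tested=2)
        assert val == pytest.approx((0.5 + 1.0) / 2)


class TestRunBenchmark:
    def test_bit_identical_rerun(self, small_base, small_collection):
        kwargs = dict(
            methods=["zscore", "svd"], grid={"alpha": [0.0, 1.0]},
            iterations=3, theta=0.5, seed=17,
        )
        a = run_benchmark(small_base, small_collection, **kwargs)
        b = run_benchmark(small_base, small_collection, **kwargs)
        assert a.records.equals(b.records)

    def test_null_condition_low_recall(self, small_base, small_collection):
        res = run_benchmark(
            small_base, small_collection, ["zscore"], {"alpha": [0.0]},
            iterations=20, theta=0.5, seed=18,
        )
        assert res.records["recall"].mean() < 0.15

    def test_signal_fraction_grid_runs(self, small_base, small_collection):
        res = run_benchmark(
            small_base, small_collection, ["zscore"],
            {"signal_fraction": [50.0, 100.0]}, iterations=3, seed=19,
        )
        assert not res.records["failed"].any()
        assert set(res.records["condition"]) == {50.0, 100.0}

    def test_coverage_grid_runs(self, small_base, small_collection):
        pid = max(
            small_collection.pathway_ids,
            key=lambda p: len(small_collection.members(p)),
        )
        res = run_benchmark(
            small_base, small_collection, ["zscore"],
            {"relative_coverage": [100.0, 60.0]}, iterations=3, seed=20,
            coverage_pathway=pid,
        )
        assert not res.records["failed"].any()


class TestPairwiseTests:
    def _result(self, shift):
        rng = np.random.default_rng(21)
        rows = []
        for method, delta in [("a", 0.0), ("b", shift)]:
            for it in range(200):
                rows.append(
                    (method, "alpha", 1.0, it, 0.5 + delta + rng.normal(0, 0.1),
                     0.5, 0.5, 0.1, 0.05, False, "")
                )
        from sspatk.benchmark import BenchmarkResult

        records = pd.DataFrame(
            rows, columns=[
                "method", "parameter", "condition", "iteration", "recall",
                "precision", "auc", "norm_rank", "reject_rate", "failed",
                "reason",
            ],
        )
        return BenchmarkResult(records=records, parameter="alpha", theta=0.5)

    def test_shifted_method_significant(self):
        table = pairwise_method_tests(self._result(0.3), "recall", 1.0)
        assert table["p_bonferroni"].iloc[0] < 0.001

    def test_bonferroni_factor_is_pair_count(self):
        res = self._result(0.0)
        extra = res.records.copy()
        extra["method"] = "c"
        res.records = pd.concat([res.records, extra], ignore_index=True)
        table = pairwise_method_tests(res, "recall", 1.0)
        assert len(table) == 3  # C(3, 2)
        assert np.all(table["p_bonferroni"] <= 1.0)
        assert np.allclose(
            np.minimum(table["p_value"] * 3, 1.0), table["p_bonferroni"]
        )

    def test_identical_values_p_one(self):
        res = self._result(0.0)
        res.records["precision"] = 0.7
        table = pairwise_method_tests(res, "precision", 1.0)
        assert np.allclose(table["p_value"], 1.0)
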