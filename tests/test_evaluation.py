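import itertools

import numpy as np
import pytest

from peptidecrf.evaluation import (
    EvaluationCounts,
    collapse_overlap_groups,
    evaluate_dataset,
    match_spans,
    precision_recall_f1,
    segments_from_probabilities,
    spans_from_labels,
)
from peptidecrf.state_space import build_state_space


def oracle_max_tp(pred, groups, tolerance):
    """Maximum one-to-one TP count by exhaustive bipartite assignment."""
    def matches(p, g):
        return any(abs(p[0] - s) <= tolerance and abs(p[1] - e) <= tolerance
                   for s, e in g.members)

    best = 0
    n = len(groups)
    for k in range(min(len(pred), n), -1, -1):
        for pred_sub in itertools.combinations(range(len(pred)), k):
            for perm in itertools.permutations(range(n), k):
                if all(matches(pred[p], groups[g]) for p, g in zip(pred_sub, perm)):
                    return k
    return best


def random_spans(rng, n_max=8, coord_max=60):
    spans = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        start = int(rng.integers(1, coord_max))
        spans.append((start, start + int(rng.integers(0, 12))))
    return spans


class TestSpansFromLabels:
    def test_merged_class_sequence(self):
        labels = ["None", "None", "Peptide", "Peptide", "Peptide", "Peptide",
                  "Peptide", "None"]
        assert spans_from_labels(labels) == [(3, 7, "Peptide")]

    def test_all_background(self):
        assert spans_from_labels(["None"] * 6) == []

    def test_back_to_back_state_spans_stay_separate(self):
        space = build_state_space(5, 50, ["Peptide", "Propeptide"])
        first = space.state_index("Peptide", 1)
        path = list(range(first, first + 5)) + list(range(first, first + 5))
        assert spans_from_labels(path, space) == [(1, 5, "Peptide"), (6, 10, "Peptide")]
        # the merged class sequence would fuse them into one run
        merged = ["Peptide"] * 10
        assert spans_from_labels(merged) == [(1, 10, "Peptide")]


class TestCollapseOverlapGroups:
    def test_pair_and_singleton(self):
        groups = collapse_overlap_groups([(1, 10), (5, 14), (30, 40)])
        assert sorted(tuple(sorted(g.members)) for g in groups) == [
            ((1, 10), (5, 14)), ((30, 40),)
        ]

    def test_disjoint_spans_become_singletons(self):
        groups = collapse_overlap_groups([(1, 5), (10, 15), (20, 25)])
        assert all(len(g.members) == 1 for g in groups)

    def test_transitive_chain_forms_one_group(self):
        groups = collapse_overlap_groups([(1, 10), (8, 20), (18, 30)])
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_matches_networkx_connected_components(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        for _ in range(30):
            spans = random_spans(rng)
            g = nx.Graph()
            g.add_nodes_from(range(len(spans)))
            for i, a in enumerate(spans):
                for j, b in enumerate(spans[:i]):
                    if a[0] <= b[1] and b[0] <= a[1]:
                        g.add_edge(i, j)
            expected = sorted(
                tuple(sorted(spans[i] for i in comp))
                for comp in nx.connected_components(g)
            )
            got = sorted(tuple(sorted(grp.members)) for grp in
                         collapse_overlap_groups(spans))
            assert got == expected


class TestMatchSpans:
    def test_within_tolerance_is_true_positive(self):
        groups = collapse_overlap_groups([(10, 20)])
        counts = match_spans([(12, 18)], groups, tolerance=3)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_outside_tolerance_is_fp_plus_fn(self):
        groups = collapse_overlap_groups([(10, 20)])
        counts = match_spans([(12, 18)], groups, tolerance=1)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_duplicate_prediction_counts_as_fp(self):
        groups = collapse_overlap_groups([(10, 20)])
        counts = match_spans([(10, 20), (11, 21)], groups, tolerance=3)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_group_satisfied_by_any_member(self):
        groups = collapse_overlap_groups([(1, 10), (5, 14)])
        assert match_spans([(5, 14)], groups, 0).tp == 1
        assert match_spans([(1, 10)], groups, 0).tp == 1
        assert len(groups) == 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_spans([], [], -1)

    def test_greedy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        mismatches = 0
        for _ in range(120):
            truth = random_spans(rng, n_max=5)
            pred = random_spans(rng, n_max=5)
            tol = int(rng.integers(0, 4))
            groups = collapse_overlap_groups(truth)
            got = match_spans(pred, groups, tol)
            assert got.tp + got.fn == len(groups)
            assert got.tp + got.fp == len(pred)
            mismatches += got.tp != oracle_max_tp(pred, groups, tol)
        assert mismatches == 0

    def test_tp_monotone_in_tolerance(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            truth = random_spans(rng)
            pred = random_spans(rng)
            groups = collapse_overlap_groups(truth)
            counts = [match_spans(pred, groups, tol) for tol in range(6)]
            tps = [c.tp for c in counts]
            assert tps == sorted(tps)
            errs = [c.fp + c.fn for c in counts]
            assert errs == sorted(errs, reverse=True)

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        truth = random_spans(rng)
        pred = random_spans(rng)
        base = match_spans(pred, collapse_overlap_groups(truth), 2)
        shift = 1000
        shifted = match_spans(
            [(s + shift, e + shift) for s, e in pred],
            collapse_overlap_groups([(s + shift, e + shift) for s, e in truth]),
            2,
        )
        assert (base.tp, base.fp, base.fn) == (shifted.tp, shifted.fp, shifted.fn)

    def test_perfect_predictions_at_every_tolerance(self):
        truth = [(3, 9), (20, 31), (50, 55)]
        groups = collapse_overlap_groups(truth)
        for tol in range(5):
            m = precision_recall_f1(match_spans(truth, groups, tol))
            assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (1, 1, 1, (0.5, 0.5, 0.5)),
        (0, 0, 5, (0.0, 0.0, 0.0)),
        (3, 1, 2, (0.75, 0.6, 2 / 3)),
        (0, 0, 0, (0.0, 0.0, 0.0)),
    ])
    def test_closed_forms(self, tp, fp, fn, expected):
        m = precision_recall_f1(EvaluationCounts(tp, fp, fn, 0))
        assert (m.precision, m.recall, m.f1) == pytest.approx(expected)


class TestSegmentsFromProbabilities:
    def test_threshold_example(self):
        segs = segments_from_probabilities([0.1, 0.6, 0.7, 0.2, 0.9], 0.5)
        assert segs == [(2, 3), (5, 5)]

    def test_all_below_threshold(self):
        assert segments_from_probabilities([0.1, 0.2], 0.5) == []

    def test_inclusive_comparison_and_default(self):
        assert segments_from_probabilities([0.5]) == [(1, 1)]
        with pytest.raises(ValueError):
            segments_from_probabilities([0.5], 0.0)


class TestEvaluateDataset:
    def _preds(self):
        truth = {"R1": [(10, 20, "Peptide")], "R2": [(5, 12, "Propeptide")]}
        predictions = {
            ("m1", "R1"): [(10, 20, "Peptide")],
            ("m1", "R2"): [(5, 12, "Propeptide")],
            ("m2", "R1"): [(10, 20, "Peptide")],
            ("m2", "R2"): [],
        }
        return predictions, truth

    def test_single_replicate_sd_zero(self):
        predictions, truth = self._preds()
        predictions = {k: v for k, v in predictions.items() if k[0] == "m1"}
        _, summary = evaluate_dataset(predictions, truth, tolerances=[0])
        assert (summary["precision_sd"] == 0).all()

    def test_mean_and_population_sd(self):
        # replicate precisions 0.4 and 0.6 -> mean 0.5, SD 0.1
        truth = {"R1": [(i * 10, i * 10 + 5, "Peptide") for i in range(1, 6)]}
        pred_a = [(10, 15, "Peptide"), (20, 25, "Peptide")] + \
                 [(100 + i, 105 + i, "Peptide") for i in range(3)]
        pred_b = [(10, 15, "Peptide"), (20, 25, "Peptide"), (30, 35, "Peptide")] + \
                 [(200, 205, "Peptide"), (300, 305, "Peptide")]
        per_rep, summary = evaluate_dataset(
            {("a", "R1"): pred_a, ("b", "R1"): pred_b}, truth, tolerances=[0],
            classes=["Peptide"], include_pooled=False,
        )
        assert sorted(per_rep["precision"]) == [0.4, 0.6]
        assert summary["precision_mean"].iloc[0] == pytest.approx(0.5)
        assert summary["precision_sd"].iloc[0] == pytest.approx(0.1)

    def test_missing_record_counts_as_fn_with_warning(self):
        truth = {"R1": [(10, 20, "Peptide")], "R2": [(5, 12, "Peptide")]}
        with pytest.warns(UserWarning, match="false negatives"):
            per_rep, _ = evaluate_dataset(
                {("m1", "R1"): [(10, 20, "Peptide")]}, truth, tolerances=[0],
                classes=["Peptide"], include_pooled=False,
            )
        row = per_rep.iloc[0]
        assert (row.tp, row.fn) == (1, 1)

    def test_pooled_precision_is_mediant(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            tp1, fp1, tp2, fp2 = rng.integers(0, 10, size=4)
            c1 = EvaluationCounts(int(tp1), int(fp1), 0, 0)
            c2 = EvaluationCounts(int(tp2), int(fp2), 0, 0)
            pooled = EvaluationCounts(c1.tp + c2.tp, c1.fp + c2.fp, 0, 0)
            ps = sorted([precision_recall_f1(c1).precision,
                         precision_recall_f1(c2).precision])
            p_all = precision_recall_f1(pooled).precision
            if (c1.tp + c1.fp) and (c2.tp + c2.fp):
                assert ps[0] - 1e-12 <= p_all <= ps[1] + 1e-12


class TestMatchingProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    span_lists = st.lists(
        st.tuples(st.integers(1, 50), st.integers(0, 12)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        max_size=8,
    )

    @given(truth=span_lists, pred=span_lists, shift=st.integers(-30, 1000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_counts_conserved_and_translation_invariant(self, truth, pred, shift):
        groups = collapse_overlap_groups(truth)
        counts = match_spans(pred, groups, 2)
        assert counts.tp + counts.fn == len(groups)
        assert counts.tp + counts.fp == len(pred)
        moved = match_spans(
            [(s + shift, e + shift) for s, e in pred],
            collapse_overlap_groups([(s + shift, e + shift) for s, e in truth]),
            2,
        )
        assert (counts.tp, counts.fp, counts.fn) == (moved.tp, moved.fp, moved.fn)
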