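"""Span-level evaluation with tolerance windows.

A prediction counts as a true positive when both of its termini fall
within a tolerance window of a ground-truth span's termini. Overlapping
ground-truth spans are collapsed into one group that counts once and is
satisfied by matching any member. True negatives are undefined at span
level, so only precision, recall and F1 are reported.

All spans here are (start, end) pairs in the same convention as the
annotation tables: 1-based inclusive. The metrics are invariant to a
common coordinate shift, so internal 0-based spans converted once at the
module boundary give identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Span = tuple[int, int]


@dataclass
class EvaluationCounts:
    tp: int
    fp: int
    fn: int
    tolerance: int
    span_class: str = "all"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    def __add__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        return EvaluationCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn,
            self.tolerance, self.span_class,
        )


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def spans_from_labels(labels, space=None) -> list[tuple[int, int, str]]:
    """Convert a label sequence into 1-based inclusive (start, end, class) spans.

    With a state space given, ``labels`` is a state path and span boundaries
    follow the state positions (a new span opens at every position-1 state,
    so back-to-back same-class spans stay separate). Without one, ``labels``
    is a merged per-position class sequence (class names or indices with an
    optional ``class_names`` mapping) and maximal same-class runs become
    spans.
    """
    labels = list(labels)
    spans: list[tuple[int, int, str]] = []
    if space is not None:
        path = np.asarray(labels, dtype=np.int64)
        cos, pos, names = space.class_of_state, space.position_of_state, space.class_names
        t, T = 0, len(path)
        while t < T:
            s = int(path[t])
            if cos[s] > 0 and pos[s] == 1:
                end = t
                while (
                    end + 1 < T
                    and cos[path[end + 1]] == cos[s]
                    and pos[path[end + 1]] == pos[path[end]] + 1
                ):
                    end += 1
                spans.append((t + 1, end + 1, names[cos[s]]))
                t = end + 1
            else:
                t += 1
        return spans
    background = {"None", "N", 0, None}
    t, T = 0, len(labels)
    while t < T:
        cls = labels[t]
        if cls in background:
            t += 1
            continue
        end = t
        while end + 1 < T and labels[end + 1] == cls:
            end += 1
        spans.append((t + 1, end + 1, str(cls)))
        t = end + 1
    return spans


@dataclass(frozen=True)
class OverlapGroup:
    """A connected component of mutually overlapping ground-truth spans."""

    members: tuple[Span, ...]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.members)


def collapse_overlap_groups(true_spans: Sequence[Span]) -> list[OverlapGroup]:
    """Group spans into connected components under interval overlap."""
    spans = sorted(true_spans)
    groups: list[list[Span]] = []
    current: list[Span] = []
    reach = -1
    for span in spans:
        if current and span[0] <= reach:
            current.append(span)
            reach = max(reach, span[1])
        else:
            if current:
                groups.append(current)
            current = [span]
            reach = span[1]
    if current:
        groups.append(current)
    return [OverlapGroup(tuple(g)) for g in groups]


def match_spans(
    pred: Sequence[Span],
    truth_groups: Sequence[OverlapGroup],
    tolerance: int,
    span_class: str = "all",
) -> EvaluationCounts:
    """Greedy one-to-one matching of predictions against truth groups.

    A prediction matches a group if some member span has both
    ``|pred.start - true.start| <= tolerance`` and
    ``|pred.end - true.end| <= tolerance``. Predictions are scanned in
    order; each takes the earliest-starting still-unmatched group it
    matches. Extra predictions on an already-matched group are false
    positives; unmatched groups are false negatives.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    matched = [False] * len(truth_groups)
    tp = fp = 0
    order = sorted(range(len(truth_groups)), key=lambda i: truth_groups[i].start)
    for p_start, p_end in pred:
        hit = None
        for i in order:
            if matched[i]:
                continue
            if any(
                abs(p_start - t_start) <= tolerance and abs(p_end - t_end) <= tolerance
                for t_start, t_end in truth_groups[i].members
            ):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            matched[hit] = True
            tp += 1
    fn = matched.count(False)
    return EvaluationCounts(tp, fp, fn, tolerance, span_class)


def precision_recall_f1(counts: EvaluationCounts) -> Metrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean.

    Zero denominators yield 0 by convention.
    """
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f1)


def segments_from_probabilities(
    probs: Sequence[float], threshold: float = 0.5
) -> list[Span]:
    """Threshold per-position probabilities into 1-based inclusive segments.

    Maximal runs of positions with probability >= threshold (inclusive
    comparison) become spans; used to score per-residue predictors under
    the same span-matching protocol. The documented default threshold
    is 0.5.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    mask = probs >= threshold
    spans: list[Span] = []
    t, T = 0, len(mask)
    while t < T:
        if mask[t]:
            end = t
            while end + 1 < T and mask[end + 1]:
                end += 1
            spans.append((t + 1, end + 1))
            t = end + 1
        else:
            t += 1
    return spans


def evaluate_dataset(
    predictions: Mapping[tuple[str, str], Sequence[tuple[int, int, str]]],
    truth: Mapping[str, Sequence[tuple[int, int, str]]],
    tolerances: Sequence[int] = (0, 1, 2, 3),
    classes: Sequence[str] = ("Peptide", "Propeptide"),
    include_pooled: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Span metrics per (replicate, class, tolerance) plus mean/SD summary.

    ``predictions`` maps (replicate, record id) to 1-based (start, end,
    class) spans; ``truth`` maps record id to ground-truth spans. Records
    with no prediction entry for a replicate count as all false negatives
    (with a warning). The "all" class pools peptide and propeptide counts
    before taking the ratios; the summary SD is the population SD over
    replicates.
    """
    replicates = sorted({rep for rep, _ in predictions})
    rows = []
    for rep in replicates:
        pred_for_rep = {rid: spans for (r, rid), spans in predictions.items() if r == rep}
        missing = sorted(set(truth) - set(pred_for_rep))
        if missing:
            warnings.warn(
                f"replicate {rep!r}: no predictions for {len(missing)} record(s); "
                "counted as false negatives"
            )
        for tol in tolerances:
            per_class: dict[str, EvaluationCounts] = {}
            for cls in classes:
                acc = EvaluationCounts(0, 0, 0, tol, cls)
                for rid, true_spans in truth.items():
                    pred_spans = pred_for_rep.get(rid, [])
                    p = [(s, e) for s, e, c in pred_spans if c == cls]
                    groups = collapse_overlap_groups(
                        [(s, e) for s, e, c in true_spans if c == cls]
                    )
                    acc = acc + match_spans(p, groups, tol, cls)
                per_class[cls] = acc
                rows.append(_metrics_row(rep, cls, tol, acc))
            if include_pooled:
                pooled = EvaluationCounts(
                    sum(c.tp for c in per_class.values()),
                    sum(c.fp for c in per_class.values()),
                    sum(c.fn for c in per_class.values()),
                    tol,
                    "all",
                )
                rows.append(_metrics_row(rep, "all", tol, pooled))
    per_replicate = pd.DataFrame(rows)
    summary = (
        per_replicate.groupby(["class", "tolerance"], as_index=False)
        .agg(
            precision_mean=("precision", "mean"),
            precision_sd=("precision", lambda x: float(np.std(x, ddof=0))),
            recall_mean=("recall", "mean"),
            recall_sd=("recall", lambda x: float(np.std(x, ddof=0))),
            f1_mean=("f1", "mean"),
            f1_sd=("f1", lambda x: float(np.std(x, ddof=0))),
        )
    )
    return per_replicate, summary


def _metrics_row(rep: str, cls: str, tol: int, counts: EvaluationCounts) -> dict:
    m = precision_recall_f1(counts)
    return {
        "replicate": rep,
        "class": cls,
        "tolerance": tol,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "precision": m.precision,
        "recall": m.recall,
        "f1": m.f1,
    }
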