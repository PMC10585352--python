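"""Span annotations -> per-position state-label paths.

Precursors can carry overlapping peptide annotations, but a state path can
realise only one label per position, so overlaps are resolved by random
sampling: each training epoch keeps a maximal non-overlapping subset drawn
uniformly, re-randomized per epoch.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .seqio import ProteinRecord, SpanAnnotation
from .state_space import StateSpace


def sample_nonoverlapping(
    annotations: list[SpanAnnotation], rng: np.random.Generator
) -> list[SpanAnnotation]:
    """Draw a maximal conflict-free subset of span annotations.

    The annotation order is shuffled uniformly and each annotation is
    greedily accepted unless it overlaps an already accepted one, so
    annotations that overlap nothing are always retained, and each member
    of a conflicting pair wins about half the time. The result is sorted
    by start coordinate.
    """
    if not annotations:
        return []
    order = rng.permutation(len(annotations))
    accepted: list[SpanAnnotation] = []
    for i in order:
        cand = annotations[i]
        if all(cand.end < a.start or cand.start > a.end for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda a: (a.start, a.end))


def labels_from_spans(
    record: ProteinRecord,
    space: StateSpace,
    rng: np.random.Generator | None = None,
    resample_overlapping: bool = True,
) -> np.ndarray:
    """Build the state-label path for one record.

    Positions inside a class-c span of length L get states (c,1)..(c,L) in
    order; everything else is the background state. Spans must already
    satisfy the length bounds (the data-preparation filters guarantee
    this) and, after overlap resolution, must not touch a span of another
    class directly, or the path would violate the transition mask.
    """
    anns = record.annotations_of_class(*space.span_classes)
    if resample_overlapping:
        if rng is None:
            rng = np.random.default_rng(0)
        anns = sample_nonoverlapping(anns, rng)
    else:
        anns = sorted(anns, key=lambda a: (a.start, a.end))

    T = len(record.sequence)
    labels = np.zeros(T, dtype=np.int64)
    prev: SpanAnnotation | None = None
    for ann in anns:
        if not (space.min_len <= ann.length <= space.max_len):
            raise ValueError(
                f"record {record.id}: span ({ann.start}, {ann.end}) has length "
                f"{ann.length} outside [{space.min_len}, {space.max_len}]"
            )
        if prev is not None and ann.start <= prev.end:
            raise ValueError(
                f"record {record.id}: overlapping spans after resolution"
            )
        if (
            prev is not None
            and ann.start == prev.end + 1
            and ann.span_class != prev.span_class
        ):
            raise ValueError(
                f"record {record.id}: adjacent spans of different classes "
                f"({prev.span_class} then {ann.span_class}) form an invalid path"
            )
        start0, end0 = ann.to_internal()
        first = space.state_index(ann.span_class, 1)
        labels[start0:end0] = np.arange(first, first + ann.length)
        prev = ann
    return labels


def epoch_labels(
    record: ProteinRecord,
    space: StateSpace,
    epoch: int,
    seed: int,
    resample_overlapping: bool = True,
) -> np.ndarray:
    """Labels for one training epoch, reproducibly seeded per (epoch, id)."""
    digest = hashlib.sha256(record.id.encode()).digest()
    rec_hash = int.from_bytes(digest[:4], "little")
    rng = np.random.default_rng((seed, epoch, rec_hash))
    return labels_from_spans(record, space, rng, resample_overlapping)
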