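"""Dataset curation: annotation filters, flanking-motif clustering, folds.

The filters reproduce the training-data selection rules: span lengths
restricted to 5-50 residues, precursors whose peptide covers the whole
mature protein discarded, and propeptides that are really sorting signals
(PROSITE ProRules PRU00477/PRU01070) removed. Cleavage-site flanking
motifs (two residues on each side of a span) are embedded, k-means
clustered (k = 50 by default) and the clusters used to stratify the
5-fold cross-validation split so that motif families spread evenly over
folds. True homology partitioning is delegated to external tools via a
partition-file hook; the cluster-stratified random assigner is the
self-contained fallback.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.cluster import KMeans

from .seqio import ProteinRecord, SpanAnnotation

logger = logging.getLogger(__name__)

SPAN_MODEL_CLASSES = ("Peptide", "Propeptide")
SORTING_CLASSES = ("Signal", "Transit")

#: ProRule evidence tags marking propeptides that are sorting signals.
PRORULE_SORTING_SIGNALS = frozenset({"PRU00477", "PRU01070"})

#: Token standing in for positions beyond the sequence termini in flanks.
BOUNDARY_TOKEN = "*"


@dataclass(frozen=True)
class MotifDescriptor:
    """Flanking motif of one peptide: 2 residues each side of the span."""

    record_id: str
    start: int  # 1-based inclusive
    end: int
    span_class: str
    n_flank: str
    c_flank: str

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.n_flank) + tuple(self.c_flank)


@dataclass
class FoldAssignment:
    fold_of_record: dict[str, int]
    cluster_of_record: dict[str, int]
    k_folds: int

    def records_in_fold(self, fold: int) -> list[str]:
        return sorted(r for r, f in self.fold_of_record.items() if f == fold)


# ---------------------------------------------------------------------------
# Filters (pure: inputs are deep-copied, never mutated)
# ---------------------------------------------------------------------------


def filter_length(
    records: Sequence[ProteinRecord], min_len: int = 5, max_len: int = 50
) -> list[ProteinRecord]:
    """Drop out-of-range Peptide/Propeptide spans, then annotation-less records.

    Sorting-signal annotations (Signal/Transit/Chain) are untouched; a record
    survives only if at least one in-range peptide/propeptide remains.
    """
    out = []
    for rec in records:
        rec = copy.deepcopy(rec)
        kept = [
            a
            for a in rec.annotations
            if a.span_class not in SPAN_MODEL_CLASSES or min_len <= a.length <= max_len
        ]
        rec.annotations = kept
        if rec.annotations_of_class(*SPAN_MODEL_CLASSES):
            out.append(rec)
    return out


def mature_protein_start(record: ProteinRecord) -> int:
    """1-based start of the mature protein: after a Signal/Transit at pos 1."""
    for ann in record.annotations_of_class(*SORTING_CLASSES):
        if ann.start == 1:
            return ann.end + 1
    return 1


def filter_full_coverage(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Discard precursors whose peptide covers the entire mature protein.

    Such "peptides" are not proteolytically released products. A record is
    dropped if any Peptide span covers [1, T], or covers [s+1, T] where a
    Signal/Transit annotation occupies [1, s].
    """
    out = []
    for rec in records:
        T = len(rec.sequence)
        mature = mature_protein_start(rec)
        full = any(
            a.end == T and a.start in (1, mature)
            for a in rec.annotations_of_class("Peptide")
        )
        if not full:
            out.append(copy.deepcopy(rec))
    return out


def filter_prorule_propeptides(
    records: Sequence[ProteinRecord],
    excluded_evidence_tags: frozenset[str] = PRORULE_SORTING_SIGNALS,
) -> list[ProteinRecord]:
    """Remove Propeptide annotations whose evidence marks a sorting signal."""
    out = []
    for rec in records:
        rec = copy.deepcopy(rec)
        rec.annotations = [
            a
            for a in rec.annotations
            if not (
                a.span_class == "Propeptide" and a.evidence in excluded_evidence_tags
            )
        ]
        out.append(rec)
    return out


def prepare_dataset(
    records: Sequence[ProteinRecord], min_len: int = 5, max_len: int = 50
) -> list[ProteinRecord]:
    """Full filter pipeline; the length filter runs last (it enforces the
    at-least-one-annotation rule)."""
    records = filter_prorule_propeptides(records)
    records = filter_full_coverage(records)
    return filter_length(records, min_len, max_len)


# ---------------------------------------------------------------------------
# Flanking motifs and clustering
# ---------------------------------------------------------------------------


def extract_flanking_motifs(
    records: Sequence[ProteinRecord], n: int = 2
) -> list[MotifDescriptor]:
    """The n residues before each span's N terminus and after its C terminus.

    Flanks that would extend past the sequence ends are padded with the
    boundary token '*'.
    """
    motifs = []
    for rec in records:
        seq = rec.sequence
        for ann in rec.annotations_of_class(*SPAN_MODEL_CLASSES):
            start0, end0 = ann.to_internal()
            n_flank = seq[max(0, start0 - n) : start0].rjust(n, BOUNDARY_TOKEN)
            c_flank = seq[end0 : end0 + n].ljust(n, BOUNDARY_TOKEN)
            motifs.append(
                MotifDescriptor(
                    rec.id, ann.start, ann.end, ann.span_class, n_flank, c_flank
                )
            )
    return motifs


def blosum62_embedding_table() -> dict[str, np.ndarray]:
    """Per-residue vectors from BLOSUM62 substitution-score rows.

    Each token (20 standard AAs, ambiguity codes and the boundary token
    '*') is represented by its vector of similarity scores against the
    matrix alphabet, giving a biochemistry-aware embedding that needs no
    learned model. Any table mapping tokens to fixed-width vectors can be
    supplied instead.
    """
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = list(mat.alphabet)
    return {aa: np.array([mat[aa, b] for b in alphabet], dtype=float) for aa in alphabet}


def embed_motifs(
    motifs: Sequence[MotifDescriptor],
    aa_embedding_table: Optional[Mapping[str, np.ndarray]] = None,
) -> np.ndarray:
    """Concatenate the four flank-residue embeddings per motif (n = 2)."""
    table = dict(aa_embedding_table) if aa_embedding_table else blosum62_embedding_table()
    fallback = table.get("X", next(iter(table.values())) * 0.0)
    rows = []
    for m in motifs:
        rows.append(np.concatenate([table.get(tok, fallback) for tok in m.tokens]))
    return np.asarray(rows)


def embed_and_cluster_motifs(
    motifs: Sequence[MotifDescriptor],
    aa_embedding_table: Optional[Mapping[str, np.ndarray]] = None,
    k: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """k-means (k-means++ init, 10 restarts, tol 1e-4) over motif embeddings.

    Returns one cluster label in 0..k-1 per motif. If fewer distinct motifs
    than k exist, k is reduced with a warning.
    """
    if not motifs:
        return np.zeros(0, dtype=int)
    X = embed_motifs(motifs, aa_embedding_table)
    n_distinct = len({tuple(row) for row in X})
    if n_distinct < k:
        logger.warning(
            "only %d distinct motifs for k=%d; reducing k to %d", n_distinct, k, n_distinct
        )
        k = n_distinct
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-4, random_state=seed)
    return km.fit_predict(X)


def majority_cluster_per_record(
    motifs: Sequence[MotifDescriptor], clusters: np.ndarray
) -> dict[str, int]:
    """Tag each record with the most common cluster among its peptides."""
    per_record: dict[str, list[int]] = {}
    for m, c in zip(motifs, clusters):
        per_record.setdefault(m.record_id, []).append(int(c))
    out = {}
    for rid, cs in per_record.items():
        vals, counts = np.unique(cs, return_counts=True)
        out[rid] = int(vals[np.argmax(counts)])  # ties -> lowest cluster id
    return out


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------


def assign_folds_stratified(
    records: Sequence[ProteinRecord],
    cluster_per_record: Mapping[str, int],
    k_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Cluster-stratified random fold assignment.

    Within each cluster, records are shuffled and dealt round-robin over
    folds (per-cluster fold counts differ by at most one), so motif
    families spread evenly and fold sizes differ by at most the number of
    clusters. This is the no-dependency fallback for external
    homology-partitioning tools.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for rec in records:
        c = int(cluster_per_record.get(rec.id, -1))
        by_cluster.setdefault(c, []).append(rec.id)
    fold_of_record: dict[str, int] = {}
    next_fold = 0
    for c in sorted(by_cluster):
        ids = by_cluster[c]
        order = rng.permutation(len(ids))
        for j, idx in enumerate(order):
            fold_of_record[ids[idx]] = (next_fold + j) % k_folds
        next_fold = (next_fold + len(ids)) % k_folds
    return FoldAssignment(fold_of_record, dict(cluster_per_record), k_folds)


def read_partition_file(path: str | Path) -> dict[str, int]:
    """Read an externally produced record-id -> fold TSV (homology hook)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue
            out[fields[0]] = int(fields[1])
    return out


def write_cluster_assignments(
    motifs: Sequence[MotifDescriptor], clusters: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tclass\tn_flank\tc_flank\tcluster\n")
        for m, c in zip(motifs, clusters):
            fh.write(
                f"{m.record_id}\t{m.start}\t{m.end}\t{m.span_class}\t"
                f"{m.n_flank}\t{m.c_flank}\t{int(c)}\n"
            )


def nested_cv_splits(
    assignment: FoldAssignment,
) -> list[tuple[int, int, list[str], list[str], list[str]]]:
    """Enumerate the nested cross-validation model splits.

    For k outer folds, each outer test fold pairs with each of the k-1
    remaining folds as inner validation, the rest training: k x (k-1)
    models (20 for the standard 5-fold setup). Returns tuples
    (test_fold, val_fold, train_ids, val_ids, test_ids).
    """
    k = assignment.k_folds
    splits = []
    for test_fold in range(k):
        for val_fold in range(k):
            if val_fold == test_fold:
                continue
            train_ids, val_ids, test_ids = [], [], []
            for rid, fold in sorted(assignment.fold_of_record.items()):
                if fold == test_fold:
                    test_ids.append(rid)
                elif fold == val_fold:
                    val_ids.append(rid)
                else:
                    train_ids.append(rid)
            splits.append((test_fold, val_fold, train_ids, val_ids, test_ids))
    return splits
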