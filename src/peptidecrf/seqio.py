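"""Sequence/annotation data model and file I/O.

External files use 1-based inclusive span coordinates (UniProt convention).
All conversion to the 0-based half-open coordinates used internally happens
in this module, nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Span classes recognised in annotation tables. Peptide/Propeptide are the
#: classes the model predicts; Signal/Transit/Chain only inform data filters.
SPAN_CLASSES = ("Peptide", "Propeptide", "Signal", "Transit", "Chain")

PREDICTION_COLUMNS = ("id", "start", "end", "class")


@dataclass
class SpanAnnotation:
    """One annotated span, 1-based inclusive coordinates."""

    start: int
    end: int
    span_class: str
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid span coordinates ({self.start}, {self.end}): "
                "need 1 <= start <= end"
            )
        if self.span_class not in SPAN_CLASSES:
            raise ValueError(f"unknown span class {self.span_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_internal(self) -> tuple[int, int]:
        """0-based half-open (start, end)."""
        return self.start - 1, self.end

    @classmethod
    def from_internal(
        cls, start: int, end: int, span_class: str, evidence: Optional[str] = None
    ) -> "SpanAnnotation":
        return cls(start + 1, end, span_class, evidence)


@dataclass
class ProteinRecord:
    """A precursor protein sequence with its ground-truth span annotations."""

    id: str
    sequence: str
    annotations: list[SpanAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: sequence must be non-empty")

    def annotations_of_class(self, *classes: str) -> list[SpanAnnotation]:
        return [a for a in self.annotations if a.span_class in classes]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records with empty annotation lists.

    The header token before the first whitespace becomes the id; sequences
    are uppercased. Duplicate ids and non-FASTA leading content are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(ProteinRecord(id=rid, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_annotations(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach spans from a TSV (id, start, end, class[, evidence]) to records.

    Rows with invalid coordinates are rejected with a warning; rows naming
    unknown ids are reported as orphans. Returns the input records.
    """
    by_id = {rec.id: rec for rec in records}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["id", "start"]:
                continue  # optional header
            if len(fields) < 4:
                logger.warning("%s: line %d: expected >=4 columns, skipped", path, lineno)
                continue
            rid, start_s, end_s, span_class = fields[:4]
            evidence = fields[4] if len(fields) > 4 and fields[4] else None
            rec = by_id.get(rid)
            if rec is None:
                logger.warning("%s: line %d: orphan row for unknown id %r", path, lineno, rid)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s: line %d: non-integer coordinates, rejected", path, lineno)
                continue
            if start > end or start < 1:
                logger.warning(
                    "%s: line %d: invalid span (%d, %d), rejected", path, lineno, start, end
                )
                continue
            if end > len(rec.sequence):
                logger.warning(
                    "%s: line %d: span (%d, %d) outside sequence %s (length %d), rejected",
                    path, lineno, start, end, rid, len(rec.sequence),
                )
                continue
            rec.annotations.append(SpanAnnotation(start, end, span_class, evidence))
    return list(records)


def write_annotations(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tclass\tevidence\n")
        for rec in records:
            for ann in rec.annotations:
                fh.write(
                    f"{rec.id}\t{ann.start}\t{ann.end}\t{ann.span_class}\t"
                    f"{ann.evidence or ''}\n"
                )


def write_predictions(
    records: Sequence[ProteinRecord],
    spans_per_record: Sequence[Sequence[tuple[int, int, str]]],
    path: str | Path,
    marginals_per_record: Optional[Sequence] = None,
    marginals_path: Optional[str | Path] = None,
) -> None:
    """Write decoded spans as a TSV; optionally dump per-position marginals.

    ``spans_per_record`` holds internal 0-based half-open (start, end, class)
    triples; they are converted to 1-based inclusive here. The marginals file
    carries one row per position with the (None, Peptide, Propeptide) class
    posteriors rounded to 4 decimals.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rec, spans in zip(records, spans_per_record):
            for start, end, cls in spans:
                fh.write(f"{rec.id}\t{start + 1}\t{end}\t{cls}\n")
    if marginals_per_record is not None:
        mpath = Path(marginals_path) if marginals_path else Path(str(path) + ".marginals.tsv")
        with open(mpath, "w") as fh:
            fh.write("id\tposition\tp_none\tp_peptide\tp_propeptide\n")
            for rec, prof in zip(records, marginals_per_record):
                post = prof.class_posteriors if hasattr(prof, "class_posteriors") else prof
                for t, row in enumerate(post, start=1):
                    vals = "\t".join(f"{v:.4f}" for v in row)
                    fh.write(f"{rec.id}\t{t}\t{vals}\n")


def read_predictions(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read a prediction TSV back as 1-based inclusive spans keyed by id."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "id":
                continue
            rid, start, end, cls = fields[:4]
            out.setdefault(rid, []).append((int(start), int(end), cls))
    return out
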