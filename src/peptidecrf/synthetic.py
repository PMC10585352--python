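"""Synthetic precursor proteomes with planted, motif-flanked spans.

Each generated record is a background amino-acid sequence carrying 0-4
non-overlapping peptide/propeptide spans of bounded length. The residues
immediately flanking each span are overwritten with a class-specific
cleavage motif (dibasic-site style for peptides) with configurable
fidelity, emulating the idea that flanking motifs are the main learnable
cleavage signal. With fidelity 1 the span boundaries are fully determined
by local sequence context; with fidelity 0 the data carry no signal at
all, which bounds what any model can learn from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord, SpanAnnotation

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Approximate natural amino-acid frequencies (vertebrate proteome averages),
#: selectable instead of the uniform default background.
NATURAL_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_records: int = 400
    length_range: tuple[int, int] = (100, 160)
    #: probability of 0..4 spans per record
    spans_per_record_probs: tuple[float, ...] = (0.10, 0.30, 0.30, 0.20, 0.10)
    span_length_range: tuple[int, int] = (5, 30)
    #: probability a span is a Peptide (else Propeptide)
    class_ratio: float = 0.5
    #: flanking motifs planted outside each span: (before-N, after-C)
    peptide_motifs: tuple[str, str] = ("KR", "RR")
    propeptide_motifs: tuple[str, str] = ("GG", "LL")
    #: per-residue probability that a motif residue is planted
    motif_fidelity: float = 1.0
    #: None -> uniform over the 20 standard AAs
    background_composition: Optional[dict[str, float]] = None
    #: minimum residues between spans; >= flank width keeps motifs collision-free
    min_gap: int = 4
    seed: int = 0
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_fidelity <= 1.0:
            raise ValueError("motif_fidelity must lie in [0, 1]")
        if abs(sum(self.spans_per_record_probs) - 1.0) > 1e-9:
            raise ValueError("spans_per_record_probs must sum to 1")
        lo, hi = self.span_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid span_length_range")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1 so flank motifs have room")


def _place_spans(
    L: int, lengths: Sequence[int], min_gap: int, rng: np.random.Generator
) -> Optional[list[tuple[int, int]]]:
    """Uniformly place non-overlapping spans with the required gap.

    Spans are kept min_gap residues from the sequence ends too, so flank
    motifs always fit inside the sequence. Returns 0-based half-open
    intervals in left-to-right order, or None if they cannot fit.
    """
    n = len(lengths)
    if n == 0:
        return []
    occupied = sum(lengths) + min_gap * (n + 1)
    slack = L - occupied
    if slack < 0:
        return None
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    spans = []
    cursor = min_gap
    for i, length in enumerate(lengths):
        start = cursor + int(cuts[i]) - (int(cuts[i - 1]) if i else 0)
        spans.append((start, start + length))
        cursor = start + length + min_gap
    return spans


def generate_record(
    config: SyntheticConfig, index: int, rng: np.random.Generator
) -> ProteinRecord:
    aas = np.array(AMINO_ACIDS)
    if config.background_composition:
        probs = np.array([config.background_composition.get(a, 0.0) for a in AMINO_ACIDS])
        probs = probs / probs.sum()
    else:
        probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    seq = rng.choice(aas, size=L, p=probs)

    spans: Optional[list[tuple[int, int]]] = None
    for _ in range(100):
        n_spans = int(rng.choice(len(config.spans_per_record_probs), p=config.spans_per_record_probs))
        lo, hi = config.span_length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_spans)]
        spans = _place_spans(L, lengths, config.min_gap, rng)
        if spans is not None:
            break
    if spans is None:
        raise RuntimeError(
            f"could not place spans in a length-{L} sequence after bounded retries; "
            "config is infeasible"
        )

    annotations = []
    for start0, end0 in spans:
        is_peptide = rng.random() < config.class_ratio
        cls = "Peptide" if is_peptide else "Propeptide"
        n_motif, c_motif = config.peptide_motifs if is_peptide else config.propeptide_motifs
        for j, aa in enumerate(n_motif):
            pos = start0 - len(n_motif) + j
            if 0 <= pos < L and rng.random() < config.motif_fidelity:
                seq[pos] = aa
        for j, aa in enumerate(c_motif):
            pos = end0 + j
            if 0 <= pos < L and rng.random() < config.motif_fidelity:
                seq[pos] = aa
        annotations.append(SpanAnnotation.from_internal(start0, end0, cls))

    return ProteinRecord(
        id=f"{config.id_prefix}{index:05d}",
        sequence="".join(seq),
        annotations=annotations,
    )


def generate_dataset(config: SyntheticConfig) -> list[ProteinRecord]:
    """Generate the full synthetic dataset; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    return [generate_record(config, i, rng) for i in range(config.n_records)]


def dataset_summary(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Counts of records, peptides, propeptides, mean annotations per record."""
    n_pep = sum(len(r.annotations_of_class("Peptide")) for r in records)
    n_pro = sum(len(r.annotations_of_class("Propeptide")) for r in records)
    n_rec = len(records)
    mean = round((n_pep + n_pro) / n_rec, 2) if n_rec else 0.0
    return pd.DataFrame(
        [
            {
                "proteins": n_rec,
                "peptides": n_pep,
                "propeptides": n_pro,
                "mean_annotations_per_protein": mean,
                "empty_dataset": n_rec == 0,
            }
        ]
    )
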