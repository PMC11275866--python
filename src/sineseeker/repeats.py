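"""Repeat-library classification by pairwise global alignment.

A candidate inserted sequence is aligned against every consensus in a repeat
library and the full pairwise percent-identity matrix is reported, with the
best-scoring library entry as the classification.  Alignment is
Needleman-Wunsch with affine gap costs; end gaps are free on both sequences
(semi-global) and terminal-gap columns are excluded from the identity
denominator, so a full-length element embedded in a longer sequence scores
its true identity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

_ALPHABET = set("ACGTN")


@dataclasses.dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: a gap of length k costs gap_open + k * gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclasses.dataclass
class RepeatLibrary:
    """Named nucleotide consensuses; names unique, sequences non-empty."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("repeat library is empty")
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty consensus for {name}")
            _check_alphabet(seq, name)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RepeatLibrary":
        entries = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(path), "fasta")}
        return cls(entries=entries)

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.entries.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        return path


@dataclasses.dataclass
class AlignmentResult:
    score: float
    identity_pct: float
    aligned_a: str
    aligned_b: str


@dataclasses.dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over {query} + library entries."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def identity(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")
        return path


@dataclasses.dataclass(frozen=True)
class BestHit:
    name: str
    identity_pct: float
    ties: tuple[str, ...] = ()


def _check_alphabet(seq: str, label: str = "sequence") -> None:
    bad = set(seq.upper()) - _ALPHABET
    if bad:
        raise ValueError(f"{label} contains non-nucleotide characters: {sorted(bad)}")


def _make_aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges the open score on the first gap base; our convention
    # is open + extend per additional base, so the first base costs both.
    settings = {
        "open_internal_gap_score": scoring.gap_open + scoring.gap_extend,
        "extend_internal_gap_score": scoring.gap_extend,
        "open_end_gap_score": 0.0,
        "extend_end_gap_score": 0.0,
    }
    legacy = {
        "open_internal_gap_score": "internal_open_gap_score",
        "extend_internal_gap_score": "internal_extend_gap_score",
        "open_end_gap_score": "end_open_gap_score",
        "extend_end_gap_score": "end_extend_gap_score",
    }
    for name, value in settings.items():
        if hasattr(aligner, name):
            setattr(aligner, name, value)
        else:
            setattr(aligner, legacy[name], value)
    return aligner


def global_align(seq_a: str, seq_b: str,
                 scoring: AlignmentScoring = AlignmentScoring()) -> AlignmentResult:
    """Align two sequences and report percent identity.

    Percent identity = 100 x matched columns / aligned columns, with
    terminal-gap columns excluded from the denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _check_alphabet(seq_a, "seq_a")
    _check_alphabet(seq_b, "seq_b")
    aligner = _make_aligner(scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    identity = _identity_excluding_terminal_gaps(gapped_a, gapped_b)
    return AlignmentResult(score=float(alignment.score), identity_pct=identity,
                           aligned_a=gapped_a, aligned_b=gapped_b)


def _identity_excluding_terminal_gaps(a: str, b: str) -> float:
    first_a = len(a) - len(a.lstrip("-"))
    first_b = len(b) - len(b.lstrip("-"))
    last_a = len(a.rstrip("-")) - 1
    last_b = len(b.rstrip("-")) - 1
    lo = max(first_a, first_b)
    hi = min(last_a, last_b)
    if hi < lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi + 1) if a[i] == b[i] and a[i] != "-")
    return 100.0 * matches / (hi - lo + 1)


def identity_matrix(query_seq: str, library: RepeatLibrary,
                    query_name: str = "query",
                    scoring: AlignmentScoring = AlignmentScoring(),
                    ) -> tuple[IdentityMatrix, BestHit]:
    """All pairwise identities among {query} + library; best hit to the query.

    Ties on identity are broken lexicographically by entry name and reported
    in ``BestHit.ties``.
    """
    labels = [query_name] + sorted(library.entries)
    seqs = [query_seq] + [library.entries[n] for n in labels[1:]]
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(seqs[i], seqs[j], scoring).identity_pct
            values[i, j] = values[j, i] = ident
    query_row = values[0, 1:]
    best_identity = float(query_row.max())
    tied = [labels[1 + k] for k in np.flatnonzero(
        np.isclose(query_row, best_identity, atol=1e-9))]
    best = BestHit(name=sorted(tied)[0], identity_pct=best_identity,
                   ties=tuple(sorted(tied)) if len(tied) > 1 else ())
    return IdentityMatrix(labels=labels, values=values), best
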