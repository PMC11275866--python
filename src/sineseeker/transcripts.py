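"""Transcript models: genomic exon structure, CDS coordinates, isoforms.

A gene carries one or more isoforms; each isoform is an ordered list of
genomic exons with a CDS interval and a strand.  An exon flagged
``alternatively_spliced`` is present in some isoforms and skipped in others
(the 'long' vs 'short' isoform pattern); the CDS length of every isoform must
be divisible by three.

Models round-trip through a small JSON schema (see :meth:`TranscriptModel.to_json`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


class CoordinateError(ValueError):
    """A genomic position that has no CDS coordinate in an isoform.

    ``category`` is one of ``intronic``, ``utr``, ``not_in_isoform``.
    """

    def __init__(self, category: str, message: str):
        super().__init__(message)
        self.category = category


@dataclasses.dataclass(frozen=True)
class Exon:
    """Genomic 1-based inclusive interval."""

    start: int
    end: int
    alternatively_spliced: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("exon start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class Isoform:
    """Ordered exon list with CDS bounds; exons ascend genomically."""

    isoform_id: str
    exons: list[Exon]
    strand: str
    cds_start: int  # genomic, 1-based, lower coordinate of the CDS span
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end:
                raise ValueError("exons overlap or are unsorted")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.isoform_id} "
                "not divisible by 3")

    def coding_segments(self) -> list[tuple[int, int]]:
        """Genomic CDS pieces in transcript (5'->3') order."""
        pieces = []
        for exon in self.exons:
            lo = max(exon.start, self.cds_start)
            hi = min(exon.end, self.cds_end)
            if lo <= hi:
                pieces.append((lo, hi))
        if self.strand == "-":
            pieces = pieces[::-1]
        return pieces

    @property
    def cds_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.coding_segments())

    def contains_in_cds(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.coding_segments())

    def exon_of(self, pos: int) -> Exon | None:
        for exon in self.exons:
            if exon.start <= pos <= exon.end:
                return exon
        return None

    def cds_sequence(self, contig_seq: str) -> str:
        """Extract the coding sequence (coding strand) from a contig string."""
        parts = []
        for lo, hi in (self.coding_segments() if self.strand == "+"
                       else self.coding_segments()[::-1]):
            parts.append(contig_seq[lo - 1:hi])
        seq = "".join(parts)
        if self.strand == "-":
            seq = _revcomp(seq)
        return seq


@dataclasses.dataclass
class TranscriptModel:
    gene_id: str
    accession: str
    chrom: str
    isoforms: list[Isoform]

    @property
    def span(self) -> tuple[int, int]:
        starts = [iso.exons[0].start for iso in self.isoforms]
        ends = [iso.exons[-1].end for iso in self.isoforms]
        return min(starts), max(ends)

    def isoform(self, isoform_id: str) -> Isoform:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(isoform_id)

    # -- JSON schema: {gene_id, accession, chrom, isoforms: [{isoform_id,
    #    strand, cds_start, cds_end, exons: [{start, end, alternatively_spliced}]}]}
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gene_id": self.gene_id,
            "accession": self.accession,
            "chrom": self.chrom,
            "isoforms": [
                {
                    "isoform_id": iso.isoform_id,
                    "strand": iso.strand,
                    "cds_start": iso.cds_start,
                    "cds_end": iso.cds_end,
                    "exons": [dataclasses.asdict(e) for e in iso.exons],
                }
                for iso in self.isoforms
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TranscriptModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        isoforms = [
            Isoform(
                isoform_id=iso["isoform_id"],
                strand=iso["strand"],
                cds_start=iso["cds_start"],
                cds_end=iso["cds_end"],
                exons=[Exon(**e) for e in iso["exons"]],
            )
            for iso in payload["isoforms"]
        ]
        return cls(gene_id=payload["gene_id"], accession=payload["accession"],
                   chrom=payload["chrom"], isoforms=isoforms)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
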