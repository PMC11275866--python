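"""Protein-level consequence of an insertion within a transcript model.

The model: splice the inserted bases into the coding sequence at the mapped
CDS position, translate from the first altered codon, and count aberrant
residues until the first stop.  For an insertion inside an alternatively
spliced exon only the isoforms containing that exon are affected; the others
are reported unaffected — the mechanism by which a 'long' isoform can be
truncated while the 'short' isoform escapes.

Bookkeeping conventions:

- ``protein_start_position`` is the codon index of the first codon containing
  (or shifted by) inserted bases.
- ``aberrant_aa_count`` counts every residue from that codon up to, and
  excluding, the first stop of the mutant frame; a residue inside this window
  that coincidentally matches wild type is still part of the disrupted tract.
- ``wildtype_tail_aa`` is the number of wild-type residues from the same
  codon through the end of the exon carrying the insertion, so
  ``exon_extension_aa = aberrant_aa_count - wildtype_tail_aa`` is how far the
  mutant reading extends past the wild-type exon end.
"""

from __future__ import annotations

import dataclasses
import warnings

from Bio.Seq import Seq

from sineseeker.transcripts import (
    CoordinateError,
    Isoform,
    TranscriptModel,
    _revcomp,
)


@dataclasses.dataclass
class InsertionConsequence:
    isoform_id: str
    affected: bool
    cds_insertion_position: int | None = None  # 1-based first inserted base
    protein_start_position: int | None = None
    in_frame: bool | None = None
    aberrant_aa_count: int | None = None
    stop_protein_position: int | None = None
    stop_lost: bool = False
    wildtype_tail_aa: int | None = None
    exon_extension_aa: int | None = None

    def __post_init__(self) -> None:
        if (self.stop_protein_position is not None
                and self.aberrant_aa_count is not None):
            expected = self.protein_start_position + self.aberrant_aa_count
            if self.stop_protein_position != expected:
                raise ValueError(
                    "stop position inconsistent with aberrant residue count")


# ----------------------------------------------------------------------
def map_genomic_to_cds(model: TranscriptModel, isoform_id: str,
                       pos: int) -> tuple[int, int]:
    """Map a genomic position to (cds position, codon index) in an isoform.

    Raises :class:`CoordinateError` with category ``not_in_isoform``,
    ``intronic`` or ``utr`` when the position carries no CDS coordinate.
    """
    iso = model.isoform(isoform_id)
    offset = 0
    for lo, hi in iso.coding_segments():
        if lo <= pos <= hi:
            within = (pos - lo) if iso.strand == "+" else (hi - pos)
            cds_pos = offset + within + 1
            return cds_pos, (cds_pos + 2) // 3
        offset += hi - lo + 1
    exon = iso.exon_of(pos)
    if exon is None:
        span = (iso.exons[0].start, iso.exons[-1].end)
        if span[0] <= pos <= span[1]:
            raise CoordinateError(
                "intronic", f"position {pos} is intronic in {isoform_id}")
        raise CoordinateError(
            "not_in_isoform", f"position {pos} is outside isoform {isoform_id}")
    raise CoordinateError("utr", f"position {pos} is UTR in {isoform_id}")


def cds_to_genomic(model: TranscriptModel, isoform_id: str, cds_pos: int) -> int:
    """Inverse of :func:`map_genomic_to_cds`."""
    iso = model.isoform(isoform_id)
    offset = 0
    for lo, hi in iso.coding_segments():
        seg_len = hi - lo + 1
        if cds_pos <= offset + seg_len:
            within = cds_pos - offset - 1
            return lo + within if iso.strand == "+" else hi - within
        offset += seg_len
    raise CoordinateError("not_in_isoform",
                          f"cds position {cds_pos} beyond CDS of {isoform_id}")


# ----------------------------------------------------------------------
def _translate(seq: str) -> str:
    # trim to full codons; partial terminal codon carries no residue
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def predict_insertion_consequence(
    model: TranscriptModel,
    contig_seq: str,
    insertion_site: int,
    inserted_seq: str,
) -> list[InsertionConsequence]:
    """Predict the consequence of inserting ``inserted_seq`` immediately
    before the base at genomic position ``insertion_site``.

    ``inserted_seq`` is given on the forward genomic strand; for minus-strand
    isoforms it is reverse-complemented into the coding frame.  One
    :class:`InsertionConsequence` is returned per isoform; isoforms whose CDS
    does not contain the site are reported ``affected=False``.
    """
    inserted_seq = inserted_seq.upper()
    if set(inserted_seq) - set("ACGT"):
        raise ValueError("inserted sequence must be ACGT")
    span = model.span
    if not (span[0] <= insertion_site <= span[1] + 1):
        raise ValueError(f"insertion site {insertion_site} outside gene span {span}")

    results = []
    for iso in model.isoforms:
        if not iso.contains_in_cds(insertion_site):
            results.append(InsertionConsequence(iso.isoform_id, affected=False))
            continue
        results.append(_consequence_for_isoform(model, iso, contig_seq,
                                                insertion_site, inserted_seq))
    return results


def _consequence_for_isoform(model: TranscriptModel, iso: Isoform,
                             contig_seq: str, site: int,
                             inserted_seq: str) -> InsertionConsequence:
    wt_cds = iso.cds_sequence(contig_seq)
    c_site, _ = map_genomic_to_cds(model, iso.isoform_id, site)
    if iso.strand == "+":
        offset = c_site - 1          # coding bases before the insert
        coding_insert = inserted_seq
    else:
        # genomic gap (site-1, site) lies after transcript position c(site)
        offset = c_site
        coding_insert = _revcomp(inserted_seq)
    mutant = wt_cds[:offset] + coding_insert + wt_cds[offset:]

    first_codon = offset // 3 + 1    # first codon containing inserted bases
    mutant_tail = _translate(mutant[(first_codon - 1) * 3:])
    stop_offset = mutant_tail.find("*")
    stop_lost = stop_offset < 0
    aberrant = len(mutant_tail) if stop_lost else stop_offset
    stop_position = None if stop_lost else first_codon + aberrant
    if stop_lost:
        warnings.warn(
            f"{iso.isoform_id}: no stop reached before CDS end (stop-loss-like)",
            stacklevel=2)

    # wild-type residues from the first altered codon to the end of the exon
    # carrying the insertion
    exon = iso.exon_of(site) or iso.exon_of(site - 1)
    exon_last_coding = None
    if exon is not None:
        lo = max(exon.start, iso.cds_start)
        hi = min(exon.end, iso.cds_end)
        boundary = hi if iso.strand == "+" else lo
        exon_last_coding, _ = map_genomic_to_cds(model, iso.isoform_id, boundary)
    if exon_last_coding is not None:
        tail = max(0, exon_last_coding // 3 - first_codon + 1)
    else:
        tail = 0
    return InsertionConsequence(
        isoform_id=iso.isoform_id,
        affected=True,
        cds_insertion_position=offset + 1,
        protein_start_position=first_codon,
        in_frame=len(inserted_seq) % 3 == 0,
        aberrant_aa_count=aberrant,
        stop_protein_position=stop_position,
        stop_lost=stop_lost,
        wildtype_tail_aa=tail,
        exon_extension_aa=aberrant - tail,
    )


# ----------------------------------------------------------------------
def name_variant(accession: str, cds_position: int,
                 insert_length: int | None,
                 protein_start: int | None = None) -> str:
    """Render the designation string, e.g. ``ACC c.123_ins210 (p.41)``.

    An unknown insert length (partial consensus) renders as ``ins?`` with a
    warning.
    """
    if insert_length is None:
        warnings.warn("insert length unknown; rendering 'ins?'", stacklevel=2)
        length = "?"
    else:
        length = str(insert_length)
    name = f"{accession} c.{cds_position}_ins{length}"
    if protein_start is not None:
        name += f" (p.{protein_start})"
    return name
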