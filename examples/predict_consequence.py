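"""Predict the protein-level consequence of the exonic insertion.

Splices the inserted bases (element plus second TSD copy) into the coding
sequence, translates from the first altered codon, and reports the stop
position and exon extension — separately per isoform, since the target exon
is alternatively spliced.
"""

from sineseeker.consequence import name_variant, predict_insertion_consequence
from sineseeker.simulate import SimulationConfig, simulate_reference

reference = simulate_reference(SimulationConfig(seed=1))
model = reference.transcript_model

site = reference.bp_right + 1                      # insert before this base
inserted = reference.inserted_sequence + reference.tsd_sequence
results = predict_insertion_consequence(model, reference.contigs[model.chrom],
                                        site, inserted)

for r in results:
    if not r.affected:
        print(f"{r.isoform_id}: unaffected (exon spliced out)")
        continue
    print(f"{r.isoform_id}: insertion at c.{r.cds_insertion_position} "
          f"(codon {r.protein_start_position}), in frame: {r.in_frame}")
    print(f"  {r.aberrant_aa_count} aberrant residues, stop at "
          f"p.{r.stop_protein_position}")
    print(f"  wild-type exon tail {r.wildtype_tail_aa} aa -> exon extended "
          f"by {r.exon_extension_aa} aa")
    print("  designation:",
          name_variant(model.accession, r.cds_insertion_position,
                       len(reference.inserted_sequence),
                       r.protein_start_position))
long_aa = model.isoform("long").cds_length // 3 - 1
short_aa = model.isoform("short").cds_length // 3 - 1
print(f"isoforms: long {long_aa} aa, short {short_aa} aa "
      f"(difference = residues of the skipped exon)")
# Only the long isoform carries the target exon, so only it is truncated;
# the short isoform escapes — the isoform-specific disease mechanism.
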