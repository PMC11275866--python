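"""Generate a synthetic study cohort with a planted SINE insertion.

Builds the mini-reference (two-isoform gene, repeat library), the genotype
cohort sharing a homozygous-by-descent interval, paired-end alignments over
the insertion locus and an annotated variant table, then prints what was
planted.  The printed ground truth is the oracle every later stage should
recover.
"""

from sineseeker.simulate import (
    SimulationConfig,
    simulate_genotype_cohort,
    simulate_reads,
    simulate_reference,
    simulate_variant_table,
)

config = SimulationConfig(seed=1)
reference = simulate_reference(config)
matrix, truth = simulate_genotype_cohort(config, reference)
reads = simulate_reads(config, reference, truth)
variants, samples, panel = simulate_variant_table(config, reference, truth)

print(f"cohort: {len(matrix.cases)} cases + {len(matrix.controls)} controls, "
      f"{matrix.n_markers} markers on {len(matrix.chromosomes)} chromosomes")
print(f"planted shared ROH: {truth.chrom}:{truth.shared_roh[0]}-"
      f"{truth.shared_roh[1]} "
      f"({(truth.shared_roh[1] - truth.shared_roh[0] + 1) / 1e6:.1f} Mb)")
print(f"planted element: {len(truth.inserted_sequence)} bp from "
      f"{truth.source_repeat}, TSD {truth.tsd_sequence} "
      f"({len(truth.tsd_sequence)} bp) at {truth.chrom}:{truth.bp_left}")
print(f"planted recessive variant: {truth.planted_variant}")
n_reads = sum(len(r) for r in reads.records.values())
print(f"alignments: {n_reads} reads over window "
      f"{reads.window[0]}-{reads.window[1]}; "
      f"variant table: {len(variants)} records, "
      f"{len(panel.variants)} known-variant panel entries")
# The ROH is where homozygosity mapping should converge; the element and the
# variant are what the insertion caller and the recessive filter should find.
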