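"""Fragment-length assay genotyping and cohort segregation.

Designs an allele-specific assay over the insertion locus (wild-type and
element-anchored forward primers sharing a tailed reverse primer), predicts
the two diagnostic product sizes by in-silico PCR, genotypes the cohort from
simulated sized fragments, and scores segregation under a fully penetrant
recessive model.
"""

from sineseeker.assay import (
    genotype_from_fragments,
    insilico_pcr,
    segregation_report,
)
from sineseeker.simulate import (
    SimulationConfig,
    design_fragment_assay,
    simulate_fragment_observations,
    simulate_genotype_cohort,
    simulate_reference,
)

config = SimulationConfig(seed=1)
reference = simulate_reference(config)
matrix, truth = simulate_genotype_cohort(config, reference)

assay, templates = design_fragment_assay(reference)
products = insilico_pcr(templates, assay)
wt_len = products["wild_type"]["forward_wt"]
ins_len = products["insertion"]["forward_ins"]
print(f"predicted fragment sizes: wild-type {wt_len} bp, "
      f"element {ins_len} bp (16 bp fluorophore tail included)")

observed = simulate_fragment_observations(config, truth, wt_len, ins_len)
phenotype = {"case": "affected", "control": "clear"}
table = {
    sample: (phenotype[matrix.phenotypes[matrix.sample_index(sample)]],
             genotype_from_fragments(observed[sample], wt_len, ins_len))
    for sample in matrix.samples
}
report = segregation_report(table)
print("\ncontingency (phenotype x genotype):")
print(report.contingency)
print(f"\ndiscordant samples: {report.discordant or 'none'}")
print(f"insertion allele frequency: {report.allele_frequency:.3f}")
print(f"observed penetrance: {report.penetrance:.2f}")
# Zero discordant samples means every affected dog is homozygous for the
# element and no clear dog is — the fully penetrant recessive pattern.
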