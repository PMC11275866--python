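"""Homozygosity mapping: QC, ROH detection, intersection, het refinement.

Filters the marker set, scans each case for runs of homozygosity with the
PLINK-style sliding window, intersects the case runs, removes intervals any
control is homozygous across, and trims to the heterozygous anchor calls.
"""

from sineseeker.roh import (
    ROHParams,
    detect_roh,
    qc_filter,
    refine_by_het_calls,
    shared_critical_region,
)
from sineseeker.simulate import (
    SimulationConfig,
    simulate_genotype_cohort,
    simulate_reference,
)

config = SimulationConfig(seed=1)
reference = simulate_reference(config)
matrix, truth = simulate_genotype_cohort(config, reference)

filtered, qc = qc_filter(matrix)
print(f"QC: {qc.markers_removed_maf} markers below MAF {qc.maf_min}, "
      f"{qc.markers_removed_missing} above missingness {qc.missing_max}")

segments = detect_roh(filtered, ROHParams(), samples=filtered.cases)
for sample, segs in segments.items():
    for s in segs:
        print(f"{sample}: ROH {s.chrom}:{s.start}-{s.end} "
              f"({s.length_bp / 1e6:.2f} Mb, {s.n_markers} markers)")

regions = shared_critical_region(segments, filtered)
region = refine_by_het_calls(regions[0], filtered)
print(f"critical region: {region.chrom}:{region.start}-{region.end} "
      f"({region.length_bp / 1e6:.2f} Mb)")
print(f"contains planted insertion site: "
      f"{region.contains(truth.chrom, truth.insertion_site)}")
# Every case is homozygous across the region and no control is, so a fully
# penetrant recessive variant must lie inside it.
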