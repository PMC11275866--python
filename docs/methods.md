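# Methods

This note documents the models implemented in `sineseeker`, their
parameters and defaults, the design choices made where the design was
genuinely open, and what the synthetic data do and do not emulate. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Runs of homozygosity and the critical region

The ROH scanner follows the PLINK 1.9 sliding-window scheme. A window of
`window_snps` markers (default 50) slides one marker at a time along each
chromosome of each sample; a window is *homozygous* when it contains at
most `het_allow` heterozygous calls (default 1) and at most `missing_allow`
missing calls (default 5). Each marker's hit fraction is the proportion of
windows covering it that are homozygous; markers with hit fraction ≥
`hit_threshold` (default 0.05) are eligible. Maximal runs of eligible
markers are reported as ROH segments when they contain ≥ `min_markers`
markers, span ≥ `min_length_bp` (default 1 Mb), contain no inter-marker gap
above `gap_max_bp` (default 1 Mb), and average at least one marker per
`density_max_kb` (default 50 kb). `min_markers` defaults to 25, scaled to
sparse desk-scale panels; the genome-scale PLINK default of 100 is exposed
as `PLINK_MIN_MARKERS`. The scanner is verified against a brute-force
enumerator of the same criteria on random instances of up to 200 markers.

Because one heterozygous call is tolerated per window, detected segments
run *through* isolated het calls; the critical region is therefore computed
in two steps. First, the per-case segments are intersected per chromosome
and any interval across which a control shows no heterozygous call
(missing ignored) is discarded; the survivors are ordered by length.
Second, `refine_by_het_calls` trims the region to the longest sub-interval
free of case het calls, with boundaries at the outermost case-homozygous
markers flanked by the nearest het calls. A het call interior to the region
splits it; the longest piece is returned and the alternates logged. Whether
missing calls should also terminate refinement is genuinely open; they do
not here, which errs toward wider (more conservative) regions.

QC precedes scanning: markers with minor allele frequency below `maf_min`
(default 0.05, computed over all non-missing calls) or missingness above
`missing_max` (default 0.10) are removed. Samples of unknown phenotype are
treated as controls for the exclusion step only.

Coordinates are 1-based inclusive throughout the package; BED export
converts to 0-based half-open.

## Recessive variant filtering

A variant survives when every case is homozygous-alternate (a missing case
genotype disqualifies — observed homozygosity is required to prove the
recessive model; a missing control genotype is ignored), no within-cohort
control is homozygous-alternate (heterozygous controls are fine: they are
the obligate carriers), and the predicted impact reaches `impact_min` on
the four-level ladder MODIFIER < LOW < MODERATE < HIGH. "Common in the
population panel" is operationalised as alt-allele frequency > `af_max`
(default 0.05) or any panel individual homozygous-alternate (both
configurable); a variant with no called panel genotype is retained and
flagged *private*. Stage counts are recorded and checked non-increasing.

## Insertion calling

Breakpoint convention: `bp_left` / `bp_right` are the first and last
reference bases of the target-site duplication, so `tsd =
ref[bp_left..bp_right]` and reads entering the element from the left are
clipped after `bp_right` while reads leaving it on the right are clipped
before `bp_left`.

**Depth.** Per-base depth counts aligned (M/=/X) bases only. Depth is
compared against a sliding-median local background (window 301 bp), which
tracks fragment-sampling drift and is robust to a TSD-scale bump; positions
whose background falls below half the regional median (coverage ramps at
region edges) are not assessable. Candidate intervals are runs of depth ≥
`elevation_factor` × background (default 1.4); runs are kept when 4–50 bp
long (`tsd_min_bp`/`tsd_max_bp`) with mean depth ≥ `mean_factor` ×
background (default 1.5), and surviving pieces separated by dips of ≤ 2 bp
are merged. The margins reflect the signal structure at ~30× coverage: a
duplicated target site sits near 2.0× its flanks while sampling noise
rarely sustains 1.5× over a short run; at this coverage the 2× signal still
dips below the bar in roughly 0.5% of samples, which is why depth is
treated as supporting evidence — calls are driven by clip clusters.

**Clips.** Terminal soft clips of ≥ `min_clip` bases (default 20) are
grouped by (side, position ± 2 bp); fragments are justified at the junction
side and a column-wise majority consensus is taken; clusters below
`min_support` (default 3) are dropped. A call requires opposing clusters
whose positions define a TSD of ≤ `tsd_max_bp`, plus poly-A evidence
(longest terminal window with ≥ 80% adenine, ≥ 10 bp, either orientation)
in at least one consensus. The element 5′ consensus (from right-extending
clips) and 3′ consensus (from left-extending clips, ending in the tail) are
overlap-merged when they share ≥ 15 bp at ≥ 90% identity, yielding a full
length estimate; otherwise the call is *partial* with unknown length —
with 150 bp reads no single read spans a 210 bp element, so a full length
may only ever come from a successful merge, never be fabricated.
Single-sided cluster evidence yields a low-confidence call flagged
`one_sided`. Mapping-quality-0 reads count for depth and clip evidence
(repeat multi-mappers *are* the signal) but never as reference evidence.

**Genotyping.** A read supports the insertion allele if it carries a
junction clip at either breakpoint; it supports the reference allele only
if it spans the entire TSD plus 5 bp of unique flank on both sides with no
terminal clip — reads touching just one TSD copy and its flank are
sequence-identical between the two alleles and carry no information. The
two counts have unequal catchment (two junctions × nearly the whole read
length versus a single TSD+flank window), so each is divided by its
catchment length before forming the allele balance *r*, which then centres
near 1, 0.5 and 0 for hom-alt, het and hom-ref samples. Cutoffs: *r* ≥ 0.8
hom-alt, 0.2 ≤ *r* < 0.8 het, below hom-ref; fewer than `min_support`
informative reads → no-call.

**Discordance.** Region-overlapping reads whose mate is unmapped, maps to
another contig, or implies an insert beyond `max_insert` (default 1000 bp)
are counted as supporting evidence.

Calls export to VCF 4.2 with `ALT=<INS:ME:SINE>`, INFO keys TSD and POLYA,
and SVLEN only when the length is known; POS is the anchor base before
`bp_left`.

## Repeat classification

Alignment is Needleman–Wunsch with affine gaps (defaults: match +2,
mismatch −3, gap open −5, gap extend −2, so a gap of length *k* costs
5 + 2*k*), with end gaps free on both sequences — i.e. semi-global — and
percent identity is matched columns over aligned columns with terminal-gap
columns excluded from the denominator. Free end gaps and the trimmed
denominator are two faces of the same choice: consensuses of unequal
length, or a full-length element embedded in a longer query, must score
their true identity rather than be penalised for the length difference.
Poly-A tails are not trimmed before classification (a flag could be added;
tails are part of the consensus here). The identity matrix covers
{query} ∪ library; the best hit is the maximal-identity entry, ties broken
lexicographically and reported. The aligner's scores are verified against
a brute-force affine-gap enumeration on short sequences.

## Consequence prediction

Transcript models are genomic exon lists with CDS bounds and strand; an
exon may be flagged alternatively spliced, giving long/short isoform pairs
whose CDS lengths must both be divisible by three. `map_genomic_to_cds`
gives the coding coordinate and codon index (codon = ⌈c/3⌉), with explicit
error categories (intronic / UTR / not-in-isoform), and is inverted by
`cds_to_genomic` (round-trip tested on both strands).

An insertion is specified as *inserted sequence placed immediately before a
genomic position*; for the pipeline's calls the net inserted bases relative
to the reference are the element plus the second TSD copy, placed before
`bp_right + 1`. For each isoform whose CDS contains the site, the mutant
CDS is translated from the first codon containing inserted bases
(`protein_start_position`). Every residue from that codon to the first stop
(exclusive) counts as aberrant: a residue inside the disrupted tract that
coincidentally matches wild type is still aberrant, which keeps the
invariant `stop = start + aberrant` exact. The wild-type tail is the count
of complete wild-type codons from the start codon to the end of the host
exon, and `exon_extension = aberrant − tail`. If no stop is reached before
the CDS end the call is flagged stop-loss-like with no stop position.
Isoforms lacking the exon are reported unaffected. Standard genetic code
only. Designations render as `<accession> c.<pos>_ins<length> (p.<start>)`,
with `ins?` when only a partial consensus is available.

## Assay genotyping and segregation

In-silico PCR requires exact primer matches (≥ 15 bp, ACGT); the fragment
length is the distance from the forward primer's 5′ end to the reverse
primer's 5′ end, plus the fluorophore tail on tailed primers. An
allele-specific forward primer simply yields no product on the other
allele; multiple binding sites are an error, as is an assay producing no
product anywhere. Fragment-length genotyping matches observed sizes to the
two expectations within ± `tolerance` (default 1 bp, matching the bundled
±1 bp uniform sizing-error model): both sizes → het, one → the
corresponding homozygote, none → no-call; expectations closer than twice
the tolerance are a configuration error. The bundled assay fixtures are
engineered on the synthetic locus to the classic product sizes (248 bp
flanking product; 266 bp wild-type and 250 bp element-specific with the
16 bp tail) — they test the size-arithmetic contract, not any real oligos.

The segregation report scores a cohort against a fully penetrant recessive
model: discordant samples are affected-but-not-homozygous and
clear-but-homozygous; allele frequency is (2·hom + het) / (2·called);
penetrance is the affected fraction among homozygotes.

## The synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 4 array-genotyped cases
and 22 controls (6 of them carriers), a shared 2 Mb homozygous-by-descent
interval at 1 marker / 25 kb on 4 Mb contigs, 150 bp paired-end reads at
30× (fragments 400 ± 50 bp) over a 4 kb window around the locus, a 210 bp
in-frame poly-A-tailed element with a 15 bp TSD inside the alternatively
spliced fourth exon of a seven-exon gene (long isoform 716 aa, short 660
aa, insertion point ten codons before the exon's end, premature stop 50
codons into the element), one planted HIGH-impact recessive variant among
≥ 50 decoys each violating exactly one filter criterion, a typed 81-entry
known-variant panel, and a four-entry repeat library whose non-source
entries diverge by ~20%.

Deliberate generator design, documented because tests rely on it:

- Reads are emitted **pre-aligned** (no aligner dependency): clip placement
  is computed analytically from fragment coordinates, since the signatures
  of interest live in alignments, not raw reads. Reads wholly inside the
  element, and 30% of element-spanning pairs, are relocated to another
  contig at mapping quality 0, mimicking multi-copy repeat mapping.
- Sequencing error is off by default (`substitution_error_rate`
  configurable); base qualities are not modelled and FASTQ is not emitted.
- Each case's ROH is the shared interval extended by a private 0–3 markers
  per side, flanked by **two observed heterozygous anchor markers**. The
  anchors are emitted as common, well-genotyped markers (never rare, never
  missing) because they are the refinement boundaries the het-trimming
  logic presupposes; missing calls are injected everywhere else at the
  configured rate. With a single anchor, window smoothing lets eligibility
  leak one marker past the run; with two it terminates exactly.
- Contigs are 4 Mb rather than minimal so that the 2 Mb ROH keeps ~20
  markers of flank: marker windows near a chromosome edge are covered by
  few windows, where a single homozygous window can clear the 5% hit
  threshold and absorb an anchor.
- The genotype matrix is Hardy–Weinberg per marker with MAF ~ U(0.10,
  0.50) (a 10% rare-marker fraction at MAF < 0.05 provides QC fodder);
  controls inside the ROH are additionally forced heterozygous at the
  background rate (default 0.25), so the control-exclusion step is
  exercised.

What passing on this substrate does **not** show: robustness to alignment
artefacts around real repeats (mapping ambiguity here is a clean MQ0
relocation), to sequencing error and base-quality structure, to uneven
array coverage or genotyping batch effects, to nested or truncated element
insertions, or to reference genomes where the element family is already
present near the locus. The depth detector's margins are calibrated to
~30×; at materially lower coverage the TSD bump is not reliably separable
from sampling noise and calls rest on clip evidence alone.

## Scale and determinism

All randomness flows from a single integer seed through named
`numpy.random.Generator` streams; identical configuration gives
byte-identical FASTA/SAM/VCF/PED/JSON outputs, which the suite asserts.
Desk-scale problem sizes (tens-of-kb windows, hundreds of markers, ~20 k
reads per cohort) keep a full pipeline run near a second and the whole
acceptance computation under a minute while preserving the statistical
structure the methods depend on; every size is configurable upward.
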