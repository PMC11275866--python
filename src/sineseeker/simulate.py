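"""Seeded generators for every input the pipeline consumes.

The simulator plants a known ground truth into a mini-genome so that every
stage's recovery is measurable:

* a reference of random contigs carrying a seven-exon gene whose fourth exon
  is alternatively spliced — a 'long' isoform contains it, a 'short' isoform
  skips it (their protein lengths differ by exactly the residues the exon
  encodes);
* a poly-A-tailed, SINE-like element inserted homozygously into that exon in
  all cases, with a target-site duplication, drawn from one entry of a small
  repeat-consensus library with controlled mutual divergence;
* a case/control genotype cohort whose cases share a homozygous-by-descent
  interval containing the insertion, with heterozygous anchor markers just
  outside each case's run (the basis of het-call refinement), array-scale
  marker sparsity, low-MAF markers and missing calls as QC fodder;
* paired-end alignments emitted pre-aligned to the insertion-free reference,
  so breakpoint-crossing reads carry soft clips of element sequence, both TSD
  copies pile depth onto the single reference copy, and a configurable
  fraction of element-spanning pairs have their mates relocated to another
  contig (multi-copy repeat mapping mimicry);
* an annotated variant table with one planted recessive candidate among
  decoys that each violate exactly one filter criterion, plus a known-variant
  exclusion panel;
* fragment-length assay fixtures engineered to the classic 248 / 266 / 250 bp
  product sizes.

Identical configuration (including seed) yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from sineseeker.assay import PrimerAssay, insilico_pcr
from sineseeker.genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING
from sineseeker.repeats import RepeatLibrary
from sineseeker.transcripts import Exon, Isoform, TranscriptModel
from sineseeker.variantfilter import ExclusionPanel, VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS
)

# exon coding lengths engineered so the long isoform encodes 716 residues,
# the short isoform (exon 4 skipped) 660, and the insertion point at CDS
# 1729 sits 10 codons before the end of exon 4
_EXON_CODING_LENGTHS = (480, 510, 600, 168, 200, 100, 93)
_ALT_EXON_INDEX = 3          # 0-based: exon 4
_INTRON_LENGTH = 400
_INSERT_CDS_END = 1728       # CDS coordinate of the last TSD base


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the mapped scenario: four array-genotyped cases and 22
    controls sharing a ~2 Mb homozygous interval at 1 marker / 25 kb, 150 bp
    paired-end reads at 30x over the insertion locus, a 210 bp in-frame
    poly-A-tailed element with a 15 bp target-site duplication, and a
    premature stop 50 codons into the element.
    """

    seed: int = 0
    n_cases: int = 4
    n_controls: int = 22
    n_carrier_controls: int = 6
    n_chromosomes: int = 3
    chromosome_length_bp: int = 4_000_000
    markers_per_chromosome: int = 160
    roh_length_bp: int = 2_000_000
    insertion_length_bp: int = 210
    tsd_length_bp: int = 15
    read_length_bp: int = 150
    mean_depth: float = 30.0
    fragment_mean_bp: int = 400
    fragment_sd_bp: int = 50
    polyA_tail_bp: int = 30
    background_het_rate: float = 0.25
    genotyping_missing_rate: float = 0.02
    discordant_mate_fraction: float = 0.3
    substitution_error_rate: float = 0.0
    in_frame: bool = True
    stop_codon_index: int = 50
    n_decoy_variants: int = 60
    n_panel_samples: int = 40
    n_known_variants: int = 81
    read_window_bp: int = 4000
    rare_marker_fraction: float = 0.10

    def __post_init__(self) -> None:
        counts = (self.n_cases, self.n_controls, self.n_chromosomes,
                  self.markers_per_chromosome, self.chromosome_length_bp,
                  self.roh_length_bp, self.insertion_length_bp,
                  self.tsd_length_bp, self.read_length_bp)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        probs = (self.background_het_rate, self.genotyping_missing_rate,
                 self.discordant_mate_fraction, self.substitution_error_rate,
                 self.rare_marker_fraction)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.insertion_length_bp < self.polyA_tail_bp:
            raise ValueError("insertion shorter than its poly-A tail")
        if self.in_frame and (self.insertion_length_bp % 3
                              or self.tsd_length_bp % 3):
            raise ValueError(
                "in-frame insertion requires element and TSD lengths "
                "divisible by 3")
        if 3 * self.stop_codon_index > self.insertion_length_bp - self.polyA_tail_bp:
            raise ValueError("stop_codon_index beyond the element body")
        if self.n_carrier_controls > self.n_controls:
            raise ValueError("more carrier controls than controls")
        if self.roh_length_bp > self.chromosome_length_bp:
            raise ValueError("ROH longer than chromosome")

    @property
    def case_samples(self) -> list[str]:
        return [f"CASE_{i + 1}" for i in range(self.n_cases)]

    @property
    def control_samples(self) -> list[str]:
        return [f"CTRL_{i + 1}" for i in range(self.n_controls)]

    @property
    def samples(self) -> list[str]:
        return self.case_samples + self.control_samples

    @property
    def panel_samples(self) -> list[str]:
        return [f"PANEL_{i + 1}" for i in range(self.n_panel_samples)]


@dataclasses.dataclass
class Reference:
    """Mini reference: contigs, gene model, repeat library, planned insertion."""

    contigs: dict[str, str]
    transcript_model: TranscriptModel
    repeat_library: RepeatLibrary
    insertion_chrom: str
    bp_left: int          # first reference base of the TSD (1-based)
    bp_right: int         # last reference base of the TSD
    inserted_sequence: str
    source_repeat: str

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def tsd_sequence(self) -> str:
        seq = self.contigs[self.insertion_chrom]
        return seq[self.bp_left - 1:self.bp_right]

    @property
    def insertion_site(self) -> int:
        """Position before which the net inserted bases (element + second TSD
        copy) sit on the reference axis."""
        return self.bp_right + 1

    def alt_sequence(self, chrom: str) -> str:
        """Chromosome sequence carrying the insertion allele."""
        seq = self.contigs[chrom]
        if chrom != self.insertion_chrom:
            return seq
        return (seq[:self.bp_right] + self.inserted_sequence
                + seq[self.bp_left - 1:])

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        return path


@dataclasses.dataclass
class GroundTruth:
    """Oracle for recovery tests: what was planted, where, in whom."""

    chrom: str
    shared_roh: tuple[int, int]
    case_roh: dict[str, tuple[int, int]]
    bp_left: int
    bp_right: int
    insertion_site: int
    inserted_sequence: str
    tsd_sequence: str
    source_repeat: str
    planted_variant: tuple[str, int, str, str]
    insertion_genotypes: dict[str, str]
    polyA_tail_bp: int

    def __post_init__(self) -> None:
        for sample, (lo, hi) in self.case_roh.items():
            if not lo <= self.insertion_site <= hi:
                raise ValueError(
                    f"insertion site outside ROH of {sample}")
        if not (self.shared_roh[0] <= self.planted_variant[1]
                <= self.shared_roh[1]):
            raise ValueError("planted variant outside shared ROH")
        tail = self.inserted_sequence[len(self.inserted_sequence)
                                      - self.polyA_tail_bp:]
        if tail != "A" * self.polyA_tail_bp:
            raise ValueError("inserted sequence does not end in the poly-A tail")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        if isinstance(source, Path) or Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        payload["shared_roh"] = tuple(payload["shared_roh"])
        payload["case_roh"] = {k: tuple(v) for k, v in payload["case_roh"].items()}
        payload["planted_variant"] = tuple(payload["planted_variant"])
        return cls(**payload)


# ======================================================================
def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _build_element(config: SimulationConfig, rng: np.random.Generator) -> str:
    """SINE-like element: ORF-style body with a premature stop at
    ``stop_codon_index``, then filler, then the poly-A tail."""
    body_len = config.insertion_length_bp - config.polyA_tail_bp
    n_codons = body_len // 3
    prefix = _random_orf(rng, config.stop_codon_index - 1)
    filler_len = body_len - len(prefix) - 3
    filler = _random_sequence(rng, filler_len)
    element = prefix + "TAA" + filler + "A" * config.polyA_tail_bp
    # partial codon remainder when body_len % 3 != 0 lands in the filler
    return element[:config.insertion_length_bp]


def simulate_reference(config: SimulationConfig) -> Reference:
    """Generate contigs, the two-isoform gene, the repeat library and the
    planned insertion."""
    rng = np.random.default_rng([config.seed % (2 ** 31), 1])
    contigs = {
        f"chr{i + 1}": _random_sequence(rng, config.chromosome_length_bp)
        for i in range(config.n_chromosomes)
    }
    chrom = "chr1"

    gene_span = sum(_EXON_CODING_LENGTHS) + _INTRON_LENGTH * (
        len(_EXON_CODING_LENGTHS) - 1)
    gene_start = config.chromosome_length_bp // 2 - gene_span // 2
    if gene_start < 1 or gene_start + gene_span - 1 > config.chromosome_length_bp:
        raise ValueError(
            f"gene model of {gene_span} bp does not fit on a "
            f"{config.chromosome_length_bp} bp contig")

    exons = []
    pos = gene_start
    for i, length in enumerate(_EXON_CODING_LENGTHS):
        exons.append(Exon(start=pos, end=pos + length - 1,
                          alternatively_spliced=(i == _ALT_EXON_INDEX)))
        pos += length + _INTRON_LENGTH
    long_iso = Isoform(isoform_id="long", exons=exons, strand="+",
                       cds_start=exons[0].start, cds_end=exons[-1].end)
    short_iso = Isoform(isoform_id="short",
                        exons=[e for i, e in enumerate(exons)
                               if i != _ALT_EXON_INDEX],
                        strand="+",
                        cds_start=exons[0].start, cds_end=exons[-1].end)
    model = TranscriptModel(gene_id="FAM161A-like", accession="SYN_XP_0001",
                            chrom=chrom, isoforms=[long_iso, short_iso])

    # write an open reading frame into the exons so the wild-type protein is
    # stop-free until its terminal codon
    cds_len = sum(_EXON_CODING_LENGTHS)
    orf = _random_orf(rng, cds_len // 3 - 1) + "TAA"
    seq = list(contigs[chrom])
    offset = 0
    for exon in exons:
        seq[exon.start - 1:exon.end] = orf[offset:offset + exon.length]
        offset += exon.length
    contigs[chrom] = "".join(seq)

    # insertion point: last TSD base at a codon boundary 10 codons before the
    # end of the alternatively spliced exon
    from sineseeker.consequence import cds_to_genomic
    bp_right = cds_to_genomic(model, "long", _INSERT_CDS_END)
    bp_left = bp_right - config.tsd_length_bp + 1
    alt_exon = exons[_ALT_EXON_INDEX]
    if not (alt_exon.start <= bp_left and bp_right <= alt_exon.end):
        raise ValueError("TSD does not fit inside the alternatively "
                         "spliced exon")

    element = _build_element(config, rng)
    entries = {"SINEC_Aa": element}
    for name in ("SINEC_Bb", "SINEC_Cc", "MIRc"):
        body = _mutate(rng, element[:len(element) - config.polyA_tail_bp], 0.20)
        entries[name] = body + "A" * config.polyA_tail_bp
    library = RepeatLibrary(entries=entries)

    return Reference(contigs=contigs, transcript_model=model,
                     repeat_library=library, insertion_chrom=chrom,
                     bp_left=bp_left, bp_right=bp_right,
                     inserted_sequence=element, source_repeat="SINEC_Aa")


# ======================================================================
def simulate_genotype_cohort(config: SimulationConfig, reference: Reference,
                             ) -> tuple[GenotypeMatrix, GroundTruth]:
    """Marker genotypes for cases and controls plus the planted ground truth.

    All cases are homozygous-alternate across a shared interval of
    ``roh_length_bp`` containing the insertion site, each case's run extended
    by a private few markers and anchored by an observed heterozygous call
    immediately outside (two, so window smoothing terminates exactly at the
    run); controls draw Hardy-Weinberg genotypes with at least the background
    het rate inside the interval; a fraction of markers is rare (MAF < 5%)
    and missing calls are injected at the configured rate.
    """
    rng = np.random.default_rng([config.seed % (2 ** 31), 2])
    samples = config.samples
    phenotypes = (["case"] * config.n_cases + ["control"] * config.n_controls)
    chrom_names = list(reference.contigs)
    chrom_len = config.chromosome_length_bp

    marker_rows = []
    for chrom in chrom_names:
        positions = np.sort(rng.choice(chrom_len, size=config.markers_per_chromosome,
                                       replace=False)) + 1
        for k, p in enumerate(positions):
            marker_rows.append((f"{chrom}_m{k + 1}", chrom, int(p), "A", "B"))
    markers = pd.DataFrame(marker_rows,
                           columns=["marker_id", "chrom", "pos", "a1", "a2"])

    n_samples = len(samples)
    n_markers = len(markers)

    # plan the shared ROH and each case's private extension before any
    # genotype draw, so the heterozygous anchor markers flanking each run can
    # be emitted as common, well-genotyped markers (the refinement logic
    # presupposes informative flanking calls)
    site = reference.insertion_site
    roh_start = int(np.clip(site - config.roh_length_bp // 2, 1,
                            chrom_len - config.roh_length_bp + 1))
    roh_end = roh_start + config.roh_length_bp - 1
    chrom = reference.insertion_chrom
    chrom_mask = (markers["chrom"] == chrom).to_numpy()
    pos_arr = markers["pos"].to_numpy()
    in_roh = chrom_mask & (pos_arr >= roh_start) & (pos_arr <= roh_end)
    roh_idx = np.flatnonzero(in_roh)
    if roh_idx.size == 0:
        raise ValueError("no markers fall inside the planted ROH")
    chrom_idx = np.flatnonzero(chrom_mask)

    case_plan = []   # (case index, run marker ids, anchor marker ids)
    anchor_markers: set[int] = set()
    first = int(np.flatnonzero(chrom_idx == roh_idx[0])[0])
    last = int(np.flatnonzero(chrom_idx == roh_idx[-1])[0])
    for ci in range(config.n_cases):
        lo = max(0, first - int(rng.integers(0, 4)))
        hi = min(chrom_idx.size - 1, last + int(rng.integers(0, 4)))
        anchors = [chrom_idx[j] for j in range(max(0, lo - 2), lo)]
        anchors += [chrom_idx[j] for j in
                    range(hi + 1, min(chrom_idx.size, hi + 3))]
        case_plan.append((ci, chrom_idx[lo:hi + 1], anchors))
        anchor_markers.update(anchors)

    rare = rng.random(n_markers) < config.rare_marker_fraction
    rare[list(anchor_markers)] = False
    maf = np.where(rare, rng.uniform(0.002, 0.02, n_markers),
                   rng.uniform(0.10, 0.50, n_markers))
    # Hardy-Weinberg draws per sample x marker
    u = rng.random((n_samples, n_markers))
    p_hom_ref = (1 - maf) ** 2
    p_het = 2 * maf * (1 - maf)
    calls = np.full((n_samples, n_markers), HOM_ALT, dtype=np.int8)
    calls[u < p_hom_ref + p_het] = HET
    calls[u < p_hom_ref] = HOM_REF

    protected = np.zeros((n_samples, n_markers), dtype=bool)
    case_roh: dict[str, tuple[int, int]] = {}
    for ci, run, anchors in case_plan:
        sample = config.case_samples[ci]
        calls[ci, run] = HOM_ALT
        # two observed heterozygous anchors immediately outside the run:
        # window smoothing then terminates eligibility exactly at the run
        for j in anchors:
            calls[ci, j] = HET
            protected[ci, j] = True
        # anchors must stay observed for every case, or QC's missingness
        # screen could drop the refinement boundary markers
        protected[:, list(anchor_markers)] = True
        case_roh[sample] = (int(pos_arr[run[0]]), int(pos_arr[run[-1]]))

    # controls: guarantee at least the background het rate inside the interval
    for si in range(config.n_cases, n_samples):
        force = rng.random(roh_idx.size) < config.background_het_rate
        calls[si, roh_idx[force]] = HET

    # missing calls (never on the refinement anchors)
    miss = rng.random((n_samples, n_markers)) < config.genotyping_missing_rate
    calls[miss & ~protected] = MISSING

    matrix = GenotypeMatrix(markers=markers, calls=calls,
                            samples=samples, phenotypes=phenotypes)

    planted_pos = reference.bp_left - 500
    ref_base = reference.contigs[chrom][planted_pos - 1]
    alt_base = "A" if ref_base != "A" else "G"
    genotypes = {s: "hom_alt" for s in config.case_samples}
    for i, s in enumerate(config.control_samples):
        genotypes[s] = "het" if i < config.n_carrier_controls else "hom_ref"
    truth = GroundTruth(
        chrom=chrom,
        shared_roh=(roh_start, roh_end),
        case_roh=case_roh,
        bp_left=reference.bp_left,
        bp_right=reference.bp_right,
        insertion_site=site,
        inserted_sequence=reference.inserted_sequence,
        tsd_sequence=reference.tsd_sequence,
        source_repeat=reference.source_repeat,
        planted_variant=(chrom, planted_pos, ref_base, alt_base),
        insertion_genotypes=genotypes,
        polyA_tail_bp=config.polyA_tail_bp,
    )
    return matrix, truth


# ======================================================================
@dataclasses.dataclass
class ReadSimResult:
    header: dict
    records: dict[str, list[pysam.AlignedSegment]]
    stats: dict[str, dict[str, int]]
    window: tuple[int, int]          # simulated interval on the reference

    def write_sam(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        header = pysam.AlignmentHeader.from_dict(self.header)
        for sample, reads in self.records.items():
            path = directory / f"{sample}.sam"
            with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
                for read in reads:
                    fh.write(read)
            paths[sample] = path
        return paths


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r") as fh:
        return list(fh)


def _sam_header(reference: Reference) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in reference.contig_lengths.items()],
    }


def simulate_reads(config: SimulationConfig, reference: Reference,
                   truth: GroundTruth,
                   samples: Sequence[str] | None = None) -> ReadSimResult:
    """Paired-end alignments over a window around the insertion locus.

    Reads are emitted already aligned to the insertion-free reference:
    element-allele reads crossing a breakpoint carry soft clips of element
    sequence, reads wholly inside the element are relocated to another contig
    at mapping quality 0 (or unmapped on a single-contig reference), and a
    configurable fraction of element-spanning pairs have their right mate
    relocated likewise.
    """
    if samples is None:
        samples = list(truth.insertion_genotypes)
    header_dict = _sam_header(reference)
    header = pysam.AlignmentHeader.from_dict(header_dict)
    chrom = truth.chrom
    tids = {name: i for i, name in enumerate(reference.contigs)}
    ref_seq = reference.contigs[chrom]

    half = config.read_window_bp // 2
    w_start = max(1, truth.bp_left - half)
    w_end = min(len(ref_seq), truth.bp_right + half)
    ref_window = ref_seq[w_start - 1:w_end]
    ins = truth.inserted_sequence
    # alt window: reference through bp_right, element, reference from bp_left
    L1 = truth.bp_right - w_start + 1
    alt_window = (ref_window[:L1] + ins + ref_seq[truth.bp_left - 1:w_end])
    decoys = [name for name in reference.contigs if name != chrom]

    rl = config.read_length_bp
    window_len = w_end - w_start + 1
    n_frag = max(1, int(round(config.mean_depth * window_len / (2 * rl))))

    records: dict[str, list[pysam.AlignedSegment]] = {}
    stats: dict[str, dict[str, int]] = {}
    for si, sample in enumerate(samples):
        rng = np.random.default_rng([config.seed % (2 ** 31), 3, si])
        genotype = truth.insertion_genotypes.get(sample, "hom_ref")
        reads, st = _sample_reads(config, rng, sample, genotype, header,
                                  tids, chrom, decoys, ref_window, alt_window,
                                  w_start, L1, len(ins), n_frag,
                                  len(reference.contigs[decoys[0]]) if decoys else 0)
        records[sample] = reads
        stats[sample] = st
    return ReadSimResult(header=header_dict, records=records, stats=stats,
                         window=(w_start, w_end))


def _sample_reads(config, rng, sample, genotype, header, tids, chrom, decoys,
                  ref_window, alt_window, w_start, L1, ins_len, n_frag,
                  decoy_len):
    rl = config.read_length_bp
    reads: list[pysam.AlignedSegment] = []
    stats = {"fragments": n_frag, "spanning_pairs": 0, "relocated_pairs": 0,
             "insert_only_reads": 0}
    p_alt = {"hom_alt": 1.0, "het": 0.5, "hom_ref": 0.0}[genotype]
    for fi in range(n_frag):
        use_alt = rng.random() < p_alt
        hap = alt_window if use_alt else ref_window
        frag_len = int(np.clip(round(rng.normal(config.fragment_mean_bp,
                                                config.fragment_sd_bp)),
                               2 * rl, len(hap)))
        start = int(rng.integers(0, len(hap) - frag_len + 1))
        r1_seq = hap[start:start + rl]
        r2_start = start + frag_len - rl
        r2_seq = hap[r2_start:r2_start + rl]
        spans = use_alt and start < L1 + ins_len and start + frag_len > L1
        if spans:
            stats["spanning_pairs"] += 1
        relocate_r2 = spans and rng.random() < config.discordant_mate_fraction
        if relocate_r2:
            stats["relocated_pairs"] += 1

        aln1 = _place_read(r1_seq, start, use_alt, L1, ins_len, w_start,
                           config.tsd_length_bp)
        aln2 = _place_read(r2_seq, r2_start, use_alt, L1, ins_len, w_start,
                           config.tsd_length_bp)
        pair = []
        for ri, (seq, aln) in enumerate(((r1_seq, aln1), (r2_seq, aln2))):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample}_f{fi}"
            if config.substitution_error_rate > 0:
                seq = _mutate(rng, seq, config.substitution_error_rate)
            # SAM stores the forward-reference-strand sequence; the reverse
            # flag alone records that read 2 was sequenced from the other
            # strand
            a.query_sequence = seq
            a.flag = 0x1 | (0x40 if ri == 0 else 0x80)
            if ri == 1:
                a.flag |= 0x10   # read 2 on reverse strand
            else:
                a.flag |= 0x20   # mate reverse
            forced_decoy = (ri == 1 and relocate_r2)
            if aln is None or forced_decoy:
                if aln is None:
                    stats["insert_only_reads"] += 1
                if decoys:
                    a.reference_id = tids[decoys[0]]
                    a.reference_start = int(rng.integers(0, max(1, decoy_len - rl)))
                    a.cigarstring = f"{len(a.query_sequence)}M"
                    a.mapping_quality = 0
                else:
                    a.flag |= 0x4
                    a.mapping_quality = 0
            else:
                pos0, cigar = aln
                a.reference_id = tids[chrom]
                a.reference_start = pos0
                a.cigarstring = cigar
                a.mapping_quality = 60
            pair.append(a)
        _set_mate_fields(pair[0], pair[1])
        reads.extend(pair)
    # coordinate order; unmapped reads sort last
    reads.sort(key=lambda a: (a.is_unmapped, a.reference_id
                              if not a.is_unmapped else 0,
                              a.reference_start if not a.is_unmapped else 0))
    return reads, stats


def _place_read(seq: str, start: int, use_alt: bool, L1: int, ins_len: int,
                w_start: int, tsd_len: int) -> tuple[int, str] | None:
    """Alignment of one read against the insertion-free reference.

    Returns (0-based reference start, CIGAR) or None when the read lies
    wholly inside the element (no reference anchor).  A read that crosses
    the whole element (possible only when the element is shorter than the
    read) anchors on its left part; the rest is soft-clipped, since the
    right flank restarts at the first TSD copy and cannot be expressed as a
    contiguous alignment.
    """
    rl = len(seq)
    if not use_alt:
        return w_start - 1 + start, f"{rl}M"
    end = start + rl
    a_len = max(0, min(end, L1) - start)               # bases before element
    b_len = max(0, min(end, L1 + ins_len) - max(start, L1))
    c_len = max(0, end - max(start, L1 + ins_len))     # bases after element
    if a_len:
        clip = b_len + c_len
        cigar = f"{a_len}M{clip}S" if clip else f"{a_len}M"
        return w_start - 1 + start, cigar
    if c_len:
        # first aligned base maps onto the first TSD copy (position bp_left)
        pos0 = (w_start - 1) + (L1 - tsd_len) \
            + (max(start, L1 + ins_len) - (L1 + ins_len))
        cigar = f"{b_len}S{c_len}M" if b_len else f"{c_len}M"
        return pos0, cigar
    return None


def _set_mate_fields(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> None:
    for a, b in ((r1, r2), (r2, r1)):
        if b.is_unmapped:
            a.flag |= 0x8
            a.next_reference_id = a.reference_id if not a.is_unmapped else -1
            a.next_reference_start = a.reference_start if not a.is_unmapped else -1
        else:
            a.next_reference_id = b.reference_id
            a.next_reference_start = b.reference_start
    if (not r1.is_unmapped and not r2.is_unmapped
            and r1.reference_id == r2.reference_id):
        tlen = (r2.reference_start + (r2.reference_length or 0)
                - r1.reference_start)
        r1.template_length = tlen
        r2.template_length = -tlen
        if abs(tlen) < 2000:
            r1.flag |= 0x2
            r2.flag |= 0x2


def _revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ======================================================================
def simulate_variant_table(config: SimulationConfig, reference: Reference,
                           truth: GroundTruth,
                           ) -> tuple[list[VariantRecord], list[str],
                                      ExclusionPanel]:
    """Annotated variant calls: one planted recessive candidate, decoys each
    violating exactly one filter criterion, and a typed known-variant panel.

    Returns (variants, sample order including population-panel samples,
    exclusion panel).  The planted variant carries no called population-panel
    genotype, so it surfaces as 'private'.
    """
    rng = np.random.default_rng([config.seed % (2 ** 31), 4])
    cohort = config.samples
    panel = config.panel_samples
    chrom_names = list(reference.contigs)
    chrom_len = config.chromosome_length_bp
    gt_code = {"hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT}

    used_positions = {(truth.chrom, truth.planted_variant[1])}

    def fresh_position(chrom: str, lo: int = 1, hi: int | None = None) -> int:
        hi = hi or chrom_len
        while True:
            p = int(rng.integers(lo, hi + 1))
            if (chrom, p) not in used_positions:
                used_positions.add((chrom, p))
                return p

    def alleles_at(chrom: str, pos: int) -> tuple[str, str]:
        ref = reference.contigs[chrom][pos - 1]
        alt = "A" if ref != "A" else "C"
        return ref, alt

    variants: list[VariantRecord] = []

    # the planted candidate
    chrom, pos, ref, alt = truth.planted_variant
    genotypes = {s: gt_code[g] for s, g in truth.insertion_genotypes.items()}
    genotypes.update({s: MISSING for s in panel})
    variants.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                  impact="HIGH", genotypes=genotypes))

    def passing_genotypes() -> dict[str, int]:
        g = {s: HOM_ALT for s in config.case_samples}
        for s in config.control_samples:
            g[s] = HET if rng.random() < 0.3 else HOM_REF
        for s in panel:
            g[s] = HET if rng.random() < 0.01 else HOM_REF
        return g

    kinds = ["case_het", "control_hom", "panel_common", "low_impact"]
    low_impacts = ["MODERATE", "LOW", "MODIFIER"]
    for k in range(config.n_decoy_variants):
        kind = kinds[k % len(kinds)]
        if k % 2 == 0:   # half the decoys inside the shared ROH
            d_chrom = truth.chrom
            d_pos = fresh_position(d_chrom, truth.shared_roh[0],
                                   truth.shared_roh[1])
        else:
            d_chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            d_pos = fresh_position(d_chrom)
        d_ref, d_alt = alleles_at(d_chrom, d_pos)
        g = passing_genotypes()
        impact = "HIGH"
        if kind == "case_het":
            g[config.case_samples[k % config.n_cases]] = HET
        elif kind == "control_hom":
            g[config.control_samples[k % config.n_controls]] = HOM_ALT
        elif kind == "panel_common":
            for s in panel:
                r = rng.random()
                g[s] = HOM_ALT if r < 0.10 else (HET if r < 0.40 else HOM_REF)
        else:
            impact = low_impacts[k % len(low_impacts)]
        variants.append(VariantRecord(chrom=d_chrom, pos=d_pos, ref=d_ref,
                                      alt=d_alt, impact=impact, genotypes=g))

    # known-disease exclusion panel, typed hom-ref in the whole cohort
    panel_entries: dict[tuple[str, int, str, str], str] = {}
    for k in range(config.n_known_variants):
        d_chrom = chrom_names[k % len(chrom_names)]
        d_pos = fresh_position(d_chrom)
        d_ref, d_alt = alleles_at(d_chrom, d_pos)
        panel_entries[(d_chrom, d_pos, d_ref, d_alt)] = f"IED_{k + 1}"
        g = {s: HOM_REF for s in cohort}
        g.update({s: HET if rng.random() < 0.05 else HOM_REF for s in panel})
        variants.append(VariantRecord(chrom=d_chrom, pos=d_pos, ref=d_ref,
                                      alt=d_alt, impact="LOW", genotypes=g))

    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, cohort + panel, ExclusionPanel(variants=panel_entries)


# ======================================================================
def design_fragment_assay(reference: Reference, tail_bp: int = 16,
                          wt_product_bp: int = 250,
                          ins_product_bp: int = 234,
                          primer_bp: int = 20,
                          ) -> tuple[PrimerAssay, dict[str, str]]:
    """Allele-specific fragment assay over the insertion locus.

    Defaults yield the classic sizes: wild-type 250 + 16 bp tail = 266,
    element-specific 234 + 16 = 250.  Returns the assay and the two allele
    templates; construction is verified by in-silico PCR.
    """
    chrom = reference.insertion_chrom
    ref_seq = reference.contigs[chrom]
    flank = max(wt_product_bp + 50, 300)
    wt_template = ref_seq[reference.bp_left - 1 - flank:reference.bp_right + flank]
    alt_seq = reference.alt_sequence(chrom)
    ins_template = alt_seq[reference.bp_left - 1 - flank:
                           reference.bp_right + flank
                           + len(reference.inserted_sequence)
                           + reference.bp_right - reference.bp_left + 1]

    # reverse primer: 5' end 100 bp downstream of the TSD on the template
    rev5 = flank + (reference.bp_right - reference.bp_left + 1) + 100
    rev_site = wt_template[rev5 - primer_bp + 1:rev5 + 1]
    reverse = _revcomp_str(rev_site)
    fwd_wt_start = rev5 - wt_product_bp + 1
    forward_wt = wt_template[fwd_wt_start:fwd_wt_start + primer_bp]
    # element-specific forward on the insertion template
    rev5_ins = ins_template.find(rev_site)
    if rev5_ins < 0:
        raise ValueError("reverse primer site lost on insertion template")
    rev5_ins += primer_bp - 1
    fwd_ins_start = rev5_ins - ins_product_bp + 1
    forward_ins = ins_template[fwd_ins_start:fwd_ins_start + primer_bp]
    if forward_ins in wt_template:
        raise ValueError("element-specific primer also binds the wild type")
    assay = PrimerAssay(forward_wt=forward_wt, reverse=reverse,
                        forward_ins=forward_ins, tail_bp=tail_bp)
    templates = {"wild_type": wt_template, "insertion": ins_template}
    products = insilico_pcr(templates, assay)
    assert products["wild_type"]["forward_wt"] == wt_product_bp + tail_bp
    assert products["insertion"]["forward_ins"] == ins_product_bp + tail_bp
    return assay, templates


def simulate_fragment_observations(config: SimulationConfig,
                                   truth: GroundTruth,
                                   wt_length: int, ins_length: int,
                                   sizing_error_bp: int = 1,
                                   ) -> dict[str, list[int]]:
    """Observed fragment sizes per cohort sample under the planted genotypes,
    with +/- ``sizing_error_bp`` uniform capillary sizing error."""
    rng = np.random.default_rng([config.seed % (2 ** 31), 5])
    observed: dict[str, list[int]] = {}
    for sample, genotype in truth.insertion_genotypes.items():
        sizes = []
        if genotype in ("hom_ref", "het"):
            sizes.append(wt_length)
        if genotype in ("hom_alt", "het"):
            sizes.append(ins_length)
        observed[sample] = [
            int(s + rng.integers(-sizing_error_bp, sizing_error_bp + 1))
            for s in sizes
        ]
    return observed


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Substitution-mutate a sequence at the given per-base rate (test and
    example helper for classification-recovery experiments)."""
    rng = np.random.default_rng(seed)
    return _mutate(rng, seq, rate)
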