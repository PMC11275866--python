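"""Mobile-element-insertion detection from alignment records.

A non-reference retrotransposon insertion leaves three signatures when reads
are mapped to an insertion-free reference:

1. a short read-depth bump over the target-site duplication (TSD), because
   both TSD copies of the inserted allele map onto the single reference copy;
2. two clusters of soft-clipped reads — reads entering the element from the
   left are clipped after the last TSD base, reads leaving it on the right
   are clipped before the first TSD base — whose clipped bases carry element
   sequence, including the diagnostic poly-A tail;
3. read pairs whose mates map to other contigs or nowhere, because the mate
   sequence is element-derived and multi-mapping.

The caller combines the three, reconstructs what it can of the inserted
sequence from the two clip consensuses, and genotypes each sample from the
ratio of clipped to breakpoint-spanning reference reads.

Breakpoint convention: ``bp_left`` is the first and ``bp_right`` the last
reference base of the TSD (1-based inclusive), so ``tsd = ref[bp_left..bp_right]``.
Mapping-quality-0 reads contribute depth and clip evidence (repeat-derived
reads are the signal) but are excluded from genotype denominators.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pysam

_COMP = str.maketrans("ACGTN", "TGCAN")

CLIP_RIGHT_OF = "clip_right_of"   # read aligned to the left, clipped after its end
CLIP_LEFT_OF = "clip_left_of"     # read aligned to the right, clipped before its start


@dataclasses.dataclass(frozen=True)
class Region:
    chrom: str
    start: int   # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class DepthProfile:
    region: Region
    depth: np.ndarray                     # per base, aligned bases only
    elevated: list[tuple[int, int]]       # 1-based inclusive intervals
    median_depth: float


@dataclasses.dataclass
class ClipCluster:
    contig: str
    breakpoint: int        # 1-based: last aligned base (right-of) or first (left-of)
    side: str
    support: int
    consensus: str

    def __post_init__(self) -> None:
        if self.side not in (CLIP_RIGHT_OF, CLIP_LEFT_OF):
            raise ValueError(f"bad side {self.side}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclasses.dataclass
class MEICall:
    contig: str
    bp_left: int
    bp_right: int
    tsd_sequence: str
    insert_consensus: str
    insert_partial: bool
    insert_length_estimate: int | None
    polyA_length: int
    polyA_orientation: str | None
    split_support: int
    discordant_support: int
    depth_ratio: float
    genotypes: dict[str, str] = dataclasses.field(default_factory=dict)
    one_sided: bool = False

    def __post_init__(self) -> None:
        if self.bp_left > self.bp_right:
            raise ValueError("bp_left > bp_right")
        if self.tsd_sequence and len(self.tsd_sequence) != self.bp_right - self.bp_left + 1:
            raise ValueError("TSD length inconsistent with breakpoints")
        if self.polyA_length > len(self.insert_consensus):
            raise ValueError("poly-A run longer than consensus")

    @property
    def tsd_length(self) -> int:
        return self.bp_right - self.bp_left + 1


# ----------------------------------------------------------------------
def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference blocks (1-based inclusive) covered by aligned (M/=/X) bases."""
    blocks = []
    pos = read.reference_start + 1  # to 1-based
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):        # M, =, X
            blocks.append((pos, pos + length - 1))
            pos += length
        elif op in (2, 3):         # D, N consume reference
            pos += length
    return blocks


def depth_profile(alignments: Sequence[pysam.AlignedSegment], region: Region,
                  elevation_factor: float = 1.4,
                  tsd_max_bp: int = 50,
                  tsd_min_bp: int = 4,
                  mean_factor: float = 1.5,
                  heal_gap_bp: int = 2,
                  local_bg_bp: int = 301) -> DepthProfile:
    """Per-base aligned depth over the region plus TSD-scale elevated intervals.

    Depth is compared against a sliding-median local background (window
    ``local_bg_bp``), which tracks fragment-sampling drift while being
    robust to a TSD-scale bump.  Candidate intervals are maximal runs of
    depth >= elevation_factor x local background, with dips of up to
    ``heal_gap_bp`` bases healed.  A run is reported only when no longer
    than ``tsd_max_bp`` (longer runs are not TSD-scale events) and its mean
    depth reaches ``mean_factor`` x its local background: a duplicated
    target site sits near twice its flanks, whereas coverage noise rarely
    sustains that.
    """
    if region.length <= 0:
        return DepthProfile(region, np.zeros(0), [], 0.0)
    depth = np.zeros(region.length, dtype=np.int64)
    for read in alignments:
        if read.is_unmapped or read.reference_name != region.chrom:
            continue
        for lo, hi in _aligned_blocks(read):
            lo = max(lo, region.start)
            hi = min(hi, region.end)
            if lo <= hi:
                depth[lo - region.start:hi - region.start + 1] += 1
    median = float(np.median(depth))
    elevated: list[tuple[int, int]] = []
    if median > 0:
        background = _sliding_median(depth, min(local_bg_bp, depth.size))
        # elevation is only assessable where the local background itself is
        # adequately covered; coverage ramps at region edges are not events
        assessable = background >= 0.5 * median
        hot = (depth >= elevation_factor * background) & assessable
        runs: list[list[int]] = []   # 0-based [start, end] pairs
        start = None
        for i, flag in enumerate(hot):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append([start, i - 1])
                start = None
        if start is not None:
            runs.append([start, len(hot) - 1])
        # filter first (shallow noise excursions never pass the mean bar),
        # then heal small sampling dips between surviving pieces
        surviving = [
            run for run in runs
            if tsd_min_bp <= run[1] - run[0] + 1 <= tsd_max_bp
            and depth[run[0]:run[1] + 1].mean()
            >= mean_factor * background[run[0]:run[1] + 1].mean()
        ]
        merged: list[list[int]] = []
        for run in surviving:
            if merged and run[0] - merged[-1][1] - 1 <= heal_gap_bp:
                merged[-1][1] = run[1]
            else:
                merged.append(list(run))
        elevated = [(a + region.start, b + region.start) for a, b in merged]
    return DepthProfile(region, depth, elevated, median)


def _sliding_median(depth: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding median with edge replication; window forced odd."""
    if window % 2 == 0:
        window = max(1, window - 1)
    if window <= 1 or depth.size == 0:
        return depth.astype(float)
    half = window // 2
    padded = np.pad(depth, half, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


# ----------------------------------------------------------------------
def _terminal_clips(read: pysam.AlignedSegment,
                    min_clip: int) -> list[tuple[str, int, str]]:
    """Terminal soft clips >= min_clip as (side, breakpoint, clipped_seq)."""
    cig = read.cigartuples or []
    seq = read.query_sequence or ""
    out = []
    if cig and cig[0][0] == 4 and cig[0][1] >= min_clip:
        out.append((CLIP_LEFT_OF, read.reference_start + 1, seq[:cig[0][1]]))
    if cig and cig[-1][0] == 4 and cig[-1][1] >= min_clip:
        out.append((CLIP_RIGHT_OF, read.reference_end, seq[len(seq) - cig[-1][1]:]))
    return out


def _column_majority(fragments: list[str], justify_end: bool) -> str:
    """Column-wise majority consensus; fragments justified at the junction
    side (start for right-extending clips, end for left-extending clips)."""
    width = max(len(f) for f in fragments)
    cols = []
    for i in range(width):
        votes: Counter[str] = Counter()
        for frag in fragments:
            j = i if not justify_end else i - (width - len(frag))
            if 0 <= j < len(frag):
                votes[frag[j]] += 1
        if votes:
            cols.append(max(sorted(votes), key=votes.get))
    return "".join(cols)


def cluster_soft_clips(alignments: Sequence[pysam.AlignedSegment],
                       region: Region, min_clip: int = 20,
                       min_support: int = 3,
                       position_tolerance: int = 2) -> list[ClipCluster]:
    """Group terminal soft clips by (side, position +/- tolerance) and build a
    per-cluster majority consensus of the clipped fragments."""
    raw: dict[str, list[tuple[int, str]]] = {CLIP_LEFT_OF: [], CLIP_RIGHT_OF: []}
    for read in alignments:
        if read.is_unmapped or read.reference_name != region.chrom:
            continue
        for side, pos, clipped in _terminal_clips(read, min_clip):
            if region.start <= pos <= region.end:
                raw[side].append((pos, clipped))
    clusters: list[ClipCluster] = []
    for side, items in raw.items():
        items.sort(key=lambda t: t[0])
        group: list[tuple[int, str]] = []
        for item in items + [(None, "")]:
            if group and (item[0] is None
                          or item[0] - group[-1][0] > position_tolerance):
                if len(group) >= min_support:
                    positions = [p for p, _ in group]
                    fragments = [f for _, f in group]
                    consensus = _column_majority(
                        fragments, justify_end=(side == CLIP_LEFT_OF))
                    breakpoint = int(Counter(positions).most_common(1)[0][0])
                    clusters.append(ClipCluster(
                        contig=region.chrom, breakpoint=breakpoint, side=side,
                        support=len(group), consensus=consensus))
                group = []
            if item[0] is not None:
                group.append(item)
    clusters.sort(key=lambda c: (c.breakpoint, c.side))
    return clusters


# ----------------------------------------------------------------------
def detect_polyA(sequence: str, min_run: int = 10,
                 purity: float = 0.8) -> tuple[int, str | None]:
    """Longest terminal adenine-rich window on either end.

    Returns (length, orientation): orientation ``forward`` for a 3' A-tail,
    ``reverse`` for a 5' T-head (the reverse-complement presentation), or
    ``None`` when no run of at least ``min_run`` with A fraction >= purity
    exists.
    """
    sequence = sequence.upper()

    def longest_terminal(seq: str, base: str) -> int:
        # longest suffix with base fraction >= purity whose innermost
        # position is the base itself (a window may not be padded outward
        # through foreign bases)
        best = 0
        count = 0
        rev = seq[::-1]
        for i, ch in enumerate(rev, 1):
            if ch == base:
                count += 1
            if ch == base and count / i >= purity and i >= min_run:
                best = i
        return best

    tail_a = longest_terminal(sequence, "A")
    head_t = longest_terminal(sequence[::-1], "T")
    if tail_a == 0 and head_t == 0:
        return 0, None
    if tail_a >= head_t:
        return tail_a, "forward"
    return head_t, "reverse"


# ----------------------------------------------------------------------
def count_discordant(alignments: Sequence[pysam.AlignedSegment], region: Region,
                     max_insert: int = 1000) -> int:
    """Region-overlapping reads whose mate maps to a different contig, is
    unmapped, or lies beyond ``max_insert``."""
    count = 0
    any_paired = False
    for read in alignments:
        if read.is_unmapped or read.reference_name != region.chrom:
            continue
        start, end = read.reference_start + 1, read.reference_end or read.reference_start + 1
        if end < region.start or start > region.end:
            continue
        if not read.is_paired:
            continue
        any_paired = True
        if read.mate_is_unmapped:
            count += 1
        elif read.next_reference_name != read.reference_name:
            count += 1
        elif abs(read.template_length) > max_insert:
            count += 1
    if not any_paired:
        warnings.warn("no paired reads in region; discordant count is 0",
                      stacklevel=2)
    return count


# ----------------------------------------------------------------------
def _merge_consensuses(left: str, right: str, min_overlap: int = 15,
                       min_identity: float = 0.9) -> str | None:
    """Overlap-merge left (element 5') and right (element 3') consensuses.

    Returns the merged sequence when a suffix of ``left`` matches a prefix of
    ``right`` over >= min_overlap bases at >= min_identity; otherwise None.
    """
    best = None
    max_ov = min(len(left), len(right))
    for ov in range(max_ov, min_overlap - 1, -1):
        a, b = left[-ov:], right[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        if matches / ov >= min_identity:
            best = left + right[ov:]
            break
    return best


def _genotype_ratio(alignments: Sequence[pysam.AlignedSegment],
                    bp_left: int, bp_right: int, chrom: str,
                    flank: int = 5) -> tuple[int, int]:
    """(clipped, spanning) informative read counts at the breakpoints.

    A read is clipped evidence when any terminal soft clip sits at either
    breakpoint.  Reference (spanning) evidence must cross the whole TSD with
    ``flank`` aligned bases beyond both copies: reads touching only one TSD
    copy plus its flank are sequence-identical between the two alleles and
    carry no genotype information.  MQ0 reads are excluded from the
    reference count (repeat multi-mappers are not reference evidence).
    """
    clipped = spanning = 0
    for read in alignments:
        if read.is_unmapped or read.reference_name != chrom:
            continue
        clips = _terminal_clips(read, 1)
        is_clip_evidence = any(
            (side == CLIP_RIGHT_OF and abs(pos - bp_right) <= 2)
            or (side == CLIP_LEFT_OF and abs(pos - bp_left) <= 2)
            for side, pos, _ in clips)
        if is_clip_evidence:
            clipped += 1
            continue
        if read.mapping_quality == 0:
            continue
        start, end = read.reference_start + 1, read.reference_end
        if end is None:
            continue
        if start <= bp_left - flank and end >= bp_right + flank and not clips:
            spanning += 1
    return clipped, spanning


def genotype_sample(alignments: Sequence[pysam.AlignedSegment],
                    bp_left: int, bp_right: int, chrom: str,
                    min_clip: int = 20, min_support: int = 3,
                    het_min: float = 0.2, hom_min: float = 0.8,
                    flank: int = 5) -> str:
    """Genotype one sample from the clipped : spanning allele balance.

    The two raw counts have unequal catchment: a read betrays the insertion
    allele if it crosses either of two junctions anywhere along its length,
    but supports the reference allele only by spanning the whole TSD plus
    ``flank`` on both sides.  Each count is therefore divided by its
    catchment length before forming the balance r, which then centres near
    1, 0.5 and 0 for hom-alt, het and hom-ref samples; the cutoffs are
    r >= ``hom_min`` -> hom_alt, r >= ``het_min`` -> het, else hom_ref,
    with fewer than ``min_support`` informative reads -> nocall.
    """
    clipped, spanning = _genotype_ratio(alignments, bp_left, bp_right, chrom,
                                        flank=flank)
    if clipped + spanning < min_support:
        return "nocall"
    read_lengths = [len(a.query_sequence) for a in alignments
                    if a.query_sequence]
    rl = int(np.median(read_lengths)) if read_lengths else 150
    tsd_len = bp_right - bp_left + 1
    clip_catchment = max(1, 2 * (rl - 1))
    span_catchment = max(1, rl - tsd_len - 2 * flank + 1)
    clip_rate = clipped / clip_catchment
    span_rate = spanning / span_catchment
    r = clip_rate / (clip_rate + span_rate) if clip_rate + span_rate else 0.0
    if r >= hom_min:
        return "hom_alt"
    if r >= het_min:
        return "het"
    return "hom_ref"


def call_mei(region: Region,
             reference_seq: str,
             alignments_by_sample: dict[str, Sequence[pysam.AlignedSegment]],
             elevation_factor: float = 1.4,
             tsd_max_bp: int = 50,
             min_clip: int = 20,
             min_support: int = 3,
             max_insert: int = 1000,
             polyA_min_run: int = 10) -> list[MEICall]:
    """Call mobile-element insertions in a region and genotype every sample.

    ``reference_seq`` is the full sequence of ``region.chrom``.  Evidence is
    pooled across samples for discovery; genotyping is per sample.  A call
    requires opposing clip clusters defining a TSD no longer than
    ``tsd_max_bp`` plus poly-A evidence in at least one cluster consensus;
    single-sided cluster evidence yields a low-confidence call flagged
    ``one_sided``.
    """
    pooled: list[pysam.AlignedSegment] = []
    for reads in alignments_by_sample.values():
        pooled.extend(reads)
    profile = depth_profile(pooled, region, elevation_factor, tsd_max_bp)
    clusters = cluster_soft_clips(pooled, region, min_clip, min_support)
    discordant = count_discordant(pooled, region, max_insert)

    right_of = [c for c in clusters if c.side == CLIP_RIGHT_OF]
    left_of = [c for c in clusters if c.side == CLIP_LEFT_OF]

    calls: list[MEICall] = []
    used_left: set[int] = set()
    used_right: set[int] = set()
    for ri, rc in enumerate(right_of):
        # pair with a left-of cluster upstream within TSD range:
        # bp_left = left-of breakpoint, bp_right = right-of breakpoint
        partner = None
        for i, lc in enumerate(left_of):
            if i in used_left:
                continue
            if 0 <= rc.breakpoint - lc.breakpoint + 1 <= tsd_max_bp:
                partner = (i, lc)
                break
        if partner is None:
            continue
        used_left.add(partner[0])
        used_right.add(ri)
        lc = partner[1]
        bp_left, bp_right = lc.breakpoint, rc.breakpoint
        # element 5' part extends rightward past bp_right (right-of cluster);
        # element 3' part (incl. poly-A) precedes bp_left (left-of cluster)
        five_prime = rc.consensus
        three_prime = lc.consensus
        merged = _merge_consensuses(five_prime, three_prime)
        if merged is not None:
            consensus, partial, length = merged, False, len(merged)
        else:
            consensus, partial, length = five_prime + three_prime, True, None
        polyA_len, orientation = detect_polyA(three_prime, min_run=polyA_min_run)
        if polyA_len == 0:
            polyA_len, orientation = detect_polyA(five_prime,
                                                  min_run=polyA_min_run)
        if polyA_len == 0:
            continue   # no mobile-element hallmark
        tsd = reference_seq[bp_left - 1:bp_right]
        depth_ratio = _depth_ratio(profile, bp_left, bp_right)
        call = MEICall(
            contig=region.chrom, bp_left=bp_left, bp_right=bp_right,
            tsd_sequence=tsd,
            insert_consensus=consensus, insert_partial=partial,
            insert_length_estimate=length,
            polyA_length=min(polyA_len, len(consensus)),
            polyA_orientation=orientation,
            split_support=rc.support + lc.support,
            discordant_support=discordant,
            depth_ratio=depth_ratio)
        for sample, reads in alignments_by_sample.items():
            call.genotypes[sample] = genotype_sample(
                reads, bp_left, bp_right, region.chrom,
                min_clip=min_clip, min_support=min_support)
        calls.append(call)

    # unpaired clusters with poly-A evidence: low-confidence one-sided calls
    leftovers = [c for i, c in enumerate(left_of) if i not in used_left]
    leftovers += [c for i, c in enumerate(right_of) if i not in used_right]
    for c in leftovers:
        polyA_len, orientation = detect_polyA(c.consensus, min_run=polyA_min_run)
        if polyA_len == 0:
            continue
        bp = c.breakpoint
        calls.append(MEICall(
            contig=region.chrom, bp_left=bp, bp_right=bp,
            tsd_sequence=reference_seq[bp - 1:bp],
            insert_consensus=c.consensus, insert_partial=True,
            insert_length_estimate=None,
            polyA_length=min(polyA_len, len(c.consensus)),
            polyA_orientation=orientation,
            split_support=c.support, discordant_support=discordant,
            depth_ratio=_depth_ratio(profile, bp, bp), one_sided=True))
    calls.sort(key=lambda c: c.bp_left)
    return calls


def _depth_ratio(profile: DepthProfile, bp_left: int, bp_right: int) -> float:
    if profile.median_depth <= 0 or profile.depth.size == 0:
        return 0.0
    lo = max(bp_left, profile.region.start) - profile.region.start
    hi = min(bp_right, profile.region.end) - profile.region.start
    if hi < lo:
        return 0.0
    return float(profile.depth[lo:hi + 1].mean() / profile.median_depth)


# ----------------------------------------------------------------------
def calls_to_vcf(calls: Iterable[MEICall], path, contig_lengths=None) -> None:
    """Export calls as VCF 4.2 symbolic-ALT insertion records.

    POS is the anchor base before the inserted sequence (bp_left - 1); SVLEN
    is omitted when the insert length is unknown.
    """
    calls = list(calls)
    samples = sorted({s for c in calls for s in c.genotypes})
    gt = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "nocall": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS:ME:SINE,Description="SINE insertion">\n')
        for key, desc in (("TSD", "Target site duplication"),
                          ("POLYA", "Poly-A run length"),
                          ("SVLEN", "Insert length")):
            num_type = "Integer" if key in ("POLYA", "SVLEN") else "String"
            fh.write(f'##INFO=<ID={key},Number=1,Type={num_type},'
                     f'Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for c in calls:
            info = [f"TSD={c.tsd_sequence or '.'}", f"POLYA={c.polyA_length}"]
            if c.insert_length_estimate is not None:
                info.append(f"SVLEN={c.insert_length_estimate}")
            gts = "\t".join(gt.get(c.genotypes.get(s, "nocall"), "./.")
                            for s in samples)
            fh.write(f"{c.contig}\t{max(c.bp_left - 1, 1)}\t.\tN\t<INS:ME:SINE>\t."
                     f"\tPASS\t{';'.join(info)}\tGT\t{gts}\n")
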