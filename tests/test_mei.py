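"""Depth, clip-cluster, poly-A and discordant evidence, and MEI calling."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from scipy import stats

from sineseeker.mei import (
    CLIP_LEFT_OF,
    CLIP_RIGHT_OF,
    Region,
    call_mei,
    cluster_soft_clips,
    count_discordant,
    depth_profile,
    detect_polyA,
    genotype_sample,
)

HEADER = pysam.AlignmentHeader.from_dict({
    "HD": {"VN": "1.6"},
    "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
})


def read(pos1, cigar, seq=None, name="r", flag=0x1 | 0x40, mate_chrom="chr1",
         mate_pos1=None, mapq=60, tlen=300):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos1 - 1
    a.cigarstring = cigar
    length = sum(n for op, n in a.cigartuples if op in (0, 1, 4, 7, 8))
    a.query_sequence = seq if seq is not None else "A" * length
    a.mapping_quality = mapq
    a.next_reference_id = 0 if mate_chrom == "chr1" else 1
    a.next_reference_start = (mate_pos1 or pos1 + 150) - 1
    a.template_length = tlen
    return a


class TestDepthProfile:
    def test_single_read_depth_one_under_aligned_bases(self):
        profile = depth_profile([read(101, "50M")], Region("chr1", 1, 300))
        assert profile.depth[100:150].tolist() == [1] * 50
        assert profile.depth[:100].sum() == 0 and profile.depth[150:].sum() == 0

    def test_soft_clipped_bases_do_not_count(self):
        profile = depth_profile([read(101, "30M20S")], Region("chr1", 1, 300))
        assert profile.depth[100:130].tolist() == [1] * 30
        assert profile.depth[130:].sum() == 0

    def test_hom_alt_sample_elevates_exactly_the_tsd(self, bundle):
        truth = bundle.truth
        w = bundle.reads.window
        profile = depth_profile(bundle.reads.records["CASE_1"],
                                Region(truth.chrom, w[0], w[1]))
        assert len(profile.elevated) == 1
        lo, hi = profile.elevated[0]
        assert abs(lo - truth.bp_left) <= 1
        assert abs(hi - truth.bp_right) <= 1

    def test_hom_ref_sample_has_no_elevated_interval(self, bundle):
        w = bundle.reads.window
        hom_ref = [s for s, g in bundle.truth.insertion_genotypes.items()
                   if g == "hom_ref"][0]
        profile = depth_profile(bundle.reads.records[hom_ref],
                                Region(bundle.truth.chrom, w[0], w[1]))
        assert profile.elevated == []

    def test_empty_region(self):
        profile = depth_profile([], Region("chr1", 10, 10))
        assert profile.elevated == [] and profile.median_depth == 0.0


class TestClusterSoftClips:
    def test_short_clip_ignored(self):
        clusters = cluster_soft_clips([read(101, "145M5S")],
                                      Region("chr1", 1, 1000), min_support=1)
        assert clusters == []

    def test_identical_clips_give_shared_consensus(self):
        clip = "GATTACAGATTACAGATTACAGATT"
        reads = [read(101, f"50M{len(clip)}S", seq="C" * 50 + clip,
                      name=f"r{i}") for i in range(3)]
        clusters = cluster_soft_clips(reads, Region("chr1", 1, 1000))
        assert len(clusters) == 1
        assert clusters[0].side == CLIP_RIGHT_OF
        assert clusters[0].breakpoint == 150
        assert clusters[0].consensus == clip
        assert clusters[0].support == 3

    def test_below_min_support_dropped(self):
        clip = "G" * 25
        reads = [read(101, f"50M25S", seq="C" * 50 + clip, name=f"r{i}")
                 for i in range(2)]
        assert cluster_soft_clips(reads, Region("chr1", 1, 1000),
                                  min_support=3) == []

    def test_synthetic_clusters_sit_at_planted_breakpoints(self, bundle):
        truth = bundle.truth
        w = bundle.reads.window
        clusters = cluster_soft_clips(bundle.reads.records["CASE_2"],
                                      Region(truth.chrom, w[0], w[1]))
        sides = {c.side: c for c in clusters}
        assert sides[CLIP_RIGHT_OF].breakpoint == truth.bp_right
        assert sides[CLIP_LEFT_OF].breakpoint == truth.bp_left
        # left-of cluster carries the element's 3' end: the poly-A tail
        assert sides[CLIP_LEFT_OF].consensus.endswith("A" * 10)


class TestDetectPolyA:
    def test_pure_terminal_run(self):
        length, orientation = detect_polyA("GCGGCG" + "GC" + "A" * 12)
        assert (length, orientation) == (12, "forward")

    def test_poly_t_head_is_reverse_orientation(self):
        length, orientation = detect_polyA("T" * 10 + "GCAGCGGCATT")
        assert (length, orientation) == (10, "reverse")

    def test_absence(self):
        assert detect_polyA("G" * 40) == (0, None)

    def test_impure_tail_counts_with_purity(self):
        # 9 A, 1 G, 9 A: 19-window has 18/19 = 0.95 A
        length, orientation = detect_polyA("GCGC" + "A" * 9 + "G" + "A" * 9)
        assert orientation == "forward"
        assert length == 19


class TestCountDiscordant:
    def test_proper_pairs_only(self):
        reads = [read(101, "150M", name=f"r{i}", tlen=300) for i in range(5)]
        assert count_discordant(reads, Region("chr1", 1, 1000)) == 0

    def test_mate_unmapped_counted(self):
        r = read(101, "150M", flag=0x1 | 0x8 | 0x40)
        assert count_discordant([r], Region("chr1", 1, 1000)) == 1

    def test_mate_on_other_contig_counted(self):
        r = read(101, "150M", mate_chrom="chr2")
        assert count_discordant([r], Region("chr1", 1, 1000)) == 1

    def test_oversized_insert_counted(self):
        r = read(101, "150M", tlen=5000)
        assert count_discordant([r], Region("chr1", 1, 1000),
                                max_insert=1000) == 1

    def test_unpaired_data_warns_and_returns_zero(self):
        r = read(101, "150M", flag=0)
        with pytest.warns(UserWarning, match="no paired reads"):
            assert count_discordant([r], Region("chr1", 1, 1000)) == 0

    def test_relocated_fraction_within_binomial_bounds(self, bundle):
        """Mate relocation happens at the configured rate among
        element-spanning pairs."""
        p = bundle.config.discordant_mate_fraction
        for sample in ("CASE_1", "CASE_3"):
            st_ = bundle.reads.stats[sample]
            n, k = st_["spanning_pairs"], st_["relocated_pairs"]
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi
            # and the caller sees at least those relocated mates
            w = bundle.reads.window
            observed = count_discordant(bundle.reads.records[sample],
                                        Region(bundle.truth.chrom, w[0], w[1]))
            assert observed >= k


class TestCallMei:
    def test_noiseless_recovery(self, bundle):
        truth = bundle.truth
        w = bundle.reads.window
        calls = call_mei(Region(truth.chrom, w[0], w[1]),
                         bundle.reference.contigs[truth.chrom],
                         bundle.reads.records)
        two_sided = [c for c in calls if not c.one_sided]
        assert len(two_sided) == 1
        c = two_sided[0]
        assert (c.bp_left, c.bp_right) == (truth.bp_left, truth.bp_right)
        assert c.tsd_sequence == truth.tsd_sequence
        assert c.tsd_length == 15
        assert c.insert_consensus == truth.inserted_sequence
        assert c.insert_length_estimate == len(truth.inserted_sequence)
        assert c.polyA_length >= bundle.config.polyA_tail_bp
        assert c.genotypes == truth.insertion_genotypes

    def test_tsd_matches_reference_substring(self, bundle):
        truth = bundle.truth
        w = bundle.reads.window
        ref_seq = bundle.reference.contigs[truth.chrom]
        calls = call_mei(Region(truth.chrom, w[0], w[1]), ref_seq,
                         bundle.reads.records)
        for c in calls:
            assert c.tsd_sequence == ref_seq[c.bp_left - 1:c.bp_right]
            assert len(c.tsd_sequence) == c.bp_right - c.bp_left + 1

    def test_unmergeable_consensuses_reported_partial(self):
        """With 100 bp reads the two clip consensuses cannot bridge a 210 bp
        element, so the caller must report a partial consensus and an unknown
        length rather than fabricate one."""
        from conftest import make_bundle
        b = make_bundle(seed=31, read_length_bp=100, fragment_mean_bp=260,
                        fragment_sd_bp=20)
        w = b.reads.window
        calls = call_mei(Region(b.truth.chrom, w[0], w[1]),
                         b.reference.contigs[b.truth.chrom], b.reads.records)
        two_sided = [c for c in calls if not c.one_sided]
        assert len(two_sided) == 1
        assert two_sided[0].insert_partial
        assert two_sided[0].insert_length_estimate is None

    def test_raising_min_support_never_increases_calls(self, bundle):
        truth = bundle.truth
        w = bundle.reads.window
        ref_seq = bundle.reference.contigs[truth.chrom]
        counts = [len(call_mei(Region(truth.chrom, w[0], w[1]), ref_seq,
                               bundle.reads.records, min_support=ms))
                  for ms in (1, 3, 10, 10_000)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_het_genotype_stable_across_seeds(self):
        from conftest import make_bundle
        for seed in (41, 42, 43, 44, 45):
            b = make_bundle(seed=seed, n_controls=4, n_carrier_controls=4,
                            n_panel_samples=2)
            w = b.reads.window
            het_samples = [s for s, g in b.truth.insertion_genotypes.items()
                           if g == "het"]
            for s in het_samples:
                assert genotype_sample(b.reads.records[s], b.truth.bp_left,
                                       b.truth.bp_right, b.truth.chrom) == "het"
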