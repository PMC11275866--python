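"""Generator contracts: determinism, planted structure, format round trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sineseeker.genotypes import GenotypeMatrix, HET, HOM_ALT, MISSING
from sineseeker.simulate import (
    SimulationConfig,
    read_sam,
    simulate_genotype_cohort,
    simulate_reads,
    simulate_reference,
    simulate_variant_table,
)
from sineseeker.variantfilter import read_vcf, write_vcf

SMALL = dict(n_controls=4, n_carrier_controls=2, n_panel_samples=4,
             n_known_variants=5, n_decoy_variants=8)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(n_cases=0), "counts"),
        (dict(background_het_rate=1.5), "probabilities"),
        (dict(insertion_length_bp=21, polyA_tail_bp=30), "poly-A"),
        (dict(insertion_length_bp=211, polyA_tail_bp=31), "divisible by 3"),
        (dict(roh_length_bp=10 ** 9), "ROH longer"),
        (dict(stop_codon_index=100), "stop_codon_index"),
    ])
    def test_invalid_configs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimulationConfig(seed=0, **kwargs)

    def test_gene_must_fit_on_contig(self):
        with pytest.raises(ValueError, match="does not fit"):
            simulate_reference(SimulationConfig(
                seed=0, chromosome_length_bp=3000, roh_length_bp=1000))


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        paths = {}
        for run in ("a", "b"):
            cfg = SimulationConfig(seed=5, **SMALL)
            reference = simulate_reference(cfg)
            matrix, truth = simulate_genotype_cohort(cfg, reference)
            reads = simulate_reads(cfg, reference, truth)
            variants, samples, _ = simulate_variant_table(cfg, reference,
                                                          truth)
            out = tmp_path / run
            out.mkdir()
            reference.to_fasta(out / "ref.fasta")
            matrix.to_ped_map(out / "cohort")
            write_vcf(variants, samples, out / "variants.vcf")
            reads.write_sam(out / "reads")
            truth.to_json(out / "truth.json")
            paths[run] = out
        for name in ("ref.fasta", "cohort.ped", "cohort.map", "variants.vcf",
                     "truth.json", "reads/CASE_1.sam", "reads/CTRL_2.sam"):
            assert (paths["a"] / name).read_bytes() == \
                (paths["b"] / name).read_bytes(), name

    def test_different_seed_changes_reference(self):
        a = simulate_reference(SimulationConfig(seed=1))
        b = simulate_reference(SimulationConfig(seed=2))
        assert a.contigs["chr1"] != b.contigs["chr1"]


class TestReferenceStructure:
    def test_isoform_cds_difference_is_skipped_exon(self, reference):
        long_iso = reference.transcript_model.isoform("long")
        short_iso = reference.transcript_model.isoform("short")
        skipped = [e for e in long_iso.exons if e.alternatively_spliced][0]
        assert long_iso.cds_length - short_iso.cds_length == skipped.length
        assert skipped.length % 3 == 0

    def test_element_in_frame_with_poly_a_tail(self, bundle):
        element = bundle.reference.inserted_sequence
        cfg = bundle.config
        assert len(element) == cfg.insertion_length_bp
        assert len(element) % 3 == 0
        assert element.endswith("A" * cfg.polyA_tail_bp)

    def test_repeat_library_poly_a_tailed_with_divergence(self, reference):
        lib = reference.repeat_library
        assert len(lib.entries) >= 3
        for seq in lib.entries.values():
            assert seq.endswith("A" * 10)
        source = lib.entries[reference.source_repeat]
        others = [s for n, s in lib.entries.items()
                  if n != reference.source_repeat]
        for other in others:
            diff = sum(a != b for a, b in zip(source, other)) / len(source)
            assert diff > 0.10

    def test_tsd_is_reference_substring_inside_alt_exon(self, reference):
        model = reference.transcript_model
        alt_exon = [e for e in model.isoform("long").exons
                    if e.alternatively_spliced][0]
        assert alt_exon.start <= reference.bp_left
        assert reference.bp_right <= alt_exon.end
        assert len(reference.tsd_sequence) == 15


class TestCohort:
    def test_cases_homozygous_across_shared_roh(self, bundle):
        matrix, truth = bundle.matrix, bundle.truth
        idx = matrix.marker_indices(truth.chrom, *truth.shared_roh)
        for case in matrix.cases:
            calls = matrix.calls[matrix.sample_index(case), idx]
            observed = calls[calls != MISSING]
            assert np.all(observed == HOM_ALT)

    def test_every_control_heterozygous_inside_roh(self, bundle):
        matrix, truth = bundle.matrix, bundle.truth
        idx = matrix.marker_indices(truth.chrom, *truth.shared_roh)
        for control in matrix.controls:
            calls = matrix.calls[matrix.sample_index(control), idx]
            assert np.any(calls == HET)

    def test_missing_rate_within_binomial_bounds(self, bundle):
        """Missing calls on chromosomes without planted structure follow the
        configured rate."""
        matrix = bundle.matrix
        idx = np.concatenate([matrix.marker_indices("chr2"),
                              matrix.marker_indices("chr3")])
        cells = matrix.calls[:, idx]
        n = cells.size
        k = int((cells == MISSING).sum())
        lo, hi = stats.binom.interval(0.99, n,
                                      bundle.config.genotyping_missing_rate)
        assert lo <= k <= hi

    def test_rare_markers_present_as_qc_fodder(self, bundle):
        maf = bundle.matrix.minor_allele_frequency()
        assert (maf < 0.05).sum() >= 0.05 * len(maf)

    def test_ground_truth_json_round_trip(self, truth, tmp_path):
        from sineseeker.simulate import GroundTruth
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded == truth


class TestReads:
    def test_hom_ref_sample_has_no_clips_at_breakpoints(self, bundle):
        truth = bundle.truth
        hom_ref = [s for s, g in truth.insertion_genotypes.items()
                   if g == "hom_ref"][0]
        for read in bundle.reads.records[hom_ref]:
            if read.is_unmapped or read.reference_name != truth.chrom:
                continue
            for op, length in read.cigartuples:
                assert op != 4, "hom_ref read carries a soft clip"

    def test_tsd_depth_exceeds_flanks_for_hom_alt(self, bundle):
        """Both TSD copies sample the same reference bases, so the TSD mean
        depth beats equal-length flanks."""
        truth = bundle.truth
        depth = {}
        for read in bundle.reads.records["CASE_1"]:
            if read.is_unmapped or read.reference_name != truth.chrom:
                continue
            for lo, hi in read.get_blocks():
                for p in range(lo + 1, hi + 1):
                    depth[p] = depth.get(p, 0) + 1
        tsd = np.mean([depth.get(p, 0)
                       for p in range(truth.bp_left, truth.bp_right + 1)])
        span = truth.bp_right - truth.bp_left + 1
        left = np.mean([depth.get(p, 0)
                        for p in range(truth.bp_left - span, truth.bp_left)])
        right = np.mean([depth.get(p, 0)
                         for p in range(truth.bp_right + 1,
                                        truth.bp_right + 1 + span)])
        assert tsd > left and tsd > right

    def test_sam_round_trip_identity(self, bundle, tmp_path):
        paths = bundle.reads.write_sam(tmp_path)
        for sample in ("CASE_1", "CTRL_5"):
            loaded = read_sam(paths[sample])
            original = bundle.reads.records[sample]
            assert len(loaded) == len(original)
            for a, b in zip(original, loaded):
                assert a.query_name == b.query_name
                assert a.flag == b.flag
                assert a.reference_start == b.reference_start
                assert a.cigarstring == b.cigarstring
                assert a.query_sequence == b.query_sequence

    def test_cigar_consistent_with_sequence_length(self, bundle):
        for read in bundle.reads.records["CASE_2"]:
            if read.is_unmapped:
                continue
            consumed = sum(n for op, n in read.cigartuples
                           if op in (0, 1, 4, 7, 8))
            assert consumed == len(read.query_sequence)


class TestVariantTable:
    def test_planted_variant_genotypes(self, bundle):
        planted = [v for v in bundle.variants
                   if v.key == bundle.truth.planted_variant][0]
        assert planted.impact == "HIGH"
        for case in bundle.config.case_samples:
            assert planted.genotype(case) == HOM_ALT

    def test_decoys_all_fail_the_full_filter(self, bundle):
        from sineseeker.variantfilter import run_recessive_pipeline
        survivors, _ = run_recessive_pipeline(
            bundle.variants, bundle.config.case_samples,
            bundle.config.control_samples, bundle.config.panel_samples)
        assert [v.key for v in survivors] == [bundle.truth.planted_variant]

    def test_vcf_round_trip_preserves_calls(self, bundle, tmp_path):
        path = write_vcf(bundle.variants, bundle.vcf_samples,
                         tmp_path / "v.vcf")
        loaded, samples = read_vcf(path)
        assert samples == bundle.vcf_samples
        by_key = {v.key: v for v in loaded}
        for v in bundle.variants:
            parsed = by_key[v.key]
            assert parsed.impact == v.impact
            assert all(parsed.genotype(s) == v.genotype(s) for s in samples)

    def test_exclusion_panel_typed_and_clear(self, bundle):
        from sineseeker.variantfilter import screen_known_variants
        result = screen_known_variants(bundle.variants, bundle.exclusion_panel,
                                       bundle.config.case_samples)
        assert result.all_clear
        assert not result.untyped


class TestGenotypeMatrixIO:
    def test_ped_map_round_trip(self, bundle, tmp_path):
        matrix = bundle.matrix
        matrix.to_ped_map(tmp_path / "cohort")
        loaded = GenotypeMatrix.from_ped_map(tmp_path / "cohort")
        assert loaded.samples == matrix.samples
        assert loaded.phenotypes == matrix.phenotypes
        # identical het/missing pattern; hom polarity may flip with allele
        # relabelling, zygosity may not
        assert np.array_equal(loaded.calls == HET, matrix.calls == HET)
        assert np.array_equal(loaded.calls == MISSING,
                              matrix.calls == MISSING)

    def test_vcf_round_trip(self, bundle, tmp_path):
        matrix = bundle.matrix
        matrix.to_vcf(tmp_path / "cohort.vcf")
        loaded = GenotypeMatrix.from_vcf(tmp_path / "cohort.vcf")
        assert loaded.samples == matrix.samples
        assert loaded.phenotypes == matrix.phenotypes
        assert np.array_equal(loaded.calls, matrix.calls)
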