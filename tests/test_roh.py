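"""QC filtering, ROH detection (vs a brute-force oracle) and critical regions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sineseeker.genotypes import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
)
from sineseeker.roh import (
    CriticalRegion,
    ROHParams,
    detect_roh,
    qc_filter,
    refine_by_het_calls,
    shared_critical_region,
)


def make_matrix(calls, positions=None, chrom="chr1", phenotypes=None,
                samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_markers = calls.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_markers)]
    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(n_markers)],
        "chrom": [chrom] * n_markers,
        "pos": positions,
        "a1": ["A"] * n_markers,
        "a2": ["B"] * n_markers,
    })
    samples = samples or [f"S{i}" for i in range(n_samples)]
    phenotypes = phenotypes or ["control"] * n_samples
    return GenotypeMatrix(markers=markers, calls=calls, samples=samples,
                          phenotypes=phenotypes)


# ----------------------------------------------------------------------
class TestQCFilter:
    def test_low_maf_marker_removed(self):
        # het in 1 of 20 samples: MAF 1/40 = 0.025 < 0.05
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[0, 0] = HET
        calls[:10, 1] = HOM_ALT          # common marker survives
        matrix = make_matrix(calls)
        filtered, report = qc_filter(matrix)
        assert report.markers_removed_maf == 1
        assert filtered.n_markers == 1
        assert filtered.markers.iloc[0]["marker_id"] == "m1"

    def test_disabled_filter_is_identity(self):
        calls = np.array([[HOM_REF, HET, MISSING],
                          [HOM_ALT, HOM_REF, HOM_REF]], dtype=np.int8)
        matrix = make_matrix(calls)
        filtered, report = qc_filter(matrix, maf_min=0.0, missing_max=1.0)
        assert filtered.n_markers == 3
        assert report.markers_removed == 0

    def test_missingness_threshold_26_samples(self):
        # 3 of 26 missing = 11.5% > 10% -> removed
        calls = np.tile([HET], (26, 2)).astype(np.int8)
        calls[:3, 0] = MISSING
        matrix = make_matrix(calls)
        filtered, report = qc_filter(matrix)
        assert report.markers_removed_missing == 1
        assert filtered.n_markers == 1

    def test_all_markers_removed_raises_with_counts(self):
        calls = np.zeros((4, 2), dtype=np.int8)   # all hom_ref: MAF 0
        matrix = make_matrix(calls)
        with pytest.raises(ValueError, match="failed MAF"):
            qc_filter(matrix)

    def test_raising_maf_min_never_increases_markers(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        matrix = make_matrix(calls)
        counts = [qc_filter(matrix, maf_min=m, missing_max=1.0)[0].n_markers
                  for m in (0.0, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts, reverse=True)


# ----------------------------------------------------------------------
def brute_force_roh(calls, positions, params: ROHParams):
    """Independent naive enumerator of the sliding-window run criteria."""
    n = len(calls)
    w = params.window_snps
    if n < w:
        return []
    hom_windows = []
    for i in range(n - w + 1):
        window = calls[i:i + w]
        n_het = sum(1 for c in window if c == HET)
        n_mis = sum(1 for c in window if c == MISSING)
        hom_windows.append(n_het <= params.het_allow
                           and n_mis <= params.missing_allow)
    eligible = []
    for j in range(n):
        covering = [i for i in range(len(hom_windows)) if i <= j <= i + w - 1]
        hits = sum(1 for i in covering if hom_windows[i])
        eligible.append(hits / len(covering) >= params.hit_threshold)
    # maximal runs of eligible markers, split at large gaps
    runs, current = [], []
    for j in range(n):
        if not eligible[j]:
            if current:
                runs.append(current)
                current = []
            continue
        if current and positions[j] - positions[current[-1]] > params.gap_max_bp:
            runs.append(current)
            current = []
        current.append(j)
    if current:
        runs.append(current)
    out = []
    for run in runs:
        length = positions[run[-1]] - positions[run[0]] + 1
        if len(run) < params.min_markers:
            continue
        if length < params.min_length_bp:
            continue
        if length / len(run) > params.density_max_kb * 1000:
            continue
        out.append((positions[run[0]], positions[run[-1]], len(run)))
    return out


SMALL_PARAMS = ROHParams(window_snps=10, het_allow=1, missing_allow=2,
                         min_markers=5, min_length_bp=1, gap_max_bp=10 ** 9,
                         density_max_kb=10 ** 6)


class TestDetectROH:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        # blocks of homozygosity interleaved with noisy stretches
        calls = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=n,
                           p=[0.35, 0.35, 0.2, 0.1]).astype(np.int8)
        block = rng.integers(5, 40)
        start = rng.integers(0, max(1, n - block))
        calls[start:start + block] = HOM_ALT
        positions = np.cumsum(rng.integers(1, 5000, size=n))
        matrix = make_matrix(calls.reshape(1, -1), positions=list(positions))
        got = detect_roh(matrix, SMALL_PARAMS)["S0"]
        expected = brute_force_roh(list(calls), list(positions), SMALL_PARAMS)
        assert [(s.start, s.end, s.n_markers) for s in got] == expected

    def test_all_het_sample_has_no_segments(self):
        calls = np.full((1, 60), HET, dtype=np.int8)
        matrix = make_matrix(calls)
        assert detect_roh(matrix, SMALL_PARAMS)["S0"] == []

    def test_short_chromosome_skipped_with_warning(self):
        calls = np.zeros((1, 5), dtype=np.int8)
        matrix = make_matrix(calls)
        with pytest.warns(UserWarning, match="skipped"):
            segments = detect_roh(matrix, ROHParams(window_snps=50))
        assert segments["S0"] == []

    def test_raising_het_allow_never_shrinks_segments(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([HOM_REF, HET, HOM_ALT], size=(1, 150),
                           p=[0.45, 0.1, 0.45]).astype(np.int8)
        matrix = make_matrix(calls)
        lo = detect_roh(matrix, SMALL_PARAMS)["S0"]
        import dataclasses
        hi_params = dataclasses.replace(SMALL_PARAMS, het_allow=3)
        hi = detect_roh(matrix, hi_params)["S0"]
        covered_lo = sum(s.length_bp for s in lo)
        covered_hi = sum(s.length_bp for s in hi)
        assert covered_hi >= covered_lo
        for seg in lo:
            assert any(h.start <= seg.start and h.end >= seg.end for h in hi)

    def test_planted_roh_recovered_within_one_marker(self, bundle):
        matrix, _ = qc_filter(bundle.matrix)
        segments = detect_roh(matrix, ROHParams(), samples=matrix.cases)
        pos = matrix.markers.loc[matrix.markers["chrom"] == bundle.truth.chrom,
                                 "pos"].to_numpy()
        for sample, segs in segments.items():
            assert len(segs) == 1
            lo, hi = bundle.truth.case_roh[sample]
            exp_lo = pos[pos >= lo].min()
            exp_hi = pos[pos <= hi].max()
            assert abs(np.searchsorted(pos, segs[0].start)
                       - np.searchsorted(pos, exp_lo)) <= 1
            assert abs(np.searchsorted(pos, segs[0].end)
                       - np.searchsorted(pos, exp_hi)) <= 1


# ----------------------------------------------------------------------
class TestCriticalRegion:
    def test_synthetic_cohort_yields_one_region_containing_insertion(self, bundle):
        matrix, _ = qc_filter(bundle.matrix)
        segments = detect_roh(matrix, ROHParams(), samples=matrix.cases)
        regions = shared_critical_region(segments, matrix)
        assert len(regions) == 1
        refined = refine_by_het_calls(regions[0], matrix)
        assert refined.contains(bundle.truth.chrom,
                                bundle.truth.insertion_site)
        assert refined.contains(*bundle.truth.planted_variant[:2])

    def test_case_without_segments_gives_empty_result(self, bundle):
        matrix = bundle.matrix
        segments = {"CASE_1": [], "CASE_2": []}
        assert shared_critical_region(segments, matrix) == []

    def test_homozygous_control_excludes_interval(self):
        calls = np.zeros((2, 20), dtype=np.int8)
        calls[0, :] = HOM_ALT                        # case ROH everywhere
        calls[1, :] = HOM_REF                        # control fully homozygous
        matrix = make_matrix(calls, phenotypes=["case", "control"],
                             samples=["CASE", "CTRL"])
        from sineseeker.roh import ROHSegment
        segments = {"CASE": [ROHSegment("CASE", "chr1", 1000, 20000, 20, 0)]}
        assert shared_critical_region(segments, matrix) == []
        # a single het call in the control rescues the interval
        calls[1, 10] = HET
        matrix2 = make_matrix(calls, phenotypes=["case", "control"],
                              samples=["CASE", "CTRL"])
        regions = shared_critical_region(segments, matrix2)
        assert len(regions) == 1 and regions[0].start == 1000


class TestRefineByHetCalls:
    def region(self, start, end):
        return CriticalRegion(chrom="chr1", start=start, end=end,
                              case_ids=("CASE",), boundary_markers=("", ""))

    def test_flanking_hets_trim_to_adjacent_markers(self):
        calls = np.array([[HET, HOM_ALT, HOM_ALT, HOM_ALT, HET]], dtype=np.int8)
        matrix = make_matrix(calls, phenotypes=["case"], samples=["CASE"])
        refined = refine_by_het_calls(self.region(1000, 5000), matrix)
        assert (refined.start, refined.end) == (2000, 4000)

    def test_no_het_leaves_region_unchanged(self):
        calls = np.array([[HOM_ALT, MISSING, HOM_ALT, HOM_ALT]], dtype=np.int8)
        matrix = make_matrix(calls, phenotypes=["case"], samples=["CASE"])
        region = self.region(1000, 4000)
        assert refine_by_het_calls(region, matrix) == region

    def test_interior_het_splits_and_longest_piece_wins(self):
        # het at marker index 2 splits 7 markers into [0,1] and [3..6]
        calls = np.array([[HOM_ALT, HOM_ALT, HET, HOM_ALT, HOM_ALT,
                           HOM_ALT, HOM_ALT]], dtype=np.int8)
        matrix = make_matrix(calls, phenotypes=["case"], samples=["CASE"])
        refined = refine_by_het_calls(self.region(1000, 7000), matrix)
        assert (refined.start, refined.end) == (4000, 7000)

    def test_recovery_over_seeds_contains_insertion(self):
        from conftest import make_bundle
        for seed in (101, 102, 103):
            b = make_bundle(seed=seed)
            matrix, _ = qc_filter(b.matrix)
            segments = detect_roh(matrix, ROHParams(), samples=matrix.cases)
            regions = shared_critical_region(segments, matrix)
            assert regions, f"seed {seed}: no region"
            refined = refine_by_het_calls(regions[0], matrix)
            assert refined.contains(b.truth.chrom, b.truth.insertion_site)
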