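"""QC filtering, runs-of-homozygosity detection and critical-region logic.

The ROH scan follows the PLINK 1.9 sliding-window scheme: a fixed-size window
of markers slides one marker at a time; a window is called homozygous when it
contains at most ``het_allow`` heterozygous and ``missing_allow`` missing
calls; each marker's hit fraction is the proportion of windows covering it
that are homozygous, and markers at or above ``hit_threshold`` are eligible.
Maximal runs of eligible markers are reported when they satisfy the marker
count, physical length, inter-marker gap and density criteria.

The defaults below follow PLINK 1.9 except ``min_markers``, which is scaled
to sparse desk-scale panels (PLINK's genome-scale default of 100 is available
as :data:`PLINK_MIN_MARKERS`).

Coordinates are 1-based inclusive throughout; :func:`segments_to_bed`
converts to 0-based half-open BED on export.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sineseeker.genotypes import GenotypeMatrix, HET, MISSING

logger = logging.getLogger(__name__)

PLINK_MIN_MARKERS = 100


@dataclasses.dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH scan parameters (PLINK-1.9 style)."""

    window_snps: int = 50
    het_allow: int = 1
    missing_allow: int = 5
    hit_threshold: float = 0.05
    min_markers: int = 25
    min_length_bp: int = 1_000_000
    gap_max_bp: int = 1_000_000
    density_max_kb: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_markers < 1:
            raise ValueError("window_snps and min_markers must be >= 1")
        if not 0.0 <= self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class QCReport:
    markers_removed_maf: int
    markers_removed_missing: int
    maf_min: float
    missing_max: float

    @property
    def markers_removed(self) -> int:
        return self.markers_removed_maf + self.markers_removed_missing


@dataclasses.dataclass(frozen=True)
class ROHSegment:
    """A homozygous run in one sample; coordinates 1-based inclusive."""

    sample: str
    chrom: str
    start: int
    end: int
    n_markers: int
    n_het: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class CriticalRegion:
    """Case-shared, control-excluded homozygous interval."""

    chrom: str
    start: int
    end: int
    case_ids: tuple[str, ...]
    boundary_markers: tuple[str, str]

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ----------------------------------------------------------------------
def qc_filter(matrix: GenotypeMatrix, maf_min: float = 0.05,
              missing_max: float = 0.10) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with MAF < ``maf_min`` or missing fraction > ``missing_max``.

    MAF is computed over all non-missing calls of all samples.  Raises
    ``ValueError`` naming both removal counts if no marker survives.
    """
    if matrix.n_samples < 2:
        raise ValueError("QC requires at least 2 samples")
    maf = matrix.minor_allele_frequency()
    miss = matrix.missing_fraction()
    fail_maf = maf < maf_min
    fail_miss = miss > missing_max
    keep = ~(fail_maf | fail_miss)
    report = QCReport(
        markers_removed_maf=int(fail_maf.sum()),
        markers_removed_missing=int((fail_miss & ~fail_maf).sum()),
        maf_min=maf_min,
        missing_max=missing_max,
    )
    if not keep.any():
        raise ValueError(
            f"no markers survive QC: {int(fail_maf.sum())} failed MAF < {maf_min}, "
            f"{int(fail_miss.sum())} failed missing > {missing_max}"
        )
    return matrix.subset_markers(np.flatnonzero(keep)), report


# ----------------------------------------------------------------------
def _eligible_markers(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean eligibility per marker from the sliding-window hit fraction.

    ``calls`` is one sample's call vector on one chromosome.
    """
    n = calls.size
    w = params.window_snps
    het = (calls == HET).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    # window sums via cumulative sums; window i covers markers [i, i+w)
    n_win = n - w + 1
    cs_het = np.concatenate(([0], np.cumsum(het)))
    cs_mis = np.concatenate(([0], np.cumsum(mis)))
    win_het = cs_het[w:] - cs_het[:-w]
    win_mis = cs_mis[w:] - cs_mis[:-w]
    hom_win = (win_het <= params.het_allow) & (win_mis <= params.missing_allow)
    # marker j covered by windows i in [max(0, j-w+1), min(j, n_win-1)]
    cs_hom = np.concatenate(([0], np.cumsum(hom_win.astype(np.int64))))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = cs_hom[hi + 1] - cs_hom[lo]
    cover = hi - lo + 1
    return hits / cover >= params.hit_threshold


def _runs_to_segments(eligible: np.ndarray, pos: np.ndarray, calls: np.ndarray,
                      chrom: str, sample: str, params: ROHParams) -> list[ROHSegment]:
    segments: list[ROHSegment] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return segments
    # split maximal runs of consecutive eligible markers, further split at
    # physical gaps exceeding gap_max_bp
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.gap_max_bp)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        run = idx[s:e + 1]
        n_markers = run.size
        length = int(pos[run[-1]] - pos[run[0]] + 1)
        if n_markers < params.min_markers:
            continue
        if length < params.min_length_bp:
            continue
        if length / n_markers > params.density_max_kb * 1000:
            continue
        segments.append(ROHSegment(
            sample=sample, chrom=chrom,
            start=int(pos[run[0]]), end=int(pos[run[-1]]),
            n_markers=int(n_markers),
            n_het=int((calls[run] == HET).sum()),
        ))
    return segments


def detect_roh(matrix: GenotypeMatrix, params: ROHParams = ROHParams(),
               samples: Sequence[str] | None = None) -> dict[str, list[ROHSegment]]:
    """Detect homozygous runs per sample; returns {sample: [ROHSegment, ...]}.

    Chromosomes with fewer markers than ``window_snps`` are skipped with a
    warning.
    """
    if samples is None:
        samples = matrix.samples
    result: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for chrom in matrix.chromosomes:
        idx = matrix.marker_indices(chrom)
        if idx.size < params.window_snps:
            warnings.warn(
                f"chromosome {chrom} has {idx.size} markers < window of "
                f"{params.window_snps}; skipped", stacklevel=2)
            continue
        pos = matrix.markers["pos"].to_numpy()[idx]
        for sample in samples:
            calls = matrix.calls[matrix.sample_index(sample), idx]
            eligible = _eligible_markers(calls, params)
            result[sample].extend(
                _runs_to_segments(eligible, pos, calls, chrom, sample, params))
    return result


# ----------------------------------------------------------------------
def _intersect_interval_lists(lists: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Intersection of unions of 1-based inclusive intervals."""
    if not lists:
        return []
    current = sorted(lists[0])
    for other in lists[1:]:
        other = sorted(other)
        out: list[tuple[int, int]] = []
        i = j = 0
        while i < len(current) and j < len(other):
            a, b = current[i], other[j]
            lo, hi = max(a[0], b[0]), min(a[1], b[1])
            if lo <= hi:
                out.append((lo, hi))
            if a[1] < b[1]:
                i += 1
            else:
                j += 1
        current = out
        if not current:
            break
    return current


def _control_is_homozygous(matrix: GenotypeMatrix, sample: str,
                           chrom: str, start: int, end: int) -> bool:
    """True if the sample has no het call across the interval's markers
    (missing calls ignored)."""
    idx = matrix.marker_indices(chrom, start, end)
    calls = matrix.calls[matrix.sample_index(sample), idx]
    return not np.any(calls == HET)


def shared_critical_region(
    case_segments: Mapping[str, list[ROHSegment]],
    matrix: GenotypeMatrix,
    control_samples: Sequence[str] | None = None,
) -> list[CriticalRegion]:
    """Intersect case ROHs and exclude intervals where any control is fully
    homozygous; returns regions sorted by length descending.

    Samples of unknown status are treated as controls for the exclusion step
    (they cannot prove shared case homozygosity, but they can disprove
    exclusivity); a debug log line flags them.
    """
    cases = list(case_segments)
    if not cases or all(not segs for segs in case_segments.values()):
        return []
    if any(not segs for segs in case_segments.values()):
        return []
    if control_samples is None:
        control_samples = [
            s for s, p in zip(matrix.samples, matrix.phenotypes)
            if p in ("control", "unknown")
        ]
        unknowns = [s for s, p in zip(matrix.samples, matrix.phenotypes) if p == "unknown"]
        if unknowns:
            logger.info("treating %d unknown-status samples as controls: %s",
                        len(unknowns), unknowns)
    chroms = {seg.chrom for segs in case_segments.values() for seg in segs}
    regions: list[CriticalRegion] = []
    for chrom in sorted(chroms):
        per_case = [
            [(seg.start, seg.end) for seg in case_segments[c] if seg.chrom == chrom]
            for c in cases
        ]
        for lo, hi in _intersect_interval_lists(per_case):
            if any(_control_is_homozygous(matrix, ctrl, chrom, lo, hi)
                   for ctrl in control_samples):
                continue
            idx = matrix.marker_indices(chrom, lo, hi)
            mids = matrix.markers["marker_id"].to_numpy()
            boundary = (
                (str(mids[idx[0]]), str(mids[idx[-1]])) if idx.size else ("", "")
            )
            regions.append(CriticalRegion(
                chrom=chrom, start=int(lo), end=int(hi),
                case_ids=tuple(cases), boundary_markers=boundary))
    regions.sort(key=lambda r: r.length_bp, reverse=True)
    return regions


def refine_by_het_calls(region: CriticalRegion,
                        matrix: GenotypeMatrix) -> CriticalRegion:
    """Trim the region to the longest sub-interval free of case het calls.

    Boundaries are set to the outermost case-homozygous markers flanked by
    the nearest case het calls.  A het call interior to the region splits it;
    the longest piece is returned and alternates are logged.
    """
    case_idx = [matrix.sample_index(s) for s in region.case_ids
                if s in matrix.samples]
    idx = matrix.marker_indices(region.chrom, region.start, region.end)
    if idx.size == 0 or not case_idx:
        return region
    calls = matrix.calls[np.ix_(case_idx, idx)]
    any_het = np.any(calls == HET, axis=0)
    if not any_het.any():
        return region
    pos = matrix.markers["pos"].to_numpy()[idx]
    mids = matrix.markers["marker_id"].to_numpy()[idx]
    # maximal runs of het-free markers
    candidates: list[tuple[int, int]] = []  # index ranges into idx
    start = None
    for j in range(idx.size):
        if any_het[j]:
            if start is not None:
                candidates.append((start, j - 1))
                start = None
        elif start is None:
            start = j
    if start is not None:
        candidates.append((start, idx.size - 1))
    candidates = [c for c in candidates if c[0] <= c[1]]
    if not candidates:
        return region
    lengths = [pos[e] - pos[s] + 1 for s, e in candidates]
    best = candidates[int(np.argmax(lengths))]
    if len(candidates) > 1:
        logger.info("case het calls split region %s:%d-%d into %d pieces; "
                    "longest returned", region.chrom, region.start, region.end,
                    len(candidates))
    s, e = best
    return CriticalRegion(
        chrom=region.chrom, start=int(pos[s]), end=int(pos[e]),
        case_ids=region.case_ids,
        boundary_markers=(str(mids[s]), str(mids[e])))


# ----------------------------------------------------------------------
def segments_to_bed(segments: Iterable[ROHSegment], path: str | Path) -> Path:
    """Export segments as BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.sample}\n")
    return path


def segments_to_tsv(segments: Iterable[ROHSegment], path: str | Path) -> Path:
    rows = [dataclasses.asdict(s) for s in segments]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_markers", "n_het"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)
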