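"""Genotype matrix container with PED/MAP and VCF I/O.

Calls are stored as a dense ``int8`` array (samples x markers) using the
codes below.  Markers are kept in a :class:`pandas.DataFrame` sorted by
(chromosome, position); positions are unique per chromosome.  Genotypes are
unphased biallelic calls — exactly what a SNP array delivers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

PHENOTYPES = ("case", "control", "unknown")

_MARKER_COLUMNS = ["marker_id", "chrom", "pos", "a1", "a2"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x markers biallelic genotype calls with phenotype labels.

    Parameters
    ----------
    markers:
        DataFrame with columns ``marker_id, chrom, pos, a1, a2``; ``pos`` is
        1-based.  Must be sorted by (chrom, pos) with unique positions per
        chromosome.
    calls:
        ``int8`` array of shape (n_samples, n_markers) with values in
        {HOM_REF, HET, HOM_ALT, MISSING}.
    samples:
        Sample identifiers (unique).
    phenotypes:
        One of ``case``, ``control``, ``unknown`` per sample.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    samples: list[str]
    phenotypes: list[str]

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        missing_cols = set(_MARKER_COLUMNS) - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"marker table lacks columns: {sorted(missing_cols)}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = set(self.phenotypes) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        # sortedness / uniqueness per chromosome
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"markers on {chrom} not strictly sorted by position")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def samples_with_phenotype(self, phenotype: str) -> list[str]:
        return [s for s, p in zip(self.samples, self.phenotypes) if p == phenotype]

    @property
    def cases(self) -> list[str]:
        return self.samples_with_phenotype("case")

    @property
    def controls(self) -> list[str]:
        return self.samples_with_phenotype("control")

    def marker_indices(self, chrom: str, start: int | None = None,
                       end: int | None = None) -> np.ndarray:
        """Indices of markers on ``chrom`` with start <= pos <= end (inclusive)."""
        mask = (self.markers["chrom"] == chrom).to_numpy()
        if start is not None:
            mask &= self.markers["pos"].to_numpy() >= start
        if end is not None:
            mask &= self.markers["pos"].to_numpy() <= end
        return np.flatnonzero(mask)

    # ------------------------------------------------------------------
    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker MAF over all non-missing calls of all samples."""
        calls = self.calls
        observed = calls != MISSING
        alt = np.where(observed, calls, 0).sum(axis=0).astype(float)
        total = 2.0 * observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(total > 0, alt / total, 0.0)
        return np.minimum(af, 1.0 - af)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def subset_markers(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            markers=self.markers.iloc[indices].reset_index(drop=True),
            calls=self.calls[:, indices],
            samples=list(self.samples),
            phenotypes=list(self.phenotypes),
        )

    # ------------------------------------------------------------------
    # PED/MAP
    def to_ped_map(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write PLINK-style .ped/.map text files; returns the two paths."""
        prefix = Path(prefix)
        map_path = prefix.with_suffix(".map")
        ped_path = prefix.with_suffix(".ped")
        with open(map_path, "w") as fh:
            for row in self.markers.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.marker_id}\t0\t{row.pos}\n")
        pheno_code = {"control": "1", "case": "2", "unknown": "0"}
        allele_strings = _call_to_alleles(self.markers)
        with open(ped_path, "w") as fh:
            for i, sample in enumerate(self.samples):
                fields = ["FAM", sample, "0", "0", "0", pheno_code[self.phenotypes[i]]]
                row = self.calls[i]
                fields.extend(allele_strings[code][j] for j, code in enumerate(row))
                fh.write(" ".join(fields) + "\n")
        return ped_path, map_path

    @classmethod
    def from_ped_map(cls, prefix: str | Path) -> "GenotypeMatrix":
        prefix = Path(prefix)
        map_rows = []
        with open(prefix.with_suffix(".map")) as fh:
            for line in fh:
                chrom, mid, _, pos = line.split()
                map_rows.append((mid, chrom, int(pos)))
        samples, phenos, calls = [], [], []
        pheno_name = {"1": "control", "2": "case"}
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                fields = line.split()
                samples.append(fields[1])
                phenos.append(pheno_name.get(fields[5], "unknown"))
                alleles = fields[6:]
                row = np.empty(len(map_rows), dtype=np.int8)
                allele_pairs = [[None, None] for _ in map_rows]
                for j in range(len(map_rows)):
                    a, b = alleles[2 * j], alleles[2 * j + 1]
                    allele_pairs[j] = [a, b]
                calls.append(allele_pairs)
        # infer per-marker alleles: a1 = first non-zero allele seen, a2 = other
        n_markers = len(map_rows)
        a1 = ["A"] * n_markers
        a2 = ["B"] * n_markers
        for j in range(n_markers):
            seen: list[str] = []
            for pairs in calls:
                for a in pairs[j]:
                    if a != "0" and a not in seen:
                        seen.append(a)
            if seen:
                a1[j] = seen[0]
                a2[j] = seen[1] if len(seen) > 1 else seen[0]
        matrix = np.empty((len(samples), n_markers), dtype=np.int8)
        for i, pairs in enumerate(calls):
            for j, (a, b) in enumerate(pairs):
                if a == "0" or b == "0":
                    matrix[i, j] = MISSING
                elif a == b:
                    matrix[i, j] = HOM_REF if a == a1[j] else HOM_ALT
                else:
                    matrix[i, j] = HET
        markers = pd.DataFrame(
            {
                "marker_id": [r[0] for r in map_rows],
                "chrom": [r[1] for r in map_rows],
                "pos": [r[2] for r in map_rows],
                "a1": a1,
                "a2": a2,
            }
        )
        return cls(markers=markers, calls=matrix, samples=samples, phenotypes=phenos)

    # ------------------------------------------------------------------
    # VCF
    def to_vcf(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> Path:
        """Write the matrix as an uncompressed VCF 4.2 with GT fields."""
        path = Path(path)
        gt_string = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            contigs = contig_lengths or {
                c: int(self.markers.loc[self.markers["chrom"] == c, "pos"].max()) + 1
                for c in self.chromosomes
            }
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            for sample, pheno in zip(self.samples, self.phenotypes):
                fh.write(f"##SAMPLE=<ID={sample},Phenotype={pheno}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for j, row in enumerate(self.markers.itertuples(index=False)):
                ref = row.a1 if row.a1 in "ACGT" else "A"
                alt = row.a2 if row.a2 in "ACGT" and row.a2 != ref else ("C" if ref != "C" else "G")
                gts = "\t".join(gt_string[int(c)] for c in self.calls[:, j])
                fh.write(f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{ref}\t{alt}"
                         f"\t.\tPASS\t.\tGT\t{gts}\n")
        return path

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        samples: list[str] = []
        phenos: dict[str, str] = {}
        rows = []
        call_rows = []
        gt_code = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT,
                   "./.": MISSING, ".": MISSING,
                   "0|0": HOM_REF, "0|1": HET, "1|0": HET, "1|1": HOM_ALT}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##SAMPLE"):
                    body = line.strip()[len("##SAMPLE=<"):-1]
                    fields = dict(kv.split("=", 1) for kv in body.split(","))
                    phenos[fields["ID"]] = fields.get("Phenotype", "unknown")
                    continue
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    samples = line.rstrip("\n").split("\t")[9:]
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, mid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
                rows.append((mid, chrom, pos, ref, alt))
                gt_idx = fields[8].split(":").index("GT")
                call_rows.append(
                    [gt_code.get(f.split(":")[gt_idx], MISSING) for f in fields[9:]]
                )
        markers = pd.DataFrame(rows, columns=_MARKER_COLUMNS)
        calls = np.array(call_rows, dtype=np.int8).T if call_rows else np.zeros((len(samples), 0), np.int8)
        phenotypes = [phenos.get(s, "unknown") for s in samples]
        return cls(markers=markers, calls=calls, samples=samples, phenotypes=phenotypes)


def _call_to_alleles(markers: pd.DataFrame) -> dict[int, list[str]]:
    """Per call code, the two-allele PED string for each marker."""
    a1 = markers["a1"].tolist()
    a2 = markers["a2"].tolist()
    return {
        HOM_REF: [f"{a} {a}" for a in a1],
        HET: [f"{a} {b}" for a, b in zip(a1, a2)],
        HOM_ALT: [f"{b} {b}" for b in a2],
        MISSING: ["0 0"] * len(a1),
    }
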