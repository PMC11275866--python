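"""Recessive-model filtering of annotated variant calls.

Stages mirror the discovery workflow for a fully penetrant recessive trait:
(1) clear the cases of already-known disease variants from an exclusion
panel; (2) keep variants homozygous-alternate in every case and never
homozygous-alternate in a within-cohort control, at or above a minimum
predicted impact; (3) drop anything common in an external population panel;
(4) optionally restrict to a mapped critical region.

A missing genotype in a case disqualifies a variant (observed homozygosity
is required to prove the recessive model); a missing control genotype is
ignored.  'Common' in the population panel means alt-allele frequency above
``af_max`` or, by default, any panel individual homozygous-alternate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from sineseeker.genotypes import HOM_ALT, HOM_REF, HET, MISSING
from sineseeker.roh import CriticalRegion

IMPACT_ORDER = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}

VariantKey = tuple[str, int, str, str]


@dataclasses.dataclass
class VariantRecord:
    """One biallelic site with per-sample genotype codes and an impact class."""

    chrom: str
    pos: int
    ref: str
    alt: str
    impact: str
    genotypes: dict[str, int]
    info: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele.upper()) - set("ACGTN"):
                raise ValueError(f"invalid {label} allele {allele!r}")
        if self.impact not in IMPACT_ORDER:
            raise ValueError(f"unknown impact {self.impact!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample: str) -> int:
        return self.genotypes.get(sample, MISSING)


@dataclasses.dataclass
class ExclusionPanel:
    """Known disease variants: (chrom, pos, ref, alt) -> disease label."""

    variants: dict[VariantKey, str]

    def __post_init__(self) -> None:
        if len(self.variants) != len(set(self.variants)):
            raise ValueError("duplicate panel keys")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExclusionPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(variants={
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): str(r.disease)
            for r in df.itertuples(index=False)})

    def to_tsv(self, path: str | Path) -> Path:
        rows = [(c, p, r, a, d) for (c, p, r, a), d in self.variants.items()]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "disease"]) \
            .to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclasses.dataclass
class ScreenResult:
    """Outcome of the known-variant screen."""

    hits: list[tuple[VariantKey, str, list[str]]]   # key, disease, hom-alt cases
    untyped: list[tuple[VariantKey, str]]

    @property
    def all_clear(self) -> bool:
        return not self.hits


@dataclasses.dataclass
class FilterReport:
    """Per-stage survivor counts; monotonically non-increasing."""

    stage_counts: dict[str, int]
    surviving: list[VariantKey]
    private_flagged: list[VariantKey] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        counts = list(self.stage_counts.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be non-increasing")

    def to_json_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "surviving": [list(k) for k in self.surviving],
            "private_flagged": [list(k) for k in self.private_flagged],
        }


# ----------------------------------------------------------------------
def screen_known_variants(variants: Sequence[VariantRecord],
                          panel: ExclusionPanel,
                          case_samples: Sequence[str]) -> ScreenResult:
    """Check that no case is homozygous-alternate for any known panel variant.

    A case 'tests clear' of a panel variant when it is not hom-alt for it.
    Panel keys absent from the genotype data are reported as untyped (not
    clear).  An empty panel passes vacuously.
    """
    by_key = {v.key: v for v in variants}
    hits, untyped = [], []
    for key, disease in panel.variants.items():
        record = by_key.get(key)
        if record is None:
            untyped.append((key, disease))
            continue
        hom_cases = [s for s in case_samples if record.genotype(s) == HOM_ALT]
        if hom_cases:
            hits.append((key, disease, hom_cases))
    return ScreenResult(hits=hits, untyped=untyped)


def recessive_filter(variants: Sequence[VariantRecord],
                     cases: Sequence[str], controls: Sequence[str],
                     impact_min: str = "HIGH",
                     ) -> tuple[list[VariantRecord], FilterReport]:
    """Keep variants hom-alt in every case, never hom-alt in a control, with
    impact >= ``impact_min``."""
    if not cases:
        raise ValueError("at least one case required")
    overlap = set(cases) & set(controls)
    if overlap:
        raise ValueError(f"samples in both case and control lists: {sorted(overlap)}")
    min_rank = IMPACT_ORDER[impact_min]
    after_case = [v for v in variants
                  if all(v.genotype(s) == HOM_ALT for s in cases)]
    after_control = [v for v in after_case
                     if not any(v.genotype(s) == HOM_ALT for s in controls)]
    survivors = [v for v in after_control if IMPACT_ORDER[v.impact] >= min_rank]
    report = FilterReport(
        stage_counts={
            "input": len(variants),
            "case_hom_alt": len(after_case),
            "control_excluded": len(after_control),
            "impact": len(survivors),
        },
        surviving=[v.key for v in survivors],
    )
    return survivors, report


def panel_frequency_filter(variants: Sequence[VariantRecord],
                           panel_samples: Sequence[str],
                           af_max: float = 0.05,
                           hom_disqualifies: bool = True,
                           cohort_samples: Sequence[str] = (),
                           ) -> tuple[list[VariantRecord], list[VariantKey]]:
    """Remove variants common in an external population panel.

    A variant is removed when its panel alt-allele frequency exceeds
    ``af_max`` or (if ``hom_disqualifies``) any panel sample is hom-alt.
    Variants with no called panel genotype are retained and flagged private
    — the private-variant outcome.  Returns (survivors, private_keys).
    """
    overlap = set(panel_samples) & set(cohort_samples)
    if overlap:
        raise ValueError(f"panel samples overlap the cohort: {sorted(overlap)}")
    survivors: list[VariantRecord] = []
    private: list[VariantKey] = []
    for v in variants:
        calls = [v.genotypes[s] for s in panel_samples
                 if v.genotypes.get(s, MISSING) != MISSING]
        if not calls:
            private.append(v.key)
            v.info = dict(v.info, panel="absent")
            survivors.append(v)
            continue
        af = sum(calls) / (2.0 * len(calls))
        if af > af_max:
            continue
        if hom_disqualifies and any(c == HOM_ALT for c in calls):
            continue
        survivors.append(v)
    return survivors, private


def restrict_to_region(variants: Sequence[VariantRecord],
                       region: CriticalRegion) -> list[VariantRecord]:
    """Variants with position inside the region (1-based inclusive bounds)."""
    return [v for v in variants if region.contains(v.chrom, v.pos)]


# ----------------------------------------------------------------------
def run_recessive_pipeline(variants: Sequence[VariantRecord],
                           cases: Sequence[str], controls: Sequence[str],
                           panel_samples: Sequence[str] = (),
                           region: CriticalRegion | None = None,
                           impact_min: str = "HIGH",
                           af_max: float = 0.05,
                           hom_disqualifies: bool = True,
                           ) -> tuple[list[VariantRecord], FilterReport]:
    """Compose region restriction, recessive filtering and the panel filter
    into one report with non-increasing stage counts."""
    working = list(variants)
    counts = {"input": len(working)}
    if region is not None:
        working = restrict_to_region(working, region)
        counts["in_region"] = len(working)
    working, rec_report = recessive_filter(working, cases, controls, impact_min)
    counts.update({k: v for k, v in rec_report.stage_counts.items() if k != "input"})
    private: list[VariantKey] = []
    if panel_samples:
        working, private = panel_frequency_filter(
            working, panel_samples, af_max=af_max,
            hom_disqualifies=hom_disqualifies,
            cohort_samples=list(cases) + list(controls))
        counts["panel_frequency"] = len(working)
    return working, FilterReport(stage_counts=counts,
                                 surviving=[v.key for v in working],
                                 private_flagged=private)


# ----------------------------------------------------------------------
# VCF I/O (text VCF 4.2 with an IMPACT INFO key and GT per sample)
_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODE = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT,
            "./.": MISSING, ".": MISSING,
            "0|0": HOM_REF, "0|1": HET, "1|0": HET, "1|1": HOM_ALT}


def write_vcf(variants: Sequence[VariantRecord], samples: Sequence[str],
              path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> Path:
    path = Path(path)
    contigs = dict(contig_lengths or {})
    for v in variants:
        contigs.setdefault(v.chrom, max(v.pos + 1000,
                                        contigs.get(v.chrom, 0)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,'
                 'Description="Predicted impact class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            gts = "\t".join(_GT_STRING[v.genotype(s)] for s in samples)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"IMPACT={v.impact}\tGT\t{gts}\n")
    return path


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Parse a text VCF; raises ValueError naming the line on malformed rows."""
    samples: list[str] = []
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}: malformed VCF record at line {lineno}")
            try:
                chrom, pos = fields[0], int(fields[1])
                ref, alt = fields[3], fields[4]
                info = dict(kv.split("=", 1) for kv in fields[7].split(";")
                            if "=" in kv)
                gt_idx = fields[8].split(":").index("GT")
                genotypes = {
                    s: _GT_CODE.get(f.split(":")[gt_idx], MISSING)
                    for s, f in zip(samples, fields[9:])
                }
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed VCF record at line {lineno}: {exc}"
                ) from exc
            variants.append(VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                impact=info.get("IMPACT", "MODIFIER"),
                genotypes=genotypes, info=info))
    return variants, samples
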