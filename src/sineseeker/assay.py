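"""In-silico PCR, fragment-length genotyping and cohort segregation.

An allele-specific fragment-length assay pairs a shared (optionally
fluorophore-tailed) reverse primer with a wild-type forward primer and an
insertion-anchored forward primer; the two alleles yield products of
diagnostic, distinct sizes, and a sample's genotype is read directly from
which sizes appear.  The segregation report scores a cohort against a
fully penetrant recessive model and computes the insertion-allele frequency.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class PrimerSiteError(ValueError):
    """A primer with an ambiguous (multiple) binding site."""


@dataclasses.dataclass(frozen=True)
class PrimerAssay:
    """Primer set for a two-allele fragment assay.

    ``tail_bp`` bases (e.g. a fluorophore tail) are added to the reverse
    primer's product length.
    """

    forward_wt: str
    reverse: str
    forward_ins: str | None = None
    tail_bp: int = 0

    def __post_init__(self) -> None:
        for name, primer in self.primers().items():
            if len(primer) < 15:
                raise ValueError(f"primer {name} shorter than 15 bp")
            if set(primer.upper()) - set("ACGT"):
                raise ValueError(f"primer {name} contains non-ACGT characters")

    def primers(self) -> dict[str, str]:
        out = {"forward_wt": self.forward_wt, "reverse": self.reverse}
        if self.forward_ins is not None:
            out["forward_ins"] = self.forward_ins
        return out


@dataclasses.dataclass
class SegregationReport:
    contingency: pd.DataFrame        # phenotype x genotype counts
    discordant: list[str]            # sample ids violating the model
    allele_frequency: float
    penetrance: float | None
    n_called: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele frequency outside [0, 1]")


# ----------------------------------------------------------------------
def _find_sites(template: str, primer: str) -> list[int]:
    sites = []
    start = 0
    while True:
        i = template.find(primer, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


def _product_length(template: str, forward: str, reverse: str,
                    tail_bp: int, forward_name: str) -> int | None:
    """Fragment length from the forward 5' end to the reverse 5' end, plus
    the reverse primer's tail; None when either primer has no site."""
    fwd_sites = _find_sites(template, forward)
    rev_sites = _find_sites(template, _revcomp(reverse))
    if len(fwd_sites) > 1:
        raise PrimerSiteError(f"primer {forward_name} has {len(fwd_sites)} "
                              "binding sites")
    if len(rev_sites) > 1:
        raise PrimerSiteError(f"primer reverse has {len(rev_sites)} binding sites")
    if not fwd_sites or not rev_sites:
        return None
    fwd5 = fwd_sites[0]
    rev5 = rev_sites[0] + len(reverse) - 1
    if rev5 <= fwd5:
        return None
    return rev5 - fwd5 + 1 + tail_bp


def insilico_pcr(templates: Mapping[str, str],
                 assay: PrimerAssay) -> dict[str, dict[str, int]]:
    """Predicted fragment lengths per allele template per forward primer.

    ``templates`` maps allele name (e.g. ``wild_type``, ``insertion``) to its
    sequence.  A forward primer without a binding site on a template simply
    yields no product for that allele (that is the allele specificity);
    multiple binding sites raise :class:`PrimerSiteError`.  If no primer pair
    amplifies anything on any allele, the assay is broken and a ValueError is
    raised.
    """
    results: dict[str, dict[str, int]] = {}
    for allele, template in templates.items():
        template = template.upper()
        products: dict[str, int] = {}
        for fwd_name in ("forward_wt", "forward_ins"):
            primer = assay.primers().get(fwd_name)
            if primer is None:
                continue
            length = _product_length(template, primer.upper(),
                                     assay.reverse.upper(), assay.tail_bp,
                                     fwd_name)
            if length is not None:
                products[fwd_name] = length
        results[allele] = products
    if not any(results.values()):
        raise ValueError("assay produced no product on any template")
    return results


# ----------------------------------------------------------------------
def genotype_from_fragments(observed: Iterable[int],
                            wt_length: int, ins_length: int,
                            tolerance: int = 1) -> str:
    """Call a genotype from observed fragment lengths.

    Both expected sizes present -> het; insertion size only -> hom_ins;
    wild-type only -> hom_wt; neither -> nocall.  Expectations closer than
    2 x tolerance are a configuration error (a fragment could match both).
    """
    if abs(wt_length - ins_length) <= 2 * tolerance:
        raise ValueError(
            f"expected sizes {wt_length} and {ins_length} are not separable "
            f"at tolerance {tolerance}")
    has_wt = any(abs(f - wt_length) <= tolerance for f in observed)
    has_ins = any(abs(f - ins_length) <= tolerance for f in observed)
    if has_wt and has_ins:
        return "het"
    if has_ins:
        return "hom_ins"
    if has_wt:
        return "hom_wt"
    return "nocall"


# ----------------------------------------------------------------------
GENOTYPE_COLUMNS = ["hom_ins", "het", "hom_wt", "nocall"]
PHENOTYPE_ROWS = ["affected", "clear", "unknown"]


def segregation_report(genotypes: Mapping[str, tuple[str, str]],
                       model: str = "recessive_full_penetrance",
                       ) -> SegregationReport:
    """Cohort segregation under a fully penetrant recessive model.

    ``genotypes`` maps sample -> (phenotype, genotype) with phenotype in
    {affected, clear, unknown} and genotype in {hom_ins, het, hom_wt,
    nocall}.  Discordant samples are affected-but-not-hom_ins and
    clear-but-hom_ins.  Allele frequency is (2 x hom_ins + het) / (2 x
    called samples).
    """
    if model != "recessive_full_penetrance":
        raise ValueError(f"unknown model {model!r}")
    if not genotypes:
        raise ValueError("empty cohort")
    if not any(p == "affected" for p, _ in genotypes.values()):
        raise ValueError("at least one affected sample required")
    called = {s: (p, g) for s, (p, g) in genotypes.items() if g != "nocall"}
    if not called:
        raise ValueError("all samples are nocall")
    table = pd.DataFrame(0, index=PHENOTYPE_ROWS, columns=GENOTYPE_COLUMNS)
    for pheno, geno in genotypes.values():
        table.loc[pheno, geno] += 1
    discordant = sorted(
        [s for s, (p, g) in called.items()
         if (p == "affected" and g != "hom_ins") or (p == "clear" and g == "hom_ins")]
    )
    n_hom = sum(1 for p, g in called.values() if g == "hom_ins")
    n_het = sum(1 for p, g in called.values() if g == "het")
    af = (2 * n_hom + n_het) / (2 * len(called))
    affected_hom = sum(1 for p, g in called.values()
                       if p == "affected" and g == "hom_ins")
    penetrance = affected_hom / n_hom if n_hom else None
    return SegregationReport(contingency=table, discordant=discordant,
                             allele_frequency=af, penetrance=penetrance,
                             n_called=len(called))


def report_to_tsv(report: SegregationReport, path) -> None:
    with open(path, "w") as fh:
        report.contingency.to_csv(fh, sep="\t")
        fh.write(f"\nallele_frequency\t{report.allele_frequency:.4f}\n")
        fh.write(f"discordant\t{','.join(report.discordant) or 'none'}\n")
        if report.penetrance is not None:
            fh.write(f"penetrance\t{report.penetrance:.4f}\n")
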