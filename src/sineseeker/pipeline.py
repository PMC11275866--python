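"""End-to-end orchestration: simulate or load inputs, then run every stage.

Stage order mirrors the discovery route: known-variant screen -> genotype QC
and ROH mapping -> critical region (intersection + het refinement) ->
region-restricted recessive variant filtering -> MEI scan -> repeat
classification -> consequence prediction -> assay genotyping and
segregation.  Every stage reads and writes standard formats into the output
directory, so any stage can be re-run independently; a manifest records the
configuration hash, per-file checksums, stage timings and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any

import yaml

from sineseeker._version import __version__
from sineseeker.assay import genotype_from_fragments, report_to_tsv, segregation_report
from sineseeker.consequence import name_variant, predict_insertion_consequence
from sineseeker.genotypes import GenotypeMatrix
from sineseeker.mei import Region, call_mei, calls_to_vcf
from sineseeker.repeats import AlignmentScoring, identity_matrix
from sineseeker.roh import (
    CriticalRegion,
    ROHParams,
    detect_roh,
    qc_filter,
    refine_by_het_calls,
    shared_critical_region,
)
from sineseeker.simulate import (
    GroundTruth,
    SimulationConfig,
    design_fragment_assay,
    simulate_fragment_observations,
    simulate_genotype_cohort,
    simulate_reads,
    simulate_reference,
    simulate_variant_table,
)
from sineseeker.variantfilter import (
    read_vcf,
    run_recessive_pipeline,
    screen_known_variants,
    write_vcf,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on {source}: {cause}")
        self.stage = stage
        self.source = source


_STAGES = ("screen", "roh", "variant_filter", "mei", "classify",
           "consequence", "assay")

_KNOWN_KEYS = {
    "seed", "out_dir", "simulate", "stages", "region",
    "qc", "roh", "filter", "mei", "align", "assay",
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "sineseeker_out"
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in _STAGES})
    region: dict[str, Any] | None = None       # manual critical region
    qc: dict[str, Any] = dataclasses.field(default_factory=dict)
    roh: dict[str, Any] = dataclasses.field(default_factory=dict)
    filter: dict[str, Any] = dataclasses.field(default_factory=dict)
    mei: dict[str, Any] = dataclasses.field(default_factory=dict)
    align: dict[str, Any] = dataclasses.field(default_factory=dict)
    assay: dict[str, Any] = dataclasses.field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulate)

    def roh_params(self) -> ROHParams:
        return ROHParams(**self.roh)

    def scoring(self) -> AlignmentScoring:
        return AlignmentScoring(**self.align)


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)
    timings: dict[str, float] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2)
                              + "\n")


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Schema-check a pipeline configuration, collecting all errors.

    Raises ValueError listing every problem found (not first-fail).
    """
    if isinstance(source, (str, Path)):
        payload = yaml.safe_load(Path(source).read_text()) or {}
    else:
        payload = dict(source)
    errors: list[str] = []
    unknown = set(payload) - _KNOWN_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown configuration key: {key}")
    clean = {k: v for k, v in payload.items() if k in _KNOWN_KEYS}
    seed = clean.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    for block, builder in (("simulate", SimulationConfig),
                           ("roh", ROHParams), ("align", AlignmentScoring)):
        params = clean.get(block, {})
        if not isinstance(params, dict):
            errors.append(f"{block} must be a mapping")
            continue
        try:
            if block == "simulate":
                builder(seed=int(seed) if isinstance(seed, int) else 0, **params)
            else:
                builder(**params)
        except (TypeError, ValueError) as exc:
            errors.append(f"{block}: {exc}")
    for key in ("qc", "filter", "mei", "assay", "stages"):
        if key in clean and not isinstance(clean[key], dict):
            errors.append(f"{key} must be a mapping")
    qc = clean.get("qc", {})
    if isinstance(qc, dict):
        for name in ("maf_min", "missing_max"):
            if name in qc and not 0 <= qc[name] <= 1:
                errors.append(f"qc.{name} must lie in [0, 1]")
    region = clean.get("region")
    if region is not None:
        if not isinstance(region, dict) or not {"chrom", "start", "end"} <= set(region):
            errors.append("region must provide chrom, start and end")
        elif region["start"] > region["end"]:
            errors.append("region start exceeds end")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(**clean)


# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict[str, Any]]:
    """Run all enabled stages; returns (manifest, final report dict).

    The report names the surviving variant(s), the called insertion with its
    classification and predicted consequence, and the cohort segregation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest = RunManifest(version=__version__,
                           config_hash=hashlib.sha256(cfg_text.encode()).hexdigest())
    report: dict[str, Any] = {}
    timings = manifest.timings

    def timed(stage):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[stage] = round(time.perf_counter() - self_inner.t0, 4)
        return _T()

    # ---- inputs ------------------------------------------------------
    with timed("simulate"):
        sim = config.simulation_config()
        reference = simulate_reference(sim)
        matrix, truth = simulate_genotype_cohort(sim, reference)
        variants, vcf_samples, excl_panel = simulate_variant_table(
            sim, reference, truth)
        reads = simulate_reads(sim, reference, truth)

        reference.to_fasta(out / "reference.fasta")
        reference.repeat_library.to_fasta(out / "repeats.fasta")
        reference.transcript_model.to_json(out / "transcripts.json")
        matrix.to_ped_map(out / "cohort")
        matrix.to_vcf(out / "cohort.vcf", reference.contig_lengths)
        write_vcf(variants, vcf_samples, out / "variants.vcf",
                  reference.contig_lengths)
        excl_panel.to_tsv(out / "exclusion_panel.tsv")
        truth.to_json(out / "groundtruth.json")
        reads.write_sam(out / "reads")

    cases = matrix.cases
    controls = matrix.controls
    panel_samples = [s for s in vcf_samples if s.startswith("PANEL_")]

    # ---- known-variant screen ---------------------------------------
    if config.stages.get("screen", True):
        with timed("screen"):
            loaded, _ = _read_vcf_checked(out / "variants.vcf", "screen")
            screen = screen_known_variants(loaded, excl_panel, cases)
            report["known_variant_screen"] = {
                "panel_size": len(excl_panel.variants),
                "hits": [[list(k), d, s] for k, d, s in screen.hits],
                "untyped": len(screen.untyped),
                "all_clear": screen.all_clear,
            }
            if not screen.all_clear:
                raise StageError("screen", str(out / "variants.vcf"),
                                 RuntimeError(
                                     f"cases are homozygous for known disease "
                                     f"variants: {screen.hits}"))

    # ---- ROH mapping -------------------------------------------------
    region: CriticalRegion | None = None
    if config.region is not None:
        region = CriticalRegion(chrom=str(config.region["chrom"]),
                                start=int(config.region["start"]),
                                end=int(config.region["end"]),
                                case_ids=tuple(cases),
                                boundary_markers=("", ""))
    elif config.stages.get("roh", True):
        with timed("roh"):
            qc_matrix, qc_report = qc_filter(matrix, **config.qc)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                segments = detect_roh(qc_matrix, config.roh_params(),
                                      samples=cases)
                manifest.warnings.extend(str(w.message) for w in caught)
            regions = shared_critical_region(segments, qc_matrix)
            if regions:
                region = refine_by_het_calls(regions[0], qc_matrix)
            report["qc"] = {"markers_removed_maf": qc_report.markers_removed_maf,
                            "markers_removed_missing": qc_report.markers_removed_missing}
            report["roh"] = {
                "segments_per_case": {s: len(v) for s, v in segments.items()},
                "n_candidate_regions": len(regions),
            }
    if region is not None:
        report["critical_region"] = {
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "length_bp": region.length_bp,
            "length_mb": round(region.length_bp / 1e6, 2),
        }

    # ---- recessive variant filter ------------------------------------
    if config.stages.get("variant_filter", True):
        with timed("variant_filter"):
            loaded, _ = _read_vcf_checked(out / "variants.vcf", "variant_filter")
            survivors, filt_report = run_recessive_pipeline(
                loaded, cases, controls, panel_samples, region=region,
                **config.filter)
            (out / "filter_report.json").write_text(
                json.dumps(filt_report.to_json_dict(), indent=2) + "\n")
            report["variant_filter"] = {
                "stage_counts": filt_report.stage_counts,
                "surviving": [list(k) for k in filt_report.surviving],
                "private": [list(k) for k in filt_report.private_flagged],
            }

    # ---- MEI scan ----------------------------------------------------
    call = None
    if config.stages.get("mei", True):
        with timed("mei"):
            scan_chrom = region.chrom if region else truth.chrom
            spans = [r.reference_start + 1
                     for reads_ in reads.records.values() for r in reads_
                     if not r.is_unmapped and r.reference_name == scan_chrom]
            if not spans:
                raise StageError("mei", str(out / "reads"),
                                 RuntimeError("no aligned reads on the "
                                              "critical-region contig"))
            lo, hi = min(spans), max(spans) + sim.read_length_bp
            if region is not None:
                lo, hi = max(lo, region.start), min(hi, region.end)
            scan_region = Region(chrom=scan_chrom, start=lo, end=hi)
            ref_seq = reference.contigs[scan_chrom]
            calls = call_mei(scan_region, ref_seq,
                             {s: r for s, r in reads.records.items()},
                             **config.mei)
            two_sided = [c for c in calls if not c.one_sided]
            if two_sided:
                call = max(two_sided, key=lambda c: c.split_support)
            elif calls:
                call = max(calls, key=lambda c: c.split_support)
            calls_to_vcf(calls, out / "mei_calls.vcf", reference.contig_lengths)
            report["mei"] = {
                "n_calls": len(calls),
                "call": None if call is None else {
                    "chrom": call.contig, "bp_left": call.bp_left,
                    "bp_right": call.bp_right,
                    "tsd": call.tsd_sequence,
                    "tsd_length_bp": call.tsd_length,
                    "insert_length": call.insert_length_estimate,
                    "insert_partial": call.insert_partial,
                    "polyA_length": call.polyA_length,
                    "split_support": call.split_support,
                    "discordant_support": call.discordant_support,
                    "depth_ratio": round(call.depth_ratio, 3),
                    "genotypes": call.genotypes,
                    "one_sided": call.one_sided,
                },
            }

    # ---- repeat classification ---------------------------------------
    if call is not None and config.stages.get("classify", True):
        with timed("classify"):
            matrix_out, best = identity_matrix(
                call.insert_consensus, reference.repeat_library,
                query_name="candidate", scoring=config.scoring())
            matrix_out.to_tsv(out / "identity_matrix.tsv")
            report["classification"] = {
                "best_hit": best.name,
                "identity_pct": round(best.identity_pct, 1),
                "ties": list(best.ties),
            }

    # ---- consequence -------------------------------------------------
    if call is not None and not call.one_sided and config.stages.get(
            "consequence", True):
        with timed("consequence"):
            model = reference.transcript_model
            # net inserted bases before bp_right + 1: element + second TSD copy
            inserted = call.insert_consensus + call.tsd_sequence
            site = call.bp_right + 1
            consequences = predict_insertion_consequence(
                model, reference.contigs[model.chrom], site, inserted)
            affected = [c for c in consequences if c.affected]
            designation = None
            if affected:
                lead = affected[0]
                length = (call.insert_length_estimate
                          if not call.insert_partial else None)
                designation = name_variant(model.accession,
                                           lead.cds_insertion_position,
                                           length, lead.protein_start_position)
            report["consequence"] = {
                "designation": designation,
                "isoforms": [dataclasses.asdict(c) for c in consequences],
            }

    # ---- assay genotyping and segregation ----------------------------
    if config.stages.get("assay", True):
        with timed("assay"):
            assay, templates = design_fragment_assay(
                reference, **{k: v for k, v in config.assay.items()
                              if k != "tolerance"})
            wt_len = assay.tail_bp + int(config.assay.get("wt_product_bp", 250))
            ins_len = assay.tail_bp + int(config.assay.get("ins_product_bp", 234))
            observed = simulate_fragment_observations(sim, truth, wt_len,
                                                      ins_len)
            tol = int(config.assay.get("tolerance", 1))
            pheno = {"case": "affected", "control": "clear",
                     "unknown": "unknown"}
            cohort_geno = {
                s: (pheno[matrix.phenotypes[matrix.sample_index(s)]],
                    genotype_from_fragments(observed[s], wt_len, ins_len, tol))
                for s in matrix.samples
            }
            seg = segregation_report(cohort_geno)
            report_to_tsv(seg, out / "segregation.tsv")
            report["segregation"] = {
                "allele_frequency": round(seg.allele_frequency, 4),
                "discordant": seg.discordant,
                "penetrance": seg.penetrance,
                "contingency": {p: seg.contingency.loc[p].to_dict()
                                for p in seg.contingency.index},
            }

    # ---- manifest ----------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file():
            manifest.checksums[str(path.relative_to(out))] = _sha256(path)
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    manifest.to_json(out / "manifest.json")
    return manifest, report


def _read_vcf_checked(path: Path, stage: str):
    try:
        return read_vcf(path)
    except ValueError as exc:
        raise StageError(stage, str(path), exc) from exc
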