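"""Shared fixtures: one simulated bundle reused across the suite."""

from __future__ import annotations

import dataclasses

import pytest

from sineseeker.simulate import (
    SimulationConfig,
    simulate_genotype_cohort,
    simulate_reads,
    simulate_reference,
    simulate_variant_table,
)


@dataclasses.dataclass
class SimBundle:
    config: SimulationConfig
    reference: object
    matrix: object
    truth: object
    reads: object
    variants: list
    vcf_samples: list
    exclusion_panel: object


def make_bundle(seed: int, **overrides) -> SimBundle:
    config = SimulationConfig(seed=seed, **overrides)
    reference = simulate_reference(config)
    matrix, truth = simulate_genotype_cohort(config, reference)
    reads = simulate_reads(config, reference, truth)
    variants, vcf_samples, panel = simulate_variant_table(config, reference,
                                                          truth)
    return SimBundle(config=config, reference=reference, matrix=matrix,
                     truth=truth, reads=reads, variants=variants,
                     vcf_samples=vcf_samples, exclusion_panel=panel)


@pytest.fixture(scope="session")
def bundle() -> SimBundle:
    """Default-condition cohort, seed 7, shared by read-only tests."""
    return make_bundle(seed=7)


@pytest.fixture(scope="session")
def reference(bundle):
    return bundle.reference


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle.truth
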