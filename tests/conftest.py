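"""Shared fixtures: the heavy synthetic datasets are built once per session."""

import pytest

from refugium.fulllength import detect_fulllength
from refugium.sexsnv import build_pileup, naive_map
from refugium.simulate import (
    cohort_scenario,
    default_scenario,
    density_scenario,
    plant_and_mutate,
    simulate_reads,
)

STRUCTURAL_SEED = 1
COHORT_SEED = 11


@pytest.fixture(scope="session")
def structural_sim():
    """~2 Mb genome with 32 planted fl-ERVs (10 A, 2 Z, 20 W), 20 solo-LTRs
    and 20 truncated fragments, error-free."""
    return plant_and_mutate(default_scenario(), STRUCTURAL_SEED)


@pytest.fixture(scope="session")
def structural_calls(structural_sim):
    return detect_fulllength(
        structural_sim.genome, structural_sim.hits, structural_sim.domains
    )


@pytest.fixture(scope="session")
def cohort_data():
    """Simulated 3F+3M genomic (+1F/+1M RNA) cohorts with planted W-linked
    and autosomal SNVs, mapped and piled up."""
    sim = plant_and_mutate(cohort_scenario(), COHORT_SEED)
    samples, sheet = simulate_reads(sim)
    pileups = {
        sid: build_pileup(naive_map(reads, sim.library), sim.library, sample_id=sid)
        for sid, reads in samples.items()
    }
    return sim, samples, sheet, pileups


@pytest.fixture(scope="session")
def density_sim():
    """Three 100 kb chromosomes with planted TE densities 5/10/60%."""
    return plant_and_mutate(density_scenario(), 3)


def match_span(call, element, tol: int = 5) -> bool:
    """Boundary match within a small tolerance (TSD-guided refinement can
    jitter edges by a base or two)."""
    return (
        call.chromosome == element.chromosome
        and abs(call.begin - element.begin) <= tol
        and abs(call.end - element.end) <= tol
    )


def reciprocal_overlap(call, element) -> float:
    """Reciprocal overlap fraction of a call with a planted element."""
    if call.chromosome != element.chromosome:
        return 0.0
    inter = min(call.end, element.end) - max(call.begin, element.begin)
    if inter <= 0:
        return 0.0
    return inter / max(call.end - call.begin, element.end - element.begin)
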