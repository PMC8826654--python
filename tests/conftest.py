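"""Shared fixtures: simulated cohorts are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import pytest

from mutscape.core_io import AnnotationSet, GeneModel, GenomeSequence
from mutscape.pipeline import analyze_cohort, inputs_from_cohort
from mutscape.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort under the default (noisy) study conditions."""
    return simulate_cohort(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return analyze_cohort(inputs_from_cohort(default_cohort))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Cohort with perfect callers and no sequencing errors."""
    return simulate_cohort(SimulationConfig(rng_seed=3).noise_free())


@pytest.fixture(scope="session")
def noise_free_result(noise_free_cohort):
    return analyze_cohort(inputs_from_cohort(noise_free_cohort))


@pytest.fixture()
def tiny_genome():
    """A 30-bp single-chromosome genome with one gene (11-20, exon 11-14)."""
    genome = GenomeSequence(chrom_names=["c1"], sequences={"c1": "ACGT" * 7 + "AC"})
    ann = AnnotationSet(chrom_lengths={"c1": 30},
                        genes=[GeneModel("g1", "c1", 10, 20, "+", [(10, 14)])])
    return genome, ann
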