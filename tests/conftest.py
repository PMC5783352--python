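"""Shared fixtures: a small simulated sex-bias experiment run end to end."""

import pytest

from trfbin.counting import build_count_matrix, exact_match_map
from trfbin.simulate import (
    PlannedTRF,
    SimDesign,
    build_bins,
    simulate_genes,
    simulate_reads,
)

# Compact two-group (paired female/male across 5 strains) design with
# differential and null source tRFs spanning precursor, mature and loop
# origins.  Background 0 so counts can be compared with the truth exactly.
SMALL_PLAN = (
    PlannedTRF(None, "3-Pre", {"female": 2000.0, "male": 500.0}, dispersion=0.05),
    PlannedTRF(None, "5tRF", {"female": 500.0, "male": 2000.0}, dispersion=0.05),
    PlannedTRF(None, "A-loop", {"female": 800.0, "male": 800.0}, dispersion=0.05),
    PlannedTRF(None, "T-loop", {"female": 600.0, "male": 600.0}, dispersion=0.05),
    PlannedTRF(None, "5-Pre", {"female": 1200.0, "male": 300.0}, dispersion=0.05),
    PlannedTRF(None, "3-Pre", {"female": 400.0, "male": 400.0}, dispersion=0.05),
)


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(
        n_genes=20,
        n_excluded=3,
        groups=(("female", 5), ("male", 5)),
        source_plan=SMALL_PLAN,
        background_rate=0.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_genome(small_design):
    return simulate_genes(small_design)


@pytest.fixture(scope="session")
def small_bins(small_genome):
    return build_bins(small_genome)


@pytest.fixture(scope="session")
def small_reads(small_design, small_genome, small_bins):
    return simulate_reads(small_design, small_genome, small_bins)


@pytest.fixture(scope="session")
def small_counts(small_genome, small_bins, small_reads):
    sources = {
        sid: exact_match_map(reads, small_genome.reference).records
        for sid, reads in small_reads.samples.items()
    }
    return build_count_matrix(
        sources, small_bins, sample_meta=small_reads.sample_table
    )
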