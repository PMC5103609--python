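"""Shared fixtures: a small seeded xenograft simulation reused across tests."""

import pytest

from xenolink import synthetic
from xenolink.assignment import accumulate_counts, assign_pair
from xenolink.mappability import compute_mappability
from xenolink.quantify import build_gene_data


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(seed=11, n_genes=24, n_pairs=20000)


@pytest.fixture(scope="session")
def small_transcriptomes(small_config):
    return synthetic.simulate_transcriptomes(small_config)


@pytest.fixture(scope="session")
def small_tracks(small_transcriptomes):
    return compute_mappability(small_transcriptomes.transcripts)


@pytest.fixture(scope="session")
def small_reads(small_config, small_transcriptomes):
    return synthetic.simulate_reads(small_config, small_transcriptomes)


@pytest.fixture(scope="session")
def small_assignments(small_reads):
    return [assign_pair(p) for p in small_reads.pairs]


@pytest.fixture(scope="session")
def small_counts(small_assignments, small_transcriptomes):
    return accumulate_counts(small_assignments, small_transcriptomes.transcripts)


@pytest.fixture(scope="session")
def small_gene_data(small_counts, small_tracks, small_transcriptomes):
    return build_gene_data(
        small_counts, small_tracks, small_transcriptomes.transcripts
    )
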