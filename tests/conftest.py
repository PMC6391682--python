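from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles/_factories

from sirnaq import (
    SimConfig,
    align_library,
    simulate_inserts,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 20,000-read study over a compact genome; fast to align."""
    return SimConfig(
        seed=11, n_contigs=2, contig_length=20_000, n_mirna_loci=10,
        n_repeat_families=2, copies_per_family=4, library_size=20_000,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_reference):
    """Replicate-1 library of the small study, aligned perfect-match."""
    inserts, _ = simulate_inserts(small_config, small_reference, replicate=1)
    return align_library(inserts, small_reference.reference,
                         sample_id="S1", group="ctrl", replicate=1)


@pytest.fixture(scope="session")
def small_truth(small_config, small_reference):
    _, truth = simulate_inserts(small_config, small_reference, replicate=1)
    return truth
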