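import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pirnakit.align import filter_alignments, map_reads
from pirnakit.reads import collapse_and_filter, filter_low_complexity
from pirnakit.synthetic import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A light study for repeated simulation runs (no TE content)."""
    defaults = dict(
        seed=0,
        n_reads=20_000,
        genome_length=400_000,
        n_chroms=2,
        n_clusters=10,
        cluster_min_separation=15_000,
        te_families=[],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def map_dataset(ds, max_mismatch=0):
    """Collapse, duster-filter and map a simulated dataset."""
    filtered = filter_low_complexity(collapse_and_filter(ds.reads))
    return filter_alignments(map_reads(filtered, ds.genome, max_mismatch))


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_mapped(default_dataset):
    return map_dataset(default_dataset)
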