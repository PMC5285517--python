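import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hgtscreen.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    cfg = SimConfig(n_taxa=12, n_phyla=3, n_families=8, p_transfer=0.5, seq_length=200, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    """The small dataset written to disk in every on-disk format."""
    from hgtscreen.simulate import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(outdir, small_sim)
    return paths
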