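from __future__ import annotations

import pytest

from cfcna.genome import TOY_CHROM_LENGTHS, make_genome_grid
from cfcna import simulate as sim
from cfcna import normalize as norm


@pytest.fixture(scope="session")
def toy_grid():
    """4 x 125 Mb -> 500 bins at 1 Mb."""
    return make_genome_grid(TOY_CHROM_LENGTHS)


@pytest.fixture(scope="session")
def mid_grid():
    """20 x 125 Mb -> 2500 bins at 1 Mb."""
    return make_genome_grid({f"chr{i}": 125_000_000 for i in range(1, 21)})


@pytest.fixture(scope="session")
def deep_config():
    return sim.DEPTH_PRESETS["30x"]


@pytest.fixture(scope="session")
def ulp_config():
    return sim.DEPTH_PRESETS["0.1x"]


@pytest.fixture(scope="session")
def toy_gc(toy_grid):
    return sim.simulate_gc_track(toy_grid, seed=7)


@pytest.fixture(scope="session")
def toy_panel_log2(toy_grid, toy_gc, deep_config):
    """Normalized deep-depth panel of 27 donors on the toy grid."""
    donors = sim.simulate_panel_of_normals(toy_grid, 27, deep_config, gc=toy_gc, seed=7)
    return norm.build_panel_log2(donors)
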