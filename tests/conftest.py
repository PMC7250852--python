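import numpy as np
import pytest

from antdiet.pipeline import make_fixture, run_pipeline
from antdiet.simulate import SimulationConfig, build_reference_library, simulate_gut_reads


@pytest.fixture(scope="session")
def tiny_library():
    return build_reference_library(2, 2, 1, seed=11, n_predators=1, n_offtargets=1)


@pytest.fixture(scope="session")
def noiseless_config(tiny_library):
    """Four individuals, all error/artifact rates zero."""
    prey = [t.id for t in tiny_library if t.role == "prey"]
    predator = next(t.id for t in tiny_library if t.role == "predator")
    diet = {
        "spider_001": {prey[0]: 0.6, prey[1]: 0.4},
        "spider_002": {prey[1]: 0.5, prey[2]: 0.5},
        "spider_003": {prey[0]: 0.2, prey[2]: 0.3, prey[3]: 0.5},
        "spider_004": {prey[3]: 1.0},
    }
    return SimulationConfig(
        diet=diet,
        predator_taxon=predator,
        primer_failure=frozenset({("ant_specific", predator)}),
        reads_per_individual=200,
        sub_rate=0.0,
        indel_rate=0.0,
        homopolymer_indel_rate=0.0,
        chimera_rate=0.0,
        tag_jump_rate=0.0,
        contaminant_rate=0.0,
        q20_fail_fraction=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_config, tiny_library):
    return simulate_gut_reads(noiseless_config, tiny_library, "ant_specific")


@pytest.fixture(scope="session")
def tiny_result():
    """Full pipeline on the tiny noisy fixture (seed frozen)."""
    library, sim, cfg = make_fixture("tiny", 1)
    return library, sim, run_pipeline(cfg, sim, library)
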