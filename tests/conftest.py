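import warnings

import numpy as np
import pytest

from mirpipe.io import Scaffold
from mirpipe.simulate import SimulationConfig, simulate_genome, simulate_libraries


@pytest.fixture(autouse=True)
def _quiet_fold_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="folding a sequence")
        yield


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_sim():
    """A small planted simulation shared across tests (deterministic)."""
    cfg = SimulationConfig(
        seed=7,
        n_scaffolds=2,
        scaffold_len=60_000,
        n_known_mirnas=8,
        n_novel_mirnas=2,
        n_clusters=1,
        cluster_members=(4,),
        depth_per_library=3000,
    )
    sim = simulate_genome(cfg)
    libs = simulate_libraries(sim, cfg)
    return cfg, sim, libs


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(11)
    return [Scaffold("t1", random_dna(rng, 8000)), Scaffold("t2", random_dna(rng, 5000))]
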