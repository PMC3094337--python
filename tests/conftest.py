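import numpy as np
import pytest

import heatmod as hm


@pytest.fixture
def small_matrix() -> hm.DataMatrix:
    rng = np.random.default_rng(42)
    return hm.DataMatrix(rng.standard_normal((6, 4)),
                         [f"g{i}" for i in range(6)],
                         [f"s{j}" for j in range(4)])


@pytest.fixture
def small_modules() -> hm.ModuleMap:
    return hm.ModuleMap(
        {"cellcycle": ["g0", "g1", "g2"], "apoptosis": ["g2", "g3", "g4"],
         "tiny": ["g5"]},
        descriptions={"cellcycle": "division genes", "apoptosis": "death genes"})


@pytest.fixture
def event_matrix() -> hm.BinaryMatrix:
    m, _ = hm.make_event_fixture(hm.FixtureSpec(
        seed=7, n_genes=40, n_samples=10, module_size_max=10, event_rate=0.2))
    return m
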