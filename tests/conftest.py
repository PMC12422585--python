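import numpy as np
import pytest

from chimerabrain.connectome import Connectome, RegionInfo


def make_connectome(weights, systems=None, age=30.0, coords=None, volumes=None,
                    individual_id="test"):
    """Connectome from a bare weight matrix with generated metadata."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    systems = systems if systems is not None else ["S0"] * n
    rng = np.random.default_rng(12345)
    coords = coords if coords is not None else rng.uniform(-50, 50, (n, 3))
    volumes = volumes if volumes is not None else np.ones(n)
    regions = tuple(
        RegionInfo(
            name=f"r{i}",
            hemisphere="left" if i % 2 == 0 else "right",
            system=systems[i],
            volume=float(volumes[i]),
            coordinate=tuple(coords[i]),
        )
        for i in range(n)
    )
    return Connectome(weights=W, regions=regions, age=age,
                      individual_id=individual_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_connectome():
    """4 regions, 2 systems, hand-set weights."""
    W = np.array(
        [
            [0.0, 2.0, 3.0, 0.0],
            [2.0, 0.0, 0.5, 1.0],
            [3.0, 0.5, 0.0, 4.0],
            [0.0, 1.0, 4.0, 0.0],
        ]
    )
    return make_connectome(W, systems=["A", "A", "B", "B"])
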