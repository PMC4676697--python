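import numpy as np
import pytest

from slbnr.scattering import ContrastSpec, LipidComposition, ecoli_fragments
from slbnr.simulate import InstrumentSpec, ground_truth_presets


@pytest.fixture(scope="session")
def fragments():
    return ecoli_fragments()


@pytest.fixture(scope="session")
def ecoli_composition():
    return LipidComposition(0.75, 0.13, 0.12)


@pytest.fixture(scope="session")
def presets():
    return ground_truth_presets()


@pytest.fixture(scope="session")
def coarse_instrument():
    """Noise-free-capable instrument with a coarse Q grid for fast fits."""
    return InstrumentSpec(q_min=0.005, q_max=0.3, points_per_decade=25)


@pytest.fixture(scope="session")
def study_instrument():
    """The full measurement-like grid used for the recovery studies."""
    return InstrumentSpec(q_min=0.005, q_max=0.3)


def random_stack_arrays(rng, max_layers=4):
    """Random physical (fronting, layers, backing) for oracle cross-checks."""
    n = rng.integers(0, max_layers + 1)
    fronting = rng.uniform(0.0, 4.0)
    backing = rng.uniform(-0.56, 6.4)
    layers = [
        (
            rng.uniform(5.0, 300.0),
            rng.uniform(-0.6, 7.0),
            rng.uniform(0.0, 5.0),
        )
        for _ in range(n)
    ]
    backing_roughness = rng.uniform(0.0, 5.0)
    return fronting, layers, backing, backing_roughness
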