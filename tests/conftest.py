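import numpy as np
import pytest
from hypothesis import settings

from markerdiv.marker_data import MarkerMatrix
from markerdiv.synthetic_data import SimulationConfig, simulate_dominant_markers

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_matrix() -> MarkerMatrix:
    """Four individuals, three loci, two populations; hand-checkable."""
    return MarkerMatrix(
        individual_ids=["a1", "a2", "b1", "b2"],
        locus_ids=["L1", "L2", "L3"],
        values=np.array([[1, 0, 1], [1, 0, 1], [0, 0, 1], [1, 1, 1]]),
        population_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture(scope="session")
def study_scale_matrix():
    """Simulated matrix at the study design scale (20 x 13, 288 loci)."""
    matrix, truth = simulate_dominant_markers(SimulationConfig(fst=0.11, seed=42))
    return matrix, truth
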