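import numpy as np
import pytest

from paracellkit.barrier_assays import IonicSolution
from paracellkit.synthetic_data import MosaicSpec, simulate_monolayer


@pytest.fixture(scope="session")
def solution_a():
    return IonicSolution.solution_a()


@pytest.fixture(scope="session")
def solution_b():
    return IonicSolution.solution_b()


@pytest.fixture(scope="session")
def small_mosaic():
    """A small mosaic image shared by the junction tests (60 cells, 50 um)."""
    spec = MosaicSpec(n_cells=60, field_um=50.0, seed=11)
    image, genotypes, truth = simulate_monolayer(spec)
    return spec, image, genotypes, truth
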