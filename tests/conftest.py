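import numpy as np
import pytest

from agrosdm import (GridSpec, generate_predictor_stack, make_virtual_species,
                     sample_occurrences, sample_pseudo_absences)

LAYERS = ["bio02", "bio08", "bio13", "bio14"]


@pytest.fixture(scope="session")
def grid():
    return GridSpec.from_origin(40, 40, -100.0, 20.0, 0.05)


@pytest.fixture(scope="session")
def stack(grid):
    return generate_predictor_stack(grid, LAYERS, seed=11)


@pytest.fixture(scope="session")
def species(stack):
    return make_virtual_species(stack, ["bio08", "bio13"], seed=5,
                                prevalence_target=0.15, name="virt")


@pytest.fixture(scope="session")
def training_set(species, stack):
    """Thinned-scale presences + pseudo-absences ready for ensemble fitting."""
    occ = sample_occurrences(species, stack, n=200, seed=21)
    return sample_pseudo_absences(occ, stack, n=400, seed=22)
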