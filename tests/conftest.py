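import numpy as np
import pytest

from gcfield.mapping import build_cluster_assignment
from gcfield.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def assignment():
    """The schematic ring hemi-cluster assignment (expensive to rebuild)."""
    return build_cluster_assignment()


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort shared by integration-style tests."""
    cfg = GeneratorConfig(n_healthy=25, n_suspect=10, n_glaucoma=25, seed=11,
                          n_reference_vf=25)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
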