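import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scovnet import DensityGrid, GroundTruthSpec, generate_paired_cohorts, preset_pair
from scovnet.inference import PermutationConfig
from scovnet.synthetic import WattsStrogatz


@pytest.fixture(scope="session")
def small_spec():
    """20-region small-world spec: fast but structurally non-trivial."""
    return GroundTruthSpec(
        n_regions=20, topology=WattsStrogatz(k=4, p=0.1), base_correlation=0.5, seed=7
    )


@pytest.fixture(scope="session")
def null_pair():
    spec_a, spec_b = preset_pair("null", seed=3, n_regions=30)
    return generate_paired_cohorts(spec_a, spec_b, 20, 20)


@pytest.fixture(scope="session")
def fast_config():
    """Coarse grid, few permutations, no null ensembles: unit-test scale."""
    return PermutationConfig(
        n_perm=30, n_nulls=0, densities=DensityGrid(0.15, 0.45, 0.15), seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
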