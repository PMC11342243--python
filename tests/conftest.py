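import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from braintx.simulate import GroundTruth
from braintx.types import DEFAULT_PERIODS, DEFAULT_REGIONS


@pytest.fixture
def small_truth() -> GroundTruth:
    """Tiny planted universe: 4 Class-1, 4 Class-2, 12 control genes."""
    genes = [f"g{i:02d}" for i in range(20)]
    return GroundTruth(
        class1_genes=set(genes[:4]),
        class2_genes=set(genes[4:8]),
        specific_genes={
            genes[0]: ("region", DEFAULT_REGIONS[3]),
            genes[4]: ("region", DEFAULT_REGIONS[7]),
            genes[8]: ("period", DEFAULT_PERIODS[5]),
        },
        sex_biased_genes={genes[1]: "female", genes[5]: "male"},
        hub_genes={genes[18], genes[19]},
        genes=genes,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
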