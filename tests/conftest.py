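import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lungmarkers as lm

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_compendium():
    """3 probes x 5 samples with known group structure."""
    values = pd.DataFrame(
        [[5.0, 6.0, 4.0, 4.1, 3.9],
         [8.0, 8.5, 8.2, 8.1, 8.3],
         [2.0, 2.5, 2.2, 2.4, 2.1]],
        index=["p1", "p2", "p3"],
        columns=["t1", "t2", "n1", "n2", "n3"],
    )
    groups = pd.Series(
        ["lung_tumor", "lung_tumor", "lung_normal", "lung_normal", "lung_normal"],
        index=values.columns,
    )
    return lm.ExpressionCompendium(values=values, sample_group=groups)


@pytest.fixture
def planted_compendium():
    """One strongly planted probe among 200 null probes (fixed seed)."""
    spec = lm.CompendiumSpec(
        n_probes=201,
        group_sizes={"lung_tumor": 60, "lung_normal": 40},
        planted=(lm.PlantedMarkerSpec(probe_index=100, elevated_fraction=0.6, effect_log2=4.0),),
        seed=7,
    )
    comp, truth = lm.simulate_compendium(spec)
    return comp, truth
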