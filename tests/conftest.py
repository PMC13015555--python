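import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_roll():
    """One small two-genotype swiss-roll dataset with truth, shared per session."""
    from mucosa import simulate as sim

    spec = sim.SpatialSimSpec(
        seed=42, colon_length=24000.0, cells_per_mm=350.0, n_samples_per_genotype=1
    )
    cells, truth = sim.simulate_swiss_roll(spec)
    return spec, cells, truth


@pytest.fixture(scope="session")
def unrolled_roll(small_roll):
    from mucosa import unroll as ur

    _, cells, _ = small_roll
    return ur.unroll_dataset(cells)


@pytest.fixture(scope="session")
def expression_sim():
    from mucosa import simulate as sim

    return sim.simulate_expression(sim.ExpressionSimSpec(seed=7))


@pytest.fixture()
def toy_cohort():
    return pd.DataFrame(
        {"group": ["HS", "HS", "UC", "UC"], "od": [0.1, 0.3, 0.2, 0.4]}
    )
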