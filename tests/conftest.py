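import numpy as np
import pytest

from uhcmon.config import (IndicatorParams, SyntheticConfig,
                           WaveExpenditureParams)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast two-indicator scenario used across test modules."""
    base = dict(
        survey_years=[1995, 2000, 2005, 2010, 2015],
        n_clusters=20,
        households_per_cluster=10,
        n_regions=4,
        n_assets=6,
        indicator_params={
            "alpha_ind": IndicatorParams(a0=-0.5, b=0.06, g=0.8),
            "beta_ind": IndicatorParams(a0=0.5, b=0.03, g=0.2),
        },
        region_effects=[0.2, 0.0, -0.1, -0.1],
        expenditure_params={
            1995: WaveExpenditureParams(6.0, 0.6, 0.55, 18.0, 0.7, 2.8, 1.2),
            2005: WaveExpenditureParams(6.8, 0.6, 0.50, 18.0, 0.7, 2.9, 1.2),
            2015: WaveExpenditureParams(7.6, 0.6, 0.45, 18.0, 0.7, 3.0, 1.2),
        },
        expenditure_years=[1995, 2005, 2015],
        n_households_expenditure=500,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def cfg_small():
    return small_config()


@pytest.fixture(scope="session")
def coverage_small(cfg_small):
    from uhcmon.synthetic import generate_coverage_microdata

    return generate_coverage_microdata(cfg_small)


@pytest.fixture(scope="session")
def expenditure_small(cfg_small):
    from uhcmon.synthetic import generate_expenditure_microdata

    return generate_expenditure_microdata(cfg_small)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
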