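import numpy as np
import pytest
from hypothesis import settings

from sharkheal.annotations import HealingSeries, SightingMeasurement

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def series_from_ratios(pairs, injury_id="inj", shark_id="WS", metadata=None):
    """Build a HealingSeries directly from (day, area_ratio) pairs."""
    measurements = tuple(
        SightingMeasurement(day_offset=d, area_ratio=r, perimeter_ratio=r)
        for d, r in pairs
    )
    return HealingSeries(
        injury_id=injury_id,
        measurements=measurements,
        shark_id=shark_id,
        metadata=metadata or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    from sharkheal.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_injuries=8, n_sharks=6, seed=7))
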