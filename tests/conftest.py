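import pytest

from steti.cohorts import DataRange, PatientRecord
from steti.simulate import SimulationConfig
from steti.trendmodels import TrendModel

# Study conditions shared across stochastic tests: a SEER-like 1992-2020
# extract, 20-year window, trend scales matching kidney-cancer survival,
# right-skewed individual noise (gamma CV=1), integer-year rounding.
KIDNEY_RANGE = DataRange(1992, 2020)
WINDOW = 20
TRUE_LINEAR = TrendModel("linear", 1992, 2.5, 0.05)
TRUE_EXPONENTIAL = TrendModel("exponential", 1992, 3.0748, 93.0)
NOISE_SHAPE = 1.0
N_PER_YEAR = 2000


def noisy_config(true_model: TrendModel, seed: int, **overrides) -> SimulationConfig:
    kwargs = dict(
        data_range=KIDNEY_RANGE,
        window_N=WINDOW,
        true_model=true_model,
        n_per_year=N_PER_YEAR,
        noise="gamma",
        noise_param=NOISE_SHAPE,
        rounding="round",
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def kidney_range() -> DataRange:
    return KIDNEY_RANGE


@pytest.fixture
def toy_records() -> list[PatientRecord]:
    return [
        PatientRecord(1992, 1994),
        PatientRecord(1992, 2000),
        PatientRecord(2000, 2012, count=3),
        PatientRecord(1995, 2012),
    ]
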