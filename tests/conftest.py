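import numpy as np
import pytest

from leangrade import Carcass, PopulationParams, generate_population

# Zero-sum spreads so a 12-carcass subsample hits chosen means exactly.
_OFFSETS = np.array([-9.0, -6.0, -4.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0])


def make_subsample(ytd_mean: float, ypd_mean: float) -> list[Carcass]:
    """Twelve carcasses whose YTD/YPD sample means equal the given values exactly."""
    assert abs(_OFFSETS.sum()) < 1e-12
    return [
        Carcass(
            id=f"SUB{i:02d}",
            sex="gilt" if i % 2 else "castrate",
            hot_weight=95.0,
            f2=14.0,
            m2=62.0,
            ytd_true=ytd_mean + off,
            ypd_obs=ypd_mean + off,
        )
        for i, off in enumerate(_OFFSETS)
    ]


@pytest.fixture(scope="session")
def trial_subsample() -> list[Carcass]:
    """Subsample calibrated to the trial's printed means (YTD 59.62, YPD 67.12)."""
    return make_subsample(59.62, 67.12)


@pytest.fixture(scope="session")
def medium_population() -> list[Carcass]:
    """A 20k-carcass default-parameter population, reused across tests."""
    return generate_population(PopulationParams(n=20_000, seed=42))


@pytest.fixture()
def noise_free_params() -> PopulationParams:
    """Generator settings where ypd_obs is an exact linear function of (F2, M2)."""
    return PopulationParams(n=200, sigma_ytd=0.0, sigma_delta=0.0, sf_true=1.0, seed=11)
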