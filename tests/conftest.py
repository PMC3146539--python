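import numpy as np
import pytest

from ipfcm import (
    BeadPopulationSpec,
    KineticNoiseSpec,
    RateParameters,
    StimulationSchedule,
    gen_kinetic_dataset,
)


@pytest.fixture(scope="session")
def default_params() -> RateParameters:
    return RateParameters()


@pytest.fixture(scope="session")
def single_dose() -> StimulationSchedule:
    return StimulationSchedule(dose_times=(0.0,), horizon=60.0)


@pytest.fixture(scope="session")
def noiseless_dataset(default_params, single_dose):
    return gen_kinetic_dataset(
        default_params,
        single_dose,
        times=(0.0, 2.0, 5.0, 10.0, 20.0, 60.0),
        noise=KineticNoiseSpec(replicate_count=3, noise_cv_percent=0.0, seed=11),
    )


@pytest.fixture
def small_population() -> BeadPopulationSpec:
    return BeadPopulationSpec(
        n_events=2000,
        channel_geo_means={"PE": 500.0, "APC": 800.0},
        channel_geo_cv=0.3,
        seed=5,
    )


def random_rate_dict(rng: np.random.Generator) -> dict:
    """Log-uniform random rate set used by the symmetry-oracle checks."""
    d = {
        k: float(10 ** rng.uniform(-2, 1))
        for k in (
            "k_itam_p",
            "k_itam_dp",
            "k_on",
            "k_off",
            "k_y319",
            "k_y319_dp",
            "k_y493",
            "k_y493_dp",
        )
    }
    d["f_min"] = float(rng.uniform(0.01, 0.5))
    d["tau_rec"] = float(rng.uniform(5.0, 80.0))
    return d
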