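from dataclasses import replace

import pytest
from hypothesis import settings

from vaporsip.registry import default_registry
from vaporsip.synthetic import default_truth
from vaporsip.types import Phase

# deterministic property tests: no example database, same examples every run
settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
settings.load_profile("deterministic")


def drought_phase_only(truth):
    """Restrict a TruthParams to the peak-drought phase (halves the workload)."""
    keep = lambda d: {k: v for k, v in d.items() if k[0] is Phase.DROUGHT}
    return replace(
        truth,
        growth_per_day=keep(truth.growth_per_day),
        nlfa_investment=keep(truth.nlfa_investment),
        respiration=keep(truth.respiration),
        water_2h=keep(truth.water_2h),
        water_18o=keep(truth.water_18o),
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def noise_free_truth():
    return default_truth(
        delta_sd_permil=0.0, atpct_18o_sd=0.0, co2_ppm_sd=0.0,
        water_atpct_sd=0.0, plot_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_truth():
    return default_truth()
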