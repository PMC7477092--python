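import pytest
from hypothesis import HealthCheck, settings

from leafdyn.synthetic import preset, simulate_induction, simulate_response_curve

settings.register_profile(
    "leafdyn", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("leafdyn")

#: scenario update that switches off every noise channel
NOISE_OFF = {"sigma_a": 0.0, "sigma_gs": 0.0, "sigma_fluor_rel": 0.0}


def clean_preset(genotype, treatment, **overrides):
    return preset(genotype, treatment).model_copy(update={**NOISE_OFF, **overrides})


@pytest.fixture(scope="session")
def wt_control_clean():
    """Noise-free wildtype control transient: (trace, ground truth)."""
    return simulate_induction(clean_preset("WT", "control"))


@pytest.fixture(scope="session")
def flacca_control_clean():
    return simulate_induction(clean_preset("flacca", "control"))


@pytest.fixture(scope="session")
def wt_calibration_curves():
    """Noise-free calibration protocol for the wildtype control scenario:
    (scenario, 2% O2 A/PAR curve, 21% O2 A/Ci curve)."""
    sc = clean_preset("WT", "control")
    apar = simulate_response_curve(sc, "APAR", o2=2.0)
    aci21 = simulate_response_curve(sc, "ACI", o2=21.0)
    return sc, apar, aci21
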