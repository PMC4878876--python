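import dataclasses

import pytest

from cbnephys.presets import default_presets
from cbnephys.synthetic import SynthIPSCParams, SynthSpikingParams


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture()
def noiseless_params():
    """Default train parameters with noise and the mGluR component removed."""
    return SynthIPSCParams(noise_sd_pA=0.0, mglur_tonic_amplitude_pA=0.0)


@pytest.fixture()
def nodrift_params(noiseless_params):
    """Noiseless parameters with the kinetic drift over the train disabled."""
    p = noiseless_params
    return dataclasses.replace(
        p,
        tau_fast_last_ms=p.tau_fast_first_ms,
        tau_slow_last_ms=p.tau_slow_first_ms,
        frac_fast_last=p.frac_fast_first,
    )


@pytest.fixture()
def rebound_params():
    return SynthSpikingParams(baseline_rate_Hz=40.0, rebound_rate_Hz=60.0)
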