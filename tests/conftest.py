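import numpy as np
import pytest

from microsurv.core_model import CellResponseParams
from microsurv.microdosimetry import SVGeometry, normalize_event_spectrum
from microsurv.response_function import ResponseParams
from microsurv.synthetic_data import (
    SpectrumModel,
    default_scenario,
    synth_single_event_spectrum,
)


@pytest.fixture(scope="session")
def ag_photon_params():
    """Best-fit photon parameters for AG01522 fibroblasts (225 kVp)."""
    return CellResponseParams(zF=0.6749, s=(1.0, 0.8568, 0.1289),
                              lnS0=-0.05, label="AG01522 225kVp")


@pytest.fixture(scope="session")
def v79_response():
    """Best-fit tanh response parameters for V79 cells."""
    return ResponseParams(b=0.504724, c=1.51547, q0=0.137499, label="V79")


@pytest.fixture(scope="session")
def table4_rows():
    """All three fitted response-parameter rows (b keV, c, q0 keV)."""
    return [
        ResponseParams(b=1.42799, c=0.953716, q0=-0.0471277, label="AG01522"),
        ResponseParams(b=19.6033, c=0.999835, q0=-0.00223896, label="U87"),
        ResponseParams(b=0.504724, c=1.51547, q0=0.137499, label="V79"),
    ]


@pytest.fixture(scope="session")
def gamma_f1():
    """Gamma-shaped single-event spectrum (qF ~ 0.94 keV, R = 0.4 um),
    the standard synthetic surrogate used throughout the suite."""
    pp = synth_single_event_spectrum(SpectrumModel(), E=30.0, R=0.4)
    from microsurv.microdosimetry import condition_per_particle

    return condition_per_particle(pp)


@pytest.fixture(scope="session")
def uniform_f1():
    """Uniform density on [0, 1] keV (closed-form convolution checks)."""
    n = 200
    return normalize_event_spectrum(np.ones(n), dq=1.0 / n,
                                    site=SVGeometry(R=0.5))


@pytest.fixture(scope="session")
def zero_noise_dataset():
    from microsurv.synthetic_data import synth_survival_dataset

    scn = default_scenario().with_(noise_sigma=0.0)
    curves, truth = synth_survival_dataset(scn)
    return scn, curves, truth
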