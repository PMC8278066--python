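import numpy as np
import pytest

from qnmr.config import default_config
from qnmr.containers import AcquisitionParams
from qnmr.presets import FLUTICASONE, INOSITOL
from qnmr.signal_model import AnalyteSpec, Line, SampleComponent, SampleSpec


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionParams:
    """Instrument defaults at a reduced point count for fast tests."""
    return AcquisitionParams(data_points=8192)


@pytest.fixture()
def clean_config():
    """Default two-analyte configuration, noise-free, small spectra."""
    return default_config(
        acquisition={"data_points": 8192},
        simulation={"amplitude_noise_frac": 0.0},
        samples=[],
    )


@pytest.fixture(scope="session")
def single_line_analyte() -> AnalyteSpec:
    """A one-line test compound on resonance at the carrier."""
    return AnalyteSpec(
        name="probe",
        molar_mass=100.0,
        purity_percent=100.0,
        n_protons=1,
        t1_s=1.5,
        lines=(Line(6.175, 1.0, 0.5),),
    )


def make_sample(*comps: tuple[AnalyteSpec, float], **kwargs) -> SampleSpec:
    defaults = dict(solvent_amplitude=0.0)
    defaults.update(kwargs)
    return SampleSpec(
        components=[
            SampleComponent(analyte=a, concentration_mg_ml=c) for a, c in comps
        ],
        **defaults,
    )


@pytest.fixture(scope="session")
def flp() -> AnalyteSpec:
    return FLUTICASONE


@pytest.fixture(scope="session")
def inositol() -> AnalyteSpec:
    return INOSITOL


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)
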