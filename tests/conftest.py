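import itertools

import numpy as np
import pytest

from rootsip.debye import debye_forward
from rootsip.scheme import ElectrodeArray, FourPointConfig, MeasurementScheme
from rootsip.spectra import ComplexSpectrum, FrequencyGrid


@pytest.fixture(scope="session")
def survey_grid() -> FrequencyGrid:
    """The standard 23-frequency log-even survey grid, 0.1 Hz - 10 kHz."""
    return FrequencyGrid.log_spaced(0.1, 1.0e4, 23)


@pytest.fixture(scope="session")
def analysis_grid() -> FrequencyGrid:
    """Survey grid capped at the 1 kHz analysis bound."""
    return FrequencyGrid.log_spaced(0.1, 1.0e3, 23)


@pytest.fixture
def single_debye_spectrum(analysis_grid) -> ComplexSpectrum:
    """Noise-free single-term spectrum: rho0=100 Ohm*m, m=0.05, tau=0.05 s."""
    rho = debye_forward(100.0, [0.05], [0.05], analysis_grid.frequencies)
    return ComplexSpectrum.from_complex(analysis_grid, rho)


def make_scheme(n_configs: int) -> MeasurementScheme:
    """A syntactically valid scheme with exactly n_configs configurations."""
    array = ElectrodeArray.line(16, 0.25)
    configs = []
    for m, n in itertools.combinations(range(3, 17), 2):
        if len(configs) == n_configs:
            break
        configs.append(
            FourPointConfig(1, 2, m, n, 1.0 + 0.1 * len(configs))
        )
    assert len(configs) == n_configs
    return MeasurementScheme(array, [(1, 2)], configs)
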