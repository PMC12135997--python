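import numpy as np
import pytest

from saskit import mixtures, synthetic_data
from saskit.sas_io import Curve


@pytest.fixture
def sphere_curve():
    """Ideal sphere (R = 10 nm) on a log-spaced low-s grid, no noise."""
    comp = mixtures.ComponentModel("sphere", {"R": 10.0})
    s = np.geomspace(0.005, 0.5, 300)
    return Curve(s, mixtures.form_factor(comp, s), np.full_like(s, np.nan),
                 label="sphere_R10")


@pytest.fixture
def guinier_curve():
    """Exact Guinier curve I = 10 exp(-3 s^2), i.e. Rg = 3, I0 = 10."""
    s = np.linspace(0.01, 0.5, 60)
    return Curve(s, 10.0 * np.exp(-3.0 * s ** 2), np.full_like(s, np.nan))


@pytest.fixture
def two_component_series():
    """Noiseless 2-component SEC-SAXS series with ground truth."""
    spec = synthetic_data.SyntheticSECSpec(noise_model="none")
    series, C, S = synthetic_data.make_sec_series(spec)
    return spec, series, C, S
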