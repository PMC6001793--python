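import numpy as np
import pytest
from hypothesis import settings

from nmrkit.core import DiffusionEncoding, RelaxationEncoding
from nmrkit.processing import fourier_transform
from nmrkit.simulate import LineSpec, make_diffusion_set, make_fid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_lines():
    return [
        LineSpec(-0.6, 1.0, 3.0),
        LineSpec(0.1, 0.7, 3.0),
        LineSpec(0.65, 0.5, 3.0),
    ]


@pytest.fixture(scope="session")
def single_line_spec():
    """One 2 Hz Lorentzian at 0.3 ppm, finely digitised."""
    fid = make_fid([LineSpec(0.3, 1.0, 2.0)], n_points=16384, dwell=2.5e-4)
    return fourier_transform(fid)


@pytest.fixture(scope="session")
def mixture_diffusion():
    """Two-component 60:40 mixture (D = 5e-10 / 1e-10 m^2/s) with
    overlapping spectra, 16 gradients equally spaced in g^2, noiseless."""
    lines = [
        LineSpec(-0.5, 0.36, 2.0, component_id=0, D=5e-10),
        LineSpec(0.1, 0.24, 2.0, component_id=0, D=5e-10),
        LineSpec(0.0, 0.20, 2.0, component_id=1, D=1e-10),
        LineSpec(0.5, 0.20, 2.0, component_id=1, D=1e-10),
    ]
    fid, enc = make_diffusion_set(
        lines, n_increments=16, gmax=0.5, gmin=0.03, n_points=1024, dwell=5e-4
    )
    return lines, fourier_transform(fid), enc


@pytest.fixture(scope="session")
def mono_diffusion():
    """Single-component decay, D = 5e-10 m^2/s, 16 gradients, noiseless."""
    lines = [LineSpec(0.0, 1.0, 2.0, D=5e-10)]
    fid, enc = make_diffusion_set(
        lines, n_increments=16, gmax=0.5, gmin=0.03, n_points=512, dwell=5e-4
    )
    return lines, fourier_transform(fid), enc


@pytest.fixture
def relaxation_times():
    return np.geomspace(0.05, 6.0, 12)


@pytest.fixture
def t2_encoding():
    return RelaxationEncoding(np.geomspace(0.05, 3.0, 12), mode="t2_decay")
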