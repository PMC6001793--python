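"""Multivariate mixture resolution: DECRA (algebraic) and SCORE (fitted).

A 60:40 two-component mixture with overlapping spectra is resolved into
component spectra, diffusion coefficients and integral fractions.
"""

import numpy as np

from nmrkit.decomposition import DecompositionOptions, decra, score_fit
from nmrkit.processing import fourier_transform
from nmrkit.simulate import LineSpec, make_diffusion_set

lines = [
    LineSpec(-0.5, 0.36, 2.0, component_id=0, D=5e-10),
    LineSpec(0.1, 0.24, 2.0, component_id=0, D=5e-10),
    LineSpec(0.0, 0.20, 2.0, component_id=1, D=1e-10),
    LineSpec(0.5, 0.20, 2.0, component_id=1, D=1e-10),
]
fid, enc = make_diffusion_set(
    lines, n_increments=16, gmax=0.5, gmin=0.03, n_points=1024, dwell=5e-4
)
X = fourier_transform(fid).data.real

d = decra(X, enc, 2)  # needs equal g^2 spacing; exact for pure exponentials
print("DECRA  D:", np.array2string(d.parameters, precision=3),
      " fractions %:", np.round(d.fractions, 2))

s = score_fit(X, enc, DecompositionOptions(n_components=2, init="decra"))
print("SCORE  D:", np.array2string(s.parameters, precision=3),
      " fractions %:", np.round(s.fractions, 2))
print(f"SCORE residual {s.residual_norm:.3e} <= DECRA residual {d.residual_norm:.3e}")
# both methods recover D = 5e-10 / 1e-10 m^2/s and the 60:40 split; DECRA
# is non-iterative and serves as SCORE's starting point
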