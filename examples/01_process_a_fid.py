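"""Process a single FID: apodise, Fourier transform, autophase, baseline.

Builds a three-line synthetic proton FID, deliberately misphases it, and
runs the standard processing chain.
"""

import numpy as np

from nmrkit.core import ApodisationParams
from nmrkit.processing import apodise, autophase, fourier_transform, phase
from nmrkit.simulate import LineSpec, make_fid

lines = [LineSpec(-0.6, 1.0, 3.0), LineSpec(0.1, 0.7, 3.0), LineSpec(0.65, 0.5, 3.0)]
fid = make_fid(lines, n_points=4096, dwell=5e-4, noise_sigma=0.002, seed=1)

# 1 Hz exponential line broadening for sensitivity, then FT
spec = fourier_transform(apodise(fid, ApodisationParams(lw=1.0)), fn=8192)
spec.pivot_hz = spec.axis_hz[int(np.argmax(np.abs(spec.data[0])))]

# inject a known misphase and let autophase find the correction
mis = phase(spec, 30.0, 40.0)
p0, p1 = autophase(mis)
fixed = phase(mis, p0[0], p1[0])

print(f"injected misphase : ph0=30.0  ph1=40.0 degrees")
print(f"autophase found   : ph0={-p0[0]:.2f} ph1={-p1[0]:.2f} degrees")
neg = fixed.data[0].real.min() / fixed.data[0].real.max()
print(f"most negative point after correction: {neg:.2e} of the tallest peak")
# the recovered phases match the injection to well under a degree, and the
# corrected spectrum is essentially pure absorption
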