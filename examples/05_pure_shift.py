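"""Pure shift reconstruction: concatenate interferogram chunks into a
homodecoupled 1D FID whose spectrum shows singlets only."""

import numpy as np
import scipy.signal

from nmrkit.processing import fourier_transform
from nmrkit.pure_shift import reconstruct
from nmrkit.simulate import LineSpec, make_pureshift_raw

decoupled = [LineSpec(-0.8, 1.0, 2.0), LineSpec(0.15, 0.7, 2.0),
             LineSpec(0.6, 0.9, 2.0)]
raw = make_pureshift_raw(decoupled, chunks=32, chunk_points=64, drop_points=2,
                         dwell=5e-4)
print(f"raw interferogram: {raw.n_increments} increments x {raw.n_points} points")

rec = reconstruct(raw)  # geometry read from the dataset metadata
print(f"reconstructed 1D FID: {rec.n_points} points")

spec = fourier_transform(rec, 4096)
r = spec.data[0].real
peaks, _ = scipy.signal.find_peaks(r, height=0.1 * r.max())
print(f"peaks in the pure shift spectrum: {len(peaks)} "
      f"(at {np.round(spec.axis_ppm[peaks], 2)} ppm)")
# one singlet per chemical shift: the multiplet structure is gone because
# each chunk samples the decoupled evolution only
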