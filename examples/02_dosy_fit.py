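"""High-resolution DOSY: peak-picked monoexponential Stejskal–Tanner fits.

Simulates a two-compound mixture over a 16-step gradient ramp and fits a
diffusion coefficient to every picked peak.
"""

from nmrkit.diffusion import dosy
from nmrkit.processing import fourier_transform
from nmrkit.simulate import LineSpec, make_diffusion_set

# two compounds: a fast diffuser (5e-10 m^2/s, two lines) and a slow one
lines = [
    LineSpec(-0.5, 1.0, 2.0, component_id=0, D=5e-10),
    LineSpec(0.1, 0.7, 2.0, component_id=0, D=5e-10),
    LineSpec(0.5, 0.6, 2.0, component_id=1, D=1e-10),
]
fid, encoding = make_diffusion_set(
    lines, n_increments=16, gmax=0.5, gmin=0.03, n_points=2048, dwell=5e-4,
    noise_sigma=0.003, seed=4,
)
spec = fourier_transform(fid)

pmap = dosy(spec, encoding, threshold=0.1 * spec.data.real.max())
print("peak ppm   D / 1e-10 m^2 s^-1   std.err.")
for p in sorted(pmap.peaks, key=lambda p: -p.position_ppm):
    print(f"  {p.position_ppm:6.2f}   {p.value * 1e10:8.4f}          {p.stderr * 1e10:.4f}")
# peaks of the same compound share a diffusion coefficient; the two
# compounds separate cleanly along the D axis of the DOSY map
print(f"DOSY map: {pmap.matrix.shape[0]} shift bins x {pmap.matrix.shape[1]} D bins")
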