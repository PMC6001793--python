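# nmrkit

Processing and analysis of single and arrayed 1D NMR data in Python:
Fourier processing, reference deconvolution, pure shift reconstruction,
diffusion (DOSY) and relaxation (ROSY) fitting, multivariate and multiway
decompositions, and arrayed-spectra diagnostics — with a built-in
synthetic-data simulator that every algorithm is validated against.

## Who this is for

Spectroscopists and method developers who work with *series* of 1D
spectra: pulsed-field-gradient diffusion arrays, inversion-recovery /
CPMG relaxation series, reaction-monitoring time courses, or long
stability runs. The package reads Bruker and Varian/Agilent raw data (and
its own plain internal format), processes it, and turns per-peak decays
or whole data matrices into physical parameters.

## The models at the core

**Diffusion.** Signal attenuation in a pulsed-gradient experiment follows
the Stejskal–Tanner equation

    I(g) = I0 · exp(−γ² δ² g² D Δ′)

with magnetogyric ratio γ, gradient pulse length δ, gradient amplitude g,
diffusion coefficient D and corrected diffusion time Δ′. `nmrkit.diffusion`
fits this per peak (optionally with a non-uniform-gradient power-series
exponent, or several components reduced by an F-test); `nmrkit.decomposition`
fits whole matrices: SCORE (bilinear `X = C(θ)·S`, spectra solved linearly),
OUTSCORE (minimal spectral cross-talk), DECRA (exact algebraic solution via
a generalized eigenproblem when g² is equally spaced), and a
Tikhonov-regularised inverse Laplace transform with GCV-chosen λ.

**Relaxation.** `nmrkit.relaxation` fits inversion recovery
`I = A + B·exp(−τ/T1)`, saturation recovery `A(1 − exp(−τ/T1))` and T2
decay `I0·exp(−t/T2)` (counter lists × loop duration supported), and
builds ROSY displays; RSCORE applies the SCORE machinery with relaxation
kernels.

**Reference deconvolution (FIDDLE).** Instrumental distortions multiply
the whole FID by one complex envelope. Dividing by the experimental FID
of a resolved reference signal and multiplying by an ideal one (with
TMS/TSP satellite patterns and a user-chosen target lineshape) removes
the distortion from every line in the spectrum.

**Pure shift.** Interferogram experiments record chunks of a
homodecoupled FID in successive increments; `nmrkit.pure_shift`
concatenates them into a 1D FID whose spectrum shows one singlet per
chemical shift.

**Multiway.** `nmrkit.multiway` fits the PARAFAC trilinear model
`X[i,j,k] = Σ_f A[i,f]·B[j,f]·C[k,f]` by alternating least squares
(optionally non-negative per mode), and PowerSlicing builds an artificial
third mode from shifted windows of an exponential axis so 2-way decays
become trilinear.

## A worked example

Resolve a two-compound mixture from a 16-step gradient array
(`examples/03_score_decra_mixture.py`):

```python
from nmrkit.decomposition import DecompositionOptions, decra, score_fit
from nmrkit.processing import fourier_transform
from nmrkit.simulate import LineSpec, make_diffusion_set

lines = [
    LineSpec(-0.5, 0.36, 2.0, component_id=0, D=5e-10),
    LineSpec(0.1, 0.24, 2.0, component_id=0, D=5e-10),
    LineSpec(0.0, 0.20, 2.0, component_id=1, D=1e-10),
    LineSpec(0.5, 0.20, 2.0, component_id=1, D=1e-10),
]
fid, enc = make_diffusion_set(lines, n_increments=16, gmax=0.5, gmin=0.03,
                              n_points=1024, dwell=5e-4)
X = fourier_transform(fid).data.real
d = decra(X, enc, 2)
s = score_fit(X, enc, DecompositionOptions(n_components=2, init="decra"))
```

prints

```
DECRA  D: [5.e-10 1.e-10]  fractions %: [60. 40.]
SCORE  D: [5.e-10 1.e-10]  fractions %: [60. 40.]
SCORE residual 2.400e-13 <= DECRA residual 2.552e-13
```

i.e. both methods recover the two diffusion coefficients
(5×10⁻¹⁰ and 1×10⁻¹⁰ m²/s) and the 60:40 signal split exactly on
noiseless data; DECRA is the non-iterative starting point for SCORE's
refinement. The `examples/` directory has one narrative script per
capability (processing + autophase, DOSY, FIDDLE, pure shift, ROSY,
PARAFAC, series diagnostics), each printing the numbers it computes and a
line on what they mean.

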