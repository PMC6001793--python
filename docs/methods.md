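# Methods

This note records the models, conventions, numerical choices and known
limitations behind `nmrkit`, in the order data flows through the package.

## Data model and conventions

A `FidSet` is a complex matrix of one FID per row with `dwell` (s per
complex point), `sfrq` (MHz) and a reference offset; a `SpectrumSet` adds
a **descending**, uniformly spaced Hz axis (left = high ppm, the NMR
display convention) and a per-column boolean mask that fitting routines
consult, so pruned regions are excluded without being deleted. Chemical
shift referencing is `ppm = (hz − ref_offset_hz)/sfrq`; `set_reference`
moves only the offset. Arrays over two independent variables are stored
flattened row-major with the first axis fastest, matching Bruker `ser`
ordering. Pruning increments removes rows from the data, every attached
axis and the encoding in lockstep; `prune-then-fit` equals
`fit-with-mask` by construction and is tested on synthetic data.

## Fourier processing

The forward transform halves the first FID point — the standard
correction that removes the flat baseline offset a one-sided signal
otherwise produces — then applies an FFT and maps to the descending axis.
`spectrum_to_fid` is its exact inverse (the first point is restored), so
"save processed spectra as a FID" round-trips to 1e-10 or better. A
real-only variant rebuilds the imaginary part by causal reconstruction
(double the first half of the inverse transform, zero the second); this
assumes the FID has decayed by the half-way point and is accurate to the
residual at that point.

Apodisation multiplies by
`w(t) = exp(−π·lw·t) · exp(−(π·gw·t/(2√ln2))²)`,
the unique form for which `lw` and `gw` are the *additional* Lorentzian
and Gaussian full widths at half height convolved into the spectrum; the
property tests verify exactly that (FT of a weighted constant FID has
FWHM = lw, resp. gw, within one grid step). Negative `lw` with positive
`gw` gives Lorentz–Gauss resolution enhancement.

### Automatic phasing

Each magnitude peak's misphase is measured in the time domain: the FID is
demodulated at the peak's refined frequency and summed under a
raised-cosine window that (a) is zero at t = 0, making the first-point
convention irrelevant, and (b) is confined to about six decay times of
the line (from its measured width), so signal-free samples do not dilute
the estimate with noise. At the magnitude-maximising frequency the sum's
angle is the line's phase error; `−(ph0 + ph1·(f−pivot)/SW)` is then
fitted to the per-peak angles by amplitude-weighted least squares with
unwrapping. Peak finding runs on a 4× trigonometrically interpolated
spectrum with a prominence filter that rejects interpolation ripples
riding on strong tails. On synthetic three-line spectra the injected
(30°, 40°) misphase is recovered to better than 0.1° even with 1% noise;
a single usable peak constrains ph0 only, and an all-noise spectrum
returns (0, 0) with a warning. The first-order term is normalised per
full sweep width; the default pivot is the tallest peak.

### Baseline correction

Manual mode fits a user-order polynomial (numerically conditioned on
[−1, 1]) to the real part at points outside the declared signal regions
and subtracts it. Automatic mode iterates fit → reclassify (|residual| <
3σ is baseline) → refit until the classification stabilises, at most 20
passes. The operation is idempotent on its own output to the tail-ripple
level. Note that Lorentzian absorption tails decay only as 1/Δf², so "the
baseline" under a polynomial model is only exactly recoverable for
well-decayed Gaussian-like lines; the exactness tests use those.

## Reference deconvolution (FIDDLE)

Per increment: the displayed spectrum is zeroed outside the reference
region and inverse-transformed (plain inverse DFT) to the experimental
reference FID `r_exp(t)`. The ideal reference — centre line plus
configurable satellites (defaults: ²⁹Si 4.7% at J = 6.6 Hz for TMS, ¹³C
1.1% at J = 118 Hz for TMS/TSP), times the target weighting — is passed
through the *same* windowed extraction, so the correction
`c(t) = r_id(t)/r_exp(t)` is exactly unity wherever the region content
already matches the ideal. The ideal's complex amplitude is fitted to
`r_exp` by least squares and its phase discarded (the ideal is pure
absorption), which is what removes constant phase errors; the ideal is
built at one common frequency (the first increment's tallest point), so
per-increment frequency drift is realigned. The division is stabilised by
hard truncation: `c = 0` where `|r_exp|` falls below `eps` (default 1e-3)
of its maximum.

Consequences worth knowing: (i) data whose reference already has the
target shape are a fixed point (identity to 1e-10 with `eps` below the
decay floor); (ii) when the correction genuinely changes the lineshape, a
second application still moves the result at the level of the dispersion
tails truncated at the region edges (~1e-3 relative) — inherent to
windowed extraction, not iteration error; (iii) the tests drive a
five-line spectrum distorted by one random smooth complex envelope to a
1 Hz Gaussian target and verify every line lands within 5%.

## Pure shift reconstruction

`reconstruct` concatenates `inc_1[drop : drop+first_chunk]` then
`inc_r[drop : drop+chunk_points]` for the remaining chunks; the output
length is exactly `first_chunk + (chunks−1)·chunk_points` and the dwell
is preserved. `drop_points` applies to **every** chunk including the
first, and `first_chunk` counts points *kept* — the composition rule is
stated here because acquisition schemes differ; the simulator generates
raw data under the same rule, giving the tests an exact closed-form
target (equality to 1e-12). No chunk-edge apodisation is applied;
sidebands are accepted as in interferogram practice. Geometry errors name
the offending increment.

## Diffusion fitting

`fit_monoexp` runs Levenberg–Marquardt on `(I0, ln D)` — positivity of D
by construction, no bound-related stalling — with a two-point log-linear
initial D and standard errors from the Jacobian (delta method back to D).
A 200-repeat Monte-Carlo check confirms the reported standard error
tracks the empirical scatter within 30% at 1% noise. Flat decays pin D
near zero and set a warning flag rather than raising. The optional NUG
kernel replaces the exponent by the power series `Σ c_m (X·D)^m`
(`c = [1]` reproduces the pure exponential bit-near).

`fit_multiexp` fits K, K−1, … components (multi-start in log-spaced
rates) and keeps the largest k whose F-test against k−1 components is
significant at α = 0.05 *and* whose amplitudes all exceed twice their
standard error — a concrete reduction rule chosen here; an RSS already at
machine precision is treated as unimprovable so the F-test is not applied
to numerical noise.

DOSY maps place one Gaussian ridge per peak along a log-spaced D axis
(default 64 bins spanning 0.1–10× the fitted range), σ = the fit's
standard error floored at one bin, normalised on the actual grid so each
ridge integrates to its peak amplitude within 1%. Peak amplitudes for
decay extraction are real-part heights at the picked index (HR-DOSY
practice); integral-region mode uses region sums.

## Multivariate decompositions

SCORE minimises `‖X − C(θ)S‖²` over per-component decay constants θ with
S solved per frequency column by (optionally non-negative) linear least
squares; the outer search is a Nelder–Mead simplex on log θ, initialised
from DECRA when the spacing allows (else log-spaced), restarted once from
a perturbed start if the noiseless-quality relative residual 1e-6 is not
reached. Integral fractions are `100·Σ_j S_kj / ΣΣ`. OUTSCORE keeps the
parameterisation but minimises the normalised cross-talk
`Σ_{a<b} Σ_j |S_aj||S_bj|/(‖S_a‖‖S_b‖)`, started from the SCORE solution
(so its cross-talk can only improve); with strictly disjoint spectral
supports it is exact.

DECRA splits the matrix into the two row-shifted sub-arrays A, B; in A's
rank-K SVD basis the transfer matrix `T = Σ⁻¹U′BV` has eigenvalues
`ρ_k = exp(−D_k ΔX)` — exact for noiseless exponentials on an equally
spaced g² grid (checked to 1e-6 relative spacing; unequal spacing raises
rather than silently interpolating). Component amplitudes are
extrapolated to zero gradient before fractions are computed. Complex or
non-positive eigenvalues flag a model violation; with K = n−1 the
truncated SVD retains A's full rank and the eigen-system is solved
exactly (`svd_residual` = 0), which is the honest meaning of the
"interpolation regime".

The ILT solves `min ‖Kx − b‖² + λ²‖x‖²` (identity regularisation
operator, the cited toolbox's simplest form) on a log-spaced rate grid,
non-negative by default via NNLS on the augmented system; λ comes from
generalized cross-validation on the SVD filter factors when not given.
Solution mass at the grid edge triggers a warning.

## Relaxation

Inversion recovery uses the robust three-parameter form
`A + B·exp(−τ/T1)` by default (imperfect inversion; `B = −2A` recovers
the textbook case, available by flag), saturation recovery the
two-parameter form, T2 a plain exponential with counter-list ×
loop-duration support. All fits are amplitude-scale invariant. ROSY maps
mirror the DOSY construction with a T axis, or a rate axis 1/T on request
(both offered; neither is privileged). RSCORE is SCORE with the t1ir /
t1sr / t2 kernel.

## PARAFAC and PowerSlicing

ALS solves each mode's unfolding in turn (NNLS per row when
constrained); the residual is checked every iteration and a genuine
increase aborts with diagnostics. Initialisation: leading singular
vectors of the unfoldings (`svd`), `random`, or `best_of_n` (five random
starts plus one SVD start, 30 trial iterations each, best continued).
Factors are reported with modes B and C unit-norm, scale in A, ordered by
explained variation. The default stop is a relative fit change below
1e-12 (2500 iterations cap): 1e-9-level tolerances can stop inside an ALS
"swamp" where the fit looks converged while factors are still mixing —
with strongly correlated concentration profiles even 1e-12 may leave a
weak component biased, and tightening `tol` toward 1e-16 resolves it (see
`examples/07_parafac_reaction.py`). Degeneracy of this kind is inherent
to trilinear fitting, not an implementation artefact.

PowerSlicing maps a points × increments matrix to a cube whose slab s
holds columns [s, s+L); for pure exponentials on an equally spaced
exponent grid the third-mode loading of component k is `ρ_k^s`, so
PARAFAC reproduces DECRA's decay constants (two-slab slicing is exactly
DECRA's split, and the tests verify agreement to 1e-8). Only unit-shift
slabs are implemented; the default slab count is 3. Diagnostics return
per-mode leverages `diag(F(FᵀF)⁻¹Fᵀ)` and residual sums per slice —
values only, plotting is left to the caller.

## Series diagnostics

`track_peak` follows the tallest real-part peak per increment (parabolic
position refinement, FWHM by linear interpolation at half height);
increments with no qualifying peak record NaN. Temperature change is
`ΔT_i = (δ_i − δ_1)/coeff`, **relative to the first increment**, with
calibration slopes 2.97×10⁻⁴ ppm/K (HDO) and 1.14×10⁻² ppm/K (TSP);
positive ppm drift maps to positive ΔT through the positive slope, the
estimator is exactly linear in the displacement, and the tracked peak
must stay inside the analysed window. Phase deviation shifts the spectrum
by +90° and inverts the closed-form Lorentzian excursion asymmetry
`ρ(φ)` (extrema at `x = tanφ ± secφ`; monotone for |φ| < 45°, beyond
which NaN is recorded); a broad Lorentzian apodisation beforehand makes
real lines sufficiently Lorentzian, and a brute-force tabulation oracle
agrees within 0.2° over ±20°. Integration is region sum × ppm step with
optional offset/tilt removal (line through the means of the first/last
max(1, 3%) points) and region-anchored normalisation. Binning sums real
intensities into contiguous ppm bins (total conserved exactly).
Alignment is integer-point, non-circular (edges zero-filled): manual
per-increment shifts, or per-interval cross-correlation against the
median spectrum — a deliberately simplified interval aligner, not a full
reimplementation of the published interval-correlation algorithm.

## The simulator and what passing tests mean

`nmrkit.simulate` generates every test input: multi-line complex FIDs
with Lorentzian/Gaussian lineshapes (J-multiplets are modelled as
explicit line lists, not spin dynamics), per-component Stejskal–Tanner
attenuation over gradient ramps (equal-g or equal-g², defaults 16
increments, g from 0.03 to 0.5 T/m, ¹H γ, δ = 2 ms, Δ′ = 100 ms — so
X·D spans ~0.01–3.6 for D = 10⁻¹⁰–5×10⁻¹⁰ m²/s, a realistic small-
molecule window), IR/SR/T2 relaxation series, exactly trilinear reaction
cubes, common-envelope lineshape distortions, interferogram pure shift
raw data with an exact reconstruction target, and on-disk Bruker/Varian
fixture directories for the readers. Noise is complex circular Gaussian
with an absolute σ per quadrature component; all generators are pure
functions of (parameters, seed).

What the simulator does *not* emulate — and therefore what green tests do
not certify about real data: radiation damping, convection, temperature
drift beyond a linear shift, J-modulation during gradient encoding,
rf-inhomogeneity, baseline roll from transient effects, and non-common
(line-specific) lineshape distortions, which FIDDLE cannot remove by
design.

## I/O

Bruker: JCAMP `acqus` keys (TD, SW_h, SFO1, O1, BYTORDA, DTYPA, GRPDLY,
NC), interleaved real/imag `fid`/`ser`, `difflist`/`vdlist`/`vclist`
arrays. The digital-filter group delay is handled by discarding
`round(GRPDLY)` complex points — the simplest defensible choice; a
first-order-phase treatment is possible but not default. DTYPA absent
means int32 (the legacy default); int data are scaled by the
power-of-two `NC` exponent, so fixture round-trips are exact to half an
LSB. The fixture writer does not emulate Bruker's 1024-byte row padding;
readers and writers here agree and are exercised against each other.
Varian: big-endian `fid` with file/block headers (16/32-bit int and
float storage by status flags; unknown flags raise with a flag dump) and
a minimal `procpar` parser; one global scale per dataset preserves
relative block amplitudes under integer storage. Consecutively numbered
1D directories are stacked after checking dwell/sfrq agreement. The
internal format is `meta.json` plus IEEE-754 double little-endian binary
or "real imag"-per-line ASCII; write∘read is the identity (bit-exact in
binary). Exporters write CSV at 17 significant digits in a fixed column
order, or JSON that reloads equal.

## Scale of the validation problems

Test and acceptance problems are sized for interactive runs: 512–16384
complex points, 8–32 increments, 200-repeat Monte-Carlo for the noise
calibration, 10×12×200 reaction cubes. These sizes are comfortably past
the asymptotic behaviour of every algorithm here (FFTs, small dense
eigenproblems, few-parameter nonlinear fits), so nothing qualitative
changes at acquisition-sized data beyond runtime.
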