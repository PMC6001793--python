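"""Basic FID/spectrum processing: zero-filling, apodisation, Fourier
transformation, phase correction, baseline correction and referencing.

The forward transform halves the first FID point (the standard DC-offset
convention) and produces a descending frequency axis spanning the sweep
width, centred on the carrier.  :func:`spectrum_to_fid` is its exact inverse
and is what "save as FID" style round-trips build on.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import ApodisationParams, FidSet, SpectrumSet, ppm_to_hz

__all__ = [
    "zero_fill",
    "apodise",
    "apodisation_weights",
    "fourier_transform",
    "spectrum_to_fid",
    "phase",
    "autophase",
    "baseline_correct",
    "set_reference",
]

_GAUSS_NORM = 2.0 * np.sqrt(np.log(2.0))


def zero_fill(fid: FidSet, fn: int) -> FidSet:
    """Pad with zeros (or truncate) to ``fn`` complex points."""
    if fn < 2:
        raise ValueError("fn must be >= 2")
    out = fid.copy()
    n = fid.n_points
    if fn <= n:
        out.data = out.data[:, :fn].copy()
    else:
        pad = np.zeros((fid.n_increments, fn - n), dtype=complex)
        out.data = np.hstack([out.data, pad])
    return out


def apodisation_weights(n_points: int, dwell: float, params: ApodisationParams) -> np.ndarray:
    """w(t) = exp(-pi*lw*t) * exp(-(pi*gw*t / (2*sqrt(ln 2)))**2).

    ``lw`` and ``gw`` are the Lorentzian and Gaussian FWHM (Hz) convolved
    into the spectrum; w(0) = 1 for any parameters.
    """
    t = np.arange(n_points) * dwell
    w = np.exp(-np.pi * params.lw * t)
    if params.gw != 0.0:
        w = w * np.exp(-((np.pi * params.gw * t / _GAUSS_NORM) ** 2))
    return w


def apodise(fid: FidSet, params: ApodisationParams) -> FidSet:
    """Multiply every FID by the Lorentzian/Gaussian weighting function."""
    out = fid.copy()
    out.data = out.data * apodisation_weights(fid.n_points, fid.dwell, params)
    return out


def fourier_transform(fid: FidSet, fn: int | None = None) -> SpectrumSet:
    """Discrete FT with first-point-halved convention.

    The Fourier number ``fn`` sets the spectrum size (zero-filling or
    truncation applied internally); the axis is descending Hz relative to
    the carrier.
    """
    if fn is None:
        fn = fid.n_points
    if fn < 2:
        raise ValueError("fn must be >= 2")
    work = fid.data[:, :fn] if fn < fid.n_points else fid.data
    work = work.copy()
    work[:, 0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(work, n=fn, axis=1), axes=1)
    freqs = np.fft.fftshift(np.fft.fftfreq(fn, d=fid.dwell))
    return SpectrumSet(
        data=spec[:, ::-1],
        axis_hz=freqs[::-1],
        sfrq=fid.sfrq,
        dwell=fid.dwell,
        ref_offset_hz=fid.ref_offset_hz,
        arrays=[a for a in fid.arrays],
        meta=dict(fid.meta),
    )


def spectrum_to_fid(spec: SpectrumSet) -> FidSet:
    """Exact inverse of :func:`fourier_transform` (first point un-halved)."""
    asc = spec.data[:, ::-1]
    work = np.fft.ifft(np.fft.ifftshift(asc, axes=1), axis=1)
    work[:, 0] *= 2.0
    return FidSet(
        data=work,
        dwell=spec.dwell,
        sfrq=spec.sfrq,
        ref_offset_hz=spec.ref_offset_hz,
        arrays=[a for a in spec.arrays],
        meta=dict(spec.meta),
    )


def _phase_factor(
    axis_hz: np.ndarray, sw: float, ph0: float, ph1: float, pivot_hz: float
) -> np.ndarray:
    phi = np.deg2rad(ph0 + ph1 * (axis_hz - pivot_hz) / sw)
    return np.exp(1j * phi)


def phase(
    spec: SpectrumSet,
    ph0,
    ph1=0.0,
    pivot_hz: float | None = None,
    mode: str = "global",
) -> SpectrumSet:
    """Apply zeroth/first order phase correction.

    ``S'(f) = S(f) * exp(i*(ph0 + ph1*(f - pivot)/SW) * pi/180)``; the value
    at the pivot is untouched by ``ph1``.  In ``individual`` mode ``ph0``
    and ``ph1`` may be per-increment sequences.
    """
    out = spec.copy()
    if pivot_hz is None:
        pivot_hz = spec.pivot_hz
    sw = spec.sweep_width_hz
    if mode == "global":
        fac = _phase_factor(spec.axis_hz, sw, float(np.asarray(ph0).ravel()[0]),
                            float(np.asarray(ph1).ravel()[0]), pivot_hz)
        out.data = out.data * fac
        out.ph0 += float(np.asarray(ph0).ravel()[0])
        out.ph1 += float(np.asarray(ph1).ravel()[0])
    elif mode == "individual":
        p0 = np.broadcast_to(np.asarray(ph0, dtype=float), (spec.n_increments,))
        p1 = np.broadcast_to(np.asarray(ph1, dtype=float), (spec.n_increments,))
        for i in range(spec.n_increments):
            out.data[i] *= _phase_factor(spec.axis_hz, sw, p0[i], p1[i], pivot_hz)
    else:
        raise ValueError("mode must be 'global' or 'individual'")
    out.pivot_hz = pivot_hz
    return out


def _zoom_row(row: np.ndarray, factor: int) -> np.ndarray:
    """Trigonometric interpolation of a (descending-axis) spectrum row onto
    a ``factor``-times finer grid over the same sweep width."""
    n = row.size
    td = np.fft.ifft(np.fft.ifftshift(row[::-1]))
    td = np.concatenate([td, np.zeros((factor - 1) * n, dtype=complex)])
    return np.fft.fftshift(np.fft.fft(td))[::-1]


def _find_magnitude_peaks(mag: np.ndarray, threshold_frac: float, min_sep: int):
    """Local maxima of a magnitude spectrum above ``threshold_frac`` of the
    tallest, at least ``min_sep`` bins apart (strongest wins).  A
    prominence requirement rejects interpolation ripples riding on the
    tails of strong lines."""
    import scipy.signal

    top = mag.max()
    idx, _ = scipy.signal.find_peaks(
        mag,
        height=threshold_frac * top,
        prominence=0.5 * threshold_frac * top,
    )
    idx = sorted(idx, key=lambda i: -mag[i])
    kept: list[int] = []
    for i in idx:
        if all(abs(i - j) > min_sep for j in kept):
            kept.append(int(i))
    return kept


def _demodulated_phase(
    td: np.ndarray, dwell: float, fc0: float, search_hz: float,
    lw_hz: float | None = None,
) -> tuple[float, float]:
    """Phase of the resonance near ``fc0`` measured in the time domain.

    The FID is demodulated at a trial frequency and summed under a raised-
    cosine window (zero at both ends, so the first-point convention is
    irrelevant and neighbouring-line leakage is strongly suppressed).  The
    window is confined to roughly six decay times of the line (from its
    measured width ``lw_hz``) so late, signal-free samples do not dilute
    the estimate with noise.  The frequency is refined by maximising the
    demodulated magnitude, at which point the sum's angle is the line's
    misphase.  Returns (angle_rad, fc).
    """
    n = td.size
    t = np.arange(n) * dwell
    if lw_hz is not None and lw_hz > 0:
        t_w = min(n * dwell, 6.0 / (np.pi * lw_hz))
    else:
        t_w = n * dwell
    m = max(int(round(t_w / dwell)), 8)
    window = np.zeros(n)
    window[:m] = np.sin(np.pi * np.arange(m) / m) ** 2

    def negmag(fc: float) -> float:
        return -abs(np.sum(td * np.exp(-2j * np.pi * fc * t) * window))

    res = minimize_scalar(
        negmag, bounds=(fc0 - search_hz, fc0 + search_hz), method="bounded",
        options={"xatol": 1e-7 * max(abs(fc0), 1.0) + 1e-9},
    )
    fc = float(res.x)
    z = np.sum(td * np.exp(-2j * np.pi * fc * t) * window)
    return float(np.angle(z)), fc


def autophase(
    spec: SpectrumSet, mode: str = "global", fit_ph1: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the (ph0, ph1) correction that brings spectra to absorption.

    Each magnitude peak's misphase is measured by Hann-windowed time-domain
    demodulation at its (refined) frequency; ``-(ph0 + ph1*(f-pivot)/SW)``
    is then fitted to the measured angles by amplitude-weighted least
    squares (phases unwrapped across the spectrum).  A single usable peak
    fixes ph0 only.  Returns per-increment arrays; in ``global`` mode every
    entry is the same pair, measured on the increment-summed data.  Apply
    via :func:`phase`.  An all-noise spectrum yields (0, 0) with a warning.
    """
    axis = spec.axis_hz
    sw = spec.sweep_width_hz
    pivot = spec.pivot_hz
    n_inc = spec.n_increments

    zoom = 4

    def solve(row: np.ndarray) -> tuple[float, float]:
        mag = np.abs(row)
        noise = 1.4826 * np.median(np.abs(mag - np.median(mag)))
        if mag.max() == 0.0 or mag.max() < 8 * noise:
            warnings.warn("no signal above noise; returning zero phases")
            return 0.0, 0.0
        n = row.size
        fine = _zoom_row(row, zoom)
        fine_axis = np.fft.fftshift(np.fft.fftfreq(zoom * n, d=spec.dwell))[::-1]
        fine_mag = np.abs(fine)
        kept = _find_magnitude_peaks(fine_mag, 0.1, 8 * zoom)
        if not kept:
            warnings.warn("no peaks found; returning zero phases")
            return 0.0, 0.0
        td = np.fft.ifft(np.fft.ifftshift(row[::-1]))
        step = abs(fine_axis[1] - fine_axis[0])
        meas = []
        for i in kept:
            # half-height width of this peak, for the demodulation window
            half = fine_mag[i] / 2.0
            left = i
            while left > 0 and fine_mag[left] > half:
                left -= 1
            right = i
            while right < fine_mag.size - 1 and fine_mag[right] > half:
                right += 1
            lw = (right - left) * step
            ang, fc = _demodulated_phase(td, spec.dwell, fine_axis[i], step, lw)
            meas.append((fc, fine_mag[i], ang))
        meas.sort(key=lambda m: m[0])
        angles = np.unwrap(np.array([m[2] for m in meas]))
        x = np.array([(m[0] - pivot) / sw for m in meas])
        wts = np.array([m[1] for m in meas])
        if fit_ph1 and len(meas) > 1:
            A = np.column_stack([np.ones_like(x), x])
            sol, *_ = np.linalg.lstsq(A * wts[:, None], angles * wts, rcond=None)
            p0, p1 = -np.rad2deg(sol)
        else:
            p0 = -np.rad2deg(np.average(angles, weights=wts))
            p1 = 0.0
        p0 = (p0 + 180.0) % 360.0 - 180.0
        return float(p0), float(p1)

    if mode == "global":
        p0, p1 = solve(spec.data.sum(axis=0))
        return np.full(n_inc, p0), np.full(n_inc, p1)
    elif mode == "individual":
        pairs = [solve(spec.data[i]) for i in range(n_inc)]
        return (np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))
    raise ValueError("mode must be 'global' or 'individual'")


def baseline_correct(
    spec: SpectrumSet,
    signal_regions: Sequence[tuple[float, float]] | None = None,
    order: int = 2,
    max_iter: int = 20,
) -> SpectrumSet:
    """Polynomial baseline correction of the real part.

    With ``signal_regions`` (ppm intervals) given, every point outside them
    is baseline; the degree-``order`` polynomial least-squares fit to those
    points is subtracted.  Without regions the automatic mode iterates:
    fit on the current baseline set, reclassify points with residual
    magnitude below 3 sigma as baseline, refit — until the classification
    is stable (at most ``max_iter`` passes).
    """
    out = spec.copy()
    n = spec.fn
    x = np.linspace(-1.0, 1.0, n)  # conditioning

    if signal_regions is not None:
        base = np.ones(n, dtype=bool)
        for lo, hi in signal_regions:
            base &= ~spec.region_slice(lo, hi)
        if base.sum() <= order:
            raise ValueError("polynomial order >= number of baseline points")
        for i in range(spec.n_increments):
            y = out.data[i].real
            coeffs = np.polynomial.polynomial.polyfit(x[base], y[base], order)
            fit = np.polynomial.polynomial.polyval(x, coeffs)
            out.data[i] = (y - fit) + 1j * out.data[i].imag
        return out

    for i in range(spec.n_increments):
        y = out.data[i].real
        base = np.ones(n, dtype=bool)
        for _ in range(max_iter):
            if base.sum() <= order:
                raise ValueError("polynomial order >= number of baseline points")
            coeffs = np.polynomial.polynomial.polyfit(x[base], y[base], order)
            fit = np.polynomial.polynomial.polyval(x, coeffs)
            resid = y - fit
            sigma = resid[base].std()
            new_base = np.abs(resid) < 3.0 * sigma if sigma > 0 else base
            if not new_base.any():
                break
            if np.array_equal(new_base, base):
                break
            base = new_base
        out.data[i] = (y - fit) + 1j * out.data[i].imag
    return out


def set_reference(
    spec: SpectrumSet, observed_ppm: float, assigned_ppm: float
) -> SpectrumSet:
    """Recalibrate the ppm axis so the peak observed at ``observed_ppm``
    reads ``assigned_ppm``.  Shifts the reference offset; the Hz axis
    relative to the carrier is untouched."""
    out = spec.copy()
    out.ref_offset_hz = spec.ref_offset_hz - ppm_to_hz(
        assigned_ppm - observed_ppm, spec.sfrq, 0.0
    )
    return out
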