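"""ROSY: per-peak T1/T2 fitting and pseudo-2D relaxation maps, plus the
RSCORE multivariate variant.

Inversion recovery uses the robust three-parameter form
``I(tau) = A + B exp(-tau/T1)`` (B ~ -2A for perfect inversion) by
default; a two-parameter perfect-inversion fit is available by flag.
CPMG/PROJECT-style T2 series may be specified by counter lists, in which
case the evolution time is ``counter * loop_duration``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .core import PeakFit, PseudoMap, RelaxationEncoding, SpectrumSet
from .decomposition import DecompositionOptions, score_fit
from .diffusion import _ridge_matrix, peak_decays, pick_peaks

__all__ = [
    "fit_t1_ir",
    "fit_t1_sr",
    "fit_t2",
    "build_rosy_map",
    "rscore_fit",
    "rosy",
]


def _finish(popt, pcov, t_index, y, model, position_ppm, amplitude, extra):
    resid = model(None) - y
    rss = float(resid @ resid)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return PeakFit(
        position_ppm=position_ppm,
        amplitude=amplitude,
        value=float(popt[t_index]),
        stderr=float(se[t_index]),
        rss=rss,
        n_points_used=int(y.size),
        extra=extra,
    )


def fit_t1_ir(
    decay: np.ndarray,
    times: np.ndarray | RelaxationEncoding,
    position_ppm: float = 0.0,
    two_parameter: bool = False,
) -> PeakFit:
    """Inversion-recovery T1 fit: ``I = A + B exp(-tau/T1)``.

    ``two_parameter`` fixes B = -2A (perfect inversion).
    """
    tau = times.times if isinstance(times, RelaxationEncoding) else np.asarray(times, float)
    y = np.asarray(decay, dtype=float)
    A0 = y[np.argmax(tau)]
    T0 = tau[np.argmin(np.abs(y))] / np.log(2) if np.any(y < 0) else np.median(tau)
    T0 = T0 if T0 > 0 else np.median(tau)
    if two_parameter:
        def f(t, A, T1):
            return A * (1.0 - 2.0 * np.exp(-t / T1))

        popt, pcov = curve_fit(f, tau, y, p0=[A0, T0], maxfev=20000)
        model = lambda _: f(tau, *popt)  # noqa: E731
        return _finish(popt, pcov, 1, y, model, position_ppm, float(popt[0]),
                       {"A": float(popt[0]), "form": "ir2"})

    def f(t, A, B, T1):
        return A + B * np.exp(-t / T1)

    popt, pcov = curve_fit(f, tau, y, p0=[A0, -2 * A0, T0], maxfev=20000)
    model = lambda _: f(tau, *popt)  # noqa: E731
    return _finish(popt, pcov, 2, y, model, position_ppm, float(popt[0]),
                   {"A": float(popt[0]), "B": float(popt[1]), "form": "ir3"})


def fit_t1_sr(
    decay: np.ndarray,
    times: np.ndarray | RelaxationEncoding,
    position_ppm: float = 0.0,
) -> PeakFit:
    """Saturation-recovery T1 fit: ``I = A (1 - exp(-tau/T1))``."""
    tau = times.times if isinstance(times, RelaxationEncoding) else np.asarray(times, float)
    y = np.asarray(decay, dtype=float)

    def f(t, A, T1):
        return A * (1.0 - np.exp(-t / T1))

    popt, pcov = curve_fit(f, tau, y, p0=[y[np.argmax(tau)], np.median(tau)], maxfev=20000)
    model = lambda _: f(tau, *popt)  # noqa: E731
    return _finish(popt, pcov, 1, y, model, position_ppm, float(popt[0]),
                   {"A": float(popt[0]), "form": "sr"})


def fit_t2(
    decay: np.ndarray,
    times: np.ndarray | RelaxationEncoding | None = None,
    counters: np.ndarray | None = None,
    loop_duration: float | None = None,
    position_ppm: float = 0.0,
) -> PeakFit:
    """T2 decay fit ``I = I0 exp(-t/T2)``; CPMG/PROJECT counter lists are
    converted with ``t = counter * loop_duration``."""
    if counters is not None:
        if loop_duration is None or loop_duration <= 0:
            raise ValueError("counters require a positive loop_duration")
        t = np.asarray(counters, dtype=float) * loop_duration
    elif isinstance(times, RelaxationEncoding):
        t = times.times
    elif times is not None:
        t = np.asarray(times, dtype=float)
    else:
        raise ValueError("either times or counters must be given")
    y = np.asarray(decay, dtype=float)

    def f(tt, I0, T2):
        return I0 * np.exp(-tt / T2)

    span = t.max() - t.min() or 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = y[np.argmax(t)] / y[np.argmin(t)]
    T0 = span / np.log(1 / ratio) if 0 < ratio < 1 else np.median(t)
    popt, pcov = curve_fit(f, t, y, p0=[y[np.argmin(t)], T0], maxfev=20000)
    model = lambda _: f(t, *popt)  # noqa: E731
    return _finish(popt, pcov, 1, y, model, position_ppm, float(popt[0]),
                   {"I0": float(popt[0]), "form": "t2"})


def build_rosy_map(
    peaks: list[PeakFit],
    n_bins: int = 64,
    t_range: tuple[float, float] | None = None,
    shift_axis_ppm: np.ndarray | None = None,
    rate: bool = False,
) -> PseudoMap:
    """Chemical shift × T (or rate 1/T with ``rate=True``) pseudo-2D map,
    one Gaussian ridge per fitted peak (mirror of the DOSY display)."""
    good = [p for p in peaks if np.isfinite(p.value) and p.value > 0]
    if not good:
        raise ValueError("no successful fits to map")
    if rate:
        from dataclasses import replace

        good = [
            replace(p, value=1.0 / p.value, stderr=p.stderr / p.value**2)
            for p in good
        ]
    if t_range is None:
        vmin = min(p.value for p in good)
        vmax = max(p.value for p in good)
        t_range = (0.1 * vmin, 10.0 * vmax)
    axis = np.geomspace(t_range[0], t_range[1], n_bins)
    if shift_axis_ppm is None:
        ppms = [p.position_ppm for p in good]
        lo, hi = min(ppms), max(ppms)
        pad = 0.05 * (hi - lo + 1.0)
        shift_axis_ppm = np.linspace(hi + pad, lo - pad, max(len(good) * 8, 64))
    matrix = _ridge_matrix(good, shift_axis_ppm, axis)
    return PseudoMap(
        matrix=matrix,
        shift_axis_ppm=shift_axis_ppm,
        rate_axis=axis,
        peaks=good,
        rate_label="R / s^-1" if rate else "T / s",
    )


_MODE_TO_KERNEL = {
    "inversion_recovery": "t1ir",
    "saturation_recovery": "t1sr",
    "t2_decay": "t2",
}

_MODE_TO_FIT = {
    "inversion_recovery": fit_t1_ir,
    "saturation_recovery": fit_t1_sr,
    "t2_decay": fit_t2,
}


def rscore_fit(X, times, opts: DecompositionOptions):
    """SCORE machinery with a relaxation kernel (t1ir, t1sr or t2)."""
    if opts.kernel not in ("t1ir", "t1sr", "t2"):
        raise ValueError("rscore requires a relaxation kernel")
    enc = times if isinstance(times, RelaxationEncoding) else RelaxationEncoding(
        np.asarray(times, dtype=float),
        mode={"t1ir": "inversion_recovery", "t1sr": "saturation_recovery",
              "t2": "t2_decay"}[opts.kernel],
    )
    out = score_fit(X, enc, opts)
    out.method = "rscore"
    return out


def rosy(
    spec: SpectrumSet,
    encoding: RelaxationEncoding,
    threshold: float,
    window_ppm: tuple[float, float] | None = None,
    rate: bool = False,
    n_bins: int = 64,
) -> PseudoMap:
    """Peak-picked ROSY pipeline: pick on the increment with the largest
    total signal, fit each peak's recovery/decay, assemble the map."""
    strongest = int(np.argmax(np.abs(spec.data.real).sum(axis=1)))
    picked = pick_peaks(spec, threshold, window_ppm, row=strongest)
    if not picked:
        raise ValueError("no peaks above threshold")
    decays = peak_decays(spec, picked)
    fitter = _MODE_TO_FIT[encoding.mode]
    fits = [
        fitter(decays[k], encoding, position_ppm=picked[k]["ppm"])
        for k in range(len(picked))
    ]
    return build_rosy_map(fits, n_bins=n_bins, rate=rate)
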