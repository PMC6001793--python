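"""Univariate diffusion analysis (high-resolution DOSY).

Each picked peak's amplitude decay across the gradient array is fitted to
the Stejskal–Tanner law ``I(g) = I0 exp(-gamma^2 delta^2 g^2 D Delta')``
(optionally with a NUG power-series exponent, or with several exponential
components reduced to the statistically supported number), and the results
are laid out as a chemical-shift × D pseudo-2D map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .core import DiffusionEncoding, PeakFit, PseudoMap, SpectrumSet

__all__ = [
    "DecayModel",
    "st_attenuation",
    "pick_peaks",
    "peak_decays",
    "fit_monoexp",
    "fit_multiexp",
    "build_dosy_map",
    "dosy",
]


@dataclass
class DecayModel:
    """Multi-exponential decay description: per-component (I0, D)."""

    kind: str
    amplitudes: np.ndarray
    rates: np.ndarray  # D per component, m^2/s
    stderr_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    stderr_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    rss: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.rates)


def st_attenuation(encoding: DiffusionEncoding, D: float, increment=None) -> np.ndarray:
    """Attenuation factor exp(-sum_m c_m (X_i D)^m), X = gamma^2 delta^2 g^2 Delta'.

    Pure Stejskal–Tanner exponential when ``nug_coeffs == [1]``.
    """
    X = encoding.exponent_scale
    if increment is not None:
        X = X[np.asarray(increment)]
    xd = X * D
    c = np.asarray(encoding.nug_coeffs)
    powers = xd[..., None] ** np.arange(1, c.size + 1)
    return np.exp(-np.sum(c * powers, axis=-1))


def pick_peaks(
    spec: SpectrumSet,
    threshold: float,
    window_ppm: tuple[float, float] | None = None,
    row: int = 0,
) -> list[dict]:
    """Local maxima of the real part above ``threshold`` within the window.

    Positions are refined by 3-point parabolic interpolation; masked
    columns are ignored.  Returns dicts with index, ppm and amplitude.
    """
    r = spec.data[row].real.copy()
    allowed = spec.mask.copy()
    if window_ppm is not None:
        allowed &= spec.region_slice(*window_ppm)
    r = np.where(allowed, r, -np.inf)
    peaks = []
    for i in range(1, r.size - 1):
        if r[i] >= r[i - 1] and r[i] > r[i + 1] and r[i] > threshold:
            denom = r[i - 1] - 2 * r[i] + r[i + 1]
            if np.isfinite(denom) and denom != 0:
                shift = 0.5 * (r[i - 1] - r[i + 1]) / denom
            else:
                shift = 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            step_ppm = spec.axis_ppm[1] - spec.axis_ppm[0]
            ppm = spec.axis_ppm[i] + shift * step_ppm
            amp = r[i] - 0.25 * (r[i - 1] - r[i + 1]) * shift
            peaks.append({"index": i, "ppm": float(ppm), "amplitude": float(amp)})
    return peaks


def peak_decays(spec: SpectrumSet, peaks: list[dict]) -> np.ndarray:
    """Per-increment real-part height at each picked index
    ``[n_peaks, n_increments]`` (HR-DOSY practice: height, not integral)."""
    idx = [p["index"] for p in peaks]
    return spec.data[:, idx].real.T.copy()


def _st_model(X, i0, log_d, c):
    xd = X * np.exp(log_d)
    expo = np.sum(c * xd[:, None] ** np.arange(1, c.size + 1), axis=1)
    return i0 * np.exp(-np.clip(expo, -50.0, 700.0))


def fit_monoexp(
    decay: np.ndarray,
    encoding: DiffusionEncoding,
    position_ppm: float = 0.0,
) -> PeakFit:
    """Nonlinear least-squares monoexponential (or NUG) Stejskal–Tanner fit.

    D is initialised from a two-point log-linear estimate; standard errors
    come from the Jacobian at the solution.  Non-decaying data pin D at the
    lower bound and set a warning flag in ``extra``.
    """
    y = np.asarray(decay, dtype=float)
    X = encoding.exponent_scale
    if y.size != X.size:
        raise ValueError("decay length must match encoding increments")
    if y.size < 3:
        raise ValueError("at least 3 increments required")
    c = np.asarray(encoding.nug_coeffs)

    i0_init = y[np.argmin(X)]
    scale = abs(i0_init) or 1.0
    lo, hi = np.argmin(X), np.argmax(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = y[hi] / y[lo] if y[lo] != 0 else np.nan
    if np.isfinite(ratio) and 0 < ratio < 1:
        d_init = np.log(1.0 / ratio) / (X[hi] - X[lo])
    else:
        d_init = 1.0 / (X.max() or 1.0)

    d0 = max(d_init, 1e-3 / (X.max() or 1.0))
    res = least_squares(
        lambda p: _st_model(X, p[0], p[1], c) - y,
        x0=np.array([i0_init, np.log(d0)]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    i0_hat, d_hat = res.x[0], float(np.exp(res.x[1]))
    rss = float(2 * res.cost)
    dof = max(y.size - 2, 1)
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    se_d = float(se[1] * d_hat)  # delta method: fit runs in log D
    flat = d_hat * (X.max() or 1.0) < 1e-6  # attenuation indistinguishable from 1
    extra = {"I0": float(i0_hat), "I0_stderr": float(se[0]), "flat_decay": bool(flat)}
    if flat:
        warnings.warn("decay is flat; D estimate at lower bound")
    return PeakFit(
        position_ppm=position_ppm,
        amplitude=float(i0_hat) if abs(i0_hat) > 0 else float(scale),
        value=d_hat,
        stderr=se_d,
        rss=rss,
        n_points_used=int(y.size),
        extra=extra,
    )


def _multi_model(X, amps, rates, c):
    out = np.zeros_like(X)
    for a, d in zip(amps, rates):
        xd = X * d
        out = out + a * np.exp(
            -np.sum(c * xd[:, None] ** np.arange(1, c.size + 1), axis=1)
        )
    return out


def _fit_k_exponentials(X, y, k, c, n_starts=4):
    """Best least-squares fit with k exponential components (multi-start)."""
    span = X.max() - X.min() or 1.0
    best = None
    rng = np.random.default_rng(0)
    for s in range(n_starts):
        if s == 0:
            rates0 = np.geomspace(0.3 / span, 30.0 / span, k)
        else:
            rates0 = np.geomspace(0.3 / span, 30.0 / span, k) * rng.uniform(0.3, 3.0, k)
        amps0 = np.full(k, y[np.argmin(X)] / k)
        p0 = np.concatenate([amps0, np.log(rates0)])

        def resid(p):
            return _multi_model(X, p[:k], np.exp(p[k:]), c) - y

        res = least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    amps, rates = best.x[:k], np.exp(best.x[k:])
    rss = float(2 * best.cost)
    dof = max(y.size - 2 * k, 1)
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(2 * k, np.nan)
    se_amps, se_lograte = se[:k], se[k:]
    return amps, rates, se_amps, se_lograte * rates, rss


def fit_multiexp(
    decay: np.ndarray,
    encoding: DiffusionEncoding,
    max_components: int = 3,
    alpha: float = 0.05,
    amp_se_factor: float = 2.0,
) -> DecayModel:
    """Multi-exponential fit with statistical reduction.

    Fits ``max_components, max_components-1, ..., 1`` and keeps the largest
    k for which the F-test of k against k-1 components is significant at
    ``alpha`` *and* every amplitude exceeds ``amp_se_factor`` times its
    standard error; otherwise the component count is reduced.
    """
    y = np.asarray(decay, dtype=float)
    X = encoding.exponent_scale
    c = np.asarray(encoding.nug_coeffs)
    fits = {}
    for k in range(1, max_components + 1):
        fits[k] = _fit_k_exponentials(X, y, k, c)

    chosen = 1
    for k in range(max_components, 1, -1):
        amps, rates, se_a, se_r, rss_k = fits[k]
        rss_km1 = fits[k - 1][4]
        dof_k = y.size - 2 * k
        if dof_k <= 0:
            continue
        rss_floor = (1e-12 * np.abs(y).max()) ** 2 * y.size
        if rss_km1 <= max(rss_floor, 0.0):
            f_p = 1.0  # k-1 components already fit to machine precision
        elif rss_k <= 0 or not np.isfinite(rss_k):
            f_p = 1.0 if rss_km1 <= rss_k else 0.0
        elif rss_km1 <= rss_k:
            f_p = 1.0
        else:
            F = ((rss_km1 - rss_k) / 2.0) / (rss_k / dof_k)
            f_p = float(stats.f.sf(F, 2, dof_k))
        amps_ok = np.all(
            np.abs(amps) > amp_se_factor * np.where(np.isfinite(se_a), se_a, np.inf)
        ) or np.all(se_a == 0)
        if f_p < alpha and amps_ok:
            chosen = k
            break
    amps, rates, se_a, se_r, rss = fits[chosen]
    order = np.argsort(-np.abs(amps))
    return DecayModel(
        kind="nug" if c.size > 1 else "exponential",
        amplitudes=amps[order],
        rates=rates[order],
        stderr_amplitudes=se_a[order],
        stderr_rates=se_r[order],
        rss=rss,
        extra={"candidates": {k: fits[k][4] for k in fits}},
    )


def _ridge_matrix(
    peaks: list[PeakFit], shift_axis: np.ndarray, rate_axis: np.ndarray
) -> np.ndarray:
    """Shift × rate intensity matrix: one Gaussian ridge per peak along the
    rate axis (sigma = standard error, floored at one bin), normalised so
    the ridge integrates (trapezoid on the actual grid) to the peak
    amplitude."""
    m = np.zeros((shift_axis.size, rate_axis.size))
    for p in peaks:
        if not np.isfinite(p.value) or p.value <= 0:
            continue
        si = int(np.argmin(np.abs(shift_axis - p.position_ppm)))
        ri = int(np.argmin(np.abs(rate_axis - p.value)))
        bin_w = abs(
            rate_axis[min(ri + 1, rate_axis.size - 1)]
            - rate_axis[max(ri - 1, 0)]
        ) / 2.0
        sigma = max(p.stderr if np.isfinite(p.stderr) else 0.0, bin_w)
        ridge = np.exp(-0.5 * ((rate_axis - p.value) / sigma) ** 2)
        norm = np.trapezoid(ridge, rate_axis)
        if norm == 0:
            continue
        m[si] += abs(np.abs(ridge / abs(norm) * p.amplitude))
    return m


def build_dosy_map(
    peaks: list[PeakFit],
    n_bins: int = 64,
    d_range: tuple[float, float] | None = None,
    shift_axis_ppm: np.ndarray | None = None,
) -> PseudoMap:
    """Assemble the DOSY display: log-spaced D axis (default spanning
    [0.1x, 10x] the fitted range over ``n_bins`` bins), Gaussian ridge per
    peak with width = fit standard error (floor one bin)."""
    good = [p for p in peaks if np.isfinite(p.value) and p.value > 0]
    if not good:
        raise ValueError("no successful fits to map")
    if d_range is None:
        dmin = min(p.value for p in good)
        dmax = max(p.value for p in good)
        d_range = (0.1 * dmin, 10.0 * dmax)
    rate_axis = np.geomspace(d_range[0], d_range[1], n_bins)
    if shift_axis_ppm is None:
        ppms = [p.position_ppm for p in good]
        lo, hi = min(ppms), max(ppms)
        pad = 0.05 * (hi - lo + 1.0)
        shift_axis_ppm = np.linspace(hi + pad, lo - pad, max(len(good) * 8, 64))
    matrix = _ridge_matrix(good, shift_axis_ppm, rate_axis)
    return PseudoMap(
        matrix=matrix,
        shift_axis_ppm=shift_axis_ppm,
        rate_axis=rate_axis,
        peaks=good,
        rate_label="D / m^2 s^-1",
    )


def dosy(
    spec: SpectrumSet,
    encoding: DiffusionEncoding,
    threshold: float,
    window_ppm: tuple[float, float] | None = None,
    n_bins: int = 64,
) -> PseudoMap:
    """Peak-picked HR-DOSY pipeline: pick on the first increment, extract
    per-peak decays, monoexponential fit each, assemble the map."""
    picked = pick_peaks(spec, threshold, window_ppm)
    if not picked:
        raise ValueError("no peaks above threshold")
    decays = peak_decays(spec, picked)
    fits = [
        fit_monoexp(decays[k], encoding, position_ppm=picked[k]["ppm"])
        for k in range(len(picked))
    ]
    return build_dosy_map(fits, n_bins=n_bins)
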