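"""Synthetic NMR data generation.

Every downstream algorithm in this package is exercised against data built
here: multi-line complex FIDs with Lorentzian/Gaussian lineshapes, gradient
arrays with Stejskal–Tanner attenuation, relaxation recovery/decay series,
trilinear diffusion x time reaction cubes, lineshape distortions for
reference-deconvolution tests, interferogram-style pure shift raw data, and
on-disk Bruker/Varian fixture directories for the readers.

All generators are pure functions of their parameters and a seed; noise is
complex circular Gaussian with absolute standard deviation ``noise_sigma``
per quadrature component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import (
    DiffusionEncoding,
    FidSet,
    IncrementAxis,
    RelaxationEncoding,
    ppm_to_hz,
)

__all__ = [
    "LineSpec",
    "make_fid",
    "gradient_array",
    "lorentzian_spectrum",
    "decoupled_fid_samples",
    "make_diffusion_set",
    "make_relaxation_set",
    "make_reaction_cube",
    "distort_lineshape",
    "make_pureshift_raw",
    "write_bruker_fixture",
    "write_varian_fixture",
]

_GAUSS_NORM = 2.0 * np.sqrt(np.log(2.0))


@dataclass
class LineSpec:
    """One resonance: position, intensity, lineshape and per-component
    diffusion/relaxation parameters.

    ``lw_hz``/``gw_hz`` are Lorentzian/Gaussian FWHM contributions; ``D`` is
    the diffusion coefficient (m^2/s); ``component_id`` groups lines that
    belong to one chemical species (shared decays in mixture data).
    """

    shift_ppm: float
    amplitude: float = 1.0
    lw_hz: float = 1.0
    gw_hz: float = 0.0
    phase_deg: float = 0.0
    D: float = 5e-10
    t1: float = 1.0
    t2: float = 0.5
    component_id: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.lw_hz < 0 or self.gw_hz < 0:
            raise ValueError("amplitude, lw_hz and gw_hz must be >= 0")
        if self.D <= 0 or self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("D, t1 and t2 must be > 0")


def _line_signal(line: LineSpec, t: np.ndarray, sfrq: float, ref_offset_hz: float) -> np.ndarray:
    f = ppm_to_hz(line.shift_ppm, sfrq, ref_offset_hz)
    s = line.amplitude * np.exp(
        1j * (2.0 * np.pi * f * t + np.deg2rad(line.phase_deg))
    )
    if line.lw_hz:
        s = s * np.exp(-np.pi * line.lw_hz * t)
    if line.gw_hz:
        s = s * np.exp(-((np.pi * line.gw_hz * t / _GAUSS_NORM) ** 2))
    return s


def _check_in_sweep(lines: Sequence[LineSpec], dwell: float, sfrq: float, ref_offset_hz: float) -> None:
    sw = 1.0 / dwell
    for ln in lines:
        f = ppm_to_hz(ln.shift_ppm, sfrq, ref_offset_hz)
        if abs(f) >= sw / 2.0:
            raise ValueError(
                f"line at {ln.shift_ppm} ppm ({f:.1f} Hz) lies outside the "
                f"sweep width ±{sw / 2:.1f} Hz"
            )


def _noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(shape, dtype=complex)
    return sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def make_fid(
    lines: Sequence[LineSpec],
    n_points: int = 2048,
    dwell: float = 1e-3,
    sfrq: float = 500.0,
    ref_offset_hz: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> FidSet:
    """Single complex FID from a line list.

    ``s(t) = sum_k A_k exp(i(2 pi f_k t + phi_k)) exp(-pi lw_k t)
    exp(-(pi gw_k t / (2 sqrt(ln 2)))^2)`` plus complex Gaussian noise.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    _check_in_sweep(lines, dwell, sfrq, ref_offset_hz)
    t = np.arange(n_points) * dwell
    sig = np.zeros(n_points, dtype=complex)
    for ln in lines:
        sig += _line_signal(ln, t, sfrq, ref_offset_hz)
    rng = np.random.default_rng(seed)
    sig = sig + _noise(rng, n_points, noise_sigma)
    return FidSet(data=sig, dwell=dwell, sfrq=sfrq, ref_offset_hz=ref_offset_hz)


def gradient_array(
    n_increments: int, gmax: float, gmin: float = 0.0, spacing: str = "equal_g2"
) -> np.ndarray:
    """Gradient ramp, equally spaced in g (``equal_g``) or g^2 (``equal_g2``,
    the spacing DECRA and PowerSlicing require)."""
    if gmax <= 0:
        raise ValueError("gmax must be > 0")
    if spacing == "equal_g":
        return np.linspace(gmin, gmax, n_increments)
    if spacing == "equal_g2":
        return np.sqrt(np.linspace(gmin**2, gmax**2, n_increments))
    raise ValueError("spacing must be 'equal_g' or 'equal_g2'")


def make_diffusion_set(
    lines: Sequence[LineSpec],
    n_increments: int = 16,
    gmax: float = 0.5,
    gmin: float = 0.03,
    spacing: str = "equal_g2",
    encoding: DiffusionEncoding | None = None,
    n_points: int = 2048,
    dwell: float = 1e-3,
    sfrq: float = 500.0,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[FidSet, DiffusionEncoding]:
    """Gradient-arrayed FIDs with per-component Stejskal–Tanner attenuation.

    Increment *i* scales every line of component *k* by
    ``exp(-gamma^2 delta^2 g_i^2 D_k bigDelta')`` (or the NUG power-series
    exponent when the encoding carries extra coefficients).  A caller-built
    ``encoding`` overrides the (n_increments, gmax, gmin, spacing) ramp.
    """
    if encoding is None:
        g = gradient_array(n_increments, gmax, gmin, spacing)
        encoding = DiffusionEncoding(g=g)
    g = encoding.g
    n_inc = g.size
    _check_in_sweep(lines, dwell, sfrq, 0.0)
    t = np.arange(n_points) * dwell
    X = encoding.exponent_scale
    c = np.asarray(encoding.nug_coeffs)
    data = np.zeros((n_inc, n_points), dtype=complex)
    for ln in lines:
        base = _line_signal(ln, t, sfrq, 0.0)
        xd = X * ln.D
        atten = np.exp(-np.sum(c[None, :] * xd[:, None] ** np.arange(1, c.size + 1)[None, :], axis=1))
        data += atten[:, None] * base[None, :]
    rng = np.random.default_rng(seed)
    data += _noise(rng, data.shape, noise_sigma)
    fid = FidSet(
        data=data,
        dwell=dwell,
        sfrq=sfrq,
        arrays=[IncrementAxis("gradient", g, "g / T m^-1")],
    )
    return fid, encoding


def make_relaxation_set(
    lines: Sequence[LineSpec],
    encoding: RelaxationEncoding,
    n_points: int = 2048,
    dwell: float = 1e-3,
    sfrq: float = 500.0,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[FidSet, RelaxationEncoding]:
    """Relaxation series: per-component amplitude follows
    inversion recovery ``A (1 - 2 exp(-tau/T1))``, saturation recovery
    ``A (1 - exp(-tau/T1))`` or T2 decay ``A exp(-t/T2)``.
    """
    _check_in_sweep(lines, dwell, sfrq, 0.0)
    t = np.arange(n_points) * dwell
    tau = encoding.times
    data = np.zeros((tau.size, n_points), dtype=complex)
    for ln in lines:
        base = _line_signal(ln, t, sfrq, 0.0)
        if encoding.mode == "inversion_recovery":
            amp = 1.0 - 2.0 * np.exp(-tau / ln.t1)
        elif encoding.mode == "saturation_recovery":
            amp = 1.0 - np.exp(-tau / ln.t1)
        else:  # t2_decay
            amp = np.exp(-tau / ln.t2)
        data += amp[:, None] * base[None, :]
    rng = np.random.default_rng(seed)
    data += _noise(rng, data.shape, noise_sigma)
    fid = FidSet(
        data=data,
        dwell=dwell,
        sfrq=sfrq,
        arrays=[IncrementAxis("delay", tau, "tau / s")],
    )
    return fid, encoding


def lorentzian_spectrum(
    lines: Sequence[LineSpec], freq_hz: np.ndarray, sfrq: float = 500.0
) -> np.ndarray:
    """Absorption-mode spectrum on an explicit frequency grid (closed form),
    used where a frequency-domain component shape is needed directly."""
    s = np.zeros(freq_hz.size)
    for ln in lines:
        f0 = ppm_to_hz(ln.shift_ppm, sfrq, 0.0)
        hw = max(ln.lw_hz, 1e-6) / 2.0
        s += ln.amplitude * hw**2 / ((freq_hz - f0) ** 2 + hw**2)
    return s


def make_reaction_cube(
    lines: Sequence[LineSpec],
    encoding: DiffusionEncoding,
    concentrations: np.ndarray,
    n_freq: int = 256,
    freq_span_hz: float = 500.0,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear reaction cube ``X[time, gradient, frequency]``.

    ``X[j, i, f] = sum_k c_k(t_j) * exp(-X_i D_k) * spectrum_k(f)`` — exactly
    trilinear by construction.  ``concentrations`` is ``[n_times,
    n_components]``; component *k*'s spectrum collects the lines with
    ``component_id == k``.  Returns ``(cube, freq_axis_hz)`` with the
    frequency axis descending.
    """
    concentrations = np.atleast_2d(np.asarray(concentrations, dtype=float))
    comp_ids = sorted({ln.component_id for ln in lines})
    if concentrations.shape[1] != len(comp_ids):
        raise ValueError("concentration columns must match number of components")
    freq = np.linspace(freq_span_hz / 2.0, -freq_span_hz / 2.0, n_freq)
    X = encoding.exponent_scale
    cube = np.zeros((concentrations.shape[0], X.size, n_freq))
    for k, cid in enumerate(comp_ids):
        spec_k = lorentzian_spectrum([ln for ln in lines if ln.component_id == cid], freq)
        D_k = next(ln.D for ln in lines if ln.component_id == cid)
        decay = np.exp(-X * D_k)
        cube += (
            concentrations[:, k][:, None, None]
            * decay[None, :, None]
            * spec_k[None, None, :]
        )
    rng = np.random.default_rng(seed)
    if noise_sigma:
        cube = cube + noise_sigma * rng.standard_normal(cube.shape)
    return cube, freq


def distort_lineshape(
    fid: FidSet,
    envelope: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | None = 0,
    roughness: float = 0.5,
) -> FidSet:
    """Multiply every increment's FID by one common complex envelope.

    Models static-field inhomogeneity (bad shimming): every resonance in
    every increment is convolved with the same distortion — exactly the
    precondition reference deconvolution exploits.  Without an explicit
    envelope a random smooth complex one is drawn (low-order random Fourier
    series of the given roughness, unit value at t = 0).
    """
    t = fid.times
    if envelope is None:
        rng = np.random.default_rng(seed)
        T = t[-1] if t[-1] > 0 else 1.0
        env = np.ones_like(t, dtype=complex)
        for k in range(1, 4):
            a = roughness * (rng.standard_normal() + 1j * rng.standard_normal()) / k
            env = env * np.exp(a * (1.0 - np.cos(np.pi * k * t / (2.0 * T))))
        env = env / env[0]
    elif callable(envelope):
        env = np.asarray(envelope(t), dtype=complex)
    else:
        env = np.asarray(envelope, dtype=complex)
        if env.size != fid.n_points:
            raise ValueError("envelope length must equal n_points")
    out = fid.copy()
    out.data = out.data * env[None, :]
    return out


def decoupled_fid_samples(
    lines: Sequence[LineSpec],
    indices: np.ndarray,
    dwell: float,
    sfrq: float,
) -> np.ndarray:
    """The continuous homodecoupled FID evaluated at sample ``indices``
    (may be negative: the analytic signal extends through t = 0)."""
    t = np.asarray(indices, dtype=float) * dwell
    sig = np.zeros(t.size, dtype=complex)
    for ln in lines:
        sig += _line_signal(ln, t, sfrq, 0.0)
    return sig


def make_pureshift_raw(
    lines: Sequence[LineSpec],
    chunks: int = 16,
    chunk_points: int = 64,
    first_chunk: int | None = None,
    drop_points: int = 0,
    dwell: float = 1e-3,
    sfrq: float = 500.0,
) -> FidSet:
    """Interferogram-style pseudo-2D raw data for pure shift reconstruction.

    Increment *i* holds the decoupled FID evaluated over the time window its
    chunk occupies in the final 1D FID, preceded by ``drop_points`` lead-in
    samples, so reconstruction has an exact closed-form target.
    """
    if first_chunk is None:
        first_chunk = chunk_points
    if chunks < 1 or chunk_points < 1 or first_chunk < 1 or drop_points < 0:
        raise ValueError("invalid pure shift geometry")
    _check_in_sweep(lines, dwell, sfrq, 0.0)
    n_pts = drop_points + max(first_chunk, chunk_points)
    data = np.zeros((chunks, n_pts), dtype=complex)
    for r in range(chunks):
        start = 0 if r == 0 else first_chunk + (r - 1) * chunk_points
        length = first_chunk if r == 0 else chunk_points
        idx = np.arange(start - drop_points, start + length)
        data[r, : idx.size] = decoupled_fid_samples(lines, idx, dwell, sfrq)
    fid = FidSet(
        data=data,
        dwell=dwell,
        sfrq=sfrq,
        arrays=[IncrementAxis("counter", np.arange(1, chunks + 1), "chunk")],
        meta={
            "pureshift": {
                "chunks": chunks,
                "chunk_points": chunk_points,
                "first_chunk": first_chunk,
                "drop_points": drop_points,
            }
        },
    )
    return fid


# ---------------------------------------------------------------------------
# on-disk fixtures for the io module


def write_bruker_fixture(
    fid: FidSet,
    path: str | Path,
    byte_order: str = "little",
    dtype: str = "int32",
    group_delay: int = 0,
    encoding: DiffusionEncoding | None = None,
    relaxation: RelaxationEncoding | None = None,
    counters: Sequence[int] | None = None,
) -> Path:
    """Emit a Bruker-dialect directory (acqus + fid/ser [+ difflist/vdlist/
    vclist]) that :func:`nmrkit.io.read_bruker` parses back to ``fid``.

    int32 storage quantises with a power-of-two NC scaling exponent recorded
    in acqus; group-delay points are prepended as zeros and declared via
    GRPDLY.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = fid.data
    if group_delay:
        pad = np.zeros((fid.n_increments, group_delay), dtype=complex)
        data = np.hstack([pad, data])
    n_inc, n_pts = data.shape
    inter = np.empty((n_inc, 2 * n_pts))
    inter[:, 0::2] = data.real
    inter[:, 1::2] = data.imag

    nc = 0
    if dtype == "int32":
        maxabs = np.abs(inter).max() or 1.0
        nc = int(np.ceil(np.log2(maxabs / (2**29))))
        stored = np.round(inter / 2.0**nc).astype("<i4" if byte_order == "little" else ">i4")
    elif dtype == "float64":
        stored = inter.astype("<f8" if byte_order == "little" else ">f8")
    else:
        raise ValueError("dtype must be 'int32' or 'float64'")

    fname = "fid" if n_inc == 1 else "ser"
    stored.tofile(path / fname)

    keys = {
        "TD": 2 * n_pts,
        "SW_h": 1.0 / fid.dwell,
        "SFO1": fid.sfrq,
        "O1": fid.ref_offset_hz,
        "BYTORDA": 0 if byte_order == "little" else 1,
        "DTYPA": 0 if dtype == "int32" else 2,
        "GRPDLY": group_delay,
        "NC": nc,
    }
    with open(path / "acqus", "w") as fh:
        fh.write("##TITLE= synthetic fixture (nmrkit)\n##JCAMPDX= 5.0\n")
        for k, v in keys.items():
            fh.write(f"##${k}= {v}\n")
        fh.write("##END=\n")
    if n_inc > 1:
        with open(path / "acqu2s", "w") as fh:
            fh.write("##TITLE= synthetic fixture (nmrkit)\n")
            fh.write(f"##$TD= {n_inc}\n##END=\n")

    if encoding is not None:
        np.savetxt(path / "difflist", encoding.g, fmt="%.10g")
        with open(path / "diff_params.json", "w") as fh:
            import json

            json.dump(
                {
                    "gamma": encoding.gamma,
                    "delta": encoding.delta,
                    "big_delta_prime": encoding.big_delta_prime,
                    "nug_coeffs": list(encoding.nug_coeffs),
                    "sequence_type": encoding.sequence_type,
                },
                fh,
            )
    if relaxation is not None:
        np.savetxt(path / "vdlist", relaxation.times, fmt="%.10g")
    if counters is not None:
        np.savetxt(path / "vclist", np.asarray(counters, dtype=int), fmt="%d")
    return path


_VARIAN_BE_I32 = np.dtype(">i4")


def write_varian_fixture(
    fid: FidSet,
    path: str | Path,
    storage: str = "float32",
    arrayed_param: str | None = None,
    arrayed_values: Sequence[float] | None = None,
) -> Path:
    """Emit a Varian-dialect directory (procpar + big-endian binary fid with
    file/block headers) parsable by :func:`nmrkit.io.read_varian`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = fid.data
    n_inc, n_pts = data.shape
    np_total = 2 * n_pts

    if storage == "float32":
        ebytes, status = 4, 0x1 | 0x8  # S_DATA | S_FLOAT
        dt = np.dtype(">f4")
    elif storage == "int32":
        ebytes, status = 4, 0x1 | 0x4  # S_DATA | S_32
        dt = np.dtype(">i4")
    elif storage == "int16":
        ebytes, status = 2, 0x1
        dt = np.dtype(">i2")
    else:
        raise ValueError("storage must be float32, int32 or int16")

    tbytes = np_total * ebytes
    bbytes = tbytes + 28
    # one scale for the whole dataset so relative block amplitudes survive
    # integer quantisation
    global_scale = np.abs(data.view(float)).max() or 1.0
    with open(path / "fid", "wb") as fh:
        fh.write(
            np.array([n_inc, 1, np_total, ebytes, tbytes, bbytes], dtype=_VARIAN_BE_I32).tobytes()
        )
        fh.write(np.array([0, status], dtype=">i2").tobytes())
        fh.write(np.array([1], dtype=_VARIAN_BE_I32).tobytes())  # nbheaders
        for i in range(n_inc):
            # block header: scale, status, index, mode (i2 x4); ctcount (i4);
            # lpval, rpval, lvl, tlt (f4 x4)
            fh.write(np.array([0, status, i + 1, 0], dtype=">i2").tobytes())
            fh.write(np.array([1], dtype=_VARIAN_BE_I32).tobytes())
            fh.write(np.array([0.0, 0.0, 0.0, 0.0], dtype=">f4").tobytes())
            inter = np.empty(np_total)
            inter[0::2] = data[i].real
            inter[1::2] = data[i].imag
            if storage != "float32":
                limit = 2**30 if storage == "int32" else 2**14
                inter = np.round(inter / global_scale * limit)
            fh.write(inter.astype(dt).tobytes())

    def par(fh, name: str, values: Sequence[float]) -> None:
        fh.write(f"{name} 1 1 1e9 -1e9 0 1 0 1 64 1\n")
        fh.write(str(len(values)) + " " + " ".join(f"{v:.10g}" for v in values) + "\n")
        fh.write("0\n")

    with open(path / "procpar", "w") as fh:
        par(fh, "sw", [1.0 / fid.dwell])
        par(fh, "sfrq", [fid.sfrq])
        par(fh, "np", [np_total])
        if arrayed_param and arrayed_values is not None:
            par(fh, arrayed_param, list(arrayed_values))
            fh.write('array 2 1 0 0 0 1 0 1 64 1\n1 "' + arrayed_param + '"\n0\n')
    return path
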