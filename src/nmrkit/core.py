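"""Domain types and unit bookkeeping shared by every analysis module.

The universal raw object is a :class:`FidSet` — a complex matrix of one FID
per row (increments of a gradient, delay or time series) plus the acquisition
metadata needed to build a frequency axis.  Its processed counterpart is a
:class:`SpectrumSet`.  Encodings (:class:`DiffusionEncoding`,
:class:`RelaxationEncoding`) attach the physics of the increment dimension.

Conventions
-----------
* Frequency axes are stored **descending** (left = high ppm), the standard
  NMR display order; consumers read the axis rather than assume index order.
* ``ppm = (hz - ref_offset_hz) / sfrq`` with ``sfrq`` in MHz, so
  ``ppm_to_hz(p) = p * sfrq + ref_offset_hz``.
* Increments are rows; a two-axis array is flattened row-major with the
  first axis fastest (Bruker ``ser`` ordering).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "IncrementAxis",
    "FidSet",
    "SpectrumSet",
    "ApodisationParams",
    "DiffusionEncoding",
    "RelaxationEncoding",
    "PeakFit",
    "PseudoMap",
    "ComponentDecomposition",
    "ppm_to_hz",
    "hz_to_ppm",
    "prune",
]

AXIS_KINDS = ("gradient", "delay", "counter", "time", "generic")


@dataclass
class IncrementAxis:
    """One independent variable of an arrayed acquisition.

    ``values`` are T/m for gradients, seconds for delay/time axes and
    dimensionless for counters.
    """

    kind: str
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis kind {self.kind!r}; one of {AXIS_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("IncrementAxis.values must be non-empty")
        if self.kind == "gradient" and np.any(self.values < 0):
            raise ValueError("gradient amplitudes must be >= 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FidSet:
    """Complex time-domain data, one FID per row, plus acquisition metadata.

    Parameters
    ----------
    data:
        complex array ``[n_increments, n_points]`` (a 1D array is promoted).
    dwell:
        seconds per complex point.
    sfrq:
        spectrometer frequency in MHz.
    ref_offset_hz:
        frequency of the ppm-axis zero relative to the carrier, Hz.
    arrays:
        up to two :class:`IncrementAxis` records; for two axes the first is
        the fast one and ``n_increments == len(axis1) * len(axis2)``.
    """

    data: np.ndarray
    dwell: float
    sfrq: float
    ref_offset_hz: float = 0.0
    arrays: list[IncrementAxis] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=complex))
        if self.data.shape[1] < 2:
            raise ValueError("FidSet needs at least 2 complex points")
        if not (np.isfinite(self.dwell) and self.dwell > 0):
            raise ValueError("dwell must be positive and finite")
        if not (np.isfinite(self.sfrq) and self.sfrq > 0):
            raise ValueError("sfrq must be positive and finite")
        if len(self.arrays) > 2:
            raise ValueError("at most two increment axes are supported")
        if self.arrays:
            prod = 1
            for ax in self.arrays:
                prod *= len(ax)
            if prod != self.n_increments:
                raise ValueError(
                    f"increment axes ({prod} combinations) inconsistent with "
                    f"{self.n_increments} increments"
                )

    @property
    def n_increments(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    @property
    def sweep_width_hz(self) -> float:
        return 1.0 / self.dwell

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each complex point, s."""
        return np.arange(self.n_points) * self.dwell

    def copy(self) -> "FidSet":
        out = copy.copy(self)
        out.data = self.data.copy()
        out.arrays = [
            IncrementAxis(ax.kind, ax.values.copy(), ax.label) for ax in self.arrays
        ]
        out.meta = copy.deepcopy(self.meta)
        return out


@dataclass
class SpectrumSet:
    """Complex frequency-domain data with a calibrated, descending Hz axis.

    ``mask`` is a per-column keep flag consulted by the fitting modules so
    that pruned spectral regions are excluded without being deleted.
    """

    data: np.ndarray
    axis_hz: np.ndarray
    sfrq: float
    dwell: float
    ref_offset_hz: float = 0.0
    ph0: float = 0.0
    ph1: float = 0.0
    pivot_hz: float = 0.0
    arrays: list[IncrementAxis] = field(default_factory=list)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=complex))
        self.axis_hz = np.asarray(self.axis_hz, dtype=float)
        if self.axis_hz.size != self.data.shape[1]:
            raise ValueError("axis_hz length must match data columns")
        steps = np.diff(self.axis_hz)
        if self.axis_hz.size > 1:
            if not np.all(steps < 0):
                raise ValueError("frequency axis must be strictly descending")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
                raise ValueError("frequency axis must be uniformly spaced")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.data.shape[1]:
                raise ValueError("mask length must match data columns")

    @property
    def n_increments(self) -> int:
        return self.data.shape[0]

    @property
    def fn(self) -> int:
        """Fourier number: complex points in the spectrum."""
        return self.data.shape[1]

    @property
    def sweep_width_hz(self) -> float:
        return 1.0 / self.dwell

    @property
    def axis_ppm(self) -> np.ndarray:
        return hz_to_ppm(self.axis_hz, self.sfrq, self.ref_offset_hz)

    def index_of_hz(self, hz: float) -> int:
        return int(np.argmin(np.abs(self.axis_hz - hz)))

    def index_of_ppm(self, ppm: float) -> int:
        return self.index_of_hz(ppm_to_hz(ppm, self.sfrq, self.ref_offset_hz))

    def region_slice(self, ppm_lo: float, ppm_hi: float) -> np.ndarray:
        """Boolean column selector for a ppm interval (order-insensitive)."""
        lo, hi = sorted((ppm_lo, ppm_hi))
        p = self.axis_ppm
        sel = (p >= lo) & (p <= hi)
        if not sel.any():
            raise ValueError(f"ppm interval [{lo}, {hi}] is outside the axis")
        return sel

    def copy(self) -> "SpectrumSet":
        out = copy.copy(self)
        out.data = self.data.copy()
        out.axis_hz = self.axis_hz.copy()
        out.mask = None if self.mask is None else self.mask.copy()
        out.arrays = [
            IncrementAxis(ax.kind, ax.values.copy(), ax.label) for ax in self.arrays
        ]
        out.meta = copy.deepcopy(self.meta)
        return out


@dataclass
class ApodisationParams:
    """Line-broadening parameters: the *additional* Lorentzian (``lw``, Hz,
    may be negative for resolution enhancement) and Gaussian (``gw``, Hz,
    non-negative) full widths at half height convolved into the spectrum."""

    lw: float = 0.0
    gw: float = 0.0

    def __post_init__(self) -> None:
        if self.gw < 0:
            raise ValueError("gw must be >= 0")


@dataclass
class DiffusionEncoding:
    """Stejskal–Tanner constants for a pulsed-field-gradient experiment.

    The attenuation of component *k* at increment *i* is
    ``exp(-sum_m c_m * (X_i * D_k)**m)`` with
    ``X_i = gamma**2 * delta**2 * g_i**2 * big_delta_prime``;
    ``nug_coeffs == [1]`` gives the pure Stejskal–Tanner exponential.
    """

    g: np.ndarray
    gamma: float = 2.6752218744e8  # 1H, rad s^-1 T^-1
    delta: float = 2e-3
    big_delta_prime: float = 0.1
    nug_coeffs: Sequence[float] = (1.0,)
    sequence_type: str = "bipolar"

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("gradient amplitudes must be >= 0")
        if self.delta <= 0 or self.big_delta_prime <= 0:
            raise ValueError("delta and big_delta_prime must be positive")
        self.nug_coeffs = tuple(float(c) for c in self.nug_coeffs)
        if not self.nug_coeffs or self.nug_coeffs[0] != 1.0:
            raise ValueError("nug_coeffs must start with c1 = 1")

    @property
    def n_increments(self) -> int:
        return self.g.size

    @property
    def exponent_scale(self) -> np.ndarray:
        """``X_i = gamma^2 delta^2 g_i^2 bigDelta'`` per increment, s/m^2."""
        return (self.gamma * self.delta * self.g) ** 2 * self.big_delta_prime

    def subset(self, keep: np.ndarray) -> "DiffusionEncoding":
        return DiffusionEncoding(
            self.g[keep], self.gamma, self.delta, self.big_delta_prime,
            self.nug_coeffs, self.sequence_type,
        )


RELAXATION_MODES = ("inversion_recovery", "saturation_recovery", "t2_decay")


@dataclass
class RelaxationEncoding:
    """Evolution times of a relaxation series.

    For CPMG/PROJECT-style T2 data acquired with a counter list, the
    effective time is ``counter * loop_duration``; build with
    :meth:`from_counters`.
    """

    times: np.ndarray
    mode: str = "inversion_recovery"
    loop_duration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.mode not in RELAXATION_MODES:
            raise ValueError(f"mode must be one of {RELAXATION_MODES}")
        if np.any(self.times <= 0):
            raise ValueError("evolution times must be strictly positive")
        if np.any(np.diff(np.sort(self.times)) <= 0):
            raise ValueError("evolution times must be distinct")
        if self.loop_duration is not None and self.loop_duration <= 0:
            raise ValueError("loop_duration must be positive")

    @classmethod
    def from_counters(
        cls, counters: Sequence[float], loop_duration: float, mode: str = "t2_decay"
    ) -> "RelaxationEncoding":
        if loop_duration <= 0:
            raise ValueError("loop_duration must be positive when counters are used")
        t = np.asarray(counters, dtype=float) * loop_duration
        return cls(t, mode=mode, loop_duration=loop_duration)

    @property
    def n_increments(self) -> int:
        return self.times.size

    def subset(self, keep: np.ndarray) -> "RelaxationEncoding":
        out = copy.copy(self)
        out.times = self.times[keep]
        return out


@dataclass
class PeakFit:
    """Result of a per-peak exponential fit (D in m^2/s or T in s)."""

    position_ppm: float
    amplitude: float
    value: float
    stderr: float
    rss: float
    n_points_used: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error must be >= 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


@dataclass
class PseudoMap:
    """DOSY/ROSY display matrix: chemical shift x (D or T) intensity map."""

    matrix: np.ndarray
    shift_axis_ppm: np.ndarray
    rate_axis: np.ndarray
    peaks: list[PeakFit] = field(default_factory=list)
    rate_label: str = "D / m^2 s^-1"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("pseudo-map intensities must be >= 0")


@dataclass
class ComponentDecomposition:
    """Output of SCORE/OUTSCORE/DECRA/RSCORE: component spectra, decays,
    per-component parameters and integral fractions (percent of total)."""

    spectra: np.ndarray            # [n_components, n_points]
    decays: np.ndarray             # [n_increments, n_components]
    parameters: np.ndarray         # D (m^2/s) or T (s) per component
    fractions: np.ndarray          # percent, sums to 100
    residual_norm: float
    method: str = ""
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.decays = np.atleast_2d(np.asarray(self.decays, dtype=float))
        self.parameters = np.asarray(self.parameters, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)

    @property
    def n_components(self) -> int:
        return self.spectra.shape[0]


def ppm_to_hz(ppm, sfrq: float, ref_offset_hz: float = 0.0):
    """Chemical shift (ppm) to Hz relative to the carrier.

    ``hz = ppm * sfrq + ref_offset_hz`` with ``sfrq`` in MHz.
    """
    ppm = np.asarray(ppm, dtype=float)
    if not np.all(np.isfinite(ppm)) or not np.isfinite(sfrq) or not np.isfinite(
        ref_offset_hz
    ):
        raise ValueError("non-finite input to ppm_to_hz")
    if sfrq <= 0:
        raise ValueError("sfrq must be positive")
    out = ppm * sfrq + ref_offset_hz
    return float(out) if out.ndim == 0 else out


def hz_to_ppm(hz, sfrq: float, ref_offset_hz: float = 0.0):
    """Inverse of :func:`ppm_to_hz`."""
    hz = np.asarray(hz, dtype=float)
    if not np.all(np.isfinite(hz)) or not np.isfinite(sfrq) or not np.isfinite(
        ref_offset_hz
    ):
        raise ValueError("non-finite input to hz_to_ppm")
    if sfrq <= 0:
        raise ValueError("sfrq must be positive")
    out = (hz - ref_offset_hz) / sfrq
    return float(out) if out.ndim == 0 else out


def prune(
    obj: FidSet | SpectrumSet,
    drop_increments: Sequence[int] = (),
    drop_regions: Sequence[tuple[float, float]] = (),
    encoding: DiffusionEncoding | RelaxationEncoding | None = None,
):
    """Remove increments and mask spectral regions before analysis.

    Increments are deleted from the data and from every attached axis (and
    from ``encoding`` when given) in lockstep.  Regions (ppm intervals, only
    meaningful for a :class:`SpectrumSet`) are *masked*, not deleted: fits
    consult ``SpectrumSet.mask``.

    Returns the pruned object, or ``(pruned, pruned_encoding)`` when an
    encoding is supplied.
    """
    drop_increments = sorted(set(int(i) for i in drop_increments))
    n_inc = obj.n_increments
    for i in drop_increments:
        if not (0 <= i < n_inc):
            raise IndexError(f"increment index {i} out of range 0..{n_inc - 1}")
    if len(drop_increments) >= n_inc:
        raise ValueError("cannot prune away every increment")
    keep = np.ones(n_inc, dtype=bool)
    keep[drop_increments] = False

    out = obj.copy()
    out.data = out.data[keep]
    new_axes = []
    for ax in out.arrays:
        if len(ax) == n_inc:
            new_axes.append(IncrementAxis(ax.kind, ax.values[keep], ax.label))
        else:  # one factor of a two-axis array; cannot drop single rows from it
            new_axes.append(ax)
    out.arrays = new_axes

    if drop_regions:
        if not isinstance(obj, SpectrumSet):
            raise TypeError("region pruning applies to frequency-domain data")
        mask = out.mask.copy()
        for lo, hi in drop_regions:
            mask &= ~out.region_slice(lo, hi)
        if not mask.any():
            raise ValueError("cannot mask away every spectral point")
        out.mask = mask

    if encoding is not None:
        return out, encoding.subset(keep)
    return out
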