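"""Readers and writers: Bruker and Varian raw data, the package's own
internal format, and result exporters.

Bruker directories carry JCAMP-style ``acqus`` metadata plus an interleaved
real/imag ``fid``/``ser`` binary; byte order follows BYTORDA, the element
type follows DTYPA (int32 assumed when absent — the legacy default), int
data are scaled by ``2**NC``, and ``round(GRPDLY)`` leading complex points
(the digital-filter group delay) are discarded on read.  Gradient lists come
from ``difflist``, delay lists from ``vdlist``, counter lists from
``vclist``.

Varian directories carry a ``procpar`` parameter file and a big-endian
``fid`` binary with a file header and per-block headers; 16-bit int, 32-bit
int and float storage are supported, selected by the header status flags.

The internal format is a directory of ``meta.json`` plus ``data.bin``
(IEEE-754 double, little-endian, interleaved real/imag) or ``data.txt``
(one "real imag" pair per line); write followed by read is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ComponentDecomposition,
    DiffusionEncoding,
    FidSet,
    IncrementAxis,
    PeakFit,
    PseudoMap,
    RelaxationEncoding,
    SpectrumSet,
)
from .processing import spectrum_to_fid

__all__ = [
    "FormatError",
    "CorruptFileError",
    "UnsupportedVersionError",
    "read_bruker",
    "read_varian",
    "read_numbered",
    "write_internal",
    "read_internal",
    "save_as_fid",
    "export_results",
]

INTERNAL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """File does not look like the expected vendor format."""


class CorruptFileError(ValueError):
    """File sizes/contents inconsistent with the declared metadata."""


class UnsupportedVersionError(ValueError):
    """Internal-format version not understood by this reader."""


# ---------------------------------------------------------------------------
# Bruker


def _parse_jcamp(path: Path) -> dict:
    params: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##$") and "=" in line:
                key, _, val = line[3:].partition("=")
                params[key.strip()] = val.strip()
    return params


def _jcamp_float(params: dict, key: str, default: float | None = None) -> float:
    if key not in params:
        if default is None:
            raise FormatError(f"acqus is missing required key {key}")
        return default
    return float(params[key])


def read_bruker(directory: str | Path):
    """Read a Bruker dataset directory.

    Returns ``(fid_set, encoding)`` where ``encoding`` is a
    :class:`DiffusionEncoding` (``difflist`` present), a
    :class:`RelaxationEncoding` (``vdlist``/``vclist`` present) or ``None``.
    """
    directory = Path(directory)
    acqus = directory / "acqus"
    if not acqus.exists():
        raise FormatError(f"no acqus file in {directory}")
    params = _parse_jcamp(acqus)

    datafile = None
    for name in ("ser", "fid"):
        if (directory / name).exists():
            datafile = directory / name
            break
    if datafile is None:
        raise FormatError(f"no fid or ser file in {directory}")

    td = int(_jcamp_float(params, "TD"))
    if td % 2:
        raise FormatError(f"TD={td} is odd; complex pairs expected")
    sw_h = _jcamp_float(params, "SW_h")
    sfrq = _jcamp_float(params, "SFO1")
    ref_offset = _jcamp_float(params, "O1", 0.0)
    byteorder = "<" if int(_jcamp_float(params, "BYTORDA", 0)) == 0 else ">"
    dtypa = int(_jcamp_float(params, "DTYPA", 0))  # absent -> int32 legacy default
    dt = np.dtype(byteorder + ("i4" if dtypa == 0 else "f8"))
    grpdly = int(round(_jcamp_float(params, "GRPDLY", 0.0)))
    nc = int(_jcamp_float(params, "NC", 0))

    raw = np.fromfile(datafile, dtype=dt)
    if raw.size == 0 or raw.size % td:
        raise CorruptFileError(
            f"{datafile.name} holds {raw.size} values, not a multiple of TD={td}"
        )
    n_inc = raw.size // td
    raw = raw.reshape(n_inc, td).astype(float)
    if dtypa == 0 and nc:
        raw = raw * 2.0**nc
    data = raw[:, 0::2] + 1j * raw[:, 1::2]
    if grpdly:
        data = data[:, grpdly:]

    arrays: list[IncrementAxis] = []
    encoding = None
    difflist = directory / "difflist"
    vdlist = directory / "vdlist"
    vclist = directory / "vclist"
    if difflist.exists():
        g = np.loadtxt(difflist, ndmin=1)
        arrays.append(IncrementAxis("gradient", g, "g / T m^-1"))
        kwargs = {}
        pj = directory / "diff_params.json"
        if pj.exists():
            kwargs = json.loads(pj.read_text())
        encoding = DiffusionEncoding(g=g, **kwargs)
    elif vdlist.exists():
        times = np.loadtxt(vdlist, ndmin=1)
        arrays.append(IncrementAxis("delay", times, "tau / s"))
        encoding = RelaxationEncoding(times)
    elif vclist.exists():
        counters = np.loadtxt(vclist, ndmin=1)
        arrays.append(IncrementAxis("counter", counters, "loop count"))

    fid = FidSet(
        data=data,
        dwell=1.0 / sw_h,
        sfrq=sfrq,
        ref_offset_hz=ref_offset,
        arrays=[a for a in arrays if len(a) == n_inc],
        meta={"source": str(directory), "vendor": "bruker"},
    )
    return fid, encoding


# ---------------------------------------------------------------------------
# Varian

_S_DATA, _S_32, _S_FLOAT = 0x1, 0x4, 0x8
_KNOWN_STATUS = 0x1 | 0x2 | 0x4 | 0x8 | 0x10  # data/spec/32/float/complex


def _read_procpar(path: Path) -> dict:
    params: dict[str, list] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        tokens = lines[i].split()
        if tokens and tokens[0][0].isalpha():
            name = tokens[0]
            i += 1
            vtokens = lines[i].split()
            count = int(vtokens[0])
            values = vtokens[1:]
            while len(values) < count:
                i += 1
                values.extend(lines[i].split())
            parsed = []
            for v in values[:count]:
                if v.startswith('"'):
                    parsed.append(v.strip('"'))
                else:
                    try:
                        parsed.append(float(v))
                    except ValueError:
                        parsed.append(v)
            params[name] = parsed
            i += 1  # the trailing enumeration line ("0 ...")
        i += 1
    return params


def read_varian(directory: str | Path):
    """Read a Varian/Agilent dataset directory (procpar + fid).

    Returns ``(fid_set, encoding_or_None)``; an arrayed ``gzlvl*`` parameter
    becomes a gradient axis, arrayed delays a delay axis.
    """
    directory = Path(directory)
    procpar = directory / "procpar"
    fidfile = directory / "fid"
    if not procpar.exists() or not fidfile.exists():
        raise FormatError(f"procpar and fid required in {directory}")
    params = _read_procpar(procpar)

    with open(fidfile, "rb") as fh:
        head = np.frombuffer(fh.read(24), dtype=">i4")
        nblocks, ntraces, np_total, ebytes, tbytes, bbytes = (int(v) for v in head)
        vers_status = np.frombuffer(fh.read(4), dtype=">i2")
        status = int(vers_status[1])
        nbheaders = int(np.frombuffer(fh.read(4), dtype=">i4")[0])
        if status & ~_KNOWN_STATUS:
            raise FormatError(
                f"unknown Varian status flags 0x{status:04x} "
                f"(known mask 0x{_KNOWN_STATUS:04x})"
            )
        if np_total % 2 or nblocks < 1:
            raise CorruptFileError(
                f"bad Varian header: np={np_total}, nblocks={nblocks}"
            )
        if status & _S_FLOAT:
            dt = np.dtype(">f4")
        elif status & _S_32:
            dt = np.dtype(">i4")
        else:
            dt = np.dtype(">i2")
        if dt.itemsize != ebytes:
            raise CorruptFileError(
                f"ebytes={ebytes} inconsistent with status flags 0x{status:04x}"
            )
        data = np.empty((nblocks, np_total // 2), dtype=complex)
        for b in range(nblocks):
            fh.seek(28 * nbheaders, 1)
            block = np.frombuffer(fh.read(np_total * ebytes), dtype=dt).astype(float)
            if block.size != np_total:
                raise CorruptFileError(f"block {b} truncated")
            data[b] = block[0::2] + 1j * block[1::2]

    sw = float(params["sw"][0])
    sfrq = float(params["sfrq"][0])

    arrays: list[IncrementAxis] = []
    encoding = None
    arrayed_names: list[str] = []
    if "array" in params and params["array"] and params["array"][0]:
        arrayed_names = [n for n in str(params["array"][0]).split(",") if n]
    for name in arrayed_names:
        if name in params and len(params[name]) == nblocks:
            values = np.asarray(params[name], dtype=float)
            if name.startswith("gzlvl"):
                arrays.append(IncrementAxis("gradient", values, name))
                encoding = DiffusionEncoding(g=values)
            elif name.startswith(("d", "vd", "tau")):
                arrays.append(IncrementAxis("delay", values, name))
            else:
                arrays.append(IncrementAxis("generic", values, name))

    fid = FidSet(
        data=data,
        dwell=1.0 / sw,
        sfrq=sfrq,
        arrays=arrays,
        meta={"source": str(directory), "vendor": "varian"},
    )
    return fid, encoding


def read_numbered(parent: str | Path, vendor: str = "bruker"):
    """Read consecutively numbered 1D datasets (directories ``1..N``) and
    stack them as increments.  All members must share dwell and sfrq."""
    parent = Path(parent)
    dirs = sorted(
        (d for d in parent.iterdir() if d.is_dir() and d.name.isdigit()),
        key=lambda d: int(d.name),
    )
    if not dirs:
        raise FormatError(f"no numbered dataset directories in {parent}")
    reader = read_bruker if vendor == "bruker" else read_varian
    fids = [reader(d)[0] for d in dirs]
    first = fids[0]
    for f in fids[1:]:
        if not (
            np.isclose(f.dwell, first.dwell, rtol=1e-12)
            and np.isclose(f.sfrq, first.sfrq, rtol=1e-12)
        ):
            raise FormatError("numbered datasets disagree in dwell or sfrq")
    data = np.vstack([f.data for f in fids])
    return FidSet(
        data=data,
        dwell=first.dwell,
        sfrq=first.sfrq,
        ref_offset_hz=first.ref_offset_hz,
        arrays=[IncrementAxis("counter", np.arange(1, len(fids) + 1), "dataset")],
        meta={"source": str(parent), "vendor": vendor, "numbered": len(fids)},
    )


# ---------------------------------------------------------------------------
# internal format


def _axes_payload(arrays: list[IncrementAxis]) -> list[dict]:
    return [
        {"kind": a.kind, "values": a.values.tolist(), "label": a.label}
        for a in arrays
    ]


def _axes_from_payload(payload: list[dict]) -> list[IncrementAxis]:
    return [IncrementAxis(p["kind"], np.asarray(p["values"]), p.get("label", "")) for p in payload]


def write_internal(
    obj: FidSet | SpectrumSet, path: str | Path, mode: str = "binary"
) -> Path:
    """Write a FidSet or SpectrumSet as ``meta.json`` + ``data.bin``/``data.txt``."""
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    if not np.all(np.isfinite(obj.data)):
        raise ValueError("refusing to write non-finite data")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "format": "nmrkit-internal",
        "version": INTERNAL_FORMAT_VERSION,
        "mode": mode,
        "shape": list(obj.data.shape),
        "dwell": obj.dwell,
        "sfrq": obj.sfrq,
        "ref_offset_hz": obj.ref_offset_hz,
        "arrays": _axes_payload(obj.arrays),
        "meta": obj.meta,
    }
    if isinstance(obj, SpectrumSet):
        meta["type"] = "spectrum"
        meta["axis_hz_first"] = float(obj.axis_hz[0])
        meta["axis_hz_step"] = float(obj.axis_hz[1] - obj.axis_hz[0]) if obj.fn > 1 else 0.0
        meta["ph0"] = obj.ph0
        meta["ph1"] = obj.ph1
        meta["pivot_hz"] = obj.pivot_hz
        meta["mask"] = obj.mask.astype(int).tolist()
    else:
        meta["type"] = "fid"
    (path / "meta.json").write_text(json.dumps(meta, indent=1))

    inter = np.empty((obj.data.shape[0], 2 * obj.data.shape[1]))
    inter[:, 0::2] = obj.data.real
    inter[:, 1::2] = obj.data.imag
    if mode == "binary":
        inter.astype("<f8").tofile(path / "data.bin")
    else:
        np.savetxt(
            path / "data.txt",
            inter.reshape(-1, 2),
            fmt="%.17g",
            header=f"real imag ({obj.data.shape[0]} rows x {obj.data.shape[1]} complex points)",
        )
    return path


def read_internal(path: str | Path) -> FidSet | SpectrumSet:
    """Inverse of :func:`write_internal`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format") != "nmrkit-internal":
        raise FormatError(f"{path} is not an internal-format directory")
    if meta.get("version") != INTERNAL_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"internal format version {meta.get('version')} not supported "
            f"(this reader understands {INTERNAL_FORMAT_VERSION})"
        )
    shape = tuple(meta["shape"])
    if meta["mode"] == "binary":
        inter = np.fromfile(path / "data.bin", dtype="<f8").reshape(shape[0], 2 * shape[1])
    else:
        inter = np.loadtxt(path / "data.txt").reshape(shape[0], 2 * shape[1])
    data = inter[:, 0::2] + 1j * inter[:, 1::2]
    arrays = _axes_from_payload(meta["arrays"])
    if meta["type"] == "spectrum":
        axis = meta["axis_hz_first"] + meta["axis_hz_step"] * np.arange(shape[1])
        return SpectrumSet(
            data=data,
            axis_hz=axis,
            sfrq=meta["sfrq"],
            dwell=meta["dwell"],
            ref_offset_hz=meta["ref_offset_hz"],
            ph0=meta["ph0"],
            ph1=meta["ph1"],
            pivot_hz=meta["pivot_hz"],
            arrays=arrays,
            mask=np.asarray(meta["mask"], dtype=bool),
            meta=meta["meta"],
        )
    return FidSet(
        data=data,
        dwell=meta["dwell"],
        sfrq=meta["sfrq"],
        ref_offset_hz=meta["ref_offset_hz"],
        arrays=arrays,
        meta=meta["meta"],
    )


# ---------------------------------------------------------------------------
# processed spectra back to time domain


def save_as_fid(spec: SpectrumSet, real_only: bool = False) -> FidSet:
    """Inverse Fourier transform of processed spectra, freezing any
    processing (baseline correction, deconvolution, ...) into a new FID.

    With ``real_only`` the imaginary part is first rebuilt from the real
    part by causal (conjugate-symmetric) reconstruction: the inverse
    transform of the real spectrum is doubled over the first half of the
    time domain and zeroed over the second.  This assumes the underlying
    FID has decayed by the half-way point.
    """
    if not np.all(np.isfinite(spec.data)):
        raise ValueError("non-finite spectrum")
    if not real_only:
        return spectrum_to_fid(spec)
    work = spec.copy()
    work.data = work.data.real.astype(complex)
    fid = spectrum_to_fid(work)
    n = fid.n_points
    half = n // 2
    data = 2.0 * fid.data
    data[:, 0] = fid.data[:, 0]  # t = 0 already restored by the inverse FT
    data[:, half:] = 0.0
    fid.data = data
    return fid


# ---------------------------------------------------------------------------
# result export


def _to_payload(obj) -> dict:
    if isinstance(obj, PeakFit):
        obj = [obj]
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], PeakFit):
        return {
            "kind": "peak_fits",
            "columns": ["position_ppm", "amplitude", "value", "stderr", "rss", "n_points_used"],
            "rows": [
                [p.position_ppm, p.amplitude, p.value, p.stderr, p.rss, p.n_points_used]
                for p in obj
            ],
        }
    if isinstance(obj, ComponentDecomposition):
        return {
            "kind": "decomposition",
            "method": obj.method,
            "parameters": obj.parameters.tolist(),
            "fractions": obj.fractions.tolist(),
            "residual_norm": obj.residual_norm,
            "spectra": obj.spectra.tolist(),
            "decays": obj.decays.tolist(),
        }
    if isinstance(obj, PseudoMap):
        return {
            "kind": "pseudo_map",
            "shift_axis_ppm": obj.shift_axis_ppm.tolist(),
            "rate_axis": obj.rate_axis.tolist(),
            "matrix": obj.matrix.tolist(),
        }
    if isinstance(obj, pd.DataFrame):
        return {
            "kind": "table",
            "columns": list(obj.columns),
            "rows": obj.values.tolist(),
        }
    raise TypeError(f"cannot export object of type {type(obj).__name__}")


def export_results(obj, path: str | Path, format: str = "csv") -> Path:
    """Export a result object as CSV (deterministic column order, 17
    significant digits) or JSON.  JSON payloads round-trip through
    :func:`json.load` to an equal dictionary."""
    path = Path(path)
    payload = _to_payload(obj)
    if format == "json":
        path.write_text(json.dumps(payload, indent=1))
        return path
    if format != "csv":
        raise ValueError("format must be 'csv' or 'json'")
    if payload["kind"] == "peak_fits" or payload["kind"] == "table":
        df = pd.DataFrame(payload["rows"], columns=payload["columns"])
    elif payload["kind"] == "decomposition":
        df = pd.DataFrame(
            {
                "component": np.arange(1, len(payload["parameters"]) + 1),
                "parameter": payload["parameters"],
                "fraction_pct": payload["fractions"],
            }
        )
    else:  # pseudo_map
        df = pd.DataFrame(
            payload["matrix"],
            index=payload["shift_axis_ppm"],
            columns=payload["rate_axis"],
        )
        df.to_csv(path, float_format="%.17g")
        return path
    df.to_csv(path, index=False, float_format="%.17g")
    return path
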