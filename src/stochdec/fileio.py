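"""Plain-text serialization: JCAMP-DX-style shape/FID files and delimited text.

The shape format follows the labelled-data-record convention of JCAMP-DX
pulse-shape files (``##LABEL= value`` header records followed by
amplitude-percent / phase-degree rows).  Delimited files are two-column
(or paired real/imaginary) text with ``# key: value`` header lines.
Parsers report the offending line number on malformed input.
"""

from __future__ import annotations

from typing import TextIO

import numpy as np

from .containers import AcquisitionParams, FIDData, SpectrumData
from .waveforms import RFWaveform

__all__ = [
    "ParseError",
    "write_shape",
    "read_shape",
    "write_delimited_waveform",
    "read_delimited_waveform",
    "sniff_waveform_format",
    "write_delimited_fid",
    "read_delimited_fid",
    "write_jcamp_fid",
    "read_jcamp_fid",
    "write_delimited_spectrum",
]


class ParseError(ValueError):
    """Malformed serialized file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------- shape files


def write_shape(wf: RFWaveform, path) -> None:
    peak = wf.peak
    with open(path, "w") as fh:
        fh.write(f"##TITLE= {wf.label or 'rf shape'}\n")
        fh.write("##JCAMPDX= 5.00\n")
        fh.write("##DATA TYPE= RF SHAPE\n")
        fh.write(f"##NPOINTS= {wf.n_samples}\n")
        fh.write(f"##DWELL SEC= {wf.dwell!r}\n")
        fh.write(f"##CARRIER PPM= {wf.carrier_ppm!r}\n")
        fh.write(f"##MAXAMP HZ= {peak!r}\n")
        fh.write("##XYPOINTS= (AMPLITUDE PERCENT, PHASE DEGREE)\n")
        pct = np.zeros(wf.n_samples) if peak == 0 else 100.0 * wf.amplitude / peak
        for p, ph in zip(pct, wf.phase_deg):
            fh.write(f"{p:.6f}, {ph:.6f}\n")
        fh.write("##END=\n")


def read_shape(path) -> RFWaveform:
    headers: dict[str, str] = {}
    pct: list[float] = []
    phase: list[float] = []
    in_data = False
    saw_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            saw_any = True
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##END"):
                    break
                if "=" not in line:
                    raise ParseError(path, lineno, "header record missing '='")
                key, _, value = line[2:].partition("=")
                headers[key.strip().upper()] = value.strip()
                if key.strip().upper() == "XYPOINTS":
                    in_data = True
                continue
            if not in_data:
                raise ParseError(path, lineno, "data row before ##XYPOINTS record")
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
            try:
                pct.append(float(parts[0]))
                phase.append(float(parts[1]))
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric data row {line!r}") from None
    if not saw_any:
        raise ParseError(path, 1, "empty file")
    for key in ("NPOINTS", "DWELL SEC", "MAXAMP HZ"):
        if key not in headers:
            raise ParseError(path, 1, f"missing required header ##{key}=")
    n = int(headers["NPOINTS"])
    if n != len(pct):
        raise ParseError(path, 1, f"##NPOINTS= {n} but {len(pct)} data rows found")
    peak = float(headers["MAXAMP HZ"])
    amp = np.asarray(pct) * peak / 100.0
    return RFWaveform(
        amp,
        np.asarray(phase),
        float(headers["DWELL SEC"]),
        float(headers.get("CARRIER PPM", 4.755)),
        label=headers.get("TITLE", ""),
    )


# ----------------------------------------------------------- delimited files


def _write_header(fh: TextIO, pairs: dict[str, object]) -> None:
    for key, value in pairs.items():
        fh.write(f"# {key}: {value}\n")


def _read_headers_and_rows(path, ncols: int):
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    saw_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            saw_any = True
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, value = line.lstrip("#").partition(":")
                if sep:
                    headers[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != ncols:
                raise ParseError(path, lineno, f"expected {ncols} columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric data row {line!r}") from None
    if not saw_any:
        raise ParseError(path, 1, "empty file")
    if not rows:
        raise ParseError(path, 1, "no data rows found")
    return headers, np.asarray(rows)


def write_delimited_waveform(wf: RFWaveform, path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {
            "dwell_s": repr(wf.dwell),
            "carrier_ppm": repr(wf.carrier_ppm),
            "label": wf.label,
            "columns": "amplitude_hz phase_deg",
        })
        for a, p in zip(wf.amplitude, wf.phase_deg):
            fh.write(f"{float(a)!r} {float(p)!r}\n")


def read_delimited_waveform(path) -> RFWaveform:
    headers, rows = _read_headers_and_rows(path, 2)
    if "dwell_s" not in headers:
        raise ParseError(path, 1, "missing '# dwell_s:' header")
    return RFWaveform(
        rows[:, 0],
        rows[:, 1],
        float(headers["dwell_s"]),
        float(headers.get("carrier_ppm", 4.755)),
        label=headers.get("label", ""),
    )


def sniff_waveform_format(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "shape" if line.startswith("##") else "delimited"
    raise ParseError(path, 1, "empty file")


def _acq_headers(acq: AcquisitionParams) -> dict[str, object]:
    return {
        "sw_hz": repr(acq.sw_hz),
        "n_points": acq.n_points,
        "f0_mhz": repr(acq.f0_mhz),
        "carrier_ppm": repr(acq.carrier_ppm),
        "tr_s": repr(acq.tr_s),
        "ns": acq.ns,
    }


def _acq_from_headers(headers: dict[str, str]) -> AcquisitionParams:
    kwargs = {}
    for key, cast in (
        ("sw_hz", float), ("n_points", int), ("f0_mhz", float),
        ("carrier_ppm", float), ("tr_s", float), ("ns", int),
    ):
        if key in headers:
            kwargs[key] = cast(headers[key])
    return AcquisitionParams(**kwargs)


def write_delimited_fid(fid: FIDData, path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {**_acq_headers(fid.acq), "columns": "real imag"})
        for z in fid.data:
            fh.write(f"{float(z.real)!r} {float(z.imag)!r}\n")


def read_delimited_fid(path) -> FIDData:
    headers, rows = _read_headers_and_rows(path, 2)
    acq = _acq_from_headers(headers)
    if rows.shape[0] != acq.n_points:
        raise ParseError(path, 1, f"n_points header {acq.n_points} != {rows.shape[0]} rows")
    return FIDData(rows[:, 0] + 1j * rows[:, 1], acq, {"source": str(path)})


def write_delimited_spectrum(spec: SpectrumData, path) -> None:
    """Spectrum rows ordered ppm-descending (conventional NMR display)."""
    ppm = spec.ppm[::-1]
    data = spec.data[::-1]
    with open(path, "w") as fh:
        _write_header(fh, {
            **_acq_headers(spec.acq),
            "order": "ppm descending",
            "columns": "ppm real imag",
        })
        for x, z in zip(ppm, data):
            fh.write(f"{float(x)!r} {float(z.real)!r} {float(z.imag)!r}\n")


def write_jcamp_fid(fid: FIDData, path, title: str = "fid") -> None:
    acq = fid.acq
    t = acq.time_axis()
    with open(path, "w") as fh:
        fh.write(f"##TITLE= {title}\n")
        fh.write("##JCAMPDX= 5.00\n")
        fh.write("##DATA TYPE= NMR FID\n")
        fh.write(f"##.OBSERVE FREQUENCY= {acq.f0_mhz!r}\n")
        fh.write(f"##.SHIFT REFERENCE= {acq.carrier_ppm!r}\n")
        fh.write(f"##SW HZ= {acq.sw_hz!r}\n")
        fh.write(f"##TR SEC= {acq.tr_s!r}\n")
        fh.write(f"##NS= {acq.ns}\n")
        fh.write(f"##NPOINTS= {acq.n_points}\n")
        fh.write("##XYDATA= (T, R, I)\n")
        for ti, z in zip(t, fid.data):
            fh.write(f"{float(ti)!r} {float(z.real)!r} {float(z.imag)!r}\n")
        fh.write("##END=\n")


def read_jcamp_fid(path) -> FIDData:
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    in_data = False
    saw_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            saw_any = True
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##END"):
                    break
                if "=" not in line:
                    raise ParseError(path, lineno, "header record missing '='")
                key, _, value = line[2:].partition("=")
                headers[key.strip().upper().lstrip(".")] = value.strip()
                if key.strip().upper() == "XYDATA":
                    in_data = True
                continue
            if not in_data:
                raise ParseError(path, lineno, "data row before ##XYDATA record")
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric data row {line!r}") from None
    if not saw_any:
        raise ParseError(path, 1, "empty file")
    if not rows:
        raise ParseError(path, 1, "no data rows found")
    arr = np.asarray(rows)
    acq = AcquisitionParams(
        sw_hz=float(headers.get("SW HZ", 5000.0)),
        n_points=int(headers.get("NPOINTS", len(rows))),
        f0_mhz=float(headers.get("OBSERVE FREQUENCY", 75.0)),
        carrier_ppm=float(headers.get("SHIFT REFERENCE", 177.0)),
        tr_s=float(headers.get("TR SEC", 5.0)),
        ns=int(headers.get("NS", 1)),
    )
    if arr.shape[0] != acq.n_points:
        raise ParseError(path, 1, f"##NPOINTS= {acq.n_points} but {arr.shape[0]} rows found")
    return FIDData(arr[:, 1] + 1j * arr[:, 2], acq, {"source": str(path)})
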