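"""File formats.

* Signal CSV: a header line ``# fs=<Hz>`` followed by one sample per
  row.  Numbers are written with 17 significant digits so a write/read
  round trip is bit-exact for doubles.
* Coefficient CSV: ``band,level,index,value`` rows for either
  decomposition type, plus a JSON form carrying the same content.
* Spectrum CSV: two columns ``freq_hz,magnitude``.
* Report JSON: the :class:`~shiftwave.diagnostics.ShiftSensitivityReport`
  serialisation with a schema version field, and a flat CSV with one
  row per band.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .diagnostics import ShiftSensitivityReport, Spectrum
from .dwt import DecimatedDecomposition
from .errors import SignalFormatError
from .rdwt import RedundantDecomposition
from .signal import DiscreteSignal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "write_coefficients_csv",
    "write_coefficients_json",
    "write_spectrum_csv",
    "write_report_json",
    "write_report_csv",
]

_FMT = "%.17g"

Decomposition = Union[DecimatedDecomposition, RedundantDecomposition]


def write_signal_csv(path: Union[str, Path], signal: DiscreteSignal) -> None:
    """Write a signal as ``# fs=<Hz>`` header plus one sample per row."""
    lines = [f"# fs={_FMT % signal.sampling_rate}"]
    lines.extend(_FMT % v for v in signal.samples)
    Path(path).write_text("\n".join(lines) + "\n")


def read_signal_csv(path: Union[str, Path]) -> DiscreteSignal:
    """Read a signal written by :func:`write_signal_csv`.

    Raises :class:`~shiftwave.errors.SignalFormatError` with the
    offending line number for a missing ``# fs=`` header, a blank row
    or a non-numeric sample.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SignalFormatError(f"{path}: file is empty")
    lines = text.splitlines()
    header = lines[0].strip()
    if not header.startswith("#") or "fs=" not in header:
        raise SignalFormatError(
            f"{path}: line 1 must be a '# fs=<Hz>' header, got {header!r}"
        )
    try:
        rate = float(header.split("fs=", 1)[1].strip())
    except ValueError as exc:
        raise SignalFormatError(f"{path}: cannot parse sampling rate in line 1") from exc
    samples = []
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if lineno == len(lines) and not stripped:
            break  # single trailing newline is fine
        if not stripped:
            raise SignalFormatError(f"{path}: blank row at line {lineno}")
        if stripped.startswith("#") or stripped == "sample":
            continue  # tolerate comments and a column-name row
        try:
            samples.append(float(stripped))
        except ValueError as exc:
            raise SignalFormatError(
                f"{path}: non-numeric sample {stripped!r} at line {lineno}"
            ) from exc
    if not samples:
        raise SignalFormatError(f"{path}: no samples after the header")
    return DiscreteSignal(np.asarray(samples), rate)


def _coefficient_rows(dec: Decomposition) -> list[tuple[str, int, int, float]]:
    rows = []
    labels = dec.band_labels()
    for j, band in enumerate(dec.detail_coeffs, start=1):
        rows.extend((labels[j - 1], j, i, float(v)) for i, v in enumerate(band))
    rows.extend(
        (labels[-1], dec.levels, i, float(v)) for i, v in enumerate(dec.approx_coeffs)
    )
    return rows


def write_coefficients_csv(path: Union[str, Path], dec: Decomposition) -> None:
    """Write ``band,level,index,value`` rows for every coefficient."""
    lines = ["band,level,index,value"]
    lines.extend(
        f"{band},{level},{index},{_FMT % value}"
        for band, level, index, value in _coefficient_rows(dec)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_coefficients_json(path: Union[str, Path], dec: Decomposition) -> None:
    """Write a decomposition as JSON: bands keyed by label, plus metadata."""
    labels = dec.band_labels()
    payload = {
        "schema_version": 1,
        "kind": type(dec).__name__,
        "filterbank": dec.filterbank_name,
        "levels": dec.levels,
        "original_length": dec.original_length,
        "sampling_rate": dec.sampling_rate,
        "bands": {
            **{
                labels[j - 1]: band.tolist()
                for j, band in enumerate(dec.detail_coeffs, start=1)
            },
            labels[-1]: dec.approx_coeffs.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_spectrum_csv(path: Union[str, Path], spectrum: Spectrum) -> None:
    """Write a one-sided magnitude spectrum as ``freq_hz,magnitude`` rows."""
    lines = ["freq_hz,magnitude"]
    lines.extend(
        f"{_FMT % f},{_FMT % m}"
        for f, m in zip(spectrum.freq_hz, spectrum.magnitude)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_json(path: Union[str, Path], report: ShiftSensitivityReport) -> None:
    Path(path).write_text(json.dumps(report.to_json_dict(), indent=2) + "\n")


def write_report_csv(path: Union[str, Path], report: ShiftSensitivityReport) -> None:
    """Flat per-band view of a shift-sensitivity report."""
    lines = [
        "transform,band,label,estimated_period,distinct_pattern_count,"
        "max_equivariance_deviation"
    ]
    for b in report.per_band:
        lines.append(
            f"{report.transform_label},{b.band},{b.label},{b.estimated_period},"
            f"{b.distinct_pattern_count},{_FMT % b.max_equivariance_deviation}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
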