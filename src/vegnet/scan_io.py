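"""Read/write IML scan files.

One file holds one full-azimuth acquisition: a ``#``-prefixed ``key: value``
header (instrument id, scan-start timestamp, zenith angle, truncation flag)
followed by comma-delimited shot records ``index,azimuth_deg,range_m``.

Instrument conventions honoured by this format:

* a range of ``0.000`` m encodes a canopy gap or an invalid measurement;
* valid ranges are stored at millimetre precision below 10 m and
  centimetre precision at or above 10 m;
* azimuths are stored at the encoder precision of 0.1 degree;
* a scan carries between 1 and 7360 records.

The on-card byte format of the real instrument is unpublished; this
human-readable text layout is a stand-in with the same information content
and a comparable size (a 920-shot scan is a few tens of KB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterator, List

import numpy as np

__all__ = [
    "MAX_SHOTS_PER_SCAN",
    "GAP_RANGE",
    "ShotRecord",
    "Scan",
    "ScanFormatError",
    "quantize_range",
    "quantize_azimuth",
    "format_range",
    "write_scan",
    "read_scan",
]

MAX_SHOTS_PER_SCAN = 7360
GAP_RANGE = 0.0

_FORMAT_LINE = "vegnet-iml-scan v1"


class ScanFormatError(ValueError):
    """Raised when a scan file cannot be parsed; message names the line."""


@dataclass(frozen=True)
class ShotRecord:
    """One laser shot: ordinal index, azimuth (deg), slant range (m, 0 = gap)."""

    index: int
    azimuth: float
    range_m: float

    @property
    def is_gap(self) -> bool:
        return self.range_m == GAP_RANGE


def _round_half_up(values: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return np.floor(values * scale + 0.5) / scale


def quantize_range(d):
    """Quantize slant ranges to the storage precision (half-up rounding).

    mm precision below 10 m, cm precision at or above 10 m; the gap code
    0.000 is preserved.  Idempotent.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("range must be >= 0")
    scale = np.where(arr < 10.0, 1000.0, 100.0)
    q = _round_half_up(arr, scale)
    return q if arr.ndim else float(q)


def quantize_azimuth(az):
    """Quantize azimuths to the 0.1 degree encoder precision, wrapped to [0, 360)."""
    arr = np.asarray(az, dtype=float) % 360.0
    q = _round_half_up(arr, np.full_like(arr, 10.0)) % 360.0
    return q if arr.ndim else float(q)


def format_range(r: float) -> str:
    """Render a quantized range with its storage precision."""
    return f"{r:.3f}" if r < 10.0 else f"{r:.2f}"


@dataclass
class Scan:
    """One full-azimuth acquisition.

    Shots are stored as parallel arrays (``azimuth_deg``, ``range_m``)
    ordered by shot index; ``records`` yields them as `ShotRecord`s.
    ``truncated`` marks scans cut short by the firmware's rain rule
    (50 consecutive sub-300 mm ranges).
    """

    instrument_id: str
    timestamp: datetime
    zenith_deg: float
    azimuth_deg: np.ndarray
    range_m: np.ndarray
    truncated: bool = False
    extra_header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.azimuth_deg = np.asarray(self.azimuth_deg, dtype=float)
        self.range_m = np.asarray(self.range_m, dtype=float)
        if self.azimuth_deg.shape != self.range_m.shape or self.azimuth_deg.ndim != 1:
            raise ValueError("azimuth and range must be 1-D arrays of equal length")
        n = self.azimuth_deg.size
        if not (1 <= n <= MAX_SHOTS_PER_SCAN):
            raise ValueError(
                f"a scan must hold between 1 and {MAX_SHOTS_PER_SCAN} records, got {n}"
            )
        if np.any((self.azimuth_deg < 0) | (self.azimuth_deg >= 360)):
            raise ValueError("azimuths must lie in [0, 360) degrees")
        if np.any(self.range_m < 0):
            raise ValueError("ranges must be >= 0 (0.000 encodes a gap)")

    @property
    def n_shots(self) -> int:
        return int(self.range_m.size)

    @property
    def records(self) -> List[ShotRecord]:
        return [
            ShotRecord(i, float(a), float(r))
            for i, (a, r) in enumerate(zip(self.azimuth_deg, self.range_m))
        ]

    def valid_ranges(self) -> np.ndarray:
        """Ranges of valid returns (gaps excluded)."""
        return self.range_m[self.range_m > 0]

    def truncate_at(self, n: int) -> "Scan":
        return replace(
            self,
            azimuth_deg=self.azimuth_deg[:n].copy(),
            range_m=self.range_m[:n].copy(),
            truncated=True,
        )

    def __eq__(self, other) -> bool:  # noqa: D105 — value equality incl. arrays
        if not isinstance(other, Scan):
            return NotImplemented
        return (
            self.instrument_id == other.instrument_id
            and self.timestamp == other.timestamp
            and self.zenith_deg == other.zenith_deg
            and self.truncated == other.truncated
            and np.array_equal(self.azimuth_deg, other.azimuth_deg)
            and np.array_equal(self.range_m, other.range_m)
        )


def write_scan(scan: Scan, path) -> Path:
    """Write a scan to ``path`` in the delimited-text format (see module docs)."""
    path = Path(path)
    lines = [
        f"# format: {_FORMAT_LINE}",
        f"# instrument_id: {scan.instrument_id}",
        f"# timestamp: {scan.timestamp.isoformat()}",
        f"# zenith_deg: {scan.zenith_deg:g}",
        f"# truncated: {str(scan.truncated).lower()}",
        f"# n_records: {scan.n_shots}",
    ]
    lines += [f"# {k}: {v}" for k, v in scan.extra_header.items()]
    lines.append("index,azimuth_deg,range_m")
    for i, (a, r) in enumerate(zip(scan.azimuth_deg, scan.range_m)):
        lines.append(f"{i},{a:.1f},{format_range(r)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_header(lines: Iterator, header: dict) -> tuple[int, str]:
    """Consume header lines; return (line_no, first non-header line)."""
    for line_no, raw in lines:
        line = raw.rstrip("\r\n").rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
            continue
        return line_no, line
    raise ScanFormatError("scan file contains no records")


def read_scan(path) -> Scan:
    """Parse a scan file written by :func:`write_scan`.

    Tolerates CRLF line endings and trailing whitespace; raises
    :class:`ScanFormatError` naming the offending line on malformed input.
    """
    path = Path(path)
    header: dict = {}
    with path.open("r", newline="") as fh:
        numbered = enumerate(fh, start=1)
        line_no, first = _parse_header(numbered, header)

        required = ("instrument_id", "timestamp", "zenith_deg", "truncated")
        missing = [k for k in required if k not in header]
        if missing:
            raise ScanFormatError(
                f"{path.name}: header missing required field(s): {', '.join(missing)}"
            )

        if first.replace(" ", "") != "index,azimuth_deg,range_m":
            raise ScanFormatError(
                f"{path.name}, line {line_no}: expected column header "
                f"'index,azimuth_deg,range_m', got {first!r}"
            )

        azimuths: list[float] = []
        ranges: list[float] = []
        expected_index = 0
        for line_no, raw in numbered:
            line = raw.rstrip("\r\n").rstrip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ScanFormatError(
                    f"{path.name}, line {line_no}: expected 3 comma-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                idx = int(parts[0])
                az = float(parts[1])
                rng = float(parts[2])
            except ValueError as exc:
                raise ScanFormatError(
                    f"{path.name}, line {line_no}: unparseable record: {exc}"
                ) from None
            if idx != expected_index:
                raise ScanFormatError(
                    f"{path.name}, line {line_no}: record index {idx} out of "
                    f"order (expected {expected_index})"
                )
            if not (0.0 <= az < 360.0):
                raise ScanFormatError(
                    f"{path.name}, line {line_no}: azimuth {az} outside [0, 360)"
                )
            if rng < 0 or not math.isfinite(rng):
                raise ScanFormatError(
                    f"{path.name}, line {line_no}: invalid range {rng}"
                )
            azimuths.append(az)
            ranges.append(rng)
            expected_index += 1

    if not azimuths:
        raise ScanFormatError(f"{path.name}: scan contains no records")

    known = {"format", "instrument_id", "timestamp", "zenith_deg", "truncated", "n_records"}
    try:
        timestamp = datetime.fromisoformat(header["timestamp"])
    except ValueError:
        raise ScanFormatError(
            f"{path.name}: unparseable timestamp {header['timestamp']!r}"
        ) from None
    return Scan(
        instrument_id=header["instrument_id"],
        timestamp=timestamp,
        zenith_deg=float(header["zenith_deg"]),
        azimuth_deg=np.array(azimuths),
        range_m=np.array(ranges),
        truncated=header["truncated"].lower() == "true",
        extra_header={k: v for k, v in header.items() if k not in known},
    )
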