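"""Weather-based scan quality control.

Two failure modes are screened, per whole scan (a partially affected scan
is excluded entirely, since keeping only some azimuths would bias the
plot-scale gap fraction):

* **rain** — droplets on the scan-head prism return short ranges near
  270 mm; scans are flagged when the firmware truncated them, or when they
  contain a run of 50 or more consecutive sub-300 mm readings;
* **wind / low quality** — degraded scans show an anomalously low sum of
  valid within-scan ranges; scans whose summed range falls strictly below
  a per-instrument threshold are excluded.  Thresholds are chosen from the
  bimodal histogram of summed ranges (see :func:`summed_range_histogram`
  and :func:`suggest_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scan_io import Scan

__all__ = [
    "THRESHOLD_PRESETS",
    "RAIN_RANGE_THRESHOLD_M",
    "RAIN_RUN_LENGTH",
    "ScanQC",
    "QCPartition",
    "detect_rain",
    "sum_valid_ranges",
    "classify_scan",
    "apply_threshold",
    "summed_range_histogram",
    "suggest_threshold",
    "exclusion_summary",
]

#: Summed-range exclusion thresholds (m) used in the original three-
#: instrument deployment, keyed by instrument id.
THRESHOLD_PRESETS = {"VN5": 8000.0, "VN6": 9000.0, "VN7": 8100.0}

RAIN_RANGE_THRESHOLD_M = 0.300
RAIN_RUN_LENGTH = 50


@dataclass(frozen=True)
class ScanQC:
    """QC verdict for one scan; ``excluded`` iff ``reason != "retained"``."""

    instrument_id: str
    timestamp: datetime
    sum_valid_ranges: float
    rain_flag: bool
    reason: str  # "rain" | "below_threshold" | "retained"

    @property
    def excluded(self) -> bool:
        return self.reason != "retained"


@dataclass
class QCPartition:
    """Disjoint partition of input scans with per-scan verdicts."""

    retained: list  # [Scan]
    excluded: list  # [Scan]
    verdicts: list  # [ScanQC], input order


def _max_short_run(ranges: np.ndarray, *, count_gaps: bool) -> int:
    short = ranges < RAIN_RANGE_THRESHOLD_M
    if not count_gaps:
        short &= ranges > 0  # gaps (0.000) are not short *measurements*
    if not short.any():
        return 0
    padded = np.concatenate([[False], short, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[0::2]).max())


def detect_rain(scan: Scan, *, count_gaps: bool = False) -> bool:
    """True if the scan was rain-affected.

    Either the firmware already truncated it (50 consecutive short readings
    during acquisition), or a post-hoc run-length check finds >= 50
    consecutive non-gap readings below 300 mm.  Gap records (0.000 m) break
    a run by default — droplets return ~270 mm hits, not gaps — but
    ``count_gaps=True`` includes them for a more conservative screen.
    """
    if scan.truncated:
        return True
    return _max_short_run(scan.range_m, count_gaps=count_gaps) >= RAIN_RUN_LENGTH


def sum_valid_ranges(scan: Scan) -> float:
    """Sum of within-scan valid range measurements, m (gaps excluded)."""
    return float(scan.valid_ranges().sum())


def classify_scan(scan: Scan, threshold: float) -> ScanQC:
    """Apply the rain check and the summed-range threshold to one scan.

    A scan is excluded if rain-flagged, or if its summed range is strictly
    below ``threshold`` (a sum exactly at the threshold is retained).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    total = sum_valid_ranges(scan)
    rain = detect_rain(scan)
    if rain:
        reason = "rain"
    elif total < threshold:
        reason = "below_threshold"
    else:
        reason = "retained"
    return ScanQC(
        instrument_id=scan.instrument_id,
        timestamp=scan.timestamp,
        sum_valid_ranges=total,
        rain_flag=rain,
        reason=reason,
    )


def apply_threshold(scans: Iterable[Scan], threshold: float) -> QCPartition:
    """Partition scans into retained and excluded sets (whole scans only)."""
    retained, excluded, verdicts = [], [], []
    for scan in scans:
        qc = classify_scan(scan, threshold)
        verdicts.append(qc)
        (excluded if qc.excluded else retained).append(scan)
    return QCPartition(retained=retained, excluded=excluded, verdicts=verdicts)


def summed_range_histogram(scans: Sequence[Scan], bin_width: float = 500.0):
    """Histogram of per-scan summed valid ranges, for threshold selection.

    Returns a DataFrame with ``bin_left``, ``bin_right`` and ``count``;
    with clean and weather-degraded scan populations mixed the histogram
    is bimodal and the exclusion threshold is placed in the gap.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("at least one scan is required")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    sums = np.array([sum_valid_ranges(s) for s in scans])
    top = max(sums.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(sums, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def suggest_threshold(sums) -> float:
    """Data-driven threshold between the two modes of a summed-range mix.

    Otsu's criterion on the raw sums: the split that maximizes the
    between-class variance.  Deterministic and label-free; intended as an
    aid when choosing a per-instrument threshold from the histogram, not a
    replacement for inspection.
    """
    s = np.sort(np.asarray(list(sums), dtype=float))
    if s.size < 2 or s[0] == s[-1]:
        raise ValueError("need at least two distinct summed-range values")
    n = s.size
    cum = np.cumsum(s)
    k = np.arange(1, n)  # split: low class s[:k], high class s[k:]
    w0 = k / n
    w1 = 1.0 - w0
    mu0 = cum[k - 1] / k
    mu1 = (cum[-1] - cum[k - 1]) / (n - k)
    between = w0 * w1 * (mu0 - mu1) ** 2
    kbest = int(k[np.argmax(between)])
    return float(0.5 * (s[kbest - 1] + s[kbest]))


def exclusion_summary(verdicts: Sequence[ScanQC]) -> pd.DataFrame:
    """Monthly exclusion summary from per-scan QC verdicts.

    One row per calendar month spanning the campaign (months with no scans
    appear with zero counts and an undefined percentage), with columns
    ``n_scans``, ``n_excluded``, ``n_rain``, ``n_below_threshold`` and
    ``percent_excluded``.  The mean of the defined monthly percentages is
    stored in ``df.attrs["mean_percent_excluded"]``.
    """
    if not verdicts:
        raise ValueError("at least one QC verdict is required")
    df = pd.DataFrame(
        {
            "month": [pd.Period(q.timestamp, freq="M") for q in verdicts],
            "excluded": [q.excluded for q in verdicts],
            "rain": [q.reason == "rain" for q in verdicts],
            "below": [q.reason == "below_threshold" for q in verdicts],
        }
    )
    months = pd.period_range(df["month"].min(), df["month"].max(), freq="M")
    g = df.groupby("month")
    out = pd.DataFrame(
        {
            "n_scans": g.size(),
            "n_excluded": g["excluded"].sum(),
            "n_rain": g["rain"].sum(),
            "n_below_threshold": g["below"].sum(),
        }
    ).reindex(months, fill_value=0)
    out.index.name = "month"
    with np.errstate(invalid="ignore"):
        out["percent_excluded"] = 100.0 * out["n_excluded"] / out["n_scans"].replace(0, np.nan)
    out.attrs["mean_percent_excluded"] = float(out["percent_excluded"].mean())
    return out
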