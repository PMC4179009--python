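"""Monthly aggregation, summary statistics and long-term PAI trends.

Daily retained profiles are aggregated per calendar month (arithmetic mean
of the daily PAI(z)/PAVD(z) profiles by default; shot-weighted pooling of
gap fractions as an option), summarized Table-style (mean / max / min /
range / relative range), and smoothed into a long-term trend by a cubic
spline through the month midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .profiles import PAI_COEFFICIENT, VerticalProfile

__all__ = [
    "MonthlySeries",
    "monthly_aggregate",
    "pai_summary_stats",
    "relative_range_percent",
    "fit_trend",
]


@dataclass
class MonthlySeries:
    """Per-month mean vertical structure for one instrument.

    ``months`` is an ascending PeriodIndex of the months that contained at
    least one retained profile; ``monthly_pai`` the mean top-of-canopy PAI
    per month; ``pai_profiles`` / ``pavd_profiles`` DataFrames indexed by
    height with one column per month.
    """

    instrument_id: str
    months: pd.PeriodIndex
    monthly_pai: np.ndarray
    pai_profiles: pd.DataFrame
    pavd_profiles: pd.DataFrame
    n_scans: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months.astype(str),
                "mean_pai_top": self.monthly_pai,
                "n_scans": self.n_scans,
            }
        )


def monthly_aggregate(
    profiles,
    *,
    instrument_id: str | None = None,
    method: str = "mean_profiles",
) -> MonthlySeries:
    """Aggregate daily profiles to a monthly series.

    ``method="mean_profiles"`` (default) averages the daily PAI(z) and
    PAVD(z) profiles within each calendar month; ``method="pooled"``
    combines the month's scans at the gap-fraction level (shot-weighted
    mean Pgap, re-inverted to PAI), equivalent to pooling all shots of the
    month into one large scan.  Months without retained profiles are
    simply absent from the output.
    """
    profiles = [p for p in profiles if instrument_id is None or p.instrument_id == instrument_id]
    if not profiles:
        raise ValueError("at least one retained profile is required")
    if method not in ("mean_profiles", "pooled"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if any(p.timestamp is None for p in profiles):
        raise ValueError("profiles must carry timestamps for monthly aggregation")
    height = profiles[0].height
    for p in profiles[1:]:
        if not np.array_equal(p.height, height):
            raise ValueError("all profiles must share the same height grid")

    ids = {p.instrument_id for p in profiles}
    inst = instrument_id if instrument_id is not None else (ids.pop() if len(ids) == 1 else "mixed")

    bw = profiles[0].bin_width
    groups: dict[pd.Period, list[VerticalProfile]] = {}
    for p in profiles:
        groups.setdefault(pd.Period(p.timestamp, freq="M"), []).append(p)

    months = pd.PeriodIndex(sorted(groups), freq="M")
    pai_cols, pavd_cols, tops, counts = {}, {}, [], []
    for m in months:
        grp = groups[m]
        if method == "mean_profiles":
            pai = np.mean([p.pai for p in grp], axis=0)
        else:
            w = np.array([p.n_shots for p in grp], dtype=float)
            pgap = np.average([p.pgap for p in grp], axis=0, weights=w)
            pai = -PAI_COEFFICIENT * np.log(np.maximum(pgap, 1.0 / (2.0 * w.sum())))
        pai_cols[str(m)] = pai
        pavd_cols[str(m)] = np.diff(pai) / bw
        tops.append(pai[-1])
        counts.append(len(grp))

    return MonthlySeries(
        instrument_id=inst,
        months=months,
        monthly_pai=np.array(tops),
        pai_profiles=pd.DataFrame(pai_cols, index=pd.Index(height, name="height_m")),
        pavd_profiles=pd.DataFrame(
            pavd_cols, index=pd.Index(height[:-1], name="height_m")
        ),
        n_scans=np.array(counts),
    )


def relative_range_percent(mean: float, vmax: float, vmin: float) -> int:
    """Temporal range as a percentage of the mean, to the nearest integer."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return int(round(100.0 * (vmax - vmin) / mean))


def pai_summary_stats(monthly_pai) -> dict:
    """Long-term summary of a monthly PAI series.

    Returns mean, max, min, range (max - min) and ``range_percent``
    (range as an integer percentage of the mean).
    """
    vals = np.asarray(list(monthly_pai), dtype=float)
    if vals.size == 0:
        raise ValueError("at least one monthly value is required")
    mean, vmax, vmin = float(vals.mean()), float(vals.max()), float(vals.min())
    return {
        "mean": mean,
        "max": vmax,
        "min": vmin,
        "range": vmax - vmin,
        "range_percent": relative_range_percent(mean, vmax, vmin),
    }


def _month_midpoints(months: pd.PeriodIndex) -> np.ndarray:
    """Month midpoints as fractional days since the first month's start."""
    starts = months.to_timestamp(how="start")
    ends = months.to_timestamp(how="end")
    mid = starts + (ends - starts) / 2
    t0 = months[0].to_timestamp(how="start")
    return ((mid - t0) / pd.Timedelta(days=1)).to_numpy(dtype=float)


def fit_trend(
    series: MonthlySeries,
    *,
    samples_per_month: int = 30,
    bridge_gaps: bool = False,
) -> pd.DataFrame:
    """Cubic-spline trend through monthly PAI means, sampled ~daily.

    The spline interpolates the monthly values at the month midpoints, so
    it passes through every monthly point exactly.  With
    ``bridge_gaps=False`` (default) the trend is fitted piecewise over
    contiguous runs of months and not drawn across missing months;
    ``bridge_gaps=True`` fits one spline across the whole span.
    Requires at least 4 monthly points.
    """
    months, pai = series.months, series.monthly_pai
    if len(months) < 4:
        raise ValueError(
            "need >= 4 monthly points for a spline trend; interpolation is "
            "unreliable on fewer"
        )
    t = _month_midpoints(months)
    t0 = months[0].to_timestamp(how="start")

    if bridge_gaps:
        blocks = [np.arange(len(months))]
    else:
        gap_after = np.flatnonzero(np.diff(months.asi8) > 1)
        blocks = np.split(np.arange(len(months)), gap_after + 1)

    frames = []
    for block in blocks:
        tb, yb = t[block], pai[block]
        ts = np.linspace(tb[0], tb[-1], max(2, samples_per_month * len(block)))
        if len(block) >= 4:
            ys = CubicSpline(tb, yb)(ts)
        elif len(block) >= 2:
            ys = np.interp(ts, tb, yb)
        else:
            ts, ys = tb, yb
        frames.append(pd.DataFrame({"time": t0 + pd.to_timedelta(ts, unit="D"), "pai": ys}))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["instrument_id"] = series.instrument_id
    return out
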