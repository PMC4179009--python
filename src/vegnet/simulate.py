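"""Synthetic scan generator with known ground truth.

Simulates full-azimuth hinge-angle scans of a horizontally homogeneous,
vertically layered canopy.  Each laser shot either intercepts plant
material at some height or escapes through the canopy; the interception
height is drawn exactly from the Beer-Lambert survival law

    S(z) = exp(-K * L(z))

where ``L(z)`` is the true cumulative plant area index below height ``z``
and ``K`` the ellipsoidal extinction coefficient at the scan zenith.
On top of this clean process the generator reproduces the instrument's
known artefacts: the live-foliage detection limit (interceptions beyond
60 m slant range appear as gaps), mm/cm range quantization, rain-droplet
returns at ~270 mm with firmware truncation after 50 consecutive short
readings, and wind perturbation (canopy elements leaving or entering the
beam path between shots).

All randomness flows through an explicit ``numpy.random.Generator``;
there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from .geometry import InstrumentGeometry
from .lad import EllipsoidalLAD, extinction_coefficient
from .scan_io import MAX_SHOTS_PER_SCAN, Scan, quantize_azimuth, quantize_range

__all__ = [
    "CanopyModel",
    "WeatherScenario",
    "CALM",
    "SimulationConfig",
    "simulate_scan",
    "inject_rain",
    "CampaignConfig",
    "CampaignResult",
    "simulate_campaign",
]


@dataclass(frozen=True)
class CanopyModel:
    """Layered true plant-area profile: the simulation ground truth.

    ``layer_tops`` are strictly increasing heights (m, instrument datum);
    layer ``i`` spans from the previous top (0 for the first) to
    ``layer_tops[i]`` with constant plant area volume density
    ``layer_pavd[i]`` (m^2 m^-3).
    """

    layer_tops: tuple
    layer_pavd: tuple
    lad: EllipsoidalLAD = field(default_factory=EllipsoidalLAD)

    def __post_init__(self) -> None:
        tops = np.asarray(self.layer_tops, dtype=float)
        pavd = np.asarray(self.layer_pavd, dtype=float)
        if tops.ndim != 1 or tops.size == 0 or tops.shape != pavd.shape:
            raise ValueError("layer_tops and layer_pavd must be 1-D and equal length")
        if tops[0] <= 0 or np.any(np.diff(tops) <= 0):
            raise ValueError("layer_tops must be positive and strictly increasing")
        if np.any(pavd < 0):
            raise ValueError("layer PAVD values must be >= 0")
        object.__setattr__(self, "layer_tops", tuple(float(t) for t in tops))
        object.__setattr__(self, "layer_pavd", tuple(float(u) for u in pavd))

    @classmethod
    def uniform(cls, pai_top: float, height: float, lad: EllipsoidalLAD | None = None):
        """Single homogeneous layer with total PAI ``pai_top`` up to ``height``."""
        if height <= 0 or pai_top < 0:
            raise ValueError("height must be > 0 and pai_top >= 0")
        return cls((height,), (pai_top / height,), lad or EllipsoidalLAD())

    @property
    def canopy_height(self) -> float:
        return self.layer_tops[-1]

    @property
    def _bounds(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.layer_tops)])

    @property
    def _cum_pai(self) -> np.ndarray:
        pavd = np.asarray(self.layer_pavd)
        return np.concatenate([[0.0], np.cumsum(pavd * np.diff(self._bounds))])

    def cumulative_pai(self, z):
        """True cumulative plant area index L(z): piecewise-linear,
        non-decreasing, L(0) = 0, constant above the canopy top."""
        z = np.asarray(z, dtype=float)
        if np.any(z < 0):
            raise ValueError("height must be >= 0")
        L = np.interp(z, self._bounds, self._cum_pai)
        return L if z.ndim else float(L)

    @property
    def pai_top(self) -> float:
        return float(self._cum_pai[-1])

    def scaled_to(self, pai_top: float) -> "CanopyModel":
        """Same vertical shape, rescaled so the total PAI equals ``pai_top``."""
        if self.pai_top <= 0:
            raise ValueError("cannot rescale an empty canopy")
        f = pai_top / self.pai_top
        return CanopyModel(
            self.layer_tops, tuple(u * f for u in self.layer_pavd), self.lad
        )


@dataclass(frozen=True)
class WeatherScenario:
    """Per-shot weather perturbation of a scan.

    ``wind_gap_prob``: probability a true interception is lost (the element
    moved out of the beam, or moved enough that no range was returned),
    producing an apparent gap.  ``wind_hit_prob``: probability a gap shot
    instead hits an element blown into the beam, returning a spurious range
    drawn uniformly from ``spurious_range_m``.  Wind is applied i.i.d. per
    shot.  ``rain`` marks the scan for rain-droplet injection.
    """

    rain: bool = False
    wind_gap_prob: float = 0.0
    wind_hit_prob: float = 0.0
    spurious_range_m: tuple = (0.5, 10.0)

    def __post_init__(self) -> None:
        for p in (self.wind_gap_prob, self.wind_hit_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("weather probabilities must lie in [0, 1]")
        lo, hi = self.spurious_range_m
        if not (0 < lo <= hi):
            raise ValueError("spurious range bounds must satisfy 0 < lo <= hi")


CALM = WeatherScenario()


@dataclass(frozen=True)
class SimulationConfig:
    """Scan acquisition settings: shot count, geometry, quantization."""

    n_shots: int = 920
    geom: InstrumentGeometry = field(default_factory=InstrumentGeometry)
    quantize: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n_shots <= MAX_SHOTS_PER_SCAN):
            raise ValueError(
                f"n_shots must be in [1, {MAX_SHOTS_PER_SCAN}], got {self.n_shots}"
            )

    @property
    def shots_per_degree(self) -> float:
        return self.n_shots / 360.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        raise ValueError("an explicit seed or numpy Generator is required")
    return np.random.default_rng(rng)


def simulate_scan(
    canopy: CanopyModel,
    cfg: SimulationConfig = SimulationConfig(),
    weather: WeatherScenario = CALM,
    *,
    rng,
    instrument_id: str = "SIM",
    timestamp: datetime | None = None,
) -> Scan:
    """Simulate one full-azimuth scan of ``canopy``.

    Azimuths lie on a deterministic uniform grid over [0, 360) (stepper-motor
    stepping).  Interception heights are drawn by inverse-transform sampling
    from the piecewise-exponential survival S(z) = exp(-K L(z)); a shot that
    survives to the canopy top, or whose interception lies beyond the
    detection limit, is recorded as a gap (range 0.000).  Wind effects are
    applied per shot, then ranges are quantized to the storage precision.
    Rain injection is a separate step (:func:`inject_rain`).
    """
    rng = _as_rng(rng)
    n = cfg.n_shots
    geom = cfg.geom
    azimuth = quantize_azimuth(np.arange(n) * (360.0 / n))

    K = extinction_coefficient(geom.zenith, canopy.lad)
    cum = canopy._cum_pai
    bounds = canopy._bounds
    tau = -np.log(rng.uniform(size=n))  # optical depth reached at interception

    hit = tau < K * canopy.pai_top
    z_star = np.interp(tau / K, cum, bounds)
    rng_m = np.where(hit, z_star / geom.cos_zenith, 0.0)

    # detection limit: interceptions beyond max range return no reading
    hit &= rng_m <= geom.max_detect_range

    if weather.wind_gap_prob > 0:
        hit &= ~(rng.uniform(size=n) < weather.wind_gap_prob)
    if weather.wind_hit_prob > 0:
        spurious = (~hit) & (rng.uniform(size=n) < weather.wind_hit_prob)
        lo, hi = weather.spurious_range_m
        rng_m = np.where(spurious, rng.uniform(lo, hi, size=n), rng_m)
        hit |= spurious

    rng_m = np.where(hit, rng_m, 0.0)
    if cfg.quantize:
        rng_m = quantize_range(rng_m)

    if timestamp is None:
        timestamp = datetime(2000, 1, 1, 22, 0, tzinfo=timezone.utc)
    return Scan(
        instrument_id=instrument_id,
        timestamp=timestamp,
        zenith_deg=geom.zenith,
        azimuth_deg=azimuth,
        range_m=rng_m,
    )


RAIN_RUN_LENGTH = 50
RAIN_RANGE_M = (0.260, 0.290)  # droplet returns cluster near the 270 mm prism face


def inject_rain(scan: Scan, *, rng, onset: int | None = None) -> Scan:
    """Overlay rain-droplet returns and apply the firmware termination rule.

    From a random onset shot, ranges are replaced by short readings drawn
    uniformly from ``RAIN_RANGE_M`` (the droplet-on-prism distance); after
    50 consecutive short readings the firmware stops the scan, so the
    result is truncated exactly 50 shots after onset with the truncation
    flag set.  An onset too close to the scan end (fewer than 50 shots
    remaining) leaves the tail rainy but untruncated.
    """
    rng = _as_rng(rng)
    n = scan.n_shots
    if onset is None:
        onset = int(rng.integers(0, max(1, n - RAIN_RUN_LENGTH + 1)))
    if not (0 <= onset < n):
        raise ValueError(f"rain onset {onset} outside scan of {n} shots")

    end = min(onset + RAIN_RUN_LENGTH, n)
    ranges = scan.range_m.copy()
    ranges[onset:end] = quantize_range(rng.uniform(*RAIN_RANGE_M, size=end - onset))
    out = Scan(
        instrument_id=scan.instrument_id,
        timestamp=scan.timestamp,
        zenith_deg=scan.zenith_deg,
        azimuth_deg=scan.azimuth_deg.copy(),
        range_m=ranges,
        truncated=scan.truncated,
        extra_header=dict(scan.extra_header),
    )
    if end - onset == RAIN_RUN_LENGTH:
        out = out.truncate_at(end)
    return out


# ---------------------------------------------------------------------------
# Long-term campaign

#: Vertical shape used for the synthetic forest: an open eucalypt-like
#: canopy ~25 m tall with density peaks near 6 m and 14 m.  The shape is
#: rescaled daily to the seasonal total PAI.
DEFAULT_LAYER_TOPS = (2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 25.0)
DEFAULT_LAYER_PAVD = (0.03, 0.06, 0.11, 0.06, 0.10, 0.04, 0.015)


@dataclass(frozen=True)
class CampaignConfig:
    """Multi-instrument monitoring campaign: the synthetic field trial.

    Defaults emulate an 18-month deployment of three co-located instruments
    in open eucalypt forest: one scan per instrument per night at 22:00
    local time, long-term mean PAI between 1.32 and 1.56 per instrument,
    a seasonal cycle of ~10% relative amplitude peaking in austral summer,
    and weather contamination (rain-terminated and wind-degraded scans)
    that removes roughly half the scans in QC.
    """

    start: date = date(2012, 8, 1)
    n_months: int = 18
    instrument_means: tuple = (("VN5", 1.56), ("VN6", 1.36), ("VN7", 1.32))
    seasonal_amplitude: float = 0.10  # relative, peak-to-mean
    peak_day_of_year: int = 355  # austral summer solstice
    layer_tops: tuple = DEFAULT_LAYER_TOPS
    layer_pavd: tuple = DEFAULT_LAYER_PAVD
    lad: EllipsoidalLAD = field(default_factory=EllipsoidalLAD)
    rain_prob: float = 0.25
    heavy_wind_prob: float = 0.23
    heavy_wind: WeatherScenario = WeatherScenario(
        wind_gap_prob=0.5, wind_hit_prob=0.02
    )
    scan: SimulationConfig = field(default_factory=SimulationConfig)
    utc_offset_hours: float = 10.0

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise ValueError("campaign must span at least one month")
        if not (0 <= self.rain_prob + self.heavy_wind_prob <= 1):
            raise ValueError("rain_prob + heavy_wind_prob must lie in [0, 1]")

    def seasonal_pai(self, mean_pai: float, day: date) -> float:
        """True top-of-canopy PAI on ``day`` for an instrument's mean level."""
        doy = day.timetuple().tm_yday
        phase = 2.0 * np.pi * (doy - self.peak_day_of_year) / 365.25
        return mean_pai * (1.0 + self.seasonal_amplitude * np.cos(phase))

    def dates(self):
        d0 = self.start
        # end of campaign: first day of the month n_months later
        end_month = d0.month - 1 + self.n_months
        end = date(d0.year + end_month // 12, end_month % 12 + 1, 1)
        out, d = [], d0
        while d < end:
            out.append(d)
            d += timedelta(days=1)
        return out


@dataclass
class CampaignResult:
    scans: list
    truth: pd.DataFrame  # instrument_id, date, condition, true_pai_top


def simulate_campaign(cfg: CampaignConfig = CampaignConfig(), *, rng) -> CampaignResult:
    """Run a nightly scan campaign; returns scans plus a ground-truth table.

    Each night and instrument independently experiences clear weather, rain
    (scan terminated by the firmware rule) or heavy wind (apparent gap
    fraction inflated), with the configured probabilities.
    """
    rng = _as_rng(rng)
    tz = timezone(timedelta(hours=cfg.utc_offset_hours))
    shape = CanopyModel(cfg.layer_tops, cfg.layer_pavd, cfg.lad)

    scans, rows = [], []
    for inst, mean_pai in cfg.instrument_means:
        for day in cfg.dates():
            true_pai = cfg.seasonal_pai(mean_pai, day)
            canopy = shape.scaled_to(true_pai)
            u = rng.uniform()
            if u < cfg.rain_prob:
                condition = "rain"
                weather = CALM
            elif u < cfg.rain_prob + cfg.heavy_wind_prob:
                condition = "heavy_wind"
                weather = cfg.heavy_wind
            else:
                condition = "clear"
                weather = CALM
            ts = datetime.combine(day, time(22, 0), tzinfo=tz)
            scan = simulate_scan(
                canopy, cfg.scan, weather, rng=rng, instrument_id=inst, timestamp=ts
            )
            if condition == "rain":
                scan = inject_rain(scan, rng=rng)
            scans.append(scan)
            rows.append(
                {
                    "instrument_id": inst,
                    "date": day.isoformat(),
                    "condition": condition,
                    "true_pai_top": true_pai,
                }
            )
    return CampaignResult(scans=scans, truth=pd.DataFrame(rows))
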