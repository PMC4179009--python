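"""Core inversion: scan -> Pgap(z) -> cumulative PAI(z) -> PAVD(z).

Heights are above the instrument datum (z = 0 at the scan head).  Each
valid return at slant range ``d`` is assigned the height
``z = cos(zenith) * d``; the gap probability to height ``h`` is

    Pgap(h) = 1 - (# valid returns with z_i < h) / N

over all N shots of the scan (gap records count toward N but never toward
the returns below h).  Cumulative plant area index follows from the
hinge-angle inversion PAI(z) = -1.1 ln Pgap(z), and plant area volume
density is its forward finite difference with respect to height.

Because lidar returns do not separate leaves from woody material, the
outputs are plant (not leaf) area quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .geometry import InstrumentGeometry
from .scan_io import Scan

__all__ = [
    "PAI_COEFFICIENT",
    "VerticalProfile",
    "default_height_grid",
    "gap_profile",
    "pai_profile",
    "pavd_profile",
    "compute_profile",
    "pooled_profile",
    "top_of_canopy_pai",
    "write_profile_csv",
    "read_profile_csv",
]

#: Hinge-angle gap-to-PAI inversion coefficient (1/K at 57.5 deg, to one
#: decimal, nearly independent of leaf angle distribution).
PAI_COEFFICIENT = 1.1


@dataclass
class VerticalProfile:
    """Vertical structure retrieved from one scan (or an aggregate).

    ``height`` holds the uniform grid of bin edges (m); ``pgap`` and
    ``pai`` are evaluated at each edge, while ``pavd`` has one value per
    bin (len(height) - 1).  ``saturated`` marks profiles where Pgap hit
    zero and was clipped before the log.
    """

    height: np.ndarray
    pgap: np.ndarray
    pai: np.ndarray
    pavd: np.ndarray
    n_shots: int
    saturated: bool = False
    instrument_id: str = ""
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.pgap = np.asarray(self.pgap, dtype=float)
        self.pai = np.asarray(self.pai, dtype=float)
        self.pavd = np.asarray(self.pavd, dtype=float)
        m = self.height.size
        if not (self.pgap.size == self.pai.size == m and self.pavd.size == m - 1):
            raise ValueError("profile arrays have inconsistent lengths")

    @property
    def bin_width(self) -> float:
        return float(self.height[1] - self.height[0])

    @property
    def pai_top(self) -> float:
        """Top-of-canopy (total) plant area index: the profile asymptote."""
        return float(self.pai[-1])


def default_height_grid(max_height: float = 35.0, bin_width: float = 0.5) -> np.ndarray:
    """Uniform height-bin edges from 0 to ``max_height`` (m)."""
    if max_height <= 0 or bin_width <= 0:
        raise ValueError("max_height and bin_width must be > 0")
    n_bins = int(round(max_height / bin_width))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def _check_uniform(grid: np.ndarray) -> float:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("height grid needs at least two edges")
    steps = np.diff(grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("height grid must be uniform and ascending")
    return float(steps[0])


def gap_profile(
    scan: Scan,
    geom: InstrumentGeometry = InstrumentGeometry(),
    height_grid: np.ndarray | None = None,
    *,
    literal_gap_counting: bool = False,
) -> np.ndarray:
    """Gap probability at each height-grid edge.

    Counts use a strict ``z_i < h`` comparison.  ``literal_gap_counting``
    is a debug mode in which gap records (range 0.000, hence z = 0) are
    also counted as "returns below h" and Pgap(h) is the raw below-h ratio
    — physically inconsistent (it decreases where there is no canopy) but
    useful for comparison.
    """
    if height_grid is None:
        height_grid = default_height_grid()
    _check_uniform(height_grid)
    n = scan.n_shots
    if literal_gap_counting:
        z = np.sort(geom.cos_zenith * scan.range_m)
        return np.searchsorted(z, height_grid, side="left") / n
    z = np.sort(geom.cos_zenith * scan.valid_ranges())
    below = np.searchsorted(z, height_grid, side="left")
    return 1.0 - below / n


def pai_profile(
    pgap: np.ndarray, n_shots: int, coefficient: float = PAI_COEFFICIENT
) -> tuple[np.ndarray, bool]:
    """Cumulative PAI(z) = -coefficient * ln Pgap(z).

    Pgap values of exactly zero (every shot intercepted below z) would give
    infinite PAI; they are clipped to 1/(2 N) and the profile is flagged
    ``saturated``.  Returns ``(pai, saturated)``.
    """
    pgap = np.asarray(pgap, dtype=float)
    if np.any((pgap < 0) | (pgap > 1)):
        raise ValueError("Pgap values must lie in [0, 1]")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    saturated = bool(np.any(pgap == 0.0))
    clipped = np.maximum(pgap, 1.0 / (2.0 * n_shots))
    return -coefficient * np.log(clipped), saturated


def pavd_profile(
    pai: np.ndarray, bin_width: float, *, smooth_window: int | None = None
) -> np.ndarray:
    """Plant area volume density per bin: forward difference dPAI/dz.

    Optional centred moving-average smoothing over ``smooth_window`` bins
    (odd, >= 3); off by default.  Smoothing uses edge padding so the sum
    rule bin_width * sum(pavd) = PAI(top) is preserved only without it.
    """
    pai = np.asarray(pai, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    pavd = np.diff(pai) / bin_width
    if smooth_window:
        if smooth_window < 3 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")
        half = smooth_window // 2
        padded = np.pad(pavd, half, mode="edge")
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        pavd = np.convolve(padded, kernel, mode="valid")
    return pavd


def compute_profile(
    scan: Scan,
    geom: InstrumentGeometry = InstrumentGeometry(),
    height_grid: np.ndarray | None = None,
    *,
    coefficient: float = PAI_COEFFICIENT,
    smooth_window: int | None = None,
) -> VerticalProfile:
    """Full inversion for one retained whole scan."""
    if height_grid is None:
        height_grid = default_height_grid()
    bw = _check_uniform(height_grid)
    pgap = gap_profile(scan, geom, height_grid)
    pai, saturated = pai_profile(pgap, scan.n_shots, coefficient)
    pavd = pavd_profile(pai, bw, smooth_window=smooth_window)
    return VerticalProfile(
        height=np.asarray(height_grid, dtype=float),
        pgap=pgap,
        pai=pai,
        pavd=pavd,
        n_shots=scan.n_shots,
        saturated=saturated,
        instrument_id=scan.instrument_id,
        timestamp=scan.timestamp,
    )


def top_of_canopy_pai(profile: VerticalProfile) -> float:
    """PAI at the highest grid height (the cumulative profile's asymptote)."""
    return profile.pai_top


def pooled_profile(
    scans,
    geom: InstrumentGeometry = InstrumentGeometry(),
    height_grid: np.ndarray | None = None,
    *,
    coefficient: float = PAI_COEFFICIENT,
) -> VerticalProfile:
    """Invert several scans as one pooled acquisition.

    All shots are combined before the gap-fraction count, which is how to
    exceed the per-scan shot limit (e.g. effective N = 10,000 from two
    5,000-shot scans of the same canopy).  Scans must share the zenith
    angle; the first scan's metadata is carried through.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("at least one scan is required")
    if height_grid is None:
        height_grid = default_height_grid()
    bw = _check_uniform(height_grid)
    n_total = sum(s.n_shots for s in scans)
    pgap = np.zeros_like(np.asarray(height_grid, dtype=float))
    for s in scans:
        pgap += s.n_shots * gap_profile(s, geom, height_grid)
    pgap /= n_total
    pai, saturated = pai_profile(pgap, n_total, coefficient)
    return VerticalProfile(
        height=np.asarray(height_grid, dtype=float),
        pgap=pgap,
        pai=pai,
        pavd=pavd_profile(pai, bw),
        n_shots=n_total,
        saturated=saturated,
        instrument_id=scans[0].instrument_id,
        timestamp=scans[0].timestamp,
    )


# ---------------------------------------------------------------------------
# Profile CSV round trip (used by the command-line pipeline)

def write_profile_csv(profile: VerticalProfile, path, *, header_extra: dict | None = None):
    """Write ``height,pgap,pai,pavd`` rows with a ``#`` metadata header.

    ``pavd`` belongs to the bin starting at that row's height; the last
    edge row leaves it empty.
    """
    path = Path(path)
    lines = [
        "# format: vegnet-profile v1",
        f"# instrument_id: {profile.instrument_id}",
        f"# timestamp: {profile.timestamp.isoformat() if profile.timestamp else ''}",
        f"# n_shots: {profile.n_shots}",
        f"# saturated: {str(profile.saturated).lower()}",
    ]
    for k, v in (header_extra or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("height_m,pgap,pai,pavd")
    for i, h in enumerate(profile.height):
        pavd = f"{profile.pavd[i]:.9g}" if i < profile.pavd.size else ""
        lines.append(f"{h:.3f},{profile.pgap[i]:.9g},{profile.pai[i]:.9g},{pavd}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_profile_csv(path) -> VerticalProfile:
    path = Path(path)
    header: dict = {}
    rows: list[list[str]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            header[key.strip()] = value.strip()
            continue
        if line.startswith("height_m"):
            continue
        rows.append(line.split(","))
    if not rows:
        raise ValueError(f"{path.name}: profile file contains no rows")
    height = np.array([float(r[0]) for r in rows])
    pgap = np.array([float(r[1]) for r in rows])
    pai = np.array([float(r[2]) for r in rows])
    pavd = np.array([float(r[3]) for r in rows if len(r) > 3 and r[3] != ""])
    ts = header.get("timestamp") or None
    return VerticalProfile(
        height=height,
        pgap=pgap,
        pai=pai,
        pavd=pavd,
        n_shots=int(header.get("n_shots", 0) or 0),
        saturated=header.get("saturated", "false") == "true",
        instrument_id=header.get("instrument_id", ""),
        timestamp=datetime.fromisoformat(ts) if ts else None,
    )
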