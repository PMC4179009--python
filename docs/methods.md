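# Methods

## Scan geometry and the hinge angle

The instrument performs almucantar scans: a full 0–360° azimuth sweep at a
constant view zenith angle θ = 57.5°, acquiring up to 7360 range
measurements per scan (a typical configuration is 920, i.e. 2.6 shots per
degree). Assuming flat ground, a valid return at slant range *d* is
assigned the height *z* = cos θ · *d* above the instrument datum (z = 0 at
the scan head; an option adds the 1.5 m mounting height for above-ground
reporting). With a 60 m detection limit for live foliage, profiling is
useful to cos(57.5°)·60 ≈ 32 m.

Two footprint conventions are provided. The "2H" rule of thumb — the beam
exits a uniform canopy of height H at a horizontal distance of twice H —
gives π(2H)², which is 0.985 ha ≈ 1 ha at H = 28 m. The geometrically
exact radius is H·tan θ ≈ 1.57 H, giving ~0.61 ha at the same height. The
two disagree because tan 57.5° ≠ 2; both are reported, with `2h` as
the default so the 1 ha figure is reproducible. Slope correction is out of
scope.

## Leaf angle distribution and the 1.1 coefficient

The projection coefficient (G-function) follows Campbell's (1986)
ellipsoidal closed form,

    K(θ, x) = sqrt(x² + tan²θ) / (x + 1.702 (x + 1.12)^(−0.708)),
    G = K cos θ,

with x the ratio of horizontal to vertical semi-axes of the leaf-normal
ellipsoid (x = 1 spherical). The mean leaf-normal zenith angle is derived
from x via Campbell's (1990) approximation ᾱ ≈ 9.65(3 + x)^(−1.65) rad;
both parameterizations are exposed. All interface angles are degrees.

At θ = 57.5° the inversion coefficient 1/K varies by < 0.08 over
x ∈ [0.2, 5] (vs ≈ 1.5 at θ = 30°), and 1/K(57.5°, 1) = 1.0745, which
rounds to the fixed 1.1 used in the PAI inversion. The residual
1.1·K ≈ 1.02–1.07 multiplicative factor is an inherent property of using a
fixed coefficient; the recovery tests assert against both 1.1·K·L (exact
expectation) and L itself (within 10%).

## Gap probability, PAI and PAVD

For one scan of N shots, Pgap(h) = 1 − (#valid returns with zᵢ < h)/N,
with a strict `<` in the count and gap records (range 0.000) never counted
as returns below h — they contribute only to N. A literal counting mode in
which gap records (z = 0) count as "returns below h" exists behind a debug
flag for comparison; it is physically inconsistent (Pgap would fall where
there is no canopy) and is not used anywhere.

PAI(z) = −1.1 ln Pgap(z) on a uniform height grid (default 0–35 m at
0.5 m; the binning is configurable, as no canonical grid exists). If every
shot is intercepted below some height, Pgap = 0 there; it is clipped to
1/(2N) before the log and the profile is flagged `saturated` rather than
returning infinity. PAVD is the forward finite difference ΔPAI/Δz, which
makes the conservation identity Δz·ΣPAVD = PAI(top) exact to rounding
(asserted to 1e−9). Optional moving-average smoothing of PAVD is off by
default because it breaks that identity at the profile edges. Since lidar
does not separate leaf from wood, outputs are labelled PAI/PAVD, never
LAI. Shots that intercept but return no reading (moving or distant
targets) appear as gaps and slightly inflate Pgap; this bias source is
inherited from the instrument convention and not corrected.

## Scan format and quantization

Scans are stored as human-readable delimited text: a `#`-prefixed
`key: value` header (instrument id, ISO-8601 timestamp with timezone
offset, zenith, truncation flag) and `index,azimuth_deg,range_m` rows.
Ranges are quantized half-up to mm below 10 m and cm at or above 10 m;
azimuths to the 0.1° encoder precision; gaps are `0.000`. Quantization is
idempotent and the write→read round trip is exact (property-tested). The
real instrument's on-card byte layout is unpublished; this format is a
stand-in with the same information content and similar size (~25 KB for
920 shots).

## Quality control

Rain on the exposed scan-head prism returns ranges of ≈270 mm (the
prism-face distance). The firmware terminates a scan after 50 consecutive
readings below 300 mm; `detect_rain` flags truncated scans and also
re-checks complete scans for a ≥50-run post hoc. A "reading below 300 mm"
is a non-gap record in (0, 0.3) m — gaps break a run, since droplets
produce short *hits*, not gaps — with `count_gaps=True` available as a
more conservative variant.

Wind-degraded scans are screened by the sum of valid within-scan ranges:
a scan is excluded iff rain-flagged or its sum is *strictly* below a
per-instrument threshold (a sum exactly at the threshold is retained).
Only whole scans are excluded, because dropping part of a sweep would
re-weight the surviving azimuths. The deployment presets 8000/9000/8100 m
(instruments VN5/VN6/VN7) are shipped; `summed_range_histogram` supports
manual threshold choice from the bimodal mixture and `suggest_threshold`
automates it with Otsu's between-class-variance split (deterministic,
label-free). Dynamic threshold re-estimation under distribution shift is
out of scope.

## Simulator

The simulator draws each shot's first-interception optical depth
τ ~ Exp(1) and inverts the piecewise-linear cumulative K·L(z) exactly
(inverse-CDF sampling; no vertical discretization bias). A shot survives
to the canopy top — or intercepts beyond the 60 m detection limit — as a
gap. Azimuths form a deterministic uniform grid, matching stepper-motor
stepping. Wind is modelled i.i.d. per shot: a true hit becomes a gap with
probability `wind_gap_prob`, a gap becomes a spurious near return with
probability `wind_hit_prob` (range uniform over 0.5–10 m by default);
real wind has temporal and spatial correlation that this deliberately
ignores. Rain injection replaces ranges from a random onset with draws
uniform over 0.260–0.290 m — an invented distribution around the ~270 mm
droplet signature — and truncates the scan exactly 50 shots after onset.

The campaign generator emulates an 18-month deployment of three
co-located instruments in open eucalypt-type forest: a fixed two-peak
vertical shape (density maxima near 6 m and 14 m, canopy top 25 m)
rescaled daily; per-instrument long-term means 1.56/1.36/1.32; a
sinusoidal seasonal cycle of ±10% relative amplitude peaking at the
austral summer solstice; one scan of 920 shots per instrument per night at
22:00 local; rain on 25% of nights and heavy wind (gap probability 0.5)
on 23%, so on average ~48% of scans fail QC. Clean scans of this forest
sum to ~10.3–10.9 km of range versus ~5.3 km under heavy wind, so the
shipped thresholds separate the two modes cleanly. What the simulator does
*not* emulate: radiometry and reflectance, beam divergence and partial
hits, multi-return waveforms, temporally correlated weather, topography,
and real phenology beyond a smooth sinusoid — so passing recovery tests
demonstrates correctness of the inversion and QC logic under the model's
own assumptions, not instrument accuracy in real forests.

## Time series

Monthly aggregation takes the arithmetic mean of the daily PAI(z)
profiles (and top-of-canopy PAI) within each calendar month; shot-weighted
pooling of gap fractions is available as an option (`method="pooled"`),
and summary statistics are computed over monthly aggregates by default.
Months with no retained scans are reported as missing, not interpolated.
The long-term trend is an interpolating cubic spline through the monthly
means placed at month midpoints, sampled ~daily; by default it is fitted
piecewise over contiguous month runs and not drawn across gaps
(`bridge_gaps=True` overrides). Fewer than four monthly points is an
error. Summary statistics are mean, max, min, range = max − min and
range as an integer percentage of the mean; note that printed-table
arithmetic can disagree with recomputation by one unit in the last digit
when the inputs are themselves rounded (a 0.13-vs-0.12 rounding artifact
of this kind exists in the historical deployment's summary and is
documented rather than asserted).

## Numerical and testing choices

Problem sizes were chosen so the full suite runs in seconds: recovery
tests use N = 10,000 shots (two pooled 5,000-shot scans, respecting the
7360-per-scan cap), the brute-force gap-profile oracle runs 200 random
scans of ≤50 shots, and the end-to-end check simulates the full 18-month,
three-instrument campaign (~1.6 k scans) and asserts Pearson r > 0.9
against the injected monthly truth and recovery of the injected relative
seasonal range within 5 percentage points. Monte-Carlo assertions use
3–4 binomial standard errors with fixed seeds; hypothesis property tests
run derandomized. All public simulation entry points require an explicit
seed or Generator, and equal seeds yield byte-identical scan files.
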