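# vegnet

Canopy-structure analysis for fixed-position, hinge-angle monitoring lidar
(IML / "VEGNET"-style instruments), plus a seeded scan simulator for
validating the whole chain against known ground truth.

## The problem and the method

Automated in-situ lidar instruments monitor forest leaf area by sweeping a
laser rangefinder through a full azimuth circle at a constant view zenith
angle of 57.5° — the **hinge angle**. Each nightly scan yields N shots;
every shot either returns a slant range *d* to the first intercepted plant
element or a gap code (0.000 m). Assuming flat ground, a return maps to
height *z* = cos(57.5°)·*d* above the instrument. The canopy **gap
probability** to height *h* is

    Pgap(h) = 1 − (# valid returns with zᵢ < h) / N

and inverts, via Beer–Lambert attenuation, to a cumulative **plant area
index** profile and its vertical derivative, the **plant area volume
density**:

    PAI(z)  = −1.1 · ln Pgap(z)
    PAVD(z) = dPAI/dz        [m² m⁻³]

The factor 1.1 is the hinge-angle magic: under Campbell's ellipsoidal leaf
angle distribution the inversion coefficient 1/K(57.5°, x) stays within a
few percent of 1.1 for any leaf-orientation parameter *x*, so no knowledge
of the leaf angle distribution is needed. Because lidar returns do not
separate foliage from wood, the outputs are *plant* (not leaf) area
quantities.

Around this core the package provides:

- **`vegnet.lad`** — Campbell ellipsoidal G-function, extinction
  coefficient K(θ, x), and the hinge inversion coefficient;
- **`vegnet.geometry`** — range-to-height conversion and the scan
  footprint (≈1 ha for a 28 m canopy);
- **`vegnet.scan_io`** — the delimited-text scan format with the
  instrument's gap and mm/cm precision conventions;
- **`vegnet.qc`** — weather screening: rain scans (runs of ≥50 readings
  below 300 mm, the droplet-on-prism signature) and wind-degraded scans
  (summed within-scan range below a per-instrument threshold chosen from
  the bimodal summed-range histogram); whole scans only, to avoid
  azimuthal bias;
- **`vegnet.profiles`** — the Pgap → PAI → PAVD inversion;
- **`vegnet.timeseries`** — monthly aggregation, long-term summary
  statistics (mean / max / min / range / range-%), cubic-spline trends;
- **`vegnet.simulate`** — synthetic scans drawn exactly from
  S(z) = exp(−K·L(z)) for a layered canopy with known L(z), including the
  60 m live-foliage detection limit, range quantization, rain termination
  and per-shot wind perturbation, and an 18-month multi-instrument
  campaign generator.

## Worked example

Simulate an 18-month, three-instrument campaign (nightly scans, seasonal
PAI cycle of ±10% about each instrument's mean, ~48% of nights rain- or
wind-contaminated), screen it, and recover the monthly PAI statistics:

```python
import numpy as np
from vegnet import (CampaignConfig, THRESHOLD_PRESETS, apply_threshold,
                    compute_profile, monthly_aggregate, pai_summary_stats,
                    simulate_campaign)

rng = np.random.default_rng(42)
campaign = simulate_campaign(CampaignConfig(), rng=rng)
print(f"simulated {len(campaign.scans)} nightly scans over 18 months")

for inst, _ in CampaignConfig().instrument_means:
    scans = [s for s in campaign.scans if s.instrument_id == inst]
    part = apply_threshold(scans, THRESHOLD_PRESETS[inst])
    profiles = [compute_profile(s) for s in part.retained]
    series = monthly_aggregate(profiles, instrument_id=inst)
    stats = pai_summary_stats(series.monthly_pai)
    print(f"{inst}: retained {len(part.retained)}/{len(scans)} scans | "
          f"mean PAI {stats['mean']:.2f}, range {stats['range']:.2f} "
          f"({stats['range_percent']}% of mean)")
```

Output:

```
simulated 1647 nightly scans over 18 months
VN5: retained 294/549 scans | mean PAI 1.62, range 0.30 (18% of mean)
VN6: retained 271/549 scans | mean PAI 1.41, range 0.30 (21% of mean)
VN7: retained 281/549 scans | mean PAI 1.37, range 0.28 (20% of mean)
```

About half the scans are rejected by QC (rain-truncated or low summed
range), the recovered means sit a few percent above the true instrument
means of 1.56/1.36/1.32 — the method's inherent 1.1·K ≈ 1.02 multiplicative
factor — and the recovered relative range (~20% of the mean) matches the
injected ±10% seasonal cycle.

The same pipeline is available from a shell:

```sh
vegnet simulate --out run --seed 42
vegnet filter   --scans run/scans --out run/qc
vegnet profile  --scans run/scans --retained-list run/qc/retained.txt --out run/profiles
vegnet trend    --profiles run/profiles --out run/trend --plot run/trend.png
vegnet lad-curves --out curves.csv
```

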