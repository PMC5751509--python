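# croplidar

Phenotyping of experimental crop parcels from UAV-mounted LiDAR: the
package turns posed LiDAR scans of a nitrogen trial into per-parcel
canopy height and volume estimates and a logistic dose–response fit, and
ships a synthetic-field simulator so the whole chain is testable without
flight recordings.

It is written for agronomists and robotics researchers working with
small-plot trials: fields divided into parcels of a few metres, each
under a different nutrient strategy, scanned from a UAV flying low
(≈6 m) over a canopy too dense for the sensor to see the soil between
plants.

## What it computes

**Mapping.** RTK-GNSS fixes (WGS84) are projected to UTM (Karney/Krüger
series, sub-mm accuracy); a compass heading ψ referenced to true north is
converted to a grid heading with the meridian convergence

γ(φ, λ) = arctan(tan(λ − λ₀) · sin φ),

where λ₀ is the zone's central meridian. Sensor-frame scans are mapped to
the global frame by p_global = R_pose (R_ext p + t_ext) + t_pose, with
poses interpolated (linear position, slerp orientation) from the
timestamped stream.

**Per-parcel canopy model.** For each surveyed parcel polygon:
point-in-polygon extraction → statistical outlier removal (drop point *i*
iff its mean distance to its k nearest neighbours exceeds mean + α·std of
that statistic) → voxelisation at (0.04, 0.04, 0.001) m → per-column
max-z projection into a pixel grid → iterative hole interpolation (a
missing pixel with ≥ 6 of 8 valued neighbours takes their mean, repeated
to fixpoint) → soil plane h(x, y) = a₀x + a₁y + a₂ fitted by least
squares on the uncropped border strips and subtracted → region growing
from the tallest pixel (join while within 0.1 m of the running region
mean) → mean height and volume (Σ pixel heights × cell area).

**Dose–response.** Per-parcel mean heights h and cumulative applied
nitrogen N (kg N/ha) are fitted with the saturating logistic

h(N) = c₁ / (1 + e^(−c₀·N)) + h_min

by nonlinear least squares (multi-start over c₀, optional bootstrap
standard errors), statsmodels-style: `NitrogenResponse(...).fit()`
returns a results object with `params`, `bse`, `summary()`, `predict()`
and the closed-form saturation dose ln((1+f)/(1−f))/c₀.

**Simulator.** `build_field_layout()` reproduces the trial design
(4 blocks × 21 strategies = 84 parcels of 2.28 × 8 m, 0.12 m rows, tire
tracks, tilted soil plane); `sample_field_cloud()` scatters canopy and
soil returns at a configurable density (default 500 pts/m²) with bounded
range noise (±0.03 m), row texture and optional gross outliers;
`simulate_flight()` emits sensor-frame scans plus a 20 Hz pose stream
along lawnmower paths (full-field "A", or dense first-third "B").

## Worked example

```python
import pandas as pd
from croplidar import (build_field_layout, SimConfig, sample_field_cloud,
                       ParcelInput, PipelineConfig, run_pipeline)

layout = build_field_layout()          # 4 blocks x 21 N strategies = 84 parcels
cloud = sample_field_cloud(layout, SimConfig(seed=1)).cloud
parcels = [ParcelInput(p.gross, p.net) for p in layout.parcels]
treatments = pd.DataFrame({
    "parcel_id": [p.parcel_id for p in layout.parcels],
    "n_applied_kg_ha": [p.n_applied for p in layout.parcels],
})
result = run_pipeline(cloud, parcels, treatments,
                      PipelineConfig(fit_bootstrap=200, seed=1))
print(result.summary_frame.head().to_string())
print(result.n_response.summary())
```

prints

```
  parcel_id  mean_height_m  volume_m3  n_pixels  interp_fraction
0     b1p01       0.480476   4.541074      5907         0.288302
1     b1p02       0.494625   4.597240      5809         0.282493
2     b1p03       0.510207   4.838393      5927         0.283617
3     b1p04       0.522251   4.754572      5690         0.281195
4     b1p05       0.533391   4.949866      5800         0.279138

Logistic Nitrogen Response Results
==========================================================
No. observations:                   84
Residual sum of squares:    2.44894e-05
Residual std (m):            0.0005499
----------------------------------------------------------
param         estimate   boot. std err
c0            0.020083       8.589e-05
c1            0.199854       0.0004401
hmin          0.380437       0.0004369
----------------------------------------------------------
Height at N=0 (m):              0.4804
Asymptotic height (m):          0.5803
95% saturation dose (kgN/ha):    182.4
```

Each row is one parcel: its mean canopy height above the fitted soil
plane, the integrated crop volume over the segmented region, the number
of region pixels and the fraction of them whose value was interpolated
rather than measured (a quality flag). The generating truth here was
(c₀, c₁, h_min) = (0.02, 0.20, 0.38); the fit recovers all three well
within a bootstrap standard error, and the saturation dose (~182 kg N/ha
at the 95% level) says extra nitrogen beyond that buys almost no further
height — consistent with a canopy whose height response flattens near
200 kg N/ha.

A CLI mirrors the stages: `croplidar simulate | map | extract | analyze
| fit-n` (see `croplidar --help`). Point clouds travel as ASCII PLY/PCD,
polygons as GeoJSON, rasters as ESRI ASCII grid, tables as CSV.

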