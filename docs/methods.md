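# Methods

This note documents the models and numerical choices behind the package:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and the known limitations.

## Georeferencing

Positions arrive as WGS84 latitude/longitude and are projected to UTM
with the Karney/Krüger series, sixth order in the third flattening n.
Within a UTM zone the series is accurate to well below a millimetre,
which the tests verify against an independent classic series
implementation (agreement < 0.01 m over a 55°N grid spanning the zone).
Latitudes beyond ±84° are rejected (UTM's domain).

A compass heading is referenced to true north; grid north differs by the
meridian convergence γ = arctan(tan(λ−λ₀)·sinφ). East of the central
meridian in the northern hemisphere grid north lies east of true north
(γ > 0), so grid heading = true heading − γ, wrapped to [0, 2π). The
printed form of this correction in the source material is typographically
ambiguous between a product and a two-argument arctangent; the product
reading is used because the two-argument reading divides by sin φ and
yields ~2.9° at the test site where the true convergence is ~1.96° —
the tests pin the value against a finite-difference bearing of the
projected meridian, which is sign- and magnitude-definitive.

Pose streams are interpolated linearly in position and spherically
(slerp) in orientation; querying a sample's exact timestamp returns that
sample, and extrapolation outside the stream span is an error. Scan
points map to the global frame by p = R_pose (R_ext p_s + t_ext) +
t_pose. Mapped clouds use anchor-relative UTM offsets so coordinates stay
small enough for single-precision consumers; the anchor travels in
metadata.

## Per-parcel canopy height model

Processing order per parcel: extract → outlier filter → voxelise →
max-z project → interpolate → ground fit → subtract → region grow →
metrics.

**Extraction.** Boundary-inclusive point-in-polygon against the surveyed
corner rings; corners are logged to bracket the crop, so edge plants
belong to the parcel. Rings are validated (≥3 vertices, simple) and
normalised counter-clockwise.

**Outlier filter.** Mis-registered returns from fast UAV rotations are
sparse and far from the canopy. For each point the mean distance d_i to
its k nearest neighbours is computed (k = 50, the conventional default
of the classic implementation); points with d_i > mean(d) + α·std(d)
(α = 1, population std) are dropped. The filter runs per parcel, after
extraction, and is verified exactly against an O(n²) oracle.

**Voxelisation.** Half-open floor binning at (0.04, 0.04, 0.001) m. The
4 cm plan footprint matches the scale at which plant samples are cut;
the 1 mm vertical step preserves the ranger's resolution so volume sums
are not quantised visibly (≤0.5 mm bias per pixel). The default grid
origin is the cloud minimum floored to the resolution lattice, making
indices reproducible.

**Max-z projection.** A pixel takes the centre z of the highest occupied
voxel in its column — the maximum keeps the full length of each
detectable plant; empty columns are missing.

**Hole interpolation.** Iteratively, every missing pixel with at least
6 of 8 valued neighbours receives the mean of those neighbours, until no
pixel qualifies. Decisions and means are taken on the grid as it stood at
the start of each iteration, so the result is independent of scan order
(the sequential and synchronous rules have the same final valued set; the
synchronous one also has order-independent values). Measured pixels are
never altered, and the filled mask is carried forward so summaries can
report an interpolated fraction per parcel as a quality flag.

**Ground plane.** The canopy is too dense to see soil between plants, so
the soil is modelled as a plane z = a₀x + a₁y + a₂ (the seedbed is
machine-prepared, hence locally planar) fitted by ordinary least squares
over valued pixel centres in the gross∖net ring — the 1 m end strips
where bare soil is exposed. Support must contain ≥3 non-collinear pixels
(rank check), otherwise a degenerate-support error is raised. On exact
planar support recovery is at machine precision (~1e−12); pixel support
is used rather than raw points so the fit sees the same surface the
heights are read from.

**Region growing.** Seeded at the global maximum pixel (smallest
row-major index on ties). Valued 8-neighbours of the region form a
frontier processed highest-first (row-major tie-break); a candidate joins
iff |h − region mean| ≤ 0.1 m, with the mean updated incrementally. A
candidate that fails is discarded permanently rather than ending growth:
the region mean drifts as the region grows, and terminating on the first
failure would make the result depend on one noisy pixel. The "gradient"
criterion is implemented as absolute difference from the running mean;
0.1 m cleanly separates a 0.35–0.6 m canopy from border soil. The rule is
deterministic and is verified against an independent set-based
simulation.

**Metrics.** Mean height over region pixels; volume = Σ max(h, 0) × cell
area (0.0016 m²). Negative post-subtraction heights (support noise, soil
pixels below the fitted plane) are kept in the grid and the mean for
diagnostics but clamped to zero in the volume integral.

## Nitrogen dose–response

h(N) = c₁/(1 + e^(−c₀N)) + h_min, fitted by trust-region nonlinear least
squares with bounds c₁, h_min ≥ 0. Logistic fits are
initialisation-sensitive, so the fit multi-starts c₀ over
{0.005, 0.01, 0.05, 0.1} with h_min at the minimum observed height and
c₁ at the observed range, keeping the lowest-RSS solution; tests confirm
the noiseless optimum against a coarse grid search and first-order
optimality on noisy data. Identifiability requires ≥3 distinct doses;
constant heights trigger a flat-fit warning (c₀ unidentified). Bootstrap
(parcel resampling, seeded) provides standard errors. The saturation
dose — where the rising half of the curve has covered a fraction f of
its remaining range — has the closed form N = ln((1+f)/(1−f))/c₀.

Note the asymptote of the formula is h_min + c₁ (and the value at N = 0
is h_min + c₁/2); prose descriptions elsewhere calling c₁ − h_min the
maximum contradict the formula, and the formula is authoritative here.

## Synthetic data: what it emulates, and what it does not

Defaults reproduce the trial conditions: 4 blocks × 21 cumulative N
strategies (0–300 kg N/ha) = 84 parcels of 2.28 × 8 m with 1 m trimmed
from each end for the net parcel; 0.12 m row spacing; 0.5 m tire tracks;
a tilted planar soil (default gradients 0.01 and −0.005); canopy heights
from the logistic truth (0.02, 0.20 m, 0.38 m), spanning 0.48–0.58 m over
the applied doses; 500 points/m² (the mapped field carried roughly
400–700); range noise uniform on ±0.03 m (the sensor's typical range
accuracy read as bounds, not a standard deviation); sinusoidal row
texture with 0.12 m period and 0.02 m amplitude (a free choice — real
within-parcel height variance is not quantified anywhere — picked to give
plausible texture without modelling single plants). Soil returns appear
only in tracks and end strips, because the sensor cannot see the ground
between plants; canopy is sampled over the net polygon, so a parcel's
expected count is density × gross area. Outliers, when enabled, are
placed at least their magnitude above the highest inlier, guaranteeing
the separation the filter targets.

Flights are simulated without beam physics: surface points are assigned
to the nearest lawnmower pass within a 1.4 m half-swath and binned along
track into 10 Hz scans, with 20 Hz poses and yaw along travel. Path "A"
flies one pass per parcel column (full coverage); path "B" flies 0.5 m
spaced passes over the first third of the columns, covering ⌈n/3⌉
parcels. Mapping scans back through their poses reproduces the observed
points to float round-off, which is what the round-trip tests assert.

Not emulated: occlusion and beam divergence, multiple returns, rotor
downdraft motion, GNSS/IMU drift, and the azimuthal clustering of real
scan lines. Passing tests therefore demonstrate the correctness of the
processing chain and its statistical behaviour under the stated noise
model — not sensor-level fidelity.

## Problem sizes and determinism

Tests and the acceptance script run the full 84-parcel trial at
500 pts/m² (~0.97 M points), a choice that keeps a complete run in tens
of seconds while leaving every per-parcel sample size (~9 × 10³ points,
~6 × 10³ region pixels) large enough for the statistical assertions.
All stochastic stages consume a single seed: per-parcel substreams are
derived from (seed, parcel index), so clouds are reproducible point for
point, parcels can be regenerated independently, and two runs with the
same seed produce byte-identical summary files.

## Known limitations

- **Partial pixel coverage bounds the volume estimate.** At 500 pts/m²
  a 0.04 m column receives a point with probability 1 − e^(−0.8) ≈ 55%,
  and the 6-of-8 interpolation closure raises coverage to only ≈78%, so
  the summed-pixel volume runs ≈20% below height × net-parcel area even
  though the mean height is unbiased (errors ~1 mm). Real scans cluster
  returns along scan lines and reach much higher column coverage; with
  synthetic densities ≥3000 pts/m² the closure completes and the volume
  matches height × area within a few percent (tested). Volume figures at
  low uniform densities should be read as density-limited lower bounds,
  or be corrected by the covered area (n_pixels × 0.0016 m²).
- The soil model is a single plane per parcel; terraced or rutted ground
  violates it (the rank check only catches degenerate support, not
  curvature).
- Row texture biases the max-z projection upward by up to ~half its
  amplitude at high point densities; at the default amplitude (0.02 m)
  and density this bias is within the stated 0.05 m recovery tolerance.
- Heading correction assumes one merged orientation stream; IMU fusion,
  RTK correction processing and time-sync hardware are out of scope.
- Adjacent high doses differ in true height by ~10⁻⁴ m, far below the
  per-parcel estimation noise (~10⁻³ m), so monotonicity of the response
  is a property of the fitted curve, not of raw per-parcel estimates.
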