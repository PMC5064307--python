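# Methods

## Statistical model

Partition statistics are binomial–Poisson: each of the n accepted droplets
independently contains a Poisson number of copies of each target, with mean
λ = (copies per reaction / 20 µL) × 0.00085 µL. A droplet is positive for a
target when it holds ≥ 1 copy, so the positive fraction has expectation
p = 1 − e^(−λ) and the point estimate is λ̂ = −ln(1 − k/n). Concentrations
follow from the droplet volume (0.85 nL default) and are reported both per
µL and per 20 µL reaction, the unit used in validation tables. Only
*accepted* droplets enter the estimate; no dead-volume correction is applied
(droplets generated but not read are outside the model).

Multiple occupancy is allowed and handled by the log link; amplitude depends
only on presence/absence per target, which matches end-point hydrolysis-probe
chemistry where the signal saturates rather than scaling with copy number.

## Confidence intervals

The interval is a Wilson score interval on p̂ at the configured level
(default 95%), with each bound transformed through −ln(1 − p) × 20/0.00085.
Wilson was chosen because it is well-behaved at extreme counts — 0 positives
gives a lower bound of exactly 0, a saturated well (k = n) an infinite upper
bound — and because the Poisson link is monotone, so transforming the bounds
preserves coverage. A normal-approximation interval is available as
`QuantConfig(ci_method="normal")`. Saturated wells are flagged
(`saturated=True`, infinite λ̂ and copies) rather than raised, and should be
excluded from downstream statistics.

Simulated coverage (500 wells, λ ∈ [0.01, 1], 15 000 droplets) sits at
~95%, checked in the test suite against the [0.92, 0.98] band.

## Separation-line placement

Each channel axis needs 3 lines (two targets), 1 line (one target) or none.
Automatic placement:

1. **Density valleys.** A Gaussian-kernel density estimate of the axis
   amplitudes — Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5),
   evaluated via a 512-bin histogram smoothed with that kernel — is searched
   for local maxima. If exactly the expected number of modes appears, each
   line sits at the density minimum between consecutive modes (the "middle
   between the clusters").
2. **1-D k-means fallback.** Real multiplex wells are heavily unbalanced
   (often > 95% negative droplets), which shrinks the Silverman bandwidth
   below the histogram resolution and fragments the modes, so a
   deterministic Lloyd's k-means with k = expected bands takes over; lines
   go at midpoints between consecutive sorted centers. Initial centers are
   the k inner quantiles; when those collapse onto the negative cluster
   (centers closer than span/(4k)) the init switches to centers evenly
   spread over the amplitude span — still fully deterministic. Empty
   clusters keep their stale center rather than being relocated, which is
   why this is hand-rolled instead of delegated to a library k-means.
3. **Empty double-positive band.** When both same-channel targets are
   dilute, the expectation of co-occupied droplets (n·λ₁·λ₂ at small λ) can
   be below 1 and the top band is legitimately empty; k = 4 then wants to
   split a real cluster. If the 4-cluster solution fails, a 3-cluster
   solution is tried and, if valid, the top line is placed just above the
   data maximum, leaving the double-positive band empty.
4. **Separation guard.** Any proposed solution is rejected unless adjacent
   occupied clusters are separated by at least `min_separation` (default 3)
   times the sum of their standard deviations, and the total amplitude
   spread exceeds a resolution floor (`min_spread`, default 1 unit). On
   failure an `InsufficientClusterStructureError` directs the user to manual
   lines — deliberately so for an all-negative well or a well with an absent
   target, where the band structure is not identifiable from one well's
   data alone (the original workflow sets thresholds from a positive
   control; `theoretical_grid` plays that role for simulated data).

Tie-break: an amplitude exactly on a line belongs to the upper band. Lines
sit in low-density valleys, so the choice is immaterial in practice but
makes classification deterministic. `set_line` moves single lines under a
strict-ascending constraint and tracks provenance (automatic/manual/mixed).
No spectral cross-talk compensation is applied between channels.

## Performance rules

* **RSD**: 100 × sd(n−1)/mean, per dilution level.
* **aLOQ**: lowest mean measured copy number among levels with RSD ≤ 25%
  (threshold configurable). Optional outlier removal first: values outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear interpolation at
  position (n−1)·q (numpy's default). The convention is fixed here because
  the 1.5×IQR rule is not testable without one.
* **aLOD**: a replicate is positive with ≥ 3 positive droplets; a level
  detects when at most `max_negative_replicates` (default 1) replicates are
  negative. The default generalises the 14-of-15-replicates design to any
  replicate count rather than hard-coding 14. "Lowest" for both limits is
  ordered by mean measured copies, the scale on which limits are reported.
  aLOD > aLOQ on noisy input is reported as a flag, not an error.
* **Bias**: 100 × (measured − reference)/reference, signed; not
  antisymmetric under swapping the roles (the denominator changes).
* **z-scores**: (measured − assigned)/σ, pass iff |Z| < 2; the strict
  boundary is evaluated to a relative 1e−9 so a z-score equal to 2 up to
  floating-point representation fails as intended.
* **Linearity**: OLS of measured on assigned copies on the linear scale
  (matching how dynamic-range results are plotted), log10 option available;
  R² is the squared Pearson correlation.
* **Unit conversion**: copy% = mass% × factor, mass% = copy% / factor;
  factors 0.5 (consensus), 0.4 (male GM parent), 0.6 (female), or custom.
  Both directions are exact inverses.
* **False positives**: for a target known absent, the rate is its positive
  droplets as a percentage of the co-channel high-amplitude target's
  positives. Labelling flags mark GM content ≥ 0.9% and ≥ 0.1%; they carry
  no further regulatory logic.

## Synthetic data generator

`simulate_well` emulates the measurement process the analysis assumes:
Poisson occupancy per target; channel amplitude = baseline + increments of
the same-channel targets present + Gaussian noise; increments add, putting
the double-positive cluster above both single clusters. A `rain_fraction`
subset of positive droplets instead draws its amplitude uniformly between
the baseline and its full cluster mean on each positive channel,
reproducing the intermediate-amplitude artifact by which a high-amplitude
target fakes positives for its low-amplitude partner. The uniform law is a
stand-in, not a physical claim, and is isolated so it can be replaced.

Default parameters: 15 000 droplets, 0.85 nL droplet volume, 20 µL
reaction; per channel baseline 800 ± 60, low/high increments 2200/4800,
cluster sd 150 (arbitrary instrument-like units — real amplitude scales
depend on probe batch and reader calibration, which is why none is
published to copy). Defaults give inter-cluster gaps of ≈ 7–18 combined
standard deviations, i.e. the clean separation an optimised assay shows.

Not emulated: droplet-volume variability, PCR inhibition or efficiency
effects, copy-number-dependent amplitude, concentration-dependent rain
intensity, and cross-channel spectral bleed. Passing tests therefore show
the analysis is correct *under the stated measurement model*, not that any
particular instrument or chemistry meets that model.

`GroundTruth` records per-droplet copies, true bands and rain labels.
Recovery checks compare estimates against the *realized* occupancy of the
simulated well (copies actually placed in droplets), not the generator's
nominal mean: the estimator measures the well's content, and at 500
copies/reaction with 15 000 droplets the binomial sampling noise of the
nominal mean alone is ~5.6% relative sd, which would dominate such checks.
Interval-coverage checks, by contrast, use the nominal concentration, which
is exactly what the Wilson interval's binomial sampling model covers.

`simulate_dilution_series` quantifies each simulated well through the
standard pipeline using the config-derived `theoretical_grid` (line
positions midway between true cluster means) — the simulated counterpart of
thresholds taken from a positive control — because automatic placement is
intentionally unavailable at levels where positive clusters vanish.
Per-well seeds are spawned deterministically from the master seed.

## Validation problem sizes

The bundled checks use 100 wells × 15 000 droplets for 4-plex recovery
(all targets at 500 copies/reaction), 500 wells for interval coverage
(λ log-uniform in [0.01, 1]), a 6-level × 3-replicate series spanning
10–10 000 copies for linearity, and single wells for the rain scenarios
(high target 2000 copies/reaction, rain fraction 0.02). These sizes give
stable rates while keeping the whole suite in seconds.

## Known limitations

* Automatic line placement assumes one well contains enough structure to
  reveal all bands; wells with absent targets need manual lines or a
  positive-control grid. This is inherent to amplitude coding, not a
  software restriction.
* The 16-cluster model assumes amplitude additivity and no cross-talk; probe
  chemistries that quench or compete would violate it.
* Confidence intervals reflect droplet sampling only, not pipetting or
  extraction variance between replicates; between-replicate spread is the
  performance module's domain.
* Saturated targets (all droplets positive) carry no finite upper bound;
  quantification requires dilution into the dynamic range.
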