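# Methods

## The trajectory model and its assumptions

A pixel history is modelled as a continuous piecewise-linear function of
time with vertices on observation dates. This presumes that the index
signal is dominated by abrupt-to-protracted monotone transitions between
quasi-stable states (forest, inundated sediment, built-up land) and that
sub-annual phenology can be treated as noise — appropriate for evergreen
tropical forest, inappropriate for strongly seasonal canopies.

Fitting is percentile-based rather than least-squares. Every breakpoint
value is the `prctile`-th percentile of the values in a local window, so
the fitted polyline tracks a chosen quantile envelope of the point cloud.
With symmetric noise the median (prctile 50) is the natural choice; with
cloud-contaminated optical data — where residual haze, shadow and cloud
only *depress* NDVI — a high percentile (90) tracks the clean upper
envelope and is insensitive to contamination rates far beyond what outlier
tests handle.

Errors are *orthogonal* distances from points to the fitted polyline,
measured in a plane where the date axis is in years divided by `xy_scale`
(default 1, i.e. one year of time is commensurate with one NDVI unit) and
the value axis is in index units. For near-horizontal segments this is
essentially the vertical residual; for steep disturbance segments it also
penalises time offsets.

Model selection uses `BIC = penalty · segs · ln N − 2 · logL` with `logL`
the log-likelihood of a lognormal distribution fitted (by maximum
likelihood, population variance) to the distances. The lognormal reflects
the strictly positive, right-skewed distance distribution produced by
envelope fitting. Greedy backward elimination accepts only removals that
strictly decrease the BIC, so the final BIC is never above the build
stage's; on instances small enough to enumerate, the greedy result
coincides with the exhaustive interior-subset optimum on clean inputs and
never reports a BIC below it (it is an upper bound by construction).

## Parameters

| name | default | study set | units | role |
|---|---|---|---|---|
| `prctile` | 50 | 90 | percentile | quantile envelope tracked by knot values |
| `bail_thresh` | 1 | 2 | ratio | adopt the single-segment fit when mean error / noise ≤ this |
| `max_segment` | 10 | 10 | segments | build-stage cap (breakpoints = segments + 1) |
| `filt_dist` | 3 | 3 | calendar slots | radius of the error median filter and knot value window |
| `penalty` | 1 | 4 | multiplier | BIC complexity weight; larger → simpler models |
| `xy_scale` | 1 | 1 | years per index unit | orthogonal-distance geometry |

The "study set" is the configuration used for the disturbance-mapping
application and the accuracy assessment; it prioritises correct segment
counts and robustness over per-date precision.

Window semantics: `filt_dist` windows are measured in positions along the
full acquisition calendar, not in valid-observation indices. A ±3-slot
window spans ±154 days regardless of how cloudy the pixel is; an
index-space window on a 55 %-cloudy pixel would silently stretch to ±340
days and drag knot values across trajectory corners. The two endpoint
anchor knots of the initial fit are the exception: they use the first/last
`filt_dist + 1` valid observations, because a calendar edge window can
degenerate to a single (possibly contaminated) point and fabricate a
terminal event. `filt_dist = 0` disables both filters; this is the correct
setting for noiseless data and the one under which exact recovery is
provable (below).

Classification thresholds (`Thresholds`): disturbance = crossing from
above 0.70 to below 0.40 NDVI at more than 0.10/yr, evaluated on fitted
breakpoints; consecutive declining segments merge into one event to absorb
gap-induced splits. Two tolerances handle the fact that fitted plateaus
are never exactly level: a segment only counts as declining if it loses
more than `flat_slope` = 0.01 NDVI/yr, and the event nadir is the earliest
run breakpoint within `nadir_tol` = 0.05 of the run minimum (the measured
scatter of fitted bottom-plateau breakpoints; a strict minimum is biased
late). Both defaults are far below the 0.3 NDVI magnitude floor implied by
the 0.70/0.40 crossing.

## Exact-recovery property

On a noiseless input lying exactly on a k-segment polyline whose vertices
are observation dates, the fitter at `prctile=50, filt_dist=0,
max_segment ≥ k` reproduces the polyline to machine precision: the maximum
orthogonal deviation of a polyline from a chord is attained at a true
vertex, every inserted knot takes its exact value, and the subtract stage
removes collinear extras (pure penalty gain) while keeping true vertices
(removing one floors the likelihood). With `filt_dist ≥ 1` this exactness
is lost by design: the error median filter suppresses isolated corner
residuals once breakpoints sit within the kernel of an uncaptured vertex,
and clipped edge windows displace knots on sloped terminal segments.
Filtering is a robustness device for noisy data, not part of the noiseless
contract, and the exactness tests therefore run unfiltered.

## The synthetic validation protocol

`simulate` reconstructs the accuracy-assessment machinery:

- **Trajectory library** — 100 idealized piecewise-linear histories over
  1987–2015 in five strata: stable forest (1 segment, level ≈ 0.75–0.87,
  drift ≤ 0.03), protracted urbanization decline (2 segments, < 0.10/yr),
  single inundation with no recovery (3 segments; pre-level 0.75–0.85,
  drop of 0.5–2.5 yr to 0.08–0.20, vertices in 1990–2006), inundation with
  partial regrowth (4), and full regrowth (5); composition 39/11/35/11/4
  so that 10 × 10 replication yields 3900/1100/3500/1100/400 pixels.
  Vertices are snapped to the acquisition calendar. The shapes and levels
  are a reconstruction from the strata definitions — the quantitative
  outcome of the assessment is therefore reproduction-dependent.
- **Acquisition calendar** — 199 quasi-evenly spaced dates over 28 years
  (~51-day spacing). The real mission record is denser after 1999; the
  uniform calendar is a deliberate simplification and makes day-error
  metrics conservative for late-period events.
- **Gap model** — a two-state Markov chain over the calendar with
  stationary valid probability 0.45 (55 % mean cloud cover) and mean valid
  run length 2 acquisitions, giving temporally autocorrelated gaps rather
  than independent thinning.
- **Noise model** — the default "skewed" kind emulates cloud-masked forest
  NDVI: 85 % of dates carry tight clear-sky scatter (N(0, 0.025)) and 15 %
  are strongly depressed (−|N(0.5, 0.2)|, mask leakage), the mixture
  scaled so the total SD is 0.2 NDVI. Contamination is strictly one-sided,
  which is what motivates the prctile = 90 study setting; its 90th
  percentile sits at ≈ +0.03. Gaussian and empirical-resample kinds are
  available for sensitivity work. What this generator does *not* emulate:
  spatially correlated cloud fields, seasonal phenology, sensor
  differences, and geolocation error — passing tests say nothing about
  those.

Scoring (`evaluate_fits`): absolute segment-count error; RMSE between fit
and truth on a daily grid over the common span; for truths containing a
disturbance, signed day offsets of the classified decline-start and nadir
breakpoints (fits without a detected disturbance are counted as misses and
excluded from date means). At the study set over 10,000 pixels the
assessment lands at ≈ 0.56 mean segment error and ≈ 0.031 RMSE with
decline starts biased early (≈ −180 d) and nadirs biased late (≈ +330 d) —
the two signatures of fitting through autocorrelated gaps. The nadir
lateness has a structural floor in this reconstruction: the mean spacing
of valid dates is ~114 days, and the percentile knot at the first
post-drop observation is inflated by drop-side points inside its window,
so the fitted bottom vertex lands 2–3 valid observations late regardless
of parameter choice.

## Numerical choices

- Percentiles everywhere use the linear-interpolation definition.
- Distances are floored at 1e−6 before logs; the lognormal σ̂ is floored
  at 1e−6; with zero noise the bail-out compares the fit error against a
  1e−12 numerical-zero tolerance.
- Insertion ties go to the earliest date; candidate dates already holding
  a breakpoint are excluded; subtract never removes endpoints and does not
  re-estimate surviving knot values.
- Dates are integer proleptic-Gregorian ordinal days; rates use 365.25
  days/year; calendar-year bucketing uses the civil year of the nadir.
- NDVI is clipped to [−1, 1]; zero-denominator or non-finite reflectance
  marks the date invalid instead of raising.
- SPM retrievals at ρ_w ≥ C and negative retrievals are masked invalid,
  never clipped.

## SPM component choices

Welch's unequal-variance t-test is used for outlet comparisons (no
evidence for equal variances between an impacted and a reference outlet).
Trident prong angles default to ±30° about the central bearing and are
configurable; 67 points per prong gives the 201-sample 2 km configuration.
Per-date transect medians are the replicates entering the t-tests; pooling
raw points would overstate the effective sample size under strong spatial
correlation along a transect.

## Raster layer

Rasters are read and written as plain TIFF via `tifffile`, with grid
transform, CRS string and nodata in a JSON sidecar; round-trips are
bit-exact. Mask rasters are integer class codes under a configurable
valid/invalid mapping (default: clear and water valid; shadow, snow,
cloud, fill invalid). Scene dates parse from standard scene identifiers,
with a sidecar CSV override for synthetic stacks. Image fitting is
single-process and row-major, hence bit-reproducible.

## Known limitations

- Event dating degrades gracefully but measurably with gap length; users
  dating events to better than one or two valid-observation gaps are
  over-reading the fits.
- The library, calendar and noise model are reconstructions; assessment
  numbers characterise this package under these conditions, not any
  particular archive.
- No seasonal/harmonic term: strongly phenological pixels will inflate the
  noise scalar and bail out as single segments.
- The SPM coefficients are fixed sensor-band constants, not locally
  recalibrated; retrievals near the 17 % reflectance limit are extremely
  sensitive to ρ_w error.
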