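# Methods

## The assessment model

`cfdattain` implements a cumulative-frequency-distribution (CFD) framework
for deciding whether an estuarine spatial unit attains a dissolved-oxygen
(DO) criterion, and for quantifying *how far* it misses.

The spatial grain is the **unit**: a management segment crossed with a
designated use (DU) — open water (OW), deep water (DW), or deep channel (DC),
which correspond to vertical habitat layers with their own DO requirements.
Monitoring records arrive already labeled with their unit; this package does
not perform the spatial interpolation or the density-based layer delineation
that produces those labels upstream.

**Per-event exceedance.** All records sharing a unit and a calendar date form
one sampling event. The event's exceedance is the weighted percent of the
unit's space with DO strictly below the criterion threshold; a value exactly
at the threshold attains, because criteria are minimum requirements. Weights
are any nonnegative spatial shares (interpolation-cell areas, station
Thiessen weights); when absent they default to 1, which reduces the statistic
to the fraction of stations in exceedance. Exceedance is invariant to uniform
rescaling of weights.

**The attainment curve.** For an assessment window, the per-event exceedances
are ranked and plotted across the percent-of-time axis as a step function at
plotting positions i/n: we fix the complementary (non-increasing) orientation
— events sorted by exceedance descending — so that the curve is directly
comparable to the reference curve. The conventional ascending CDF is the
mirror image and yields identical areas, so nothing downstream depends on the
choice. With steps of equal width 100/n and right-continuous closure at
(100, last value), the area under the curve is exactly the arithmetic mean of
the event exceedances — the total space-time exceedance for the window.

**The reference curve** bounds the allowable exceedance: the area beneath it
is the space-time exceedance that can occur without ecological degradation.
Production assessments use biologically derived, segment-specific curves,
which can be loaded from two-column CSV. As a default family the package
ships a hyperbolic curve y(t) = 100·k/(t + k): convex, non-increasing, 100%
at t = 0, with k calibrated by Brent root-finding so that the discretised
curve's area equals the requested allowable area (default 10%) to well within
0.01% of the assessment square. The discretisation uses 2,001 grid points
graded quadratically toward t = 0, where the curvature concentrates. This
family is a qualitative stand-in, not a reproduction of any jurisdiction's
curves.

**The attainment deficit.** The binary decision is pass/fail: a unit attains
iff its attainment curve lies nowhere above the reference curve (tolerance
10⁻⁹ percent of space — a pure floating-point guard, far below the 0.1%
reporting precision). The deficit refines this: it is the area of the region
lying under the attainment curve *and above* the reference curve — the
non-allowable exceedance — scaled to percent of the 100 × 100 square and
negated. It is 0 at full attainment and −100 under total exceedance with a
zero-area reference, and always in [−100, 0]. Two units that both "fail" for
thirty years can have very different deficit trajectories; the deficit is
what makes trends detectable.

Deficit integration is exact piecewise geometry, not quadrature: the
breakpoints of both curves are merged, both curves are linear on every merged
subinterval, and max(0, A − R) integrates in closed form with a split at the
sign crossing. The test suite checks this routine against a 10,000-point
Riemann sum on hundreds of random curve pairs.

## Windows, missing data, aggregation

Assessment runs on **running 3-year windows** (1985–1987, 1986–1988, …,
2014–2016 for a 1985–2016 span: 30 windows; 15 for 2000–2016), using summer
records only (June–September, selected by calendar month). A window needs at
least `min_events` events (default 3; a CFD from fewer events is not
meaningfully rankable). Below that the unit-window is a **missing marker**,
never a zero: silently imputing zeros would bias every aggregate toward
attainment.

Subgroup deficits are **surface-area-weighted means** over the member units
present in the window:

    AD_J = Σ_{j ∈ J, present} AD_j · A_j / Σ A_j

with A_j the segment surface area — constant over time and DU, unlike bottom
area or volume, and spanning four orders of magnitude (0.13–1,521 km²), which
is why equal weighting would be misleading. Missing members leave both sums.
Subgroups are built per designated use, per salinity zone (tidal fresh,
oligohaline, mesohaline, polyhaline), per tidal system, and one "total" group
over all units; in the total group each (segment, DU) pair carries the
segment's full area, since area does not vary by DU. The weighted mean is
associative, bounded by the member extremes, and invariant to rescaling all
areas — all property-tested.

Units with no data in the earliest windows get their "initial status" from
the earliest non-missing window (`initial_status`), mirroring standard
reporting practice for late-starting records.

## Trend and change-point inference

The deficit series is bounded, non-Gaussian, and serially dependent by
construction — adjacent 3-year windows share two summers — so inference is
nonparametric with an autocorrelation correction:

- **Mann-Kendall S** = Σ_{i<j} sgn(x_j − x_i), with tie-corrected variance
  V = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18.
- **Hamed-Rao correction factor**
  CF = 1 + 2/(n(n−1)(n−2)) · Σ_k (n−k)(n−k−1)(n−k−2)·ρ_k, with ρ_k the lag-k
  autocorrelation of the *ranks* of the Sen-detrended series, lags 1…n−3.
  Default lag policy: only lags outside the two-sided white-noise band
  ±1.96/√n enter the sum; an all-lags mode is available. **The factor is
  floored at 1.** The floor is a deliberate design choice: on uncorrelated
  series, sampled negative rank autocorrelations occasionally pass the
  significance band and would *deflate* the variance, inflating the false
  positive rate well above nominal (we measured ≈0.08 at n = 30 versus ≈0.05
  with the floor). The correction exists to keep significance honest under
  the positive autocorrelation that overlapping windows induce; it is never
  allowed to make the test more liberal than the uncorrected one. Series
  shorter than 4 fall back to CF = 1 with a notice.
- **Z** = (S ∓ 1)/√(V·CF) with continuity correction; two-sided normal p.
  Both the corrected p (primary) and the raw uncorrected p are reported,
  since published applications do not always state which variant they used.
- **Sen slope**: median of all pairwise slopes, in percent per year when the
  series index is the window start year (the default in the pipeline).
  Missing windows are dropped, with their time positions retained in the
  slope denominators — exclusion, not interpolation.
- **Significance ladder** 0.05 / 0.1 / 0.25: a trend is classed by the
  smallest alpha exceeding its p, or `ns`. The wider ladder exists because
  changes worth management attention can be real before they clear 0.05 on a
  30-point series.
- **Pettitt test** for a single shift: U_t = Σ_{i≤t} Σ_{j>t} sgn(x_j − x_i),
  K = max|U_t|, p ≈ 2·exp(−6K²/(n³+n²)) capped at 1 (a conservative
  approximation). The change point τ is the earliest argmax on ties, for
  reproducible reporting.

A constant series returns S = 0, Z = 0, p = 1, slope 0 rather than an error.
All statistics are invariant under adding a constant; S and K are invariant
under any strictly increasing transform; Sen slope scales linearly —
property-tested, alongside exhaustive pair-enumeration and exact-permutation
oracles at small n.

## The synthetic-data generator

Real tidal monitoring archives are not distributable with the package, so
every pipeline stage is exercised against `synthetic.ScenarioSpec` scenarios
that emulate the data's structure:

| parameter | default | meaning |
|---|---|---|
| `events_per_summer` | 12–20 | sampling events per unit per summer |
| `area_range` | 0.13–1,521 km² | segment surface areas, log-uniform |
| `do_mean` | 5.5 mg/L | summer event-mean DO at the start year |
| `do_trend` | 0 | linear trend, mg/L per year |
| `noise_sd` | 1.0 mg/L | stationary SD of the AR(1) event noise |
| `ar1_phi` | 0.3 | AR(1) coefficient of the event noise |
| `seasonal_amplitude` | 0.8 mg/L | within-summer sinusoidal dip (late-summer minimum near mid-August) |
| `n_stations` | 4 | records per event |
| `station_sd` | 0.4 mg/L | between-station spread within an event |
| `change_point` | none | (year, shift in mg/L) step in the mean |

AR(1) noise (not white) is the default because the running windows the
assessment uses induce serial correlation that the trend layer must face.
DO is truncated at the physical floor of 0 mg/L, with truncations counted in
the log. Everything is bit-reproducible under the scenario seed.

What the generator does *not* emulate: spatial covariance structure between
stations, stratification dynamics and layer-boundary movement, censored or
quality-flagged observations, and cross-segment correlation from shared
hydrology. Passing tests therefore demonstrate the statistical machinery is
correct and recovers known injected structure; they do not validate the
ecological realism of any particular scenario.

`generate_deficit_series` and `inject_change_point` additionally produce
bounded deficit series directly (clip(base + slope·t + AR(1), −100, 0)) so
the trend layer can be tested without the full pipeline.

## Problem sizes used in validation

The randomized suites use: 1,000 random curve pairs for the deficit bound
invariant; 200 pairs for the geometry-vs-Riemann equivalence (tolerance
0.05%); 1,000 white-noise series (n = 30) for the type-I level of the
modified test; 500 seeds for Sen-slope sign recovery on direct deficit series
(slopes ±0.5 %/window, AR(1) φ = 0.3, noise SD 5 — at these settings sign
recovery exceeds 90%); and 200 seeded single-segment scenarios (1985–2016,
one DU) for full-pipeline recovery of a −0.05 mg/L/yr DO trend (Sen slope
sign) and of a −1.5 mg/L step in 2001 (Pettitt window error, median ≤ 1
window — the step phases in across the three windows that straddle 2001, so
an error of one window is inherent to the windowing, not a test artifact).

## Degenerate inputs and numerical choices

- Exceedance and deficit values are clamped against floating-point drift at
  their theoretical bounds (e.g. weighted sums summing to 100.000…01).
- `allowable_area` 0 and 100 bypass root-finding and return the exact
  degenerate curves.
- Ties in event exceedance are kept as separate equal steps in input order;
  area and deficit are tie-order invariant, so no tie-break rule is needed.
- Zero-total-weight events are an error when scored directly and are skipped
  (with the event excluded) inside window assessment.
- Duplicate time fractions and non-monotone space values in a loaded
  reference table are format errors naming the offending row.

## Known limitations

- Criterion thresholds ship as conventional placeholder magnitudes (OW 5.0,
  DW 3.0, DC 1.0 mg/L summer); real assessments must supply the
  jurisdiction's season-specific values. Duration-based criterion components
  (30-day means, instantaneous minima) are out of scope — one threshold per
  use and season.
- The hyperbolic reference family approximates the shape, not the values, of
  production reference curves.
- Whether production systems evaluate the curve comparison on event abscissae
  or a fixed grid is not standardized; the exact piecewise geometry used here
  sidesteps the choice but may differ from production rounding at the 0.1%
  reporting precision.
- The Pettitt approximation is conservative; its false-detection rate on
  white noise runs below nominal.
- Seasonal Mann-Kendall, GAM-based station trends, and block-bootstrap
  alternatives are not implemented.
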