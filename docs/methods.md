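# Methods

This note documents the statistical procedures, the conventions and
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The circular model

Phenological event dates are points on the annual circle: a snowfall on
30 December and one on 2 January are four days apart, not 362. All
screening therefore maps days to angles, θ = 2π·(d mod T)/T, with
period **T = 365.25 days applied uniformly to all years**. No
leap-year branching: the sub-day mapping error this introduces is far
below the day-level resolution of the data and removes a source of
year-dependent behaviour.

The distributional workhorse is the von Mises distribution

    f(θ; μ, κ) = exp(κ·cos(θ − μ)) / (2π·I₀(κ)),

the circular analogue of the normal: μ is the mean direction
(the typical event date), κ ≥ 0 the concentration (κ → 0 is the
uniform circle; for large κ the distribution approaches a Gaussian
with variance 1/κ). Maximum likelihood is closed-form in μ (direction
of the mean resultant vector) and one-dimensional in κ: κ̂ solves
A₁(κ) = I₁(κ)/I₀(κ) = R̄, the mean resultant length.

Numerical choices:

* Bessel ratios use exponentially scaled `i0e`/`i1e`, stable at any κ.
* A₁ inversion: Newton iteration from Fisher's piecewise starting
  approximation, tolerance 1e-12, with a bracketed Brent fallback;
  below R̄ = 1e-4 the starting approximation is already exact to
  well beyond tolerance and is returned directly.
* **κ is capped at 500** (`KAPPA_MAX`). A constant series has R̄ = 1
  and no finite MLE; the cap keeps the fit defined and the downstream
  interval positive. At κ = 500 the 0.9999367 central interval is
  ±10.4 days — tight enough for any screening purpose.
* Central intervals: the half-width δ with mass p in [μ − δ, μ + δ] is
  found by Brent root-finding (tolerance 1e-12 rad) on the von Mises
  CDF; at κ = 0 the closed form δ = pπ is used. The CDF itself comes
  from `scipy.stats.vonmises`; tests verify the resulting masses
  against direct quadrature of the density to 1e-8.

## Outlier screen

Per (study site, taxon-or-climatic name, event type) series: fit
VM(μ̂, κ̂) on **all** points of the series, compute the central
interval of mass p, and flag every record whose circular distance from
μ̂ (in days) exceeds the interval half-width.

* **Default level p = 2Φ(4) − 1 rounded to 7 decimals = 0.9999367**,
  the two-sided Gaussian four-standard-deviation mass. It is computed
  from the normal CDF at runtime, not hard-coded, so the provenance of
  the number is visible in one place (`default_mass`). The interval
  itself is a genuine von Mises probability interval at that mass, not
  a μ ± 4σ construction; the two agree closely at moderate-to-large κ.
* **Single-pass by design.** Suspects stay in the fit and there is no
  iterative re-fitting. The screen nominates records for human review;
  iterative trimming would change the flagged set and overstate
  confidence in self-cleaning. Consequence: a series containing
  several gross errors can partially mask them (the extra outliers
  deflate κ̂ and widen the interval). The bimodality screen acts as a
  second line of defence for exactly those series, and in pipeline
  order it runs on records the outlier screen has not already flagged.
* **min_n = 10 by default**: a 6e-5 tail statement from fewer than ten
  points is meaningless, so smaller series are reported as skipped
  rather than screened.
* Calibration: under a pure von Mises null (κ = 10, n = 200 per
  series) the measured per-record flag rate over 10⁶ simulated records
  matches 1 − p within three Monte-Carlo standard errors
  (`tests/test_acceptance.py`). Estimating (μ, κ) from the same 200
  points barely perturbs the extreme-tail rate because each point's
  own pull on the fit offsets the tail-inflation from κ̂ noise.

## Bimodality screen

Per series, and again per (name, event type) pair pooled over sites:

1. fit a single von Mises (2 parameters);
2. fit a two-component von Mises mixture
   w·VM(μ₁, κ₁) + (1−w)·VM(μ₂, κ₂) (5 parameters) by EM;
3. flag iff **ΔBIC = BIC_single − BIC_mixture ≥ 5** and the circular
   distance between μ̂₁ and μ̂₂ exceeds **30 days**.

Both gates are needed: strong BIC support for two modes 20 days apart
describes seasonal spread or a skewed season, not mislabelling. The
BIC gate is inclusive (≥ 5) and the separation gate strict (> 30 d).
Mean separation is measured circularly; for separations under half a
year this coincides with the linear difference, which covers the
30-day rule in practice.

EM details:

* E-step responsibilities in log space (`logaddexp`); M-step is the
  weighted circular MLE per component plus the weight update.
* **Initialisation**: 10 random restarts, each splitting the sample by
  a random diameter through the circle's centre and fitting one
  component per arc, plus one deterministic start from the two
  strongest well-separated peaks of a von Mises kernel density
  estimate on a fixed 256-point grid. The likelihood surface is
  multimodal; restarts are cheap insurance, and the deterministic
  start makes clearly bimodal series reproducible even with a single
  restart.
* **Safeguards**: component weights floored at 0.01, κ capped at 500 —
  both prevent a component collapsing onto a single point with
  unbounded likelihood. Convergence: relative log-likelihood change
  below 1e-8 or 500 iterations. Accepted iterations are monotone in
  log-likelihood up to that tolerance (asserted in tests), and the
  mixture log-likelihood never falls below the single fit's (the
  mixture nests it at w → 1).
* **min_n_mixture = 20**: five parameters need more data than two.
* Determinism: the fit is a pure function of (data, settings, seed).
* Calibration and power (both recomputed in the acceptance tests):
  under unimodal nulls (κ ∈ {2, 5, 10} × n ∈ {50, 200}) the flag rate
  is ≤ 5% per condition; for equal modes 70 days apart (κ = 20,
  n = 200) power is ≥ 95%.

A note on what the pooled pair-level screen adds: a name used for a
spring event at some sites and an autumn event at others is unimodal
within every site and invisible to the triplet screen; pooling over
sites exposes it.

## Variance partitioning

Per event group, on the **linear** day scale (ordinary least squares
conventions; see limitations):

1. total SS about the grand mean of day-of-year;
2. `frac_site` = SS of per-site mean dates (each record replaced by
   its site's record-weighted mean over species and years) / total SS;
3. `frac_geo_within_site` = R² of OLS of the per-site mean dates on
   latitude + longitude + latitude×longitude, one point per site,
   unweighted. Coordinates enter in raw decimal degrees; the
   interaction uses mean-centred coordinates for numerical
   conditioning (R² is invariant to the centring). With fewer than
   four distinct coordinate points, or a rank-deficient design, the R²
   is reported as NaN — undefined, never silently 0;
4. `frac_species` = SS of taxon means of the site-demeaned residuals
   (record-weighted) / total SS;
5. `frac_residual` = 1 − `frac_site` − `frac_species`.

Because residuals sum to zero within each site and taxon means of
residuals are subtracted from the residuals themselves, the cross
terms vanish and the three total-variance shares form an exact
decomposition — additivity holds to 1e-9 on every group (asserted).

Conventions chosen where more than one reading was possible:

* **Site averages are record-weighted**, not species-weighted: the
  site mean is the plain mean over all of the site's records. The
  species-balanced alternative would change `frac_site` where species
  sets differ strongly across sites.
* The geographic regression is **unweighted across sites** (one point
  per site) regardless of how many records each site holds.
* **Sequential sums of squares, not mixed-model (REML) variance
  components.** Site and species enter as fixed groupings; no
  shrinkage. Groups are selected at **≥ 1000 records** by default.
* Grouping axis: phenological records group by taxonomy `class` when
  present (e.g. Aves, Magnoliopsida), falling back to `kingdom`;
  climatic records group by their climatic group (temperature / snow /
  ice), pooled over event types, with the **event type playing the
  role of the taxon** in the species component.
* Degenerate groups (one site, one taxon, fewer than three records, or
  zero variance) raise an explicit error rather than returning a
  partition.

## Database schema and conventions

* `dayofyear` accepts integers in a configurable valid range,
  **default 1..366**. The schema's "days since January 1st" wording
  would literally make 1 January day 0, but real exports are commonly
  1-based; all statistics here are invariant to that constant shift,
  so the range is a validation bound, not an origin commitment.
  Out-of-range and unparseable values are recorded as violations and
  kept, never silently dropped.
* `quality`: empty means clean; the screens write
  `suspicious_outlier` / `suspicious_bimodal`. Any non-empty token
  excludes a record from subsequent fitting.
* Column matching is case-insensitive and whitespace-trimmed; extra
  columns survive a load/write round trip; files are UTF-8, RFC-4180
  quoted.
* Screens and partition operate only on records with empty `quality`
  and parseable `dayofyear`.

## Synthetic-data generator

Each (site, taxon, event type) series gets one record per year:

    day = baseline + β_lat·lat + β_lon·lon + β_int·lat·lon
          + u_site + v_taxon + w_year + ε,

rounded to an integer and wrapped into [1, 365]. Site, taxon and year
effects and the noise ε are independent Gaussians **on the linear day
scale** — the within-season regime the variance partitioning assumes;
events straddling the year boundary can be emulated by setting the
baseline near the boundary to stress-test the circular screens. Year
effects are shared across sites and taxa within a year (common
weather) and load onto the residual fraction of the partition.

* **Effect vectors are standardized draws**: each is rescaled to
  realized mean 0 and SD exactly the configured sigma. The variance
  fractions implied by the configuration (`GroundTruth.true_fractions`,
  which also fold in the realized geographic trend variance across the
  generated sites) then hold for every seed rather than only in
  expectation — a generated database *is* its own ground truth, which
  is the property the recovery benchmarks need.
* Default scales — site 8 d, species 10 d, year 3 d, noise 5 d, ~2 d
  per degree latitude — are of the order seen in continental
  phenological archives; contamination defaults to zero.
* **Outliers**: with probability `outlier_rate` a record is replaced
  by a day drawn uniformly from the arc at least
  `outlier_min_shift_days` (default 90) from its series' seasonal
  mean, and labelled. The 90-day floor separates power measurement
  from threshold calibration: injected errors are unambiguous at the
  default screen level.
* **Bimodal contamination**: a fraction `bimodal_series_rate` of
  series draw each record from a second mode
  `bimodal_separation_days` later with probability `bimodal_weight`;
  both the records and the series are labelled.

What the generator does **not** emulate: unbalanced site×taxon×year
coverage (real archives are ragged; the generator crosses fully),
temporal trends (climate-change signal — residual variance here is
exchangeable noise), non-Gaussian season shapes (skewed onsets),
spatially correlated site effects beyond the deterministic trend, and
realistic taxonomies (names are placeholders with valid keys). Passing
benchmarks on generated data therefore demonstrate calibration and
recovery under the stated model, not robustness to raggedness,
skewness or drift in real archives.

## Known limitations

* Variance partitioning on the linear day scale inflates the variance
  of groups whose events straddle the year boundary (midwinter snow
  and ice events); this is documented, not corrected, for fidelity to
  standard linear-model practice for within-season events.
* The single-pass outlier screen can partially mask multiple gross
  errors in one series (see above).
* The bimodality thresholds (ΔBIC ≥ 5, 30 days) are screening
  configuration, not inference; no multiple-testing control is applied
  across series, because flags feed manual review rather than
  automated deletion.
* Fixed period T = 365.25 everywhere; no calendar-aware handling of
  leap days.

## Problem sizes in the checks

The calibration and recovery checks use: 10⁶ records (5000 series ×
200) for the outlier null rate; 200 replicates per null condition and
100 for power in the mixture screen; 20,000 records (50 sites × 50
taxa × 8 years) for variance recovery; 20 series of n = 2000 for the
grid-search MLE cross-check. These sizes put Monte-Carlo error well
below the tolerances they are compared against while keeping a full
run to a few minutes.
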