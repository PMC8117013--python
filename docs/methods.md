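# Methods

`dendrobai` implements a dendroecological analysis chain for boreal
mixed-stand studies: per-tree ring widths become basal-area-increment
(BAI) chronologies per species × stand-composition group; the
chronologies are confronted with monthly climate through bootstrapped
correlation functions; and a Bayesian linear model attributes growth to
a stand baseline, a long-term trend, two temperature proxies and two
insect-epidemic intensity covariates. A synthetic-data generator with
known ground truth stands in for field data, so every stage can be
validated against the parameters that generated its input.

## The growth model

For a chronology `y` (one of five groups: black spruce in pure-spruce,
mixed and pure-aspen stands; trembling aspen in pure-aspen and mixed
stands) and year `t` in 1950–2005:

    BAI_t,y = α_Baseline,y
            + Trend_t        · α_Tr,y
            + SeasonLength_t · α_SL,y
            + SummerHeat_t   · α_SH,y
            + Budworm_t      · α_SB,y
            + Caterpillar_t  · α_TC,y
            + ε_t,   ε_t ~ N(0, σ_y²)  iid

* `Trend_t = t − 1977` — integer, −27 (1950) … +28 (2005); its
  coefficient (cm²/yr) captures slow demographic change.
* `SeasonLength_t` — mean of the April and September average-temperature
  anomalies (°C; departures from the per-month 1950–2005 mean). Warm
  Aprils/Septembers lengthen the growing season.
* `SummerHeat_t` — mean June–August temperature anomaly (°C), a heat /
  evaporative-stress proxy.
* `Budworm_t` — spruce budworm epidemic intensity: a 9-year triangular
  pulse (0.2, 0.4, 0.6, 0.8, 1, 0.8, 0.6, 0.4, 0.2) centred on 1974.
* `Caterpillar_t` — forest tent caterpillar intensity: 1 in 1980 and
  2001, 0.5 in 2000, 0 elsewhere.

Priors are uniform on each α within wide data-scaled bounds and
Jeffreys (p(σ) ∝ 1/σ) on the residual scale. Because the likelihood is
linear-Gaussian, the flat-prior coefficient posterior is the classical
multivariate t centred on the least-squares solution with scale
s²(XᵀX)⁻¹ and n−p degrees of freedom; the test suite uses this closed
form as an independent oracle for the sampler.

### Sampler

Component-wise Gaussian random-walk Metropolis–Hastings, one sweep over
the seven parameters (six α, then σ) per iteration; 60,000 iterations
with the first 10,000 discarded as burn-in by default. Proposal scales
start at 2.4 × the conditional least-squares standard errors and adapt
in batches of 100 iterations **during burn-in only** (×0.7 when the
batch acceptance falls below 20%, ×1.4 above 45%), then freeze, so the
retained chain satisfies detailed balance. The chain starts at the
least-squares solution. A single chain is run per fit; split-half
stability, posterior-sd/prior-range shrinkage and a histogram
unimodality heuristic form an advisory convergence report.

### Prior bounds

"Uniform priors" need concrete bounds. Each coefficient
gets a symmetric interval of half-width max(10·|OLS estimate|,
10·sd(BAI)/sd(covariate)); the intercept uses 10·(|mean| + sd) of the
BAI series; σ is bounded in (10⁻⁶, 10·sd(BAI)). These are intended
never to bind: the fit warns if more than 0.1% of retained draws land
within 1% of any bound. A constant covariate column (e.g. an epidemic
that never occurs in the span) triggers a warning and leaves that
coefficient prior-dominated rather than failing.

### Cross-group comparison

Marginal posteriors of the same parameter in two groups are compared
with the overlapping coefficient OVL = ∫ min(f, g). It is estimated on
a shared 100-bin histogram grid spanning the pooled 0.1–99.9 percentile
range (tail mass outside the grid counts as non-overlap, a negligible
bias at these sample sizes). OVL < 0.10 (strict) is read as a
significant difference, and drives the qualitative "effects of mixture"
table (direction from the sign of the posterior-mean difference,
significance from the OVL flag).

## Chronology construction

* **Distance to pith.** Cores that missed the pith use the innermost
  visible ring's arc: a chord `c` and height `h` give the circle radius
  `c²/(8h) + h/2`. Without arc geometry, a fallback multiplies the mean
  of the five innermost widths by an expected missing-ring count
  (default 5).
* **BAI.** With cumulative radius `r_t = offset + Σ w_s` (mm),
  `BAI_t = π(r_t² − r_{t−1}²)/100` cm². The series telescopes, so
  Σ BAI = π(r_n² − offset²)/100 exactly — asserted at 1e−9 relative
  tolerance as a conservation check.
* **Cambial-age filter.** Rings with cambial age < 15 are dropped
  (age = ring index + estimated missing rings; the missing-ring count is
  the pith offset divided by the local growth rate of the five innermost
  rings). This removes juvenile growth before averaging.
* **Mean chronology.** Arithmetic mean across contributing trees per
  year, SEM = sd(n−1)/√n, with sample depth recorded; every year of the
  1950–2005 span must keep at least two trees.
* **Descriptive statistics.** Mean sensitivity
  2|w_{t+1}−w_t|/(w_{t+1}+w_t), per-series lag-1 autocorrelation, and a
  leave-one-out series intercorrelation computed on first-differenced
  widths (each series' differences against the mean differences of the
  others). First differencing replaces the spline-based high-pass of
  crossdating software with a fully specified, testable transform; the
  statistics are computed on post-juvenile rings (those that enter the
  chronology). Values are comparable in intent, not in detail, to
  COFECHA output.

## Correlation functions

Chronology vs. monthly mean temperature and monthly precipitation
totals, for January–September of the ring-formation year plus two
composites (April+September; June–August). Point estimate: Pearson r on
the full year pairing. Uncertainty: pairs bootstrap — years resampled
with replacement keeping (BAI, climate) tuples intact, 1,000 resamples,
95% percentile interval; significance means the interval excludes zero.
Previous-year months are available behind a configuration flag but off
by default, as same-year windows carry the reported signal.

**Known limitation.** Percentile bootstrap intervals for a correlation
are slightly anti-conservative at n = 56: the measured type-I rate
under an independent null is ≈6.5–7% rather than 5% (BCa reduces this
only marginally). The calibration study in the acceptance suite
documents this; treat isolated single-month significances near the
threshold accordingly.

## Synthetic data generator

The generator emulates the study conditions so that downstream
estimates can be checked against known truth.

* **Climate.** Independent Gaussian months around a fixed boreal
  climatology (July normal 16.9 °C, January −18.2 °C, annual
  precipitation ≈ 875 mm with a summer maximum), monthly temperature sd
  1.5 °C, gamma-distributed precipitation, and an optional linear
  warming slope (default 0). tmin/tmax sit a fixed 5.5 °C below/above
  tavg. Months are independent — no interannual memory or
  cross-variable correlation.
* **Group BAI.** The linear predictor above plus AR(1) Gaussian noise
  with marginal sd σ and lag-1 coefficient φ (default 0, matching the
  model's iid likelihood; nonzero φ exercises robustness tests).
  Default truths: spruce baselines 2.5/3.0/2.2 cm² (pure/mixed/
  pure-aspen), aspen 9.3/8.8 cm²; spruce responds positively to season
  length (0.3–0.4 cm²/°C), negatively to summer heat and budworm
  (−0.4 to −0.8 cm²), and positively (+0.5/+0.6 cm²) to caterpillar
  epidemics on neighbouring aspen; aspen caterpillar effects −4.5/−4.4
  cm² (roughly halving growth in epidemic years); σ = 0.3 cm² (spruce)
  and 1.4 cm² (aspen). These encode the qualitative host/non-host
  structure the pipeline is expected to recover and produce
  post-juvenile ring-width statistics (mean width ≈ 0.7–1.4 mm, sd ≈
  0.2–0.5 mm, mean lag-1 autocorrelation ≈ 0.5–0.8) inside the ranges
  typical of such chronologies.
* **Trees.** Each tree draws a unit-mean lognormal growth factor
  (sd 0.2, between-tree scatter), a unit-mean lognormal tree-year noise
  (sd 0.08, so cores disagree year to year and the intercorrelation
  falls below 1), a pith offset uniform on 0–10 mm and a start year in
  the first decade of the span. Ring widths invert cumulative-area
  growth: `w_t = √(A_t/π) − √(A_{t−1}/π)`. Offsets below 0.5 mm are
  declared pith-complete; the others carry arc geometry of the
  innermost ring with 5% multiplicative chord noise, giving the pith
  estimator a realistic, known-truth task.

What passing tests show — and don't. The generator matches the model's
structural assumptions (linearity, Gaussian noise, exact epidemic
calendar), so recovery tests validate the computations, not the model's
adequacy for real forests. Real data add standardisation error, climate
memory, spatially structured disturbance and non-deposited sampling
choices that the generator deliberately omits (no process-based growth,
no spatial structure, no insect population dynamics).

## Numerical and design choices

* Problem sizes in tests and the acceptance script: single fits use the
  full 60,000-iteration chain; replicate studies (coverage,
  calibration) use 12,000-iteration chains and 100–2,000 replicates —
  sizes at which Monte-Carlo error is comfortably below the asserted
  tolerances.
* Random streams: one root seed per run, spawned per stage
  (climate/BAI/trees; simulate/correlate/fit in the pipeline), so every
  stage is individually reproducible and reruns are byte-identical.
* Ranking ties (first-difference anomalies) go to the earlier calendar
  year; a year-to-year change is assigned to the later year, so a drop
  *into* an epidemic year is that year's anomaly.
* Tucson output uses 0.01 mm integer units with terminator 999; the
  reader auto-detects the 0.001 mm / −9999 dialect per series. Ring
  year is the calendar year of formation (no southern-hemisphere
  shift).
* Missing rings (width 0) are retained and contribute zero BAI.
* Degenerate inputs fail loudly: zero-variance chronologies, constant
  predictors in the bootstrap, empty draw sets, non-contiguous year
  runs and duplicate (tree, year) rows are errors, not repairs.

## Limitations

* The iid-Gaussian likelihood ignores residual autocorrelation; with
  strongly persistent residuals (φ ≳ 0.5) credible intervals are too
  narrow. The generator's φ option exists precisely to probe this.
* OVL estimation by shared-grid histograms carries O(bin width) bias;
  with 100 bins and ≥10,000 draws the bias is below the 0.10 decision
  threshold's practical resolution, but OVL values near the threshold
  should not be over-read.
* The bootstrap anti-conservatism noted above.
* Chronology statistics use first differences, not the 32-year-spline
  segment correlations of crossdating software; absolute values are not
  interchangeable with COFECHA reports.
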