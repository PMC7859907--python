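# Methods

## Measurement model

A wound at one sighting is a set of traced polygons in pixel coordinates
(x right, y down, origin top-left, any winding; areas are absolute
shoelace values computed through shapely). Polygons must be simple — fewer
than three vertices, repeated consecutive vertices, self-intersection or
zero area are rejected, since area is undefined for such tracings.

Photographs of the same animal differ in distance and resolution, so raw
pixel measurements are not comparable. Each image therefore carries a
tracing of one unchanging epidermal spot marking (the anchor; by
convention a rectangle, but any simple polygon is accepted and treated as
an opaque scale). The standardized extent at a sighting is

    area_ratio      = Σ section areas / anchor area
    perimeter_ratio = Σ section perimeters / anchor perimeter

Summation over sections makes the measurement robust to wounds that split
into fragments while healing. Both ratios are invariant under any uniform
rescaling of an image's pixel grid, which is the property the anchor
exists to provide.

The first date a wound is photographed defines day 0; offsets are integer
calendar-day differences. Two tracings of one injury on the same date are
rejected as ambiguous rather than averaged — sightings are dated events.
Because healing is referenced to the first *sighting* rather than the
unknown injury date, all rates are estimates of a lower bound on true
healing speed.

## Healing descriptors

Percent healed at sighting *i* compares the standardized extent with day 0:

    pᵢ = 100 − 100 · (aᵢ/a_mᵢ) / (a₀/a_m₀)

0 at day 0 by construction, 100 at full closure, negative when a wound
grows. The inter-sighting rate is the first difference over elapsed days,
yᵢ = (pᵢ − pᵢ₋₁)/(tᵢ − tᵢ₋₁) in %/day, taken over consecutive sightings
with no smoothing; the rates telescope exactly back to the final percent
healed. Surface area is the primary variable; perimeter mirrors it
throughout. For severed appendages that re-fuse rather than close, healing
is tracked as the percentage of the originally severed length reattached.

Logit transforms clamp proportions into [ε, 1−ε] with ε = 10⁻³ so that
day-0 (p = 0) and near-complete records stay finite.

## Severity and source rules

Severity is binary (major/minor), judged on the first sighting of a
series, and reflects likely resource-allocation impact, not survival.
Verified quantitative rules, all inclusive (≥), relative to the first
dorsal fin:

* laceration: major iff on the main body and total incision length ≥ fin
  vertical height; appendage lacerations are minor;
* abrasion: major iff (area ≥ 50% of fin area and perimeter ≥ fin
  perimeter) or perimeter ≥ 200% of fin perimeter;
* either type: pallid/discoloured skin around the site or necrosis forces
  major regardless of size.

Rules for the six remaining wound types (amputation, bite, blunt trauma,
abnormality, entanglement, nick) ship as per-type defaults (amputation,
bite, blunt trauma, entanglement → major; abnormality, nick → minor) that
are **implementation-chosen extrapolations**, clearly overridable through a
YAML rule table; only the laceration/abrasion rules above are treated as
authoritative. Source attribution maps observer-coded pattern flags
(parallel repeating lacerations → propeller; large blunt trauma/abrasion →
hull; crescent tooth marks → bite; constriction line → entanglement);
without flags, or with conflicting flags, the source is undetermined.

## Record exclusions

Three analysis-specific filters, applied by `apply_exclusions`:

* curve fits: sightings past 150 days are omitted (clearer temporal
  resolution; late virtually-healed records removed). The cutoff is the
  `max_day` parameter.
* rate plateau fits: the 150-day filter first, then negative rates are
  dropped (this ordering is the default; both steps are exposed).
* mixed model: fully healed records (percent healed ≥ 100 up to a 10⁻³
  tolerance) and day-0 rows (identically zero) are dropped.

## Trajectory models

**Exponential closure** `y(x) = a(1 − e^(−bx))`: `a` is the horizontal
asymptote in % (wounds that scar without fully closing have a < 100), `b`
the closure rate in 1/day. Fitted by nonlinear least squares pooled across
injuries (unweighted; per-injury fits are available but the pooled curve
is the headline). Because no initial values are published for this kind of
fit, a multi-start grid (a ∈ {80, 90, 100, 110} × b ∈ {0.01, 0.05, 0.1,
0.3}) is run and the best final residual sum of squares wins; trust-region
least squares with tight (1e-14) tolerances makes the result deterministic
given the data. Standard errors come from the Gauss–Newton covariance
σ̂²(JᵀJ)⁻¹. The day a closure threshold τ (< a) is reached is the exact
inverse x = −ln(1 − τ/a)/b; τ defaults to 90% and is a parameter.

**Quadratic plateau** for inter-sighting rates:
`y(x) = a + bx(1 − x/(2·x_cl))` below the critical day `x_cl`, constant
`a + b·x_cl/2` beyond it; the curve is continuous with zero slope at
`x_cl` by construction. Same multi-start NLS machinery (a ∈ {5, 10, 15},
b ∈ {−0.05, −0.3, −1, −3}, x_cl ∈ {10, 30, 60}); `x_cl` is reported with
its asymptotic SE and t statistic. A fitted `x_cl` beyond the observed day
range sets a warning flag.

Goodness of fit for both is a Nagelkerke pseudo-r² from Gaussian
log-likelihoods of the model vs the intercept-only null,
r² = (1 − exp(2(ℓ₀ − ℓ₁)/n)) / (1 − exp(2ℓ₀/n)).

## Mixed-model factor screen

The screen asks which of injury type, body location and severity influence
the logit healed proportion, after the mixed-model exclusions. Design
choices where the underlying analysis is underspecified:

* **Time trend**: log(day) is always in the fixed part. For an
  exponential-closure proportion, logit(p) is approximately linear in
  log-day through the active-healing range, and type differences appear as
  a near-constant shift (≈ log of the rate ratio) plus a slope difference.
* **Factor blocks**: each factor enters as main effect + log-day
  interaction and the pair is tested jointly by a likelihood-ratio χ² of
  ML fits (screening terms and interactions together). Stepwise removal
  drops the least significant block with p > α (α = 0.05) and refits until
  a minimum adequate model remains.
* **Random structure**: the intended decomposition is a shark random
  intercept plus injury-case variance components (intercept and log-day
  trend). Separating shark from injury variance needs replication —
  several sharks carrying two or more injuries. When fewer than five
  sharks do (typical at this cohort size: ~22 injuries across ~18
  individuals), or when the fitted components are degenerate (total
  random-effect variance exceeding the marginal response variance) or the
  fit fails, the screen falls back to an injury-level random intercept
  plus log-day random slope, and as a last resort intercept-only, with
  logged warnings. The random slope matters: testing factor × time
  interactions without injury-level slope variation is anticonservative.

Calibration of this screen was verified by simulation (see the acceptance
suite): with a real type effect and randomized severity/location labels,
type is retained in ≈99% of replicate cohorts and each null factor in
≤ 5%.

## Synthetic cohort generator

The generator emulates the structure of opportunistic photo archives, not
their content. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_injuries | 22 | usable injury cases per cohort |
| n_sharks | 18 | individuals (a few carry several injuries) |
| type_mix | 50/50 | laceration : abrasion |
| true (a, b) | laceration (98.124, 0.050); abrasion (94.804, 0.135) | per-type closure parameters, % and 1/day |
| mean_gap_days | 15 | mean re-sighting gap (gamma–Poisson dispersed, shape 2) |
| horizon_days | 150 | observation horizon; ≥3 sightings guaranteed |
| noise_sd | 8 | additive Gaussian noise, percent-healed scale |
| pixel_density_range | (0.5, 2.0) | per-image multiplicative scale jitter |
| split_section_prob | 0.25 | injuries rendered with a two-section sighting |

Noise is additive Gaussian on the percent-healed scale, truncated above at
100 (a wound cannot be more than fully closed) — the simplest error model
consistent with observed scatter in this kind of data. Trajectories are
rendered as regular 12-gons scaled to the target area plus a square anchor;
geometric realism is deliberately out of scope since only measured ratios
matter. Everything is driven by one `numpy` Generator seed; identical
config + seed gives byte-identical serialized cohorts.

What the generator does **not** emulate: angle-dependent foreshortening,
tracing error correlated within an observer, wound-shape change, volume,
mis-identification between sharks, or seasonal sighting effort. Passing
tests therefore demonstrate correctness of the pipeline under the stated
error model, not performance on real photographs.

### Known limitation: truncation bias near saturation

Truncating noise at 100% biases measured values near the asymptote
downward (E[min(a + ε, 100)] < a), which biases the fitted asymptote â low
by ~1% for fast-healing types whose observations concentrate in
saturation. Because day-to-90% = −ln(1 − 90/a)/b diverges as a → 90, this
small bias inflates the day-to-90% estimate systematically — ~8% for the
abrasion parameter set — and does not shrink with cohort size. The median
absolute recovery error stays within 3% for â and 10% for day-to-90%, but
tail coverage for the fast type is wider than the noise alone would give.
A censoring-aware likelihood would remove the bias; the package keeps the
plain least-squares fit that the standard analysis prescribes.

## Problem sizes in the test suite

The replicate studies run at the cohort's native size (22 injuries): 200
replicates for parameter recovery and 100 for the screen's retention
rates; geometry is validated against a 10⁶-sample Monte-Carlo
point-in-polygon oracle on 50 random convex and star-shaped polygons.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted margins.
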