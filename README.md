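# sharkheal

Quantifying wound healing in free-swimming whale sharks (*Rhincodon typus*)
from longitudinal photo annotations.

Whale sharks at coastal aggregation sites are re-sighted opportunistically
over months, and their injuries — propeller lacerations, hull abrasions,
bites, entanglement wounds — can be tracked photographically. Absolute wound
size cannot be read off a photograph, but every flank image contains
unchanging epidermal spot markings. Tracing one such **anchor marking** in
each image gives a within-image relative scale: the wound's traced area
divided by the anchor's area is a dimensionless extent that is comparable
across photographs of any pixel density.

`sharkheal` implements that measurement chain and the statistics built on
it, for researchers analysing photo-identification archives of injured
sharks (or other photogrammetrically monitored megafauna):

* **Measurement** — polygon annotations (wound sections, anchor, first
  dorsal fin) → anchor-normalized area/perimeter ratios per sighting, with
  day 0 defined as the first sighting of the open wound.
* **Classification** — a rule table assigning injury severity
  (major/minor) against first-dorsal-fin yardsticks (incision length ≥ fin
  height; abrasion area ≥ 50% of fin area with perimeter ≥ fin perimeter,
  or perimeter ≥ 200% alone; discoloration/necrosis override) and injury
  source from observer-coded pattern flags.
* **Healing statistics** — percent healed since day 0,
  `100 − 100·(aᵢ/a_mᵢ)/(a₀/a_m₀)`, the inter-sighting healing rate
  `yᵢ = Δ(percent healed)/Δt` in %/day, logit transforms, and the linear
  tissue-reattachment percentage for severed appendages.
* **Trajectory models** — statsmodels-style model objects:
  `ExponentialHealingModel` fits `y(x) = a(1 − e^(−bx))` to pooled percent
  healed vs days; `QuadraticPlateauModel` fits
  `y(x) = a + bx(1 − x/(2·x_cl))` (constant beyond the critical day `x_cl`)
  to inter-sighting rates; `HealingFactorScreen` runs a stepwise
  mixed-model screen of type/location/severity on logit healed proportion
  with shark/injury random effects. Fits report Nagelkerke pseudo-r² and
  invert to the day a closure threshold is reached,
  `x = −ln(1 − τ/a)/b` (default τ = 90%).
* **Synthetic cohorts** — a seeded generator producing pixel-space polygon
  annotations with irregular re-sighting schedules, per-image pixel-density
  jitter, type-dependent exponential healing and observation noise, so the
  whole pipeline is testable end to end without photographs.

## Worked example

```python
import sharkheal as sh

cohort = sh.generate_cohort(sh.CohortConfig(seed=1))   # 22 synthetic injuries
frame  = cohort.rates_frame()                          # tidy per-sighting table

lac = frame[(frame["type"] == "laceration") & (frame["metric"] == "area")]
print(sh.ExponentialHealingModel.from_dataframe(lac).fit().summary())
```

```
Exponential closure model  y(x) = a(1 - exp(-bx))
  n obs            141
  a (asymptote %)      97.051  (se 0.755)
  b (1/day)            0.0502  (se 0.0020)
  Nagelkerke r2         0.964
  day to 90%           52.231
```

The fitted asymptote (97.1% of the initial extent eventually closes) and
rate (0.050/day) recover the generating laceration parameters; the fitted
curve crosses 90% closure on day 52. The same table feeds the rate plateau
model and the factor screen:

```python
print(sh.QuadraticPlateauModel.from_dataframe(frame, metric="area").fit().summary())
print(sh.lmm_factor_screen(frame).summary())
```

```
Mixed-model factor screen (alpha=0.05; random: injury intercept + log-day slope (fallback))
  minimum adequate model: logit_healed ~ log_day + C(type) + log_day:C(type)
  term           chi2  df        p  retained
  type         12.297   2   0.0021  True
  location      0.737   4   0.9467  False
  severity      2.952   2   0.2285  False
```

Injury type is retained (lacerations genuinely heal slower than abrasions
in the generator), while the null factors severity and location are
dropped — exactly the behaviour the screen should show.

The same stages are available from a shell:

```bash
sharkheal simulate --seed 1 --out cohort.json --truth-out truth.csv
sharkheal measure cohort.json --out measurements.csv
sharkheal fit cohort.json --out models.csv --threshold 90 --max-day 150
sharkheal run cohort.json --out-dir report/
```

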