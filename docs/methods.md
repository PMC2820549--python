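# Methods

## Model and assumptions

`symshuffle` iterates a balance equation for each symbiont population:
density change per day equals the specific growth rate minus a shared,
non-selective loss rate. The biological assumptions baked in are:

1. The host may carry several *Symbiodinium* types at once; no exogenous
   symbionts enter (shuffling, not switching).
2. Down-welling solar insolation (SI, kW m⁻² d⁻¹) is the single limiting
   resource. It becomes scarcer as the standing stock grows (self-shading),
   expressed by the factor `max(0, 1 − ΣZ/K)` in the resource-allocation
   step. Temperature (SST, °C) is a condition, not a resource: it only
   modulates the Gaussian response terms.
3. Each type's growth response to each driver is Gaussian around a type
   optimum; narrow SDs are specialists, wide SDs generalists.
4. The host tolerates environmental departure from its own optimum
   (5.5 kW m⁻² d⁻¹, 27 °C) with Gaussian weights, which scales the
   sustainable density `Kc` between 0 and the architectural maximum `K`.
5. Whenever `ΣZ` exceeds `Kc`, the excess is shed at a rate proportional to
   the relative excess, capped at 1, identically across types (random,
   non-selective loss).
6. Densities are continuous; there is no demographic stochasticity and no
   extinction threshold, so multiplicative dynamics keep strictly positive
   densities positive.

Stochasticity enters in exactly one place: at every step, every type's
pair of optima is redrawn from `Normal(optimum, niche SD)` using per-type
random substreams. A generalist's realised optimum therefore wanders more
than a specialist's — phenotypic variance acts both through the width of
the response curve and through this step-to-step lability.

## Calendar

Months are consecutive 30-day blocks and a year is 360 days; 10-year runs
are 3600 daily steps. The warming scenario adds +1.0 °C over days 181–210
(July), +1.5 °C over 211–240 (August) and +1.0 °C over 241–270 (September),
by default in every simulated year; a `random_years(probability)` mode is
available and selects years reproducibly from a seed.

## Parameters

| Symbol | Meaning | Default | Source |
|---|---|---|---|
| SI/SST optima | type optima, 4 types | 5.5/28, 5.5/26.5, 4.5/28, 4.5/26.5 | published |
| α_i | SI niche SDs | 0.4, 0.8, 0.4, 0.8 | published |
| β_i | SST niche SDs | 0.4, 1.0, 0.4, 1.0 | published |
| R_i | resource requirement | 1 (all types) | published |
| Z_i(0) | initial densities | 1.0×10⁶ cells cm⁻² | published |
| hSI, hSST | host optima | 5.5, 27 | published |
| γ, w | host SDs | 2.0, 3.0 | published |
| C1 | resource coefficient | 0.01 | published |
| K | maximum capacity | 5×10⁶ cells cm⁻² | chosen (order of 10⁶ cells cm⁻² of tissue × four resident types) |
| C2 | growth coefficient | 3.0 | calibrated (below) |
| C3 | loss coefficient | 1.0 | chosen (sheds the full excess over Kc in one day) |

### Site forcing defaults

The sinusoid coefficients per site are **calibration defaults**, not
published values (the source climatologies exist only as figures). They
were chosen once to emulate subtropical Atlantic conditions and the
stable-vs-variable contrast between the two localities:

| Site | SST mean ± amp | SI mean ± amp | peaks |
|---|---|---|---|
| `lee_stocking` | 27.2 ± 2.3 °C | 5.8 ± 1.0 kW m⁻² d⁻¹ | SI day 166, SST day 245 |
| `key_largo` | 26.5 ± 3.5 °C | 5.2 ± 1.6 kW m⁻² d⁻¹ | same |

The June insolation peak leading the early-September temperature peak by
~80 days matters: mid-summer combines excess insolation and excess warmth
(low `Kc`, high loss), while autumn — when SST relaxes through the
high-temperature specialists' 28 °C optimum and the post-stress resource is
plentiful — is the specialists' recovery window. That phase structure, not
any single coefficient, produces both the December–April density maxima
and the warming-driven specialist gains.

### Calibrating C2

`C2` (with `C3` and `K`) is not published; it sets how fast growth-rate
differences compound into abundance differences. It was swept once over
{2, 3, 4} on 20-replicate ensembles against the qualitative predictions the
model must reproduce: type 2 top-ranked at the stable site; generalists
occupying the two top ranks at the variable site; the specialists' summed
relative abundance strictly increasing under the warming overlay; the
rarest type's final-year mean below 1 cell cm⁻² yet never exactly zero;
and annual density maxima in December–April in ≥ 8 of 10 years. `C2 = 2`
leaves the rarest type at ~8 cells cm⁻² (divergence too slow) with a flat
warming response; `C2 = 3` satisfies every condition robustly across master
seeds and is the shipped default; `C2 = 4` also passes but pushes rare
types to numerically extreme rarity. These checks are re-run by the test
suite at the defaults.

## Numerical choices

- Step size Δt = 1 day, matching the day-denominated units of the rates;
  `horizon_days` must be a whole number of steps.
- Per-type random substreams are keyed on the *label* (CRC-32), derived
  from one master seed, so permuting or extending the trait table never
  perturbs other types' draws; ensembles derive replicate seeds from one
  master seed. Runs are bit-reproducible; with all draw SDs set to 0 they
  are seed-independent.
- The loss cap `min(1, ·)` plus non-negative growth guarantees
  `Z_i ≥ 0` without clamping; the update is exactly
  `Z(1 + μ − μ_loss)`, and trajectories record `μ_i` and `μ_loss` so the
  identity can be replayed on the stored arrays bit-for-bit.
- Sinusoid fitting is linear least squares on `[1, sin ωt, cos ωt]` at the
  fixed annual frequency (mid-month sample placement), converted to
  amplitude/phase; a constant series fits amplitude 0 with a warning,
  < 4 points is an error.
- Dominance ranks break ties by trait-table order; final-year statistics
  use the last 360 recorded days (`horizon − 360 ≤ day < horizon`).

## Design choices where the design was open

- **Draw SDs vs niche widths.** The published conditions list one SD per
  driver per type, used both as the Gaussian response width and as the SD
  of the per-step optimum draws. The two roles are therefore one field by
  default, with separate `si_draw_sd`/`sst_draw_sd` overrides so degenerate
  (deterministic) runs remain expressible while niche widths stay positive.
- **Both drivers in Kc.** The host envelope is given two SDs (2.0, 3.0),
  so `Kc` depends on both SI and SST; the host acts *only* through `Kc`,
  not as an extra factor in `μ_i`.
- **Gaussian factors multiply** (independent requirements on the two
  drivers), rather than add.
- **Loss is environment-independent given Kc** — temperature affects loss
  only by lowering `Kc`.
- **"Dominance"** is operationalised as the rank of final-year mean
  relative abundance; **"emergence"** as the median share crossing the
  ~5% field-detectability level (configurable threshold).
- **Ensembles are the analysis surface** (default 20 replicates): single
  trajectories are noisy because optima are redrawn every step.
- **Warming applies every year by default**; the random-years
  interpretation is retained as an option.
- **Specialist gain under warming** is assessed on the summed share of the
  two specialist types (per replicate, then ensemble median); per-type
  medians are reported alongside.

## The synthetic climatology generator

`symshuffle.synth` emulates monthly climatology tables (12 mid-month
samples of a sinusoid plus i.i.d. Gaussian noise) for exercising the
fit → simulate pipeline without any external data. It reproduces the
seasonal mean cycle only: no interannual variability, no skewness or
autocorrelation in the residuals, no trend. Passing the fit-recovery tests
therefore shows the estimator is correct for sinusoid-plus-noise data, not
that real satellite climatologies are that well behaved.

## Limitations

- Nutrients are excluded; the resource-allocation step is the documented
  extension point for a nutrient term.
- Phenotypic variance is Gaussian; log-normal variants, selective loss, or
  Weibull/exponential loss-recovery kinetics are not implemented.
- No spatial structure (micro-irradiance partitioning within a colony) and
  no host demography.
- Because `C2`, `C3`, `K` and the site coefficients are calibrated, only
  the *qualitative* community patterns are meaningful predictions; exact
  densities are not comparable to field measurements.
- Test problem sizes (10-year horizons, 20-replicate ensembles) are the
  package's working defaults; conclusions at much longer horizons would
  need re-examining the accumulation of floating-point rarity (densities
  can underflow after centuries of decline).
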