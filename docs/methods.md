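# Methods

## Day axis and anchors

All computations run on an integer day index with 1 = 1 September of the
year preceding budburst and a fixed 365-day year (the season modelled never
crosses a leap day). Day of year of the budburst year is `DOY = index − 122`.
Fixed anchors: 1 November = 62 (Alternating-model chilling start),
1 December = 92 (warming treatments switch on), 1 January = 123
(Alternating-model forcing start), 22 February = 175 (transfer between
chambers), 30 June = 303 (prediction horizon). The axis starts in autumn
because the Unified model accumulates chilling from 1 September.

## Climate generator

Daily mean temperature is an annual sinusoid plus stationary AR(1) noise:

    T_d = µ − A·cos(2π(d − d_cold)/365) + ε_d,
    ε_d = φ·ε_{d−1} + η_d

with defaults µ = 9.6 °C, A = 7.4 °C (so monthly means span 2.2 °C in
January to 17.0 °C in July), d_cold = 137 (15 January), φ = 0.7 and a
marginal noise SD of 3.0 °C — day-to-day persistence typical of maritime
mid-latitude weather. The sinusoid-plus-AR(1) form is a modelling choice;
only the climatological normals it reproduces are observational.

Chamber treatments are piecewise-constant offsets: the winter offset
applies on [1 Dec, 22 Feb) and the spring offset from 22 February
(inclusive — saplings were moved that day, so its exposure is post-move)
to the end of the series. Treatment codes follow the WxSy convention
(x °C in winter, y °C in spring).

## Model day loops

Shared conventions, pinned by unit tests:

* The first day of an accumulation window contributes its full daily rate
  (a constant forcing rate of 1 FU/day with F\* = 10 crosses on the 10th
  day, counting the start day as day one).
* Forcing begins on the same day the chilling requirement is first met
  (trigger without lag), for the Sequential and Unified models.
* The chill-day inequality is strict: a day with mean temperature exactly
  at T_c accumulates nothing.
* Forcing sigmoids are written with a leading minus and positive slope
  parameters, so they increase with temperature by construction; this is a
  reparameterization of the historical negative-coefficient forms.
* The Alternating model re-evaluates its forcing requirement
  a + b·exp(c·S_c) daily against the running chill-day count; its start
  days are fixed (1 November / 1 January) rather than calibrated, and the
  end of its chilling period coincides with budburst itself, so it has no
  free day parameters even though the conventional parameter count (used
  in AIC) remains 8.
* The Parallel model's competence multiplier is
  K_f(S_c) = K_m + (1 − K_m)·min(S_c/C\*, 1), applied to the same-day
  sigmoid forcing rate; chilling and forcing both start at the series
  origin (1 September), as neither model exposes a start-day parameter.
* The Unified model's F\* = w·exp(k·S_c(t_2c)) is fixed by the chilling
  accumulated up to day t_2c (rounded, clamped into the series support).
* A prediction that never reaches F\* by 30 June is returned as `None` —
  a first-class outcome, not an exception. During scoring it is replaced
  by the horizon day (index 303) and flagged, so error metrics remain
  finite while chilling-failure misfits are penalized heavily.
* Exponent arguments are clamped to ±700 before `exp` to avoid overflow.

Every model has two implementations: a vectorized day loop (cumulative
sums and threshold searches) used everywhere, and a deliberately naive
one-day-at-a-time reference loop kept as an independent oracle. The test
suite checks exact agreement of the predicted day on hundreds of random
parameter draws and weather years per model.

## Calibration

Random-walk Metropolis–Hastings with flat priors on per-parameter boxes
(zero outside), so acceptance reduces to a likelihood ratio. The
likelihood is Gaussian on budburst-day residuals with a common standard
deviation σ (days); σ is not part of any model and is calibrated as a
nuisance parameter with flat prior on (0.1, 20] days (fixable via config).
A proposal for which any treatment's prediction is `None` has likelihood
zero and is rejected.

Defaults: 50 000 iterations with 10 000 burn-in (tests and the acceptance
script use 15 000–20 000 with 5 000–6 000 burn-in, which the recovery
experiments show is ample at these problem sizes); per-parameter proposal
SD of 5% of the prior range, rescaled every 200 iterations during burn-in
only (×0.7 below 20% acceptance, ×1.4 above 50%), so the post-burn-in
kernel is a fixed, valid MH transition. The start point is the best of up
to 100–200 uniform prior draws with finite likelihood. Day-valued
parameters (t_1f, t_2c) are proposed continuously and rounded only inside
the model evaluation, keeping the walk on a connected support. The
ordering T_min < T_opt < T_max is enforced by rejection.

Shipped prior boxes (°C for temperatures, day index for days): e.g.
T_b ∈ [−5, 15], F\* ∈ (0, 500] FU, C\* ∈ (0, 200] CU, t_1f ∈ [62, 203],
sigmoid slopes in sign-constrained boxes, AM's c ∈ [−1, 0), UM's k ∈
[−0.2, 0]. The T_min/T_opt boxes are wide enough to admit chilling
responses whose optimum lies below the observed winter range (see the
birch generator note below).

## Evaluation

RMSE and model efficiency (Nash–Sutcliffe) are computed on whatever set
the validation mode designates: the calibration data (internal) or a
held-out half (external). The external split is random, seeded, and
stratified by treatment so every treatment appears in both halves;
singleton treatments go to the training half. AIC = t·ln(rss/t) + 2(p+1)
uses the conventional parameter count p of each model and is computed only
for whole-dataset fits; a perfect fit (rss = 0) raises a dedicated error
and is reported as undefined rather than −∞. One calibration per species
throughout; cross-species pooling is unsupported.

The sensitivity analysis computes, per species, the least-squares slope of
treatment-mean budburst advancement (days, negative = earlier) on the mean
warming delta experienced from 1 December to the treatment's mean budburst
day; the regression is unweighted through treatment means, and the control
enters as (0 °C, 0 days) by construction.

## Synthetic experiment generator

The generator reproduces the experiment's structure: seven treatments
(W0S0, W6S0, W0S6, W6S6, W2S0, W2S2, W2S6) with transfer on 22 February;
four chambers per treatment with a Gaussian chamber offset (SD 0.3 °C,
consistent with chambers holding warming within a few percent); three
saplings per chamber (12 per treatment, 48 per species over the four main
treatments); per-sapling Gaussian date jitter (SD 2 days, rounded); and
forward censoring to a fixed 2-day monitoring grid starting 1 February
(the real protocol alternated 3- and 2-day visits by bud stage; a single
interval keeps the generator simple and is configurable). Generation
metadata records the true model, parameters and seeds; calibration never
reads it.

Each species carries a true Sequential-model parameterization. Chilling
requirements follow the established 120/100/50 chill-day ordering for
beech/oak/birch. The remaining parameters were tuned once, against the
default climatology, so that control budburst falls mid-May (beech),
early May (oak) and mid-April (birch), generated per-species date ranges
bracket the spans observed in the chamber experiment (birch DOY 60–95,
oak 78–125, beech 95–140), every warmed treatment advances budburst, and
per-degree sensitivity to spring warming exceeds winter warming:

| species | T_min | T_opt | T_max | a | b | c | C\* | F\* |
|---|---|---|---|---|---|---|---|---|
| beech | −25 | 4 | 34 | 0.4 | 8 | 1 | 120 | 45 |
| oak | −20 | 3 | 26 | 0.4 | 8 | 1 | 100 | 37 |
| birch | −60 | −10 | 21 | 0.2 | 9 | 1 | 50 | 28 |

Beech and oak use broad triangular chilling responses (breadth scaling
with the requirement) so dormancy release stays achievable in every warmed
treatment. Birch is special: with a small chilling and forcing budget, any
steep warm-side forcing response lets +6 °C winters blow far past the
forcing requirement by January. The only Sequential-model configuration
found that keeps birch realistic places the chilling optimum below the
winter temperature range, so only the declining limb of the triangle is
active: chilling efficacy decays gently with temperature, the dormancy
gate opens in January with a modest, stable warming-induced delay, and a
moderately steep forcing sigmoid then produces strong spring sensitivity
without a winter blow-up. This is a generator design choice, not an
inference about real birch.

A second scenario, `beech_stress_design`, narrows the chilling response
(T_max = 14 °C) and sets C\* = 70 so that the chilling requirement binds:
winter-warmed chambers release dormancy weeks late or not at all, winter
warming can delay budburst outright, and continuous warming can end up
later than spring-only warming — a pattern a pure degree-day model cannot
reproduce, which is what makes the model-selection experiment
discriminating. In roughly a quarter of weather years the +6 °C winter
never satisfies C\* before the horizon; the generator then raises a design
error, and consumers draw another weather year (the scenario is defined
only where budburst is observable).

What the generator does **not** emulate: photoperiod and light-quality
effects (never formalized in the models), provenance/genotype variation,
sub-daily temperature structure, soil moisture, and bud-stage progression
(only the stage-3 onset date is produced). Passing tests therefore show
that the workflow recovers and discriminates the models' own mechanisms
under realistic noise — not that these models are correct for real trees.

## Problem sizes and numerical choices

The test suite and acceptance script run chains of 15 000–20 000
iterations (5 000–6 000 burn-in), 10 replicate weather years for the
model-selection experiment, and 100 parameter draws × 10 weather years per
model for the oracle-equivalence sweep; these sizes were chosen as the
smallest at which the recovery and selection results are stable.
Threshold crossings use `searchsorted` on non-decreasing cumulative sums,
matching the reference loop's `>=` semantics exactly. Ties in the
maximum-likelihood sample are broken by earliest iteration. CSV output is
written at full float precision and read back with round-trip parsing.

## Known limitations

* The Metropolis–Hastings sampler ships no convergence diagnostics beyond
  the acceptance rate; chains are exported as CSV for external diagnosis.
* Parameters of the richer models (PM, AM, UM) are only weakly identified
  by 48–84 observations; prediction quality, not parameter equality, is
  the meaningful recovery criterion.
* AIC uses the conventional parameter counts (3/8/9/8/9) even where fixed
  anchors reduce the effectively calibrated dimension (AM), and no
  small-sample correction is applied.
* The generator's truth is always a Sequential model; conclusions about
  relative model performance on synthetic data inherit that choice.
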