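# Methods

This note records the model equations as implemented, the defaults and
why, the choices made where the underlying literature leaves the design
open, and what the tests do and do not demonstrate.

## Time stepping and state

The simulator advances an individual animal in monthly steps of 30.4
days. State is (age in years, body weight in kg, lactation month with 0 =
dry, days of gestation with 0 = open, parity). Within a step all rates
are treated as constant daily rates; body weight is updated once per step
(monthly Euler): BW ← BW + actual_gain × 30.4. A five-month run therefore
covers 152 days; runs meant to represent "140 days postpartum" are
simulated as five whole steps, the convention kept deliberately. Finer
within-month integration is out of scope.

## Potential growth

Potential daily gain follows a Gompertz curve,
dBW/dt = μ₀·BW·ln(BW_f/BW)/ln(BW_f/BW₀), with μ₀ = 0.015 d⁻¹ for cattle,
BW₀ the birth weight and BW_f the mature weight, taken as 90% of the
genetic maximum because cattle under (sub-)tropical feeding rarely reach
their genetic final weight. The rate is capped at 1.2 kg/d. The closed
form BW(t) = BW_f·exp(−ln(BW_f/BW₀)·e^{−μ₀t/ln(BW_f/BW₀)}) is used for
weight-for-age trajectories; a numerical-integration oracle in the tests
confirms the closed form.

## Potential lactation

y(n) = n/(a·e^{kn}) with a = 1/(peak·(1/T)·e) and k = 1/T needs only the
peak yield and its month T; the curve attains its maximum, equal to the
peak, exactly at n = T (verified against a brute-force grid maximisation).
Months are integers; outside (0, lactation_length] the yield is zero.

Potential milk enters requirements and partitioning multiplied by two
hooks, an age factor and a body-condition factor
(`run_simulation(..., milk_age_factor=, condition_scales_milk=)`). Both
default to the identity: the functional form of the age/body-condition
milk modifiers used in earlier herd simulators is not published in a
reproducible form, and in this model the body-condition index already
regulates performance through intake. Enabling `condition_scales_milk`
multiplies potential milk by the condition index; in calibration runs this
consistently worsened the reproduction of the evaluation dataset (mid-
lactation milk collapses because both intake and the milk ceiling shrink
together), so it is off by default.

## Requirements

* Maintenance: ME_m = b·BW^0.75, b = 0.631 MJ/kg^0.75/d for adults and
  0.53 for calves. The calf/adult boundary is age < 1 year (the source
  systems define "calf" only loosely; the boundary only matters for young
  stock scenarios).
* Lactation: ME_l = y_pot·(0.041·fat + 1.51)/k_l, fat in g/kg milk,
  k_l = 0.60 for crossbreds and 0.53 for *B. indicus*.
* Activity: ME_a = (2.6·BW·horiz + 28·BW·vert)/10⁶/0.7, distances in
  m/day. Stall-fed scenarios use zero distances.
* Gestation: ME_g = 0.044·e^{0.0165·d}/0.2, counted only during the last
  eight weeks before term (term defaults to 280 days; d is days since
  conception).
* Gain: ME_pf = (NE per kg gain)/0.4 × potential gain, with the NE per kg
  (and net protein per kg) taken from age-knot tables for female/male ×
  crossbred/*B. indicus* cattle, linearly interpolated between the knots
  {0, 0.1, 1.5, 3, 4.5, 5.5, 20} years and constant beyond. Negative
  potential gain contributes no requirement.
* uCP: uCP_pf = (net protein per kg gain)·gain·2.1. The maintenance,
  lactation and gestation components use coefficient stand-ins in the
  style of the German (GfE) system — 3.9 g/kg^0.75/d, 85 g/kg milk and
  135 g/d in late gestation — because the full formulas require dietary
  inputs outside this model's scope. The uCP balance is reported in every
  trace but never constrains intake or performance; treat the uCP columns
  as descriptive.

## Voluntary intake

DMI_raw = (NDF_capacity/NDF_diet + ME_total/ME_diet)/2 blends a physical
(rumen fill) and a physiological (energy demand) limit; NDF_capacity =
0.0135·BW. The ME_total entering the blend is the *potential* requirement
(from potential gain and potential milk), so the raw value is scaled once
by the body-weight condition index,
CI = (BW − BW_min(age))/(BW_max(age) − BW_min(age)) clamped to [0, 1],
and finally capped by the feed offered. The envelope bounds BW_min and
BW_max are Gompertz weight-for-age curves from the birth weight toward
the breed's minimum mature weight and toward 0.9 × the genetic maximum,
keeping the envelope consistent with the growth model. At age 0 the two
bounds coincide at the birth weight and the index is undefined
(`DegenerateEnvelopeError`); simulations start at post-birth ages.

## Partitioning and mobilization

Obligations are served in the order maintenance → activity → gestation
(performance MEI is defined net of these three). Of the surplus, the
lactation-stage fraction goes to milk — early (months 1–3) 100%, mid 85%,
late (last 3 months) 74% on forage-only diets; 100/88/80% when the ration
contains concentrate — capped at the energy cost of potential milk, with
any spill-over routed to gain at the age-specific cost of gain.

Body-reserve mobilization is limited to 0.23% of BW per day. In early
lactation, if MEI-funded milk falls short of 60% of potential, reserves
top milk up to that 60% target (milk already funded by MEI is not capped
below potential). If MEI is below the obligations, reserves cover the
deficit first — survival before milk, against the same shared daily cap —
and outside early lactation milk ceases entirely when MEI is below
maintenance. Mobilized tissue releases the same age-specific net energy
that deposition costs (symmetry; no separate tissue energy density is
published for this model) at an efficiency of 0.84. For milk, the credit
is converted to ME units by dividing by k_l so that the ledger
MEI + mobilized_ME = Σ allocations closes to 1e−9; for survival the
credit offsets the ME deficit directly — a deliberate simplification,
since the source system publishes no reserve-to-maintenance efficiency.
Actual gain = ME_to_gain/(ME per kg gain) − mobilized BW, and is not
separately capped (the 1.2 kg/d ceiling applies to the potential, which
bounds the requirement that drives intake).

## Evaluation statistics

MBE = Σ(obs − pred)/q (negative = over-prediction), RMSEP =
√(Σ(obs−pred)²/q), RPE = 100·RMSEP/mean(obs); q is the number of
treatment pairs. Accuracy classes by RPE: excellent < 10%, good 10–20%,
fair 21–30% (closed at the printed interval ends), poor > 30%. RMSEP ≥
|MBE| always (Cauchy–Schwarz; property-tested).

## Bundled evaluation scenarios and calibration

The two fixtures describe multiparous crossbred (B. indicus × B. taurus)
cows from an Ethiopian stall-feeding trial: 415/432 kg at calving, age
5.2 y, 10-month lactation peaking at 20 kg/d in month 2, milk fat
46.3/46.6 g/kg, on maize–lablab stover (9.4 MJ ME, 550 g NDF/kg DM) or
oats–vetch hay (9.6 MJ ME, 610 g NDF/kg DM), fed ad libitum, five monthly
steps, zero activity. The trial does not report the breed's birth weight
or envelope weights. Birth weight is set to 30 kg (typical for such
crosses). The envelope anchors — min_mature_weight = 165 kg,
max_attainable_weight = 535 kg — were recovered by calibrating the
five-step simulation against the trial's published treatment means (the
same role breed-literature envelope data play in the original herd
simulator); they are exposed in the YAML files for overriding, and both
the growth cap and the Gompertz μ₀ are left at their defaults.

With these defaults the maize–lablab run reproduces the published
modified-model treatment means to within 2% (mean DMI 10.1 vs 10.2 kg/d,
final BW 378.7 vs 385 kg, mean milk 8.2 vs 8.1 kg/d).

## Known limitations

* **Oats–vetch intake is over-predicted** (~10.7 vs 9.6 kg DM/d, with
  correspondingly high final BW and milk). This is structural: the
  condition index is a monotone function of body weight under a single
  breed envelope, so the heavier oats–vetch cow necessarily receives an
  intake multiplier at least as large as the maize–lablab cow's, while
  her published predicted intake is ~6% *lower*. No envelope choice can
  satisfy both treatments simultaneously; reproducing the published
  oats–vetch run would require unpublished internals (e.g. the original
  age/body-condition factor). The maize–lablab treatment was therefore
  prioritized in calibration.
* uCP components other than gain are stand-ins and protein never limits
  performance.
* Single-animal scope: no reproduction/conception, herd structure,
  culling, or manure/greenhouse-gas accounting.
* The synthetic-scenario generator draws uniformly over realistic
  (sub-)tropical ranges (BW 150–550 kg, diet ME 6–12 MJ/kg DM, NDF
  0.35–0.75 kg/kg, peak milk 5–25 kg/d, lactation 8–12 months) but is
  not conditioned on joint realism (e.g. a heavy cow on a very poor
  diet); it exists to exercise invariants, so passing property tests
  demonstrates internal consistency, not predictive accuracy on real
  herds.

## Problem sizes

The default test suite simulates at most a few hundred five-to-twelve-step
scenarios and evaluates closed-form expressions elsewhere; the full suite
and the acceptance script each complete in seconds on one CPU.
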