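# Methods

This note documents the model, its conventions and the design choices
made where the methodology was genuinely open, in the package's own
terms.

## Projection model

The engine is a deterministic expected-value (cohort-component) Markov
projection, not a stochastic microsimulation: cell counts are expected
persons, so identical inputs give bit-identical trajectories and exact
regression tests. The joint state space is sex × age (single years
0–95) × smoking state (never/current/former) × COPD (no/yes); with two
sexes this is 2·96·3·2 = 1152 cells, advanced by dense vectorised
updates.

**Cycle order.** Within each annual cycle the engine applies smoking
transitions, then COPD incidence (using post-transition smoking
states), then mortality, then ageing with newborn entry. The order is
a convention: alternative orders change results only at the order of
rate products (O(rate²)), which is negligible at annual cycles with the
rates involved (≤ a few percent per year for most ages). It is fixed
and tested rather than configurable.

**Age range.** Inputs span ages 0–95. Survivors of the age-95 cycle
leave the projected range; the open-ended remainder of life enters only
the life-expectancy tail (below). Consequences: the projection slightly
understates very-old-age burden, and COPD prevalence among 95+ is not
tracked.

**Structural age floors.** Smoking initiation is possible from age 11,
cessation from 16, restart from 22, COPD from 40. These floors are
enforced as input invariants (validated at load) and preserved by the
dynamics (a zero rate stays zero after any scenario scaling, because
the adjustment is multiplicative).

**Rate decomposition and freezing.** Population-average COPD incidence
and all-cause mortality are split into state-specific rates by the
attributable-risk identity i_never = total / (p_n + p_c·RR_c +
p_f·RR_f), i_k = RR_k·i_never, evaluated with the *reference* smoking
distribution at each (sex, age). The weighted average then reproduces
the inputs to machine precision (tested at 1e−12). The same frozen
rates are reused in intervention runs, so scenarios differ only through
smoking-state occupancy — the intervention's stated mechanism. Relative
risks are interpreted as current-vs-never (the data sources do not
distinguish current-vs-never from current-vs-nonsmoker; the choice is
documented here rather than hidden).

**COPD and mortality coupling.** COPD confers no mortality beyond the
smoking-mortality pathway: death probabilities depend on smoking state
only, identically for COPD yes/no. Life-expectancy gains therefore
arise from reduced smoking-attributable mortality, and COPD burden
changes arise from reduced state-specific incidence exposure. COPD has
no remission. Smoking behaviour is independent of disease status.

**Initialisation.** Baseline COPD prevalence is distributed
independently of smoking state within each (sex, age) cell (the same
prevalence applied to never, current and former smokers). No published
convention exists for this initial cross-classification; independence
is the neutral choice and only affects the early-horizon COPD-free
life-expectancy split, not incidence or mortality.

## Intervention mechanics

A scenario is a one-time price increase of P% applied before year 0.
With age-banded elasticity ε(a) (default bands: 11–18 → −1.5, 19–29 →
−0.75, 30–95 → −0.5; the band edges are inclusive and the adult band is
read as ≥ 30 so no age is uncovered):

* baseline never- and former-smoker prevalences are multiplied by
  1 + |ε(a)|·P/100 and current smoking becomes the complement to 1 —
  the elasticity is a *relative* (multiplicative) effect, consistent
  with its definition as percentage change in consumption per 1% price
  change;
* initiation and restart probabilities are multiplied by
  1 − |ε(a)|·P/100, cessation by 1 + |ε(a)|·P/100, clamped to [0, 1]
  (cessation can exceed 1 at a 50% price rise in the youth band).

**Capping.** If scaled never+former would exceed 1 (possible at large
P with ε = −1.5), both are rescaled proportionally — preserving the
never:former ratio — and current smoking is set to 0. This keeps the
complement rule exact while guaranteeing a probability vector; it is
this package's convention for a case the source methodology leaves
unspecified.

Ages below 11 are outside every elasticity band and never adjusted
(never-smoking is 1 there by construction). A 0% price increase returns
the input bundle exactly, bit for bit.

## Life expectancy

Cohort life expectancy at baseline age A follows the closed (A, sex)
slice of the bundle — no newborns — through 95 − A annual cycles, i.e.
over ages A..94. Weighted person-years per cycle use the trapezoid of
start- and end-of-cycle weighted occupancy, which equals the standard
half-cycle correction (deaths contribute half a year). Weights per
COPD state: 1/1 (overall), 1/0 (COPD-free), 1/(1 − DW)
(disability-adjusted, DW the disability weight). Survivors reaching
their 95th birthday receive a terminal tail of 1/m(95, sex) expected
remaining years — the mean of a geometric lifetime under a constant
hazard — weighted by their final COPD state; the tail is zero when
m(95) = 0, so with zero mortality life expectancy truncates exactly at
95.0. Without the tail, a 20-year-old's life expectancy would be
truncated noticeably below realistic values (~80 years).

The disability weight has no canonical published value for this
analysis; it is a required input defaulting to 0.2, and all
disability-adjusted outputs should be read as conditional on it.

**Reported calendar.** Years are indexed 0..T with labels
base_year..base_year+T (default 2018–2058); "after 10/20/40 years"
means indices 10/20/40. COPD incidence is undefined for the final year
(the last state has no following event year); the last reported
incidence is at index T−1.

**Denominators.** Reported smoking and COPD prevalences and incidence
rates use whole-population (all-age) denominators; overall COPD levels
around 1% and 1.5/1000 person-years are only meaningful on that scale.
Incidence person-years are mid-year population (start-of-year alive
minus half the deaths).

## Costs

Cost savings are `cases_saved × (annual_cost + productivity_cost) ×
duration`, undiscounted, with the defaults used in the worked examples:
5,700 EUR direct management cost per patient-year and 10 years lived
with disease, plus country-specific annual productivity losses where
known. These are indicative magnitudes, not a health-economic model:
no discounting, no age-at-incidence weighting, no cost trend.

## Synthetic data generator

The generator emulates the statistical structure of national inputs:

* **Mortality**: Gompertz m(a) = α·e^{βa} plus small infant and
  background components, capped at 0.7/year. Defaults (α = 3.2e−5 /
  1.7e−5, β = 0.095 / 0.098 for males/females) give period life
  expectancies of ≈ 76.5 and ≈ 80.7 years, inside the realistic 70–90
  envelope asserted by the tests.
* **Population**: pyramid proportional to survival times
  (1 + g)^{−a}, where g ("pyramid shape") is a historical birth-growth
  rate; newborn inflow is held at the age-0 cohort size. Total
  population defaults to one million.
* **Smoking**: initiation is a Gaussian pulse centred at age 16 with a
  slow late-uptake tail fading by ~58; cessation is low in mid-life and
  rises steeply after ~48; restart decays exponentially from age 22.
  Prevalences are obtained by *age-marching a birth cohort through
  these transition probabilities*, so baseline prevalences are
  internally consistent with the rates (reference-scenario drift then
  reflects demography and differential mortality, not inconsistent
  inputs). Initiation is rescaled in a short fixed-point loop so the
  mid-life current-smoking peak hits the target (default 20% for
  males, 85% of it for females, peaking in the 40s); overall current
  smoking lands near 13%, inside the observed 2018 European country
  range of 10.6–17.5%.
* **COPD**: incidence is zero before 40 and rises exponentially with
  age, plateauing in very old age (slope 0.09/year, capped at 1.2× the
  age-80 level of 0.01/year), giving ≈ 1.6 cases/1000 person-years
  overall; prevalence is a power curve in age calibrated so the
  overall level is ≈ 1%, bracketing the observed 0.9–1.3% range. The
  initial prevalence and incidence are *independent* inputs, as in
  real surveillance data; with absorbing COPD and no excess mortality
  the simulated prevalence drifts upward early in the projection,
  mirroring the ageing-driven plateau seen in real projections.
* **Relative risks**: smoking-on-COPD RRs per sex and the age bands
  40–59/60–79/80–95, jittered within the published range
  [8.13, 19.83]; smoking-on-mortality RRs fixed at 2.07 (males) and
  1.74 (females). Former-smoker RRs are not separately published and
  default to 1 + 0.5·(RR_current − 1) — halfway between never and
  current — as an explicit, exposed convention.
* **Regions**: transition probabilities are generated for a "north"
  and a "south" variant (south: 15% higher initiation, 15% lower
  cessation); a bundle's region tag selects the slice used throughout.
  Three illustrative profiles (italy-like, england-like, sweden-like)
  vary region, smoking level, pyramid shape and size; they are
  qualitative contrasts, not calibrated countries.

All randomness flows from one `numpy` generator seeded once; a fixed
seed yields byte-identical bundle files. Random jitter applies only to
scalar curve levels (lognormal, σ = 0.04), never per-age, so the
monotonicity and unimodality properties hold for every seed.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: cohort effects in smoking uptake
(older generations' higher historical smoking), migration, smoking
intensity, period trends in cessation, reporting error in surveillance
inputs, and the correlation structure of real national registers.
Tests on synthetic bundles validate the *mechanics and invariants* of
the method (conservation, calibration identities, monotone dose —
response, oracle equivalence), not country-specific magnitudes.

## Numerical choices

* Transition inputs are annual probabilities in [0, 1], not
  instantaneous rates; no exponential conversion is applied.
* Prevalence files store proportions in [0, 1]; percent conversion
  happens only at reporting time.
* CSV round-trips write 17 significant digits; load∘write is identity
  to ≤ 1e−12 and byte-deterministic.
* Sum-to-one of smoking states is validated at 1e−9; population
  bookkeeping (alive(t+1, a+1) + deaths(t, a) = alive(t, a)) holds to
  1e−9 relative and is tested over 100 random bundles.
* The engine raises on negative counts beyond float residue (which is
  structurally impossible and covered by tests); residues below
  1e−9·population are clipped to zero.
* Empty cells in the rate decomposition (zero denominator) yield zero
  rates rather than NaN.

## Problem sizes

The default study conditions are a one-million-person population
projected over a 40-year horizon, scenarios {0, 5, 10, 20, 30, 40,
50}% with the banded default and uniform −0.5 elasticity schedules, and
cohort life expectancies at baseline ages 20/40/60 for both sexes.
A full seven-scenario sweep takes well under a second; the dense
matrix-oracle test powers a 1152×1152 one-year matrix over 40 years.

## Known limitations

* Expected-value propagation gives no uncertainty intervals; parameter
  uncertainty would need an outer sampling loop.
* One-time price shocks only; annual repeated increases, income
  dynamics, illicit trade and e-cigarette substitution are out of
  scope.
* COPD excess mortality is not modelled (a deliberate restriction to
  the smoking-mortality pathway); COPD-free and disability-adjusted
  life expectancies are therefore driven by incidence exposure, not by
  differential survival with disease.
* The synthetic profiles are illustrative; absolute country magnitudes
  (e.g. national cases-saved counts) require real national inputs,
  which the package reads from its CSV bundle format.
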