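# Methods

## Model structure

The cohort model has four health states — waitlisted for a kidney (on
dialysis), transplanted, post-graft-failure dialysis, and death — evaluated
in one-year cycles over a 20-year horizon for a closed cohort of 1000
patients, all waitlisted at time zero. Death is absorbing; graft failure is
permanent (no re-listing or re-transplantation), so a failed graft commits
the patient to dialysis until death.

Graft failure and post-transplant mortality are fitted on the
time-since-transplant clock, so the transplanted state is expanded into
*tunnel states* indexed by years since transplant (1 … horizon). The
transplant probability from the waitlist uses model time, which coincides
with time since listing for this cohort. Recipient age is held at 50 years
throughout (no within-model ageing): the analysis age is a fixed covariate
value, not an evolving attribute. We verified that ageing the cohort
(age = 50 + cycle) degrades agreement with the reference league table and
breaks the dominance pattern, and rejected it.

### Transition probabilities

Time-dependent transitions use a Weibull proportional-hazards law with
cumulative hazard H(t) = λ·e^{β·age}·t^γ. The conditional probability of
the event in cycle *t* given event-free survival to *t−1* is

    tp(t) = 1 − S(t)/S(t−1) = 1 − exp(λ·e^{β·age}·[(t−1)^γ − t^γ]),

the standard decision-modelling construction for Weibull transitions; it
lies in [0, 1] for any λ, γ > 0 and chains to the closed-form cumulative
risk 1 − exp(−λ·e^{β·age}·T^γ) (property-tested to machine precision). The
age covariate enters uncentred (e^{β·age}, not e^{β(age−ā)}); no centring
constant is published and the calibration below absorbs the choice.

Waitlist mortality (0.0184/year) and post-graft-failure mortality
(0.1091/year) are fixed annual probabilities, identical across strategies,
derived from cumulative incidences by the rate chain r = −ln(1−p)/T,
p_annual = 1 − e^{−r}.

Competing exits from a state (transplant vs death on the waitlist; graft
failure vs death in a tunnel) are applied as independently computed annual
probabilities. If their sum ever exceeded 1 they would be proportionally
rescaled with a warning; with the shipped parameters the sum never
approaches 1.

### Parameter set

The packaged defaults (`src/renalloc/data/default_parameters.yaml`) encode
the Weibull (λ, γ, β_age) triples per strategy and transition with their
standard errors, the shared fixed probabilities, 2018-AUD costs and
utilities, for the Australian deceased-donor programme (registry-era
estimates, 2007–2017).

One value is deliberately corrected: the current-practice graft-failure age
coefficient is distributed as +0.020, while the four allocation subsets of
the same data carry −0.013 … −0.021. Taken at face value, +0.020 implies a
36% first-year graft-failure probability at age 50 and cohort totals
irreconcilable with the reference league table (every option would dominate
current practice). We treat the sign as a misprint and use −0.020; with
this correction all five arms agree with the reference totals to within
1.5% on cost and 0.6% on QALYs.

## Payoff and discounting conventions

Published cohort analyses rarely state their cycle conventions; we fixed
them by agreement with the reference league table and expose each as a
flag:

* **Payoff timing** — state payoffs are taken on end-of-cycle occupancy
  (`half_cycle_correction=False`). The half-cycle correction (average of
  start and end occupancy) is available but off by default.
* **Discount start** — cycle *t* is discounted by 1.05^−(t−1): the first
  cycle is undiscounted (`first_cycle_discounted=False` by default; the
  1.05^−t convention is the flag).
* **Transplant-year cost** — the first transplanted year carries the
  one-time transplant cost (99,968 AUD) *plus* the annual maintenance cost
  (13,916 AUD), i.e. the procedure cost is a toll on top of the ongoing
  state cost (`first_year_includes_maintenance=True`). The
  first-year-cost-only convention is the flag.
* Waitlisted and post-graft-failure patients are on dialysis and carry the
  dialysis cost (81,689.34 AUD/year) and dialysis utility (0.70);
  transplanted patients carry utility 0.82. Death accrues nothing.

Each default was selected as the convention that best reproduces the
reference totals at the level scale; none was tuned to any incremental or
PSA quantity. A structural caveat follows from this calibration: the
*differences* between arms (ΔCost ≈ 2–6 M on totals of ≈ 400 M, ΔQALY ≈
20–150 on ≈ 8500) are small relative differences of large totals, and are
far more sensitive to the precision at which the Weibull coefficients are
recorded than the totals themselves. Reproduction of between-arm increments
should therefore be expected only to within a few million AUD / a few tens
of QALYs, even where the totals agree to 1–2%.

## Economics

ICER = ΔCost/ΔQALY, undefined at ΔQALY = 0. Dominance is classified by
quadrant (cost-saving and more effective → dominant; more costly and less
effective → dominated; mixed quadrants are labelled with their signed
ICER). League tables truncate ICERs toward zero (integer AUD), matching the
usual published rendering; all internal arithmetic is real-valued.
NMB = WTP·QALY − Cost; incremental NMB subtracts the current-practice NMB
at the same WTP. The primary threshold is 28,000 AUD/QALY with scenario
analyses at 42,000 and 67,000.

## Probabilistic sensitivity analysis

20,000 Monte-Carlo iterations. Distributions per parameter class:

* Weibull λ, γ, β_age — Normal(mean, SEM), λ and γ clipped at 10⁻⁸ (SEMs
  are small, so clipping is astronomically rare and guarantees
  termination; rejection sampling would change nothing detectable).
* Fixed annual probabilities — Beta with shapes solved from (mean, SEM) by
  method of moments.
* Utilities — Uniform over their 95% CIs (transplant 0.74–0.90, dialysis
  0.62–0.78); costs — Uniform over ±15% of the base value (cost data are
  not expected to be skewed).

Costs, utilities and the two fixed probabilities are common to all
strategies, so one draw per iteration is shared across arms; Weibull
coefficients are strategy-specific and drawn independently (no covariance
between λ, γ, β is published; independence is the conservative default and
widens, rather than narrows, the incremental uncertainty). Every parameter
has its own named, seeded substream (`numpy` `SeedSequence` spawning in
sorted target order), making results invariant to iteration order and to
which subset of options is evaluated.

**Probability of error** for an option is, by default, the probability that
its incremental NMB versus current practice is not positive
(`rule="vs_current"`). The alternative reading — one minus the probability
of attaining the strictly highest NMB among *all* arms simultaneously — is
available as `rule="vs_all"`; it is necessarily larger, and the published
error probabilities for this analysis are only consistent with the pairwise
rule (under the all-arms rule the implied probabilities of being best would
sum to ≈ 2). Ties count as non-best under both rules.

The PSA evaluates all iterations through a vectorised cohort engine
(`cohort.batch_outcomes`) proven identical to the scalar engine at machine
precision; 20,000 iterations × 5 arms complete in seconds.

## Synthetic registry generator

`generate_registry` emulates the linked waitlist/transplant dataset the
Weibull transitions are fitted from:

* recipient age ~ truncated Normal(50, 13) on [18, 80]; donor age ~
  truncated Normal(45, 15) on [5, 80] — plausible Australian waitlist and
  donor profiles;
* latent event times for transplant, graft failure and post-transplant
  death drawn from the Weibull PH laws by inverse CDF,
  T = (E/λe^{βa})^{1/γ}, E ~ Exp(1);
* waitlist death and post-graft-failure death as geometric-in-years
  processes with the fixed annual probabilities (integer-year event times,
  matching their treatment as fixed annual probabilities in the model);
* competing events resolved by keeping the earliest latent time, ties
  broken in favour of death (standard latent-failure-time construction;
  ties have probability zero in continuous time);
* administrative censoring at a fixed horizon (default 11 years, the span
  of a 2007–2017 accrual window). Loss to follow-up is not modelled — the
  censoring pattern of the real linkage is not public.

EPTS and KDRI are monotone noisy functions of recipient/donor age — linear
ramp × lognormal noise, EPTS = 0.034·age·e^{0.40Z},
KDRI = (0.35 + 0.021·age_d)·e^{0.30Z} — with constants chosen once so the
allocation thresholds (EPTS 1.033/2.4806, KDRI 0.9148/1.7208) cut the
synthetic population near the intended 20/80 quantiles with realistic
overlap. No attempt is made to reproduce real KDRI/EPTS marginals; passing
tests demonstrate correct mechanics of fitting and threshold subsetting,
not distributional fidelity to the Australian registry.

`apply_allocation_option` mirrors how the hypothetical-option datasets are
carved from observed data: transplanted records whose donor/recipient pair
violates the option's rule are *excluded*, not reassigned; untransplanted
records pass through. Age rules compare donor age with recipient age at
transplant (listing age + waiting time).

## Fitting

`fit_weibull_ph` maximises the right-censored Weibull PH likelihood in
(log λ, log γ, β) via `statsmodels`' generic-likelihood machinery (BFGS),
with standard errors from the observed information mapped to the natural
scale by the delta method. Degenerate designs fail loudly: all-censored
input and a constant age covariate raise informative errors rather than
returning garbage. An independent cross-check against the Weibull AFT
parameterisation (γ = ρ, λ = e^{−ρb₀}, β = −ρb₁) is part of the test
suite.

## Problem sizes and numerical choices

Default analyses use the reference configuration (1000 patients, 20
cycles, 20,000 PSA iterations). Test-suite simulation sizes — 5,000–20,000
synthetic patients for distributional checks, 10,000 for parameter
recovery, 200,000 for the individual-level microsimulation cross-check of
the cohort engine, 20 replicates for CI-coverage calibration — were chosen
so Monte-Carlo error is comfortably below the assertion tolerances (3
standard errors throughout). Mass conservation is asserted at 1e−9
relative; scalar/vector engine agreement at 1e−12 relative.

## Known limitations

* No re-listing, re-transplantation, temporary waitlist suspension, organ
  transport costs, or within-model ageing.
* Between-arm increments are sensitive to parameter precision (see payoff
  conventions above): level agreement is 1–2%, increment agreement is
  structurally looser.
* The synthetic registry is a statistical skeleton, not a calibrated
  replica of any real registry; KDRI/EPTS links to age are convenient
  monotone forms.
* PSA samples parameters independently within and across arms (no
  covariance information), and SEM-based Normal draws for λ and γ are on
  the natural scale.
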