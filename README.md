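# renalloc

Cost-utility modelling of deceased-donor kidney allocation strategies for
Australia.

## The problem

Kidney allocation systems trade equity against total health gain. *Longevity
matching* pairs the expected survival of a donor kidney with the expected
survival of its recipient: best organs to the recipients predicted to live
longest (as in the US system), or conversely the most marginal organs to the
recipients with the shortest expected post-transplant survival (as in the
Eurotransplant senior programme). `renalloc` implements a decision-analytic
evaluation of four such strategies against current Australian practice:

| option | rule |
|---|---|
| 1 | best 20% of kidneys (KDRI ≤ 0.9148) to best 20% of recipients (EPTS ≤ 1.033) |
| 2 | worst 20% of kidneys (KDRI ≥ 1.7208) to worst 20% of recipients (EPTS ≥ 2.4806) |
| 3 | youngest 25% of donors (≤ 32 y) to youngest 25% of recipients (≤ 41 y at transplant) |
| 4 | oldest 25% of donors (≥ 58 y) to oldest 25% of recipients (≥ 60 y at transplant) |

## The model

A four-state Markov cohort model run in one-year cycles: **waitlisted** (on
dialysis), **transplanted**, **post-graft-failure dialysis** (permanent — no
re-listing) and **death**. Because graft failure and post-transplant death
hazards depend on time since transplant, the transplanted state is expanded
into tunnel states indexed by years since transplant.

Time-dependent transitions follow Weibull proportional hazards with
cumulative hazard H(t) = λ·e^{βa}·t^γ at recipient age *a*; the annual
transition probability in cycle *t* is

    tp(t) = 1 − exp(λ·e^{βa}·[(t−1)^γ − t^γ]).

Waitlist and post-graft-failure mortality are fixed annual probabilities
obtained from cumulative incidences via r = −ln(1−p)/T, p₁ = 1 − e^{−r}.
Costs (2018 AUD: transplant year 99,968 + 13,916 maintenance, subsequent
years 13,916, dialysis 81,689.34/year) and utilities (transplant 0.82,
dialysis 0.70) accumulate per cycle, discounted at 5%/year. Strategies are
compared by ICER = ΔCost/ΔQALY and net monetary benefit
NMB = WTP×QALY − Cost at a willingness to pay of 28,000 AUD/QALY, with
parameter uncertainty propagated by a 20,000-iteration probabilistic
sensitivity analysis (PSA).

A synthetic registry generator (`renalloc.registry`) emulates the linked
waitlist/transplant data the transition probabilities are fitted from, so
the Weibull fitting (`renalloc.survival`) and the threshold-based
allocation subsetting are fully testable without restricted registry
access.

## Worked example

```python
from renalloc import (ModelConfig, default_scenarios, evaluate_scenario,
                      league_table, run_psa, summarize_psa)

scenarios = default_scenarios()          # packaged Australian parameter set
config = ModelConfig()                   # 1000 patients, 20 years, 5%, age 50
results = {n: evaluate_scenario(s, config) for n, s in scenarios.items()}
print(league_table(results).to_string(index=False))

run = run_psa(scenarios, config, n_iterations=20_000, seed=1, wtp=28_000)
print(summarize_psa(run).table[["option", "inmb_mean",
                                "prob_error_vs_current"]].to_string(index=False))
```

prints

```
  option  total_cost_millions   total_qaly  cost_per_qaly                       icer_vs_comparator
 current           413.233190  8486.939384   48690.484387
option_1           419.350833  8353.791176   50198.864719  dominated (more costly, less effective)
option_2           407.070477  8637.905809   47126.061083   dominant (cost saving, more effective)
option_3           408.358640  8426.236243   48462.757016      80301 (less costly, less effective)
option_4           406.545616  8506.938078   47789.887744   dominant (cost saving, more effective)

  option     inmb_mean  prob_error_vs_current
option_1 -1.055953e+07                0.68885
option_2  9.939080e+06                0.28160
option_3  2.387389e+06                0.44580
option_4  6.721117e+06                0.34845
```

Reading: allocating the worst-quintile kidneys to the worst-quintile
recipients (option 2) and old-to-old allocation (option 4) are *dominant* —
they save money (≈6–7 M AUD per 1000 patients over 20 years) **and** add
QALYs relative to current practice. Best-to-best allocation (option 1)
costs more and delivers fewer QALYs. In the PSA, option 2 has the highest
mean incremental NMB and the lowest probability (28%) of not being
cost-effective versus current practice; the ranking
option 2 > option 4 > option 3 > option 1 is stable across WTP thresholds
of 28,000, 42,000 and 67,000 AUD/QALY.

The same pipeline is scriptable from the shell:

```
renalloc simulate-registry --n-patients 5000 --seed 1 --out registry.csv
renalloc fit-survival --registry registry.csv --out fitted.yaml
renalloc run-base-case --out league.csv
renalloc run-psa --iterations 20000 --seed 1 --wtp 28000 --out-dir psa/
renalloc report --league league.csv --psa-summary psa/psa_summary.csv --out report.md
```

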