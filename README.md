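# niptscreen

A decision-analytic model of Down's syndrome (DS) prenatal screening for a
UK-NHS-style programme, comparing three testing strategies over a hypothetical
cohort of 10,000 pregnant women:

1. **Current screening** — combined test in the first trimester (quadruple test
   for late bookers); women above the risk cut-off are offered an invasive
   diagnostic test (CVS or amniocentesis).
2. **NIPT as contingent testing** — screen-positive women are offered
   non-invasive prenatal testing (NIPT) from cell-free fetal DNA first, and
   only NIPT-positive women are offered an invasive test.
3. **NIPT as first-line testing** — the whole cohort is offered NIPT in place
   of conventional screening; positives go to invasive confirmation.

The package is aimed at health economists and screening-programme analysts who
need expected event counts (screens, NIPT tests, invasive tests,
procedure-related miscarriages, DS cases detected) and a cost decomposition
(screening / NIPT / invasive testing, optionally pregnancy outcomes) under
configurable uptake, test-performance and unit-cost assumptions.

## The model

The cohort enters at gestational week 10 split into DS-affected and unaffected
pregnancies by a maternal-age distribution and an age-by-week prevalence
surface. Expected counts flow through the pathway stages multiplicatively:

- a screening test with detection rate DR and false-positive rate FPR splits
  takers into positives and negatives (`positives_affected = takers_affected × DR`,
  `positives_unaffected = takers_unaffected × FPR`);
- NIPT (DR 99%, FPR 1%) repeats once on sample failure (5%), with zero
  procedure risk;
- invasive testing (DR 100%, procedure-related miscarriage 0.5%) confirms the
  diagnosis; confirmed cases elect termination with probability 92.1%;
- between stages, pregnancies are exposed to weekly spontaneous-loss hazards
  (unaffected: 0.0012/week in weeks 10–25, 0.00034 in 26–40; DS-affected:
  0.07067 in weeks 10–15, 0.0051 in 16–40), so survival from week *f* to *t*
  is `Π_{w=f}^{t-1} (1 − h(w))`;
- survivors deliver at term, split 75.2% vaginal / 24.8% caesarean.

Every pregnancy ends in exactly one terminal state (spontaneous loss,
procedural miscarriage, termination, live birth), and every strategy run
conserves the cohort to floating-point precision. A seedable individual-level
microsimulator realizes the same rules woman-by-woman and is used to validate
the expectation engine via per-field z-scores.

The package also pools the published NIPT validity studies (eight 2×2 tables)
into per-study and merged sensitivity/specificity with Wilson score intervals.

## Worked example

```sh
nipt-screen run --strategy contingent_nipt --cutoff 150 --nipt-cost 500
```

prints

```
       strategy  cutoff  n_screened  n_nipt  n_nipt_positive  n_invasive  n_procedure_miscarriages  n_ds_detected  cost_screening_thousands  cost_nipt_thousands  cost_invasive_thousands  total_thousands
contingent_nipt     150     6875.64  159.55             11.6        9.71                      0.05           8.48                       200                   84                        5              288
```

Read: of 10,000 pregnancies, 6,875.64 are expected to take up DS screening
(69% uptake net of early fetal losses); 159.55 screen-positive women take NIPT,
11.60 are NIPT-positive, 9.71 have an invasive test, causing 0.05 expected
procedure-related miscarriages, and 8.48 DS cases are confirmed. At £500 per
NIPT the strategy costs £288k (£200k screening + £84k NIPT + £5k invasive) —
essentially cost-neutral against current screening (£278k total with 0.80
miscarriages and 160 invasive tests). The full strategy × cut-off × price grid:

```sh
nipt-screen grid --out reports/
```

Library use mirrors the CLI:

```python
from niptscreen import default_parameters, StrategySpec, run_strategy, cost_events

params = default_parameters()
events, outcome = run_strategy(params, StrategySpec(strategy="contingent_nipt"))
costs = cost_events(events, params.costs)
```

`nipt-screen accuracy` prints the validity-study table (e.g. pooled published
counts give sensitivity 99.33%), and `nipt-screen simulate -n 200000 --seed 1`
runs the microsimulation cross-check (all |z| ≤ 3 expected).

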