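# Methods

## Model structure

`niptscreen` is an expected-value (cohort) decision model. A cohort of 10,000
pregnancies enters at gestational week 10 and is partitioned into DS-affected
and unaffected strata. Each testing strategy is a fixed sequence of stages at
booked gestational weeks; between stages the strata are thinned by weekly
spontaneous-loss hazards, and at each stage expected counts are split by the
stage's probabilities (uptake, test result, procedure outcome). Because all
operators are multiplicative on expected counts, the engine is deterministic
and exact; the microsimulator (below) provides the stochastic counterpart.

Accounting invariants, enforced by construction and checked in tests:

- **Conservation.** Every pregnancy ends in exactly one of four terminal
  states: spontaneous loss, procedure-related miscarriage, termination (TOP),
  live birth. Decliners and test-negatives are propagated to term rather than
  dropped.
- **Detection requires an invasive result.** Women who decline NIPT or
  invasive testing are never counted as detected, and a DS pregnancy lost to
  the invasive procedure itself (0.5% of procedures) is not counted as
  detected. This keeps detected ≤ diagnosable and preserves conservation.
- **Repeat rules.** NIPT sample failure (5%) and invasive sample failure
  (CVS 1.3%, amniocentesis 0.8%) each trigger exactly one repeat, which incurs
  the full test cost but adds no procedure risk and never blocks completion.
  NT measurement failure (14–19% by week, linear between the week-11 and
  week-14 anchors) likewise adds one repeat measurement cost.

## Key parameters (defaults)

All probabilities are stored as proportions; costs are 2011/12 GBP.

| Parameter | Default | Notes |
|---|---|---|
| Screening uptake | 0.69 | same value for first-line NIPT uptake |
| Late bookers (quadruple arm) | 0.15 | screened in trimester 2 |
| Combined DR/FPR at 1:150 | 0.85 / 0.025 | 1:500 0.94/0.07, 1:1000 0.96/0.12, 1:2000 0.98/0.19 |
| Quadruple DR/FPR | 0.805 / 0.04 | |
| NIPT DR/FPR/failure/risk | 0.99 / 0.01 / 0.05 / 0 | |
| Invasive uptake | 0.80 unaffected / 0.90 affected | reused for contingent NIPT uptake |
| Procedure miscarriage | 0.005 per invasive test | |
| TOP uptake | 0.921 | |
| Weekly loss, unaffected | 0.0012 (wk 10–25), 0.00034 (26–40) | |
| Weekly loss, DS-affected | 0.07067 (wk 10–15), 0.0051 (16–40) | |
| Unit costs | combined £27, quadruple £35, invasive £479, fetal loss £511, TOP £697/£882 (T1/T2), birth £1,341/£2,436 (vaginal/caesarean), blood draw £3 | |

Two parameters are package-level choices with no published unit value:

- **Repeat-NT unit cost, £6.50.** The screening cost component is defined to
  include repeat NT measurements but no unit cost is published; £6.50 makes
  the default screening component ≈ £200k for the reference run, matching the
  published screening-cost anchor. It is an explicit, documented calibration
  knob (`costs.repeat_nt`).
- **Event timing.** The published pathway gives windows, not weeks. Defaults:
  combined screen wk 12, CVS wk 13; quadruple wk 16, amniocentesis wk 17;
  contingent NIPT wk 13/17 (T1/T2 arm) with invasive follow-up wk 14/18;
  first-line NIPT wk 11 with invasive wk 12. Diagnoses at or before week 14
  are costed as first-trimester TOPs. All configurable via
  `ParameterSet.timing`.

Hazards apply per completed week (independent Bernoulli survival per week, no
within-week proration); week `w`'s hazard acts between the starts of weeks `w`
and `w+1`, stage events at week `w` precede that week's hazard, and live birth
occurs at the start of the term week (40).

## Packaged synthetic cohort tables

The national maternal-age and DS-risk tables that models of this family use
are not redistributable, so the package ships synthetic approximations
(user-replaceable via two-column CSVs with strict headers):

- **Maternal age distribution** (`age,proportion`, ages ≤13…≥50): a unimodal
  Gaussian-shaped curve with mean ≈ 29.7 y and SD ≈ 5.9 y, floored at 0.0024
  per single year in the tails and normalized to 1. Note that a 38-bin
  distribution cannot simultaneously be normalized and bounded above by the
  ~1.65% sometimes quoted per year — the realistic peak is ≈ 6.7%/year — so
  only the lower bound is enforced.
- **DS term risk by age** (`age,term_risk`): `min(0.0012 + k·exp(0.2862·(age−45)),
  0.0150)`, i.e. an exponential rise with maternal age (doubling roughly every
  2.4 years) on a floor, capped so that the back-projected surface stays
  within the published 0.1–2.6% band. The scale `k` is solved by bisection so
  the **week-10 cohort prevalence is 0.25%** (25 affected pregnancies per
  10,000), a value consistent with early-pregnancy DS prevalence for an
  England-age-structured cohort and inside the published band.
- **Back-projection.** Prevalence at week `w` is obtained from term risk by
  odds scaling: `odds_w = odds_term × S_unaffected(w→40)/S_affected(w→40)`.
  Because affected pregnancies miscarry faster, prevalence is monotone
  non-increasing in week for every age (a tested invariant).

What the synthetic tables do *not* emulate: the exact ONS single-year age
frequencies, cohort-specific risk tables, maternal-age-varying unaffected loss
hazards (a hook exists but ships no data), twins, and secular trends. Tests
that pass on these tables therefore validate the *pathway arithmetic and its
orderings*, not the demographic detail; absolute detected-case counts shift
with the prevalence calibration (see "Known limitations").

## Microsimulator

`simulate_women` realizes each woman's trajectory by independent Bernoulli
draws at the exact parameter-bundle rates, using a counter-based Philox stream
with a fixed-width uniform matrix (one row per woman, one column per
decision), so woman *i*'s draws depend only on `(seed, i)` and growing `n`
never reshuffles earlier women. Spontaneous-loss timing is drawn by inverting
the survival curve with a single uniform, which makes the simulated
"alive at week *w*" events exactly consistent across stages. Trajectories are
returned as a DataFrame (one column per trajectory field) for vectorized
tabulation; `compare_to_expectation` reports per-field z-scores with binomial
standard errors. At n = 200,000 all fields sit within |z| ≤ 3 of the engine,
and a deliberately doubled NIPT false-positive rate is flagged (|z| > 3 on the
unaffected NIPT-positive count) — the diagnostic has power as well as
calibration.

Fields with very small expectations (e.g. procedure miscarriages, ≈ 1–2 at
n = 200,000) have skewed small-count distributions for which the normal z is
approximate; the |z| ≤ 3 check is still used, with the caveat that its false
alarm rate is a few per cent across all fields jointly at an arbitrary seed.

## Numerical choices

- Expected-count propagation in float64; conservation holds to ~1e-12 on a
  1e4 cohort (asserted at 1e-6 over random parameter bundles).
- Prevalence calibration by 80-step bisection on the term-risk scale
  (deterministic, monotone).
- Wilson score intervals in closed form; boundary counts (0 or n successes)
  return exact 0/1 bounds. Reported percentages keep full precision
  internally and are rounded only for display, following each table cell's
  printed precision.
- Report rounding: counts to 2 dp; £000s rounded half-up (`decimal`); exact
  values always preserved in the JSON sidecar.
- Degenerate inputs: zero uptakes produce all-zero ledgers that still conserve
  the cohort; zero denominators in accuracy estimation raise explicit errors.

## Known limitations and documented discrepancies

- The published outcome table for this model family is not internally exactly
  reproducible from its own printed inputs: its contingent NIPT-taker count
  (153.75) is smaller than its current-screening invasive count (160.59)
  despite identical uptake assumptions at the same pathway position, and its
  first-line NIPT-positive count (28.02) is inconsistent with a 1% NIPT
  false-positive rate applied to 6,881.66 takers. This package implements the
  stated rules and reports its own internally consistent ledger: the reference
  run reproduces the screening volume to ≈ 0.1%, the contingent NIPT volume to
  ≈ 4%, and the strategy totals to ≈ 2%, while detected-case counts come out
  lower than the published 13.24/11.26/16.49 because the week-10 prevalence
  implied by those cells is inconsistent with the published testing volumes;
  the 0.25% calibration favours the volume/cost anchors. Orderings (detection
  rising with cut-off, first-line > contingent detection, contingent <
  current miscarriages) are preserved throughout.
- The published pooled 2×2 counts (tp 736, tn 11,601) are not the column sums
  of the eight published study rows (701, 11,480); both are available
  (`PUBLISHED_MERGED` vs `merge_studies`). The published merged specificity
  (99.94) and one study's sensitivity CI are not reproducible by standard
  interval methods and are not targeted.
- No QALY or lifetime-cost modelling; the horizon ends at pregnancy outcome.
- Trisomies 13/18 and sex-chromosome aneuploidies are out of scope, as is
  invasive testing after a normal NIPT for suspected structural anomalies.
- Costs are 2011/12 GBP with no inflation adjustment.
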