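# Methods

## Model structure and assumptions

The core is a deterministic Markov cohort evaluation over exactly two
90-day cycles. Three states: alive/active in care, dead, and lost to
follow-up (LTFU). Dead and LTFU are absorbing within the model
horizon; a patient classified LTFU cannot re-enter care except in the
dedicated return-to-care sensitivity analysis. Because the chain is
unidirectional and only two cycles long, every output has a closed
form — six-month survival is the product of the two quarterly survival
probabilities — and no matrix machinery is needed.

Cost timing uses a full-cycle convention: every patient entering a
quarter accrues that quarter's full ART (and, in the combined arm,
supplement) cost, whatever their end-of-quarter disposition, and
patients dying or becoming LTFU mid-quarter are costed identically.
No half-cycle correction is applied. This convention reproduces the
published willingness-to-pay values to within 0.02%, which is the
evidence that the original analysis used it; a half-cycle correction
does not. The lifetime cost assigned to six-month survivors is applied
net of the two quarters of ART cost already accrued. All monetary and
health inputs arrive pre-discounted (lifetime cost at 3%/yr upstream;
first-year and supplement costs undiscounted), so the engine itself
performs no discounting.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| annual ART cost | 556 | USD/patient-year | program-wide average, 2010 USD; quarterly cost is annual/4 |
| lifetime cost per survivor | 6,118 | USD | discounted lifetime program expenditure per patient active at 6 months |
| DALYs averted per survivor | 7.3 | DALY | fixed health gain per 6-month survivor |
| effect duration | 2 | cycles | supplementation is modelled for the first 6 months only |
| r_mort, r_ltfu | scenario | proportion | multiply quarterly death/LTFU probabilities by (1 − r) |
| ration energy target | 1,360 | kcal/day | half of a 2,100 kcal/day recommended intake, +30% metabolic increase; the derivation yields 1,365 but the published costing uses 1,360, so 1,360 is the default and the derivation is exposed separately |
| ration duration | 90 | days | one model cycle |

## Transition probability modes

Two modes derive quarterly transition rows from disposition counts:

* **counts** — exact division of the stratum's quarterly counts; the
  right choice for new data.
* **percentages** (default) — each count share is rounded to one
  decimal of a percent and the triple renormalized. This reproduces
  the one-decimal percentages printed with the source cohort table and
  is the mode that best reproduces the published thresholds
  (discrepancies ≤ 0.4% vs up to ~2% for raw counts), indicating the
  original analysis consumed the rounded table. Rounded triples
  summing to 99.9 or 100.1 are renormalized proportionally; a larger
  defect is rejected as an input error.

Two cells of the published percentage table (both in quarter 3, which
the 2-cycle model never consumes) disagree with their own printed
counts by just over half a rounding unit; the count-derived values are
used and the cells are flagged in the test suite.

## Threshold solving and numerics

The parity price solves a linear equation, so no iteration is needed:
S* = (WTP·D′ − C′)/E′ with E′ = 1 + p′_a(Q1) the expected
quarter-entries under the adjusted transitions. The supplement is
costed exactly like ART (one price per quarter-entry); this exposure
convention is not stated in the source but reproduces the published
threshold matrix to ≤ 0.4%. Each stratum is benchmarked against its
*own* historical WTP. A negative S* (possible only for harmful
effects) is returned with a warning rather than clamped.

Parity frontiers invert S*(r_mort, r_ltfu) = S for r_ltfu at each
r_mort on a grid (default resolution 0.005). S* is strictly increasing
in r_ltfu, so a bracketed root-finder (Brent, tolerance 1e-6 on r) on
[0, 1] suffices; grid points where the bracket excludes a solution are
omitted.

Sensitivity analyses: the ART-cost sweep rescales the lifetime cost
per survivor proportionally with the annual cost (the lifetime figure
is dominated by ART provision; proportional scaling reproduces the
published $23.83 anchor to 0.2%) and recomputes the WTP benchmark at
each cost. The LTFU return-to-care analysis treats a fraction f of
patients LTFU at 6 months as later resuming care with the same
lifetime cost (net of ART accrued before exit: one quarter for Q1
exits, two for Q2 exits) and DALYs as survivors, with no second course
of supplementation; the ART-alone comparator is re-benchmarked under
the same assumption so parity compares like with like. The accrual
convention for returnees and the comparator re-benchmarking are
modelling choices of this package — the source describes the analysis
but not these details.

## Synthetic cohorts

The generator draws, for each quarter, a three-category multinomial
split of the patients entering that quarter, with survivors feeding
the next quarter — the exact generative model of an aggregate
disposition table under independent per-patient outcomes. Default
experiments use the severe stratum's fitted probabilities at its real
cohort size (5,096 starters), i.e. the sampling noise the real table
carries. Simulation is at cohort-count level, not per-patient event
streams; per-replicate random streams are spawned deterministically
from one master seed.

What the generator does *not* emulate: covariates (age, sex, CD4),
within-quarter event timing, between-clinic heterogeneity, and any
dependence between patients. Passing recovery tests therefore show
that the estimation pipeline is consistent under multinomial sampling
noise at the observed scale — not that the model is robust to
structural features real programs may have (informative LTFU,
calendar trends).

A separate per-patient microsimulation oracle replays the two cycles
with categorical draws and the same costing rules; it exists purely to
cross-check the analytic engine and is kept independent of it.

## Known limitations

* The model horizon is fixed at two cycles; quarters 3–4 of the input
  table are validated but not modelled.
* Non-health costs, hospitalization, and ART-adherence effects of
  supplementation are out of scope, as in the source analysis.
* The lifetime cost and DALY inputs are single point estimates; no
  probabilistic sensitivity analysis is provided.
* The published threshold for the mild-malnutrition stratum at a
  20%/20% effect appears in the source once as $5.28 and once as
  $5.18; this package computes $5.18. Similarly its WTP benchmark
  reproduces to 0.07% rather than printed precision. Both ambiguities
  are documented rather than resolved.
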