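# Methods

This note documents the model implemented by `pucea`, the choices made
where the published description leaves the design open, and what the
synthetic data does and does not establish.

## Health states and time

Ten mutually exclusive states: no PU; single PU of grade 1–4; multiple
PUs of grade 1–4; death (absorbing). The cohort model runs in monthly
cycles for 24 cycles (a program year plus one extrapolation year). A
"measurement month" is the observational unit of the registries: 12
measurement moments spaced alternately 2 and 3 days (day offsets
0, 2, 5, …, 27), every patient observed at each moment until death.

## Effectiveness measures

* Monthly prevalence: mean over the month's moments of
  (patients in any PU state at that moment) / denominator. The
  denominator is the cohort size (88 in the shipped calibration) and
  does not shrink when patients die.
* One-month incidence: patients with a no-PU observation followed by a
  PU observation within the month, counted once each, over the same
  denominator. The grade of an incident case is the grade at its first
  PU observation.
* Pre/post comparison: two-sample t-test on per-patient any-PU
  indicators. The published description names only "a t-test"; the
  default is unpaired, with `paired=True` aligning on patient id for
  the paired variant. Two zero-variance groups make the statistic
  undefined; the result is then flagged `degenerate` instead of raised.

## Costing

Three levels, all in euros:

* **Program**: 5,506 expert hours at €115/h plus €114,000 of lump sums
  (materials and other collaborative costs), evenly allocated to the
  25 project teams and then to each team's patients. The published
  allocation equals €323/patient-year; the average team size that
  figure implies (92.5 patients) is not itself published and is stored
  as an explicit assumption.
* **Organizational**: project-team hours within each organization,
  allocated evenly over its patients; the published per-patient-year
  figure is €1,550.
* **Departmental**: per-state monthly costs. The published per-state
  monthly table is used directly as the default (`mode: published`),
  because the per-state activity mix behind it is not public; a full
  bottom-up mode (`mode: components`) computes daily labor + mattress +
  pillow + treatment × 30 days/month from activity durations, wages and
  rental prices and validates component/total consistency.
* States a given arm never observed (standard care: single grade 3/4;
  QIC: multiple grade 2/4) borrow the observed cost of the same-grade
  state of the other multiplicity, overridable per state.
* Creams and dressings are excluded throughout (assumed unchanged by
  the program); the published monthly and yearly aggregates are not
  mutually consistent (€84/month vs €1,026/year), so the monthly
  per-state totals are treated as authoritative for the model and the
  yearly figures kept only as published aggregates. The
  occupancy-weighted monthly average the model itself implies is
  available via `costing.occupancy_weighted_monthly_cost`.

## Transition matrices

* **Control arm (simulated standard care).** The no-PU row sends the
  observed monthly incidence, split over grades by the incident-grade
  mix, to the single-PU states; every PU state heals to no-PU with its
  90-day probability rescaled to 30 days under constant hazard
  (1−(1−p)^(30/90)); the rest stays put. This freezes the first
  measurement month's dynamics for the whole horizon.
* **Intervention arm.** Each patient's measurement month is summarized
  by the modal state (ties to the clinically worse state); the annual
  matrix is the row-normalized cross-tabulation of baseline vs final
  representative states. Patients absent from the final month are
  excluded: the calibrated cohort consists of survivors, and mortality
  is modelled separately. Unobserved rows fall back to self-transition
  and are flagged. The monthly matrix is the principal 12th matrix
  root (eigendecomposition), negative entries clipped and rows
  renormalized, with the clipped mass and the Frobenius distance of
  the 12th power from the input reported in `meta`; a complex or
  defective root falls back to per-element 1−(1−p)^(1/12) conversion.
* **Mortality.** A uniform monthly death probability
  d = 1−(1−annual)^(1/12) overlays every alive state, alive transitions
  rescaled by (1−d). The national average annual mortality of the
  population is not published with the study; the default of 0.30/year
  is an explicit assumption consistent with the typical 2–3 year stay
  until death. Mortality enters at the start of the extrapolation year
  in both arms, matching the published model narrative.

### Sustainability scenarios (year 2)

* **total** — the year-1 monthly intervention matrix continues.
* **partial** — identity dynamics on the alive states plus mortality:
  the achieved state distribution is frozen among survivors. This is
  the only construction that keeps "the achieved results" exactly
  stationary.
* **none** — the year's improvement is reversed. The literal
  construction (monthly root of the annual matrix's inverse, clipped
  to valid probabilities) is attempted first but is accepted only if
  clipping removes essentially nothing: the inverse of any stochastic
  matrix with real movement has negative off-diagonal entries, so
  clipping its root otherwise collapses the dynamics to near-identity;
  and annual matrices estimated from ~90 patients are frequently
  singular outright. The working reversal is the Bayes time-reversal
  of the annual chain with respect to the baseline distribution
  (B[j,i] = π₀[i]A[i,j]/π₁[j]), whose single annual application maps
  the achieved mix back to the baseline mix exactly; its monthly root
  is used and the fallback is flagged in the matrix's `meta`.

## Valuation

QALYs per cycle: occupancy · utility / 12, discounted at the end of
each cycle with t = cycle/12 years at 1.5%/year; costs analogously at
4%/year; no half-cycle correction. Program + organizational overheads
(€1,873/patient-year, intervention arm, year 1) enter as an
undiscounted time-0 lump sum by default (`overhead_timing:
discounted_monthly` spreads them over the first year's cycles).
ICER = ΔC/ΔE when informative; "dominant" (cheaper, more effective),
"dominated" (costlier, less effective) and "undefined" (ΔE = 0)
otherwise.

## Probabilistic sensitivity analysis

Each iteration multiplies every per-state monthly cost (both arms,
plus the two overhead items) and every alive-state utility by an
independent lognormal draw with mean exactly 1
(μ = −ln(1+cv²)/2, σ² = ln(1+cv²)); utilities are capped at 1.
Transition matrices are held fixed by default; a config switch
Dirichlet-perturbs the year-1 rows instead. The published analysis does
not state the lognormal variances, so the default cv = 0.2 for both
costs and effects is a package choice and the published PSA
probabilities are qualitative context, not reproduction targets; the
robust qualitative finding — the cost increase is near-certain while
the QALY gain is genuinely uncertain — holds under the default.
Draws are deterministic per (seed, iteration); summaries (quadrant
shares, P(ΔC>0), P(ΔE>0), acceptability at the threshold, the
acceptability curve) are exact functions of the stored pairs. Axis
ties on the CE plane count toward the less favourable quadrant.

## Synthetic registry generator

The generator emulates the study's structure: 88 patients, baseline
state counts 21/10/1/2 prevalent cases of grades 1–4 (with a
configurable 15% of each grade's cases assigned to the multiple-PU
state, since the published table does not split them) and 54 PU-free;
12 moments spaced 2–3 days. Between moments each at-risk patient
acquires a single new PU (grade drawn from the incident mix, default
10:3 on grades 1–2) with the monthly onset probability rescaled to the
gap; each PU patient heals to no-PU with the 90-day probability
rescaled likewise; anyone may die at the annual mortality rescaled
likewise. Defaults:

| parameter | default | basis |
| --- | --- | --- |
| monthly onset per at-risk patient | 13/54 ≈ 0.241 | 13 incident cases among 54 PU-free patients |
| 90-day healing, grades 2–4 | 0.67 / 0.44 / 0.32 | literature values used by the model |
| 90-day healing, grade 1 | 0.90 | package assumption: erythema resolves quickly once pressure is relieved (no published value) |
| annual mortality | 0.30 | package assumption, 2–3 year average stay |
| intervention onset multiplier | 4.5/15 = 0.3 | published incidence fall from 15% to 4.5% |

Over repeated seeds the generated baseline month shows ~14% incidence
and the final month ~4%, matching the published effect. The paired
generator evolves patients through 11 monthly gap steps between the
two measurement months; deaths drop out of the final registry while
the denominator stays 88.

**What the generator does not emulate.** Real PU histories are more
persistent than the literature healing probabilities imply: the study
cohort held a 38.6% prevalence that our constant-hazard dynamics erode
within months (the generated monthly average baseline prevalence is
~36% and the final month ~10% rather than the published 22.7%).
Consequently the *simulated control arm improves on its own*, and the
"none" scenario's incremental QALY on synthetic data is ≈0 rather than
clearly positive. Passing tests therefore establish the correctness of
the estimators, matrix algebra, valuation and PSA mechanics — not that
the synthetic cohort reproduces every published incremental value,
which would require the unpublished patient-level persistence
structure. The published ICERs are reproduced exactly where they are
reproducible: from the published per-person incremental values
(`cea_reference.tsv`, `icer_*` in the acceptance output).

## Numerical conventions

* Probability–horizon conversions assume constant hazards throughout.
* Transition-matrix rows must sum to 1 within 1e-9; every transform
  renormalizes exactly after clipping and reports the clipped mass.
* Representative-state ties break toward the clinically worse state;
  CE-plane axis ties toward the less favourable quadrant.
* Days per month is 30 (configurable) for daily→monthly cost
  conversion; a year is 12 cycles.
* Single global seed; each pipeline stage draws from a substream keyed
  by a CRC-32 hash of the stage name, so stages are individually
  reproducible; PSA iterations key their streams by (seed, iteration).

## Problem sizes used by the test suite

Tests and the acceptance script are sized to run in seconds: the
microsimulation oracle uses 50,000 individuals over 24 cycles (3
binomial standard errors per state per cycle, plus a 1/2n continuity
correction); transition recovery uses 5,000 patients spread over three
initial states (~1,667 per row, giving per-cell sampling error well
inside the 0.02 acceptance band); the PSA runs 10,000 iterations per
scenario in the acceptance script and smaller counts in unit tests.

## Known limitations

* No covariates, case-mix adjustment, grade-to-grade progression, or
  time-inhomogeneity beyond the year-1/year-2 switch.
* The healing probabilities apply per ulcer grade regardless of
  single/multiple status; multiple-PU states heal as a block.
* The published per-state cost table cannot be reproduced bottom-up
  from the published activity durations (the per-state activity mix is
  not printed); the components mode exists for users with their own
  activity logs.
* The €84 vs €1,026 monthly/yearly aggregate inconsistency in the
  source table is documented, not resolved.
* ICERs near ΔE = 0 are numerically unstable by nature; dominance
  labels replace ratios in the ambiguous quadrants.
* With 88 patients the incremental QALY carries sampling noise of the
  same order as its value (~0.01–0.03), so on synthetic cohorts its
  sign varies between seeds and the model ICER is reported only when
  the QALY difference is positive. The reference ICERs computed from
  the published per-person incremental values are deterministic.
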