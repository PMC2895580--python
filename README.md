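# pucea — cost-effectiveness analysis of pressure-ulcer prevention collaboratives

Pressure ulcers (PUs) are largely preventable skin and tissue injuries,
graded 1 (non-blanchable erythema) to 4 (full-thickness tissue loss),
that burden nursing-home patients and long-term-care budgets. Quality
improvement collaboratives (QICs) — programs in which expert teams coach
many care organizations through evidence-based prevention — demonstrably
reduce PU incidence and prevalence, but whether they are worth their
money is rarely quantified.

`pucea` implements a complete, tested health-economic evaluation of such
a program for biostatisticians and health-economics researchers:

- **Registry effectiveness measures.** From longitudinal surveillance
  registries (12 measurement moments per month, one observation per
  patient every 2–3 days): monthly prevalence (mean over moments of
  patients-with-PU / cohort size), one-month incidence (patients with a
  new PU / cohort size), and a pre/post t-test on per-patient PU
  indicators.
- **Three-level costing.** Program expert hours and lump sums are evenly
  allocated over project teams and their patients; organizational
  project hours over each organization's patients; departmental costs
  combine caregiver time (hours × collectively agreed hourly wage) and
  daily mattress/pillow rental, converted to per-health-state monthly
  costs.
- **A Markov cohort model** over ten states — no PU, single PU grade
  1–4, multiple PU grade 1–4, death — in monthly cycles over two years.
  The control arm is *simulated*: first-month incidence and literature
  90-day healing probabilities (67%, 44%, 32% for grades 2–4) become a
  monthly transition matrix, standing in for the unobservable
  "no-program" world. The intervention arm's annual matrix is estimated
  from the paired first/last measurement months and converted to
  monthly dynamics via the principal 12th matrix root. Mortality enters
  the extrapolation year as a uniform monthly hazard. Year 2 follows
  one of three sustainability scenarios: **total** (year-1 dynamics
  continue), **partial** (achieved state mix frozen among survivors),
  **none** (the year's improvement is reversed).
- **Valuation.** QALYs use state utilities 0.703 (no PU), 0.68 (single
  grade 1–2), 0.5 (multiple grade 1–2), 0.36 (any grade 3–4); costs and
  effects are discounted at 4%/1.5% per year. The headline statistic is
  the incremental cost-effectiveness ratio ICER = ΔC/ΔE against a
  willingness-to-pay ceiling of €80,000/QALY.
- **Probabilistic sensitivity analysis.** Every per-state cost and
  utility is resampled from a mean-1 lognormal distribution
  (σ² = ln(1+cv²), default cv = 0.2), 10,000 Monte-Carlo iterations per
  scenario, summarized on the cost-effectiveness plane.

Because the underlying 88-patient registry is not public, the package
ships a synthetic-registry generator calibrated to the published
aggregates (baseline prevalence 34/88 per-grade mix, one-month incidence
15%, healing and mortality rates), so the entire pipeline runs and is
validated end-to-end on data with the study's structure.

## Worked example

```python
from pucea import RunConfig, run_pipeline

config = RunConfig(seed=1)
config.cohort.seed = 1
bundle = run_pipeline(config, "out")
model = bundle.model
for scenario, (dc, dq) in model.deltas.items():
    print(f"{scenario:8s} dCost = {dc:7.0f} EUR  dQALY = {dq:+.5f}  "
          f"ICER = {model.icers[scenario]}")
```

prints (seed 1):

```
none     dCost =    1878 EUR  dQALY = -0.00044  ICER = dominated
partial  dCost =    1566 EUR  dQALY = +0.01265  ICER = 123801.04131849293
total    dCost =    1548 EUR  dQALY = +0.01299  ICER = 119119.59755749551
```

Read: on the synthetic cohort the program costs roughly €1,550–1,880
extra per patient over two years (dominated by €1,873/patient of
program and organizational overhead). If its effect is at least
partially sustained it buys ~0.013 QALYs, i.e. an ICER above the
€80,000 ceiling; if the improvement is lost again ("none"), the control
arm — which also improves under the model's literature healing rates —
catches up and the program is dominated. The same run writes the full
report bundle (registries, effect tables, matrices, traces, CE-plane
samples, acceptability curves, manifest) to `out/`.

The same pipeline is available from the shell:

```bash
pucea run --seed 1 --out out            # full pipeline
pucea effects --seed 1 --out out        # prevalence/incidence only
pucea model --scenario total --out out  # one scenario
pucea validate --config my.yaml         # config invariant checks
```

## Layout

| module | contents |
| --- | --- |
| `pucea.states` | the ten-state health-state vocabulary |
| `pucea.synthetic_data` | registry generator and registry CSV I/O |
| `pucea.effectiveness` | prevalence, incidence, pre/post comparison |
| `pucea.costing` | wages, rentals, overhead allocation, cost profiles |
| `pucea.markov` | transition estimation, matrix transforms, cohort runs, ICER |
| `pucea.psa` | lognormal resampling, CE-plane summaries |
| `pucea.config`, `pucea.pipeline`, `pucea.cli` | configuration, orchestration, CLI |

See `docs/methods.md` for the model's assumptions, parameter defaults
and known limitations.
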