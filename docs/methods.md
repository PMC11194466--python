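# Methods

## Model structure

`crcprev` models the natural history of colorectal neoplasia after
polypectomy as an annual-cycle Markov process.  The published seven-state
structure (normal mucosa, low-risk adenoma, high-risk adenoma, local /
regional / distant CRC, death) is expanded internally to twelve states:
each cancer stage is split into a *preclinical* (present, undetected) and a
*diagnosed* state, and death is labelled by cause (cancer, other, procedural
complication).  The split is what gives colonoscopy sensitivity and
symptomatic presentation well-defined meanings: preclinical cancer can
progress (local→regional 56%/yr, regional→distant 63%/yr), be detected at
colonoscopy (sensitivity 94.7%), or present symptomatically (22/40/85%/yr by
stage); diagnosed cancer no longer progresses but carries stage-specific
annual mortality (3.27/8.22/46.93%) plus a one-time 2% treatment mortality
in the diagnosis cycle, applied as an independent competing risk.

Within each annual cycle, events resolve in a fixed published order:
(1) other-cause death, (2) scheduled colonoscopy, (3) symptomatic
presentation, (4) cancer death in diagnosed states, (5) progression /
adenoma recurrence, (6) accrual of the cycle's cost and utility.  The order
is a reproducibility device — the underlying inputs are annual
probabilities, and some fixed order is needed to compose them; this one puts
background mortality first and accrual last.

Assumptions worth stating explicitly:

* **Stage mortality conditions on diagnosis.**  The stage-specific
  mortalities are survival-registry figures, which condition on diagnosis,
  so preclinical states face progression, presentation, and background
  mortality only.  Models without a preclinical/diagnosed split instead
  charge cancer mortality (and costs) from cancer onset; that choice
  produces systematically higher cost accrual in unsurveilled arms (see
  *Limitations*).
* **No adenoma regression**, no polyp multiplicity, no site effects.
* **Chemoprevention acts only while exposed**: berberine's reduced
  recurrence rates (18.15%/1.51% vs placebo 23.19%/3.05% per year, derived
  from the trial's two-year proportions by the constant-rate conversion
  `rate = −ln(1−p)/t`, `p = 1−exp(−rt)`) apply from 50 to 74 to adherent
  patients under a drug-containing strategy; the LRA→HRA (8.9%/yr) and
  HRA→CRC (5%/yr) transitions take placebo values in both groups because the
  trial could not measure them — a conservative reading of the drug effect.
* **Adherence**: berberine adherence is a single lifelong per-patient draw
  (80%); colonoscopy attendance is per-procedure Bernoulli (60%).  A missed
  colonoscopy stays due and is re-offered each year until attended.
* **Surveillance scheduling is finding-based**: first exam 3 years after
  entry; after an exam, the next is due in `interval_high_grade` (default 3)
  years when a high-risk adenoma was found and removed, else in
  `interval_low_or_none` (default 5) years.  All intervention stops at 75.
  Patients whose cancer is detected leave surveillance.
* **Colonoscopy performance**: removes LRA with 58%, HRA with 92%
  (returning the patient to normal mucosa); perforation 0.04% (case
  fatality 5.82%), major bleeding 0.08% (case fatality 6.0%); one-time
  0.0025 QALY disutility per attended exam.  Detection and removal are a
  single event; an unremoved polyp counts as not found.

## Accounting

Costs and QALYs are discounted at 3%/yr from entry at age 50 with no
half-cycle correction.  Event costs (procedures, complications, cancer
initial and death costs) are booked in the cycle of the event, whether or
not the patient survives it; annual amounts (state utility, drug cost,
cancer continuing cost) are booked to patients alive at the end of the
cycle.  Utilities: 0.84 for all non-diagnosed states (including preclinical
cancer), 0.74/0.67/0.25 for diagnosed local/regional/distant cancer.  The
payer block switches at attained age 65 (commercial below, Medicare at and
above); the drug's $124/yr is payer-independent and is read as an annual
cost per adherent patient-year of exposure (the source prints only a price
for 300 mg twice daily), charged in every living state during the exposure
window.  No distant-stage continuing-yearly cost is available, so distant
diagnosed patients accrue the regional continuing rate in the years between
diagnosis and death.

## Engines

The **microsimulation** walks all n patients through the cycle model with
vectorized per-decision Bernoulli draws.  Random numbers come from
per-cycle, per-decision-channel streams keyed only by the master seed, so
every strategy and every scenario replays identical uniforms — common random
numbers by construction, which makes small strategy contrasts (the combined
strategy's ~$10-per-patient saving over colonoscopy) resolvable at 10^5
patients.  Runs are bit-for-bit reproducible given a seed.

The **cohort evaluator** propagates the occupancy distribution over
(adherence stratum × years-to-next-colonoscopy × health state) — about 400
cells — through the same six-step cycle, yielding the exact expected cost
and QALY in ~10 ms.  Because newly diagnosed cancer is tracked as a
within-cycle flow, the diagnosis-year bookkeeping (initial cost, treatment
mortality, no continuing cost) is exact without enlarging the state space;
the years-since-diagnosis dimension is unnecessary because the continuing
cost is constant after the diagnosis year.  The due-counter axis is capped
at 15 years and guarded.  The test suite asserts microsimulation/evaluator
agreement within 3 Monte-Carlo SEs on the base case and perturbed
parameterizations, linearity in utilities, and closed-form degenerate cases
(annuity limit, immediate absorption).

## Parameters and uncertainty

All inputs live in `src/crcprev/data/default_parameters.yaml` (percent
convention for probability blocks, converted at load).  Every uncertain
parameter carries a range, read uniformly as a 95% interval
(sd = (high−low)/3.92), and a family: Beta for probabilities/utilities,
Gamma for costs, both moment-matched so the analytic mean equals the
baseline exactly.  Degenerate ranges fall back to fixed with a warning.  The
discount rate is fixed and excluded from the PSA, as is the life table (no
published range).  All PSA parameters are drawn independently — no
correlation structure is asserted by the sources.

One-way (tornado) analysis moves a parameter to its limits (default ±20%
costs, ±10% probabilities/utilities when a range is missing) and
re-evaluates the headline comparison (berberine+colonoscopy vs colonoscopy)
with the deterministic evaluator, summarized as incremental NMB at
$100,000/QALY.  The PSA's inner evaluation also defaults to the evaluator:
nesting 10^6-patient microsimulations inside 10^5 draws is not desk-scale,
and the evaluator isolates parameter (second-order) uncertainty exactly; a
microsimulation inner loop exists for validation.  CEAC winners are decided
by highest NMB with ties broken toward the cheaper strategy.

## Synthetic life table

Other-cause mortality uses a Gompertz–Makeham law
`q(a) = 1 − exp(−(a_M + b·e^{θ(a−50)}))` with a_M = b = 0.002, θ = 0.107,
calibrated to US-like adult mortality: q(50) ≈ 0.0040, q(80) ≈ 0.0503,
remaining life expectancy at 50 ≈ 32.3 years, q(100) capped at 1.  It
reproduces the *shape* of adult mortality but not any particular national
table: cohort-vs-period and sex aggregation are not represented, and
absolute dollar/QALY levels shift with the table (a two-column
`age,q_other` CSV can be injected to use a real one).  Passing tests
therefore demonstrate internal correctness and qualitative agreement with
the published analysis, not dollar-exact reproduction.

## Problem sizes

Default runs use 100,000 patients per strategy (≈1 s vectorized; the CLI
flag `--n 1000000` reproduces the full-size cohort), 1,000 PSA draws with
the exact inner evaluator (draw count affects only the Monte-Carlo error of
the acceptability fractions, not per-draw exactness), and the full ~56
parameter tornado.

## Known limitations

* With the synthetic life table and the diagnosis-conditioned cancer
  mortality/cost structure, the two unsurveilled arms accrue ~18–20% less
  lifetime cost than the published base case (QALYs and both surveillance
  arms agree within a few percent); the qualitative result — combined
  dominates colonoscopy dominates berberine dominates nothing — is
  unchanged, but the combined strategy's cost margin over colonoscopy is
  thinner (≈$90 vs ≈$780 per patient).  Consequently a handful of one-way
  limits (e.g. drug cost at its upper bound) turn that comparison from
  dominant into merely cost-effective (ICERs below $3,000/QALY).
* Finding-based rescheduling makes a 1-year high-risk recall partly
  self-defeating: an early clean exam pushes the next exam 5 years out, so
  the shortened interval adds procedures without reducing cancer deaths in
  this implementation.
* Berberine harms are not modelled (none serious were reported); no
  budget-impact or societal-perspective costs; no FIT/stool-test
  comparators.
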