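# Methods

`ptsd_cea` implements a decision-analytic cost-utility model of four
management strategies for post-traumatic stress disorder (PTSD) in
sexually abused children: no treatment, twelve sessions of non-directive
supportive counselling, twelve sessions of trauma-focused cognitive
behavioural therapy (TF-CBT), and TF-CBT combined with sertraline (an
SSRI).  The analysis takes the perspective of a public mental health care
system; costs are unit fees in 2010/2011 Australian dollars and outcomes
are quality-adjusted life years (QALYs).

## Model structure

**First year (decision tree).**  A cohort of 10-year-olds meeting PTSD
diagnostic criteria, of whom a share `p_comorbid_depression` (0.58) also
has depression, enters one arm.  Each arm partitions the cohort into

* *responders* (probability `p_response`: 0.42 TF-CBT, 0.44 TF-CBT+SSRI,
  0.34 counselling), who no longer meet PTSD criteria after the 12-week
  course and carry the well utility for 9 of 12 months;
* *delayed responders*, a share `p_delayed` (0.17) of the apparent
  non-responders, who respond at mid-year and are well for 6 of 12 months;
* *non-responders*, who stay at their baseline utility all year.

The untreated arm has no therapeutic response; instead a share
`p_spont_remit_year1` (0.17) remits spontaneously and, symmetrically with
delayed responders, is credited 6 of 12 months well (the source gives no
timing; mid-year is the natural symmetric choice and is the package's
default).  Baseline utility is the depression-share-weighted mix
0.58×0.53 + 0.42×0.61 = 0.5636.  First-year costs assume half the cohort
is treated by psychologists and half by psychiatrists (first plus eleven
subsequent consultations), one parental psychoeducation component
(A$58.85) per child in every active arm, and — in the combination arm —
three months of sertraline plus two GP monitoring visits.  Year-1 flows
are not discounted (costs are up-front and benefits accrue within the
year; a `discount_year1` switch applies a half-year factor if wanted).

**Years 2–31 (Markov cohort model).**  The end-of-year-1 distribution
(well / PTSD only / PTSD+depression) seeds a 3-month-cycle state-
transition model run for 120 cycles (ages 11–41).  Nine logical states
are realised as 11 matrix columns:

1. well (no PTSD, no depression);
2. PTSD only;
3. PTSD + depression, untreated;
4. depression only, untreated;
5. depression only on second-line SSRI;
6. PTSD + depression on second-line SSRI;
7. SSRI continuation tunnel (9 months ≈ 3 cycles of supervised
   medication after depression remits — three auto-advancing columns,
   since a tunnel carries memory inside a memoryless chain);
8. death by suicide (absorbing);
9. death from other causes (absorbing).

Structural assumptions:

* Recovery from the index trauma is permanent: the well state has no
  outflow back to any PTSD state.  New PTSD episodes from later unrelated
  traumas are outside the model's scope.
* PTSD+depression never transitions to depression only: successful PTSD
  treatment also remits co-morbid depression, not the reverse.
* Non-responders in treated arms who had baseline depression receive
  second-line sertraline (states 5/6); SSRI responders with PTSD move to
  *PTSD only* and then follow the spontaneous-recovery schedule.
  Remitted depression passes through the continuation tunnel back to
  well.  Depression is recurrent-remitting: well → depression and back,
  repeatedly.
* The untreated arm never contacts the care system: its depression exits
  only via spontaneous remission, and it accrues zero cost over the whole
  horizon (matching the comparator convention of the original analysis).
* PTSD only → well follows a time-since-baseline schedule of per-cycle
  probabilities (0.0083 in year 2 declining to 0.0020 in years 21–29).
  The schedule tiles years 2–29; model years 30–31 keep the last band's
  rate rather than dropping to zero, since recovery is described as
  ongoing through age 40.
* Per-cycle suicide hazards depend on health state and attained-age band
  (zero below age 15; e.g. 0.000343 per cycle for PTSD+depression at ages
  20–29); other-cause mortality depends on age only.  Tunnel occupants
  carry the general-population hazard (their depression has remitted).

Within a cycle mortality applies first and clinical transitions act on
survivors — a deterministic, order-stable resolution of competing risks
whose difference from other orderings is O(p²) at these magnitudes.
State membership is valued at the cycle midpoint (the mean of the
start- and end-of-cycle occupancy), implementing mid-cycle transitions.
Cycle *c* is discounted by (1.05)^−(1+(c+0.5)/4), i.e. continuous 5%/yr
from baseline.  QALY accrual per cycle is 0.25 × utility × corrected
occupancy × discount; cost accrual is (3 × monthly sertraline + one GP
visit) per cycle spent in any on-SSRI or tunnel state, discounted the
same way.  The well utility drops from 0.87 to 0.85 at age 30 exactly;
disease utilities (0.61 PTSD, 0.53 PTSD+depression, 0.46 depression) are
constant for the whole horizon.

## Period bases of the input probabilities

The suicide and other-cause hazards and the PTSD recovery schedule are
given per 3-month cycle and used as-is.  `p_dep_spont_remission` (0.53)
and `p_ssri_depression` (0.60) are 12-month probabilities converted with
`to_per_cycle(p) = 1 − (1 − p)^(1/4)`.  `p_dep_recurrence` (0.14) is
read as the probability that a recovered patient ever relapses into
depression over the 30-year horizon (per-cycle 1 − 0.86^(1/120)):
the published long-term cost increments (≈A$45–49 per arm, ordered by
non-responder share, with counselling more costly than TF-CBT and
therefore strictly dominated) are only consistent with a recurrence flow
of this magnitude, whereas an annual reading floods the well state with
SSRI-treated episodes and reverses the cost ordering.  The annual
reading remains available via `settings.recurrence_over_horizon: false`.
SSRI compliance is folded into the 0.6 effective response
(`ssri_compliance` multiplier, default 1.0).

## Cost-effectiveness analysis

Per-arm totals (tree + Markov) feed a league table: incremental QALYs and
ICERs versus no treatment are derived from totals at full precision;
strict dominance means costing no less and yielding no more QALYs than
some alternative (one inequality strict); frontier ICERs link successive
non-strictly-dominated strategies, the convention of published tables.
Extended dominance — an ICER that exceeds the next strategy's, so a blend
of neighbours beats the middle point — is flagged as an annotation
without removing the strategy from the frontier chain.  Exact cost/QALY
ties dominate in neither direction.  Rendering rounds costs to 0.1,
QALYs to 0.01 and ICERs to a configurable number of decimals; all
arithmetic is done unrounded.

The model does **not** reproduce the published per-arm *total* cost and
QALY cells: the published first-year totals (e.g. A$2051.1 for TF-CBT)
are not derivable from the published unit fees (which sum to A$1474.43),
and the published no-treatment first-year QALY (0.87) exceeds any
utility-weighted mix attainable in twelve months.  The package therefore
treats the published totals as worked-example *inputs*
(`data/reference_results.yaml`) that exercise the ICER/dominance engine,
and reproduces the *structure* of the results — orderings, dominance,
reversals, the ICER ceiling — from its own unit-cost arithmetic.

## Sensitivity analysis

*One-way deterministic:* every parameter except unit costs and the
population utility norms is re-set to the low and high end of its range
(printed ranges where available, otherwise ±30% of the point estimate;
structurally-zero suicide cells are skipped) and the whole model is
re-evaluated.  *Two-way:* the TF-CBT / TF-CBT+SSRI effectiveness pair is
perturbed jointly (TF-CBT effectiveness is a component of the
combination's, so independent variation would be incoherent), as is the
PTSD+depression / depression-only utility pair (their point estimates are
counter-intuitively ordered and statistically indistinguishable).

*Probabilistic:* each trial independently draws every parameter carrying
a distribution — Beta(α, β) for probabilities, shape–rate Gamma(α, λ)
for unit costs and disease utilities (mean α/λ, matching the point
estimates within 2%) — and re-evaluates all four arms.  Suicide rates,
the recovery schedule, the co-morbid depression share (its Beta cells
are not specified) and population utility norms stay fixed.  Utility
draws above 1 are clamped with a warning; the Gamma mass above 1 at
these shapes is negligible (≈4σ).  A single seed spawns one RNG
substream per trial, so runs are bit-reproducible and individual trials
replayable.  Summaries report means, 2.5/97.5 percentile intervals and
mean-based ICERs.

## Synthetic scenarios and the microsimulation oracle

`generate_scenario` draws structurally valid random parameter sets:
probabilities uniform on [0.05, 0.95]; unit costs log-uniform on
[5, 500]; utilities uniform on [0.3, 0.95] with the well utilities forced
above every disease utility; per-cycle suicide hazards up to 0.002
preserving the PTSD+depression ≥ PTSD ordering and the zero youngest
band; recovery-schedule rates on [0.0005, 0.02].  Every generated set
passes the full validator by construction.  These scenarios emulate the
*structure* of realistic inputs, not any particular population, so tests
passing on them demonstrate engine correctness — not the clinical
accuracy of any single parameterisation.

`microsimulate` replays the identical model person-by-person: each
individual samples a year-1 branch (response/delayed/none and a baseline
depression indicator) and then 120 categorical transitions drawn from
the same per-cycle matrices the cohort engine uses, accruing the same
midpoint-valued discounted utilities and costs.  Because expectation and
sampling share one transition builder, the microsimulated mean is an
unbiased estimate of the cohort result; agreement within 3 standard
errors at n = 200,000 across 20 random scenarios × 4 arms (the
acceptance suite's headline validation) checks the cohort arithmetic —
matrix construction, half-cycle correction, discounting, cost gating —
end to end.  The simulation also audits that no trajectory ever takes a
forbidden transition and that suicide incidence by age band matches the
input hazards within binomial error.

## Numerical choices and problem sizes

* Transition rows sum to 1 within 1e-12 by construction; occupancy
  simplex conservation is asserted at that tolerance.
* Only ~12 distinct (recovery-band, age-band) matrices exist per
  evaluation; they are built once and broadcast, so a full 4-arm
  evaluation takes ~3 ms and the 20,000-trial PSA about a minute.
* Default problem sizes: 120 cycles; 1,000 PSA trials (20,000 in the
  convergence check); 200,000 individuals per microsimulation cell in
  the oracle sweep, 50,000 in the quicker reproduction script.
* Undefined ICERs (zero QALY difference) are returned as NaN, never
  raised.

## Known limitations

* Health-system perspective only: employment, education and other
  societal costs of PTSD are out of scope, as are treatment costs of
  PTSD itself beyond second-line depression management.
* The published total cost/QALY cells are not reproduced (see above);
  comparisons with them should use the worked-example table inputs.
* Integrating the published recovery schedule yields ≈31% cumulative
  spontaneous recovery among year-1 non-remitters, not the ~2/3 of the
  baseline cohort the narrative describes; the schedule is implemented
  verbatim and the narrative figures are not enforced.
* Cohort homogeneity: individuals differ only in their depression
  co-morbidity indicator; there is no further patient-level
  heterogeneity, and parameters are drawn independently in the PSA
  (the two-way analyses address the one known covariance).
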