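# ptsd-cea

A decision-analytic cost-utility model comparing four management
strategies for post-traumatic stress disorder (PTSD) in sexually abused
children — no treatment, non-directive supportive counselling,
trauma-focused cognitive behavioural therapy (TF-CBT), and TF-CBT
combined with sertraline (TF-CBT + SSRI) — from the perspective of a
public mental health care system (costs in 2010/2011 Australian dollars).

The package is aimed at health economists and mental-health services
researchers who want a tested, fully scriptable implementation of the
model: every input is a typed, validated parameter; every published
worked number is reproduced by computation; and the cohort engine is
cross-validated against an individual-level microsimulation.

## The model

A cohort of 10-year-olds with PTSD (58% with co-morbid depression) passes
through a 12-month decision tree: responders (probability
*p* = 0.42 TF-CBT, 0.44 TF-CBT+SSRI, 0.34 counselling) are well for 9 of
12 months; delayed responders — a fraction 0.17 of apparent
non-responders — for 6 of 12; non-responders stay at the baseline mixed
utility 0.58×0.53 + 0.42×0.61 = 0.5636. The end-of-year state shares
seed a 30-year Markov model (3-month cycles, ages 11–41) with nine
health states covering gradual spontaneous recovery from PTSD,
recurrent-remitting depression with second-line SSRI treatment, a
9-month medication-continuation tunnel, and state- and age-dependent
suicide and background mortality. Costs and QALYs are half-cycle
corrected and discounted at 5%/yr; strategies are compared by
incremental cost-effectiveness ratios

ICER(A, B) = (C_A − C_B) / (Q_A − Q_B),

with strict and extended dominance flagged and frontier ICERs linking
successive non-dominated strategies. One-way (±30% or published ranges),
two-way (joint effectiveness; joint utility) and 1000-trial probabilistic
sensitivity analyses (Beta draws for probabilities, shape–rate Gamma for
costs and disease utilities) complete the analysis. `docs/methods.md`
describes the model, its assumptions and all numerical choices.

## Worked example

```python
import ptsd_cea as p

params = p.load_parameters()          # shipped configuration
results = p.evaluate_all(params)      # tree + 120 Markov cycles, 4 arms
table = p.build_cea_table(results)
print(p.render_table(table, icer_decimals=2).to_string(index=False))
```

```
    strategy   cost  qaly  inc_qaly_vs_comparator  icer_vs_comparator          dominance  frontier_icer  below_wtp_threshold
no_treatment    0.0 10.68                     NaN                 NaN               none            NaN                False
 counselling 1689.9 11.71                    1.04             1631.79 strictly_dominated            NaN                 True
       tfcbt 1673.0 11.95                    1.28             1311.36               none        1311.36                 True
  tfcbt_ssri 1874.7 12.01                    1.34             1403.46               none        3360.58                 True
```

Reading the table: untreated children accrue 10.68 discounted QALYs over
31 years; every active treatment adds 1.0–1.3 QALYs at under A$1,900 per
child, so all ICERs versus no treatment sit far below the customary
A$50,000-per-QALY threshold. Counselling is *strictly dominated* — it
costs more than TF-CBT (A$1,689.9 vs A$1,673.0, because its lower
response rate leaves more children needing second-line depression
treatment) while producing fewer QALYs. Among the non-dominated
strategies the frontier ICER of TF-CBT + SSRI versus TF-CBT is
A$3,360.58 per QALY.

The same surface is available from a shell:

```sh
ptsd-cea evaluate                 # base-case CEA table
ptsd-cea evaluate --tree-only     # 12-month decision-tree results
ptsd-cea dsa --param u_ptsd       # one-way sensitivity analysis
ptsd-cea dsa2 --pair effectiveness --level low
ptsd-cea psa --trials 1000 --seed 1
ptsd-cea validate --scenarios 5 --n 50000 --seed 0
```

Note the published per-arm *total* cost and QALY cells are not derivable
from the published unit fees and utilities; those totals are shipped as
worked-example inputs (`src/ptsd_cea/data/reference_results.yaml`) that
exercise the ICER/dominance engine, while the model reproduces the
result *structure* — orderings, dominance and its sensitivity reversals,
the ICER ceiling — from its own unit-cost arithmetic (see
`docs/methods.md`).

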