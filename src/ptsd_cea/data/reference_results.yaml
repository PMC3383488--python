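# Published base-case totals of the cost-utility evaluation this package
# re-implements, used as worked-example inputs to the CEA table builder
# (ICER and dominance arithmetic). The model itself does not reproduce
# these total cost/QALY cells from unit inputs; see docs/methods.md.
short_term_12m:
  # total discounted cost per child (A$ 2010/2011) and total QALYs over
  # the 12-month decision-tree horizon
  no_treatment: {cost: 0.0, qaly: 0.87}
  counselling:  {cost: 2074.0, qaly: 0.93}
  tfcbt:        {cost: 2051.1, qaly: 0.96}
  tfcbt_ssri:   {cost: 2226.3, qaly: 0.97}
long_term_31y:
  no_treatment: {cost: 0.0, qaly: 11.59}
  counselling:  {cost: 2123.2, qaly: 12.61}
  tfcbt:        {cost: 2095.7, qaly: 12.86}
  tfcbt_ssri:   {cost: 2269.8, qaly: 12.92}
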