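# Scenario definitions for `lagcost compare --config examples/scenarios.yaml
# --population pop.csv`.  The remaining-life horizons count year 0 as the
# first year (women: 24 expected remaining life years -> years 0..23).
scenarios:
  - label: skog-10yr
    lag: {kind: skog, p: 0.80, lambda1: 0.50, lambda2: 0.93}
    horizon: {mode: fixed, years: 10}
    unit_cost: 36796.75
    discount_rate: 0.03
  - label: linear-10yr
    lag: {kind: linear}
    horizon: {mode: fixed, years: 10}
    unit_cost: 36796.75
    discount_rate: 0.03
  - label: women-remaining-life
    lag: {kind: skog, p: 0.80, lambda1: 0.50, lambda2: 0.93}
    horizon: {mode: remaining_life, years: 24}
    unit_cost: 36796.75
    discount_rate: 0.03
  # Template for a men's run (21 expected remaining life years).  The
  # published men's age-specific input table is not packaged; supply your
  # own population CSV or generate a synthetic one with `lagcost synth`.
  - label: men-remaining-life-template
    lag: {kind: skog, p: 0.80, lambda1: 0.50, lambda2: 0.93}
    horizon: {mode: remaining_life, years: 21}
    unit_cost: 36796.75
    discount_rate: 0.03
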