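# lagcost

Avoidable vs unavoidable costs of an exposure-related disease when risk
declines gradually after exposure stops.

Cost-of-illness studies price the disease burden attributable to an
exposure, but say nothing about how much of that cost an intervention could
actually remove *now*: even if alcohol consumption vanished overnight,
former drinkers would carry an elevated liver-cirrhosis risk for years.
`lagcost` is for health economists and epidemiologists who need that split.
It models the post-cessation risk decline with a two-component geometric
lag structure, decays relative risks and attributable fractions along it,
runs the year-by-year cessation counterfactual, and discounts the resulting
avoidable and unavoidable cost streams. The Swedish 2002 worked example
(women's inpatient liver-cirrhosis care) ships as a packaged fixture.

## Model

Lag weights, with defaults estimated on Swedish cirrhosis-mortality series:

    w_i = p λ1^i + (1−p) λ2^i ,      p = 0.80, λ1 = 0.50, λ2 = 0.93

Truncated at a horizon and renormalized, the running sum gives the
cumulative decline fraction c_t. Each drinking category's relative risk
then decays toward 1 as RR(1−c) + c, so the attributable fraction
AAF = S/(1+S) with excess ratio S = Σ P_i (RR_i − 1) becomes

    AAF(c) = (1−c) S / (1 + (1−c) S) ,      S = PAF / (1 − PAF),

which lets the model run directly from published attributable fractions.
Each year's AAF is applied to a case base net of the cases already avoided;
avoided and remaining attributable cases are priced at a unit cost and
discounted at 3 %/year. Details and derivations: `docs/methods.md`.

## Worked example

```python
from lagcost import (NORSTROM_PARAMS, SWEDISH_COST_CONFIG, WOMEN_TABLE1,
                     build_schedule, cost_report, run_counterfactual)

schedule = build_schedule(NORSTROM_PARAMS, horizon=10)
series = run_counterfactual(WOMEN_TABLE1, schedule)
report = cost_report(series, SWEDISH_COST_CONFIG)
print(round(series.avoided_total[0]))        # 74
print(round(report.avoidable_share * 100))   # 72
```

Of the ~331 attributable cases implied by the published per-band inputs, 74
are avoided immediately in year 0 (the short-term effect is strong), and
over the 10-year horizon 72 % of the discounted cost of alcohol-related
liver cirrhosis is avoidable; the rest is locked in by prior consumption.
The same run from the shell:

```sh
$ lagcost weights --horizon 10
year    weight  proportion      cumulative
0       1.0     0.33    0.33
1       0.59    0.19    0.52
...
9       0.11    0.03    1.0

$ lagcost fixtures export --name women_table1 --out pop.csv
$ lagcost run --population pop.csv --horizon 10 --unit-cost 36796.75 --rate 0.03
```

The report mirrors the published table layout (cases, cumulative cases
avoided, then unavoidable/avoidable cost, undiscounted and discounted, with
a totals row). Scenario comparisons (`lagcost compare`), sensitivity to the
lag parameters (`lagcost sensitivity`) and synthetic test tables
(`lagcost synth`) round out the CLI; every file-writing run drops a
`*.manifest.json` provenance record next to its output.

Note on precision: the packaged inputs carry attributable fractions at two
decimals, so absolute case counts in late years differ from the
publication's internal (unrounded) figures by up to ~1 %; ratios and
year-0 counts are unaffected. See `docs/methods.md`.

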