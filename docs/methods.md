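# Methods

## Problem and model

`lagcost` splits the cost of an exposure-related disease into an *avoidable*
part — the cost that disappears in a counterfactual where exposure ceases in
year 0 — and a part that is *unavoidable due to prior exposure*, because risk
declines only gradually after cessation. The shipped worked example is
inpatient care for alcohol-related liver cirrhosis in Sweden (2002), women,
with alcohol consumption set to zero overnight.

### Lag structure

The decline of disease risk after a consumption change is modelled as a
mixture of two geometric decays,

    w_i = p * λ1^i + (1 − p) * λ2^i ,   i = 0, 1, 2, …

with a strong short-term component (weight `p`, decay `λ1`) and a weak
persistent component (`1 − p`, `λ2`). Defaults are the Swedish time-series
estimates `p = 0.80`, `λ1 = 0.50`, `λ2 = 0.93`; the alternative set
`0.85 / 0.60 / 0.95` (British/French data) is used for sensitivity analysis.
All three parameters are dimensionless; `i` counts years after the change.

The weights never reach zero, so a finite **horizon** is imposed and the
truncated weights are renormalized: proportion per year `w_i / Σ w`,
cumulative decline fraction `c_t` the running sum. This truncation-plus-
renormalization is the completion rule — the full decline finishes inside
the horizon, exactly reproducing the published 10-year schedule (weight sum
3.073, 33% of the decline immediate, 3% in the tenth year). Two alternative
shapes are provided: *linear* (equal proportions `1/horizon`, the assumption
of earlier UK work) and *immediate* (horizon 1, the assumption of the
Canadian/Australian avoidable-cost studies).

Year indexing: lag/year 0 is the year the change occurs; the pre-change
state is labelled year −1 in reports.

### Risk decay and attribution

With cumulative decline fraction `c`, each category's relative risk decays
affinely toward 1:

    RR_new = RR(1 − c) + c   ⇔   RR_new − 1 = (1 − c)(RR − 1).

The attributable fraction over drinking categories with prevalences `P_i` is

    AAF = S / (1 + S),   S = Σ_i P_i (RR_i − 1)

(`S` is the excess ratio; abstinence has RR 1 and contributes nothing).
Because the decay scales *every* category's excess risk by the same factor
`(1 − c)`, the post-decline excess ratio is `(1 − c) S`, hence

    AAF(c) = (1 − c) S / (1 + (1 − c) S).

This is the package's central derivation: the post-decline AAF depends on
the baseline excess ratio alone, and `S = PAF / (1 − PAF)`, so the model
runs from published attributable fractions without the underlying
prevalences. Both input modes (PAF, or prevalences + RRs) are first-class
and tested to agree to 1e−12. RR < 1 (protective exposure) is rejected
rather than extrapolated: the method is stated for risk-elevating
consumption.

### Counterfactual recursion

Avoided attributable cases shrink the pool of total cases, so each year's
AAF applies to a base adjusted for the cases already avoided, per age band
`g` with `N_g` total cases:

    A_{−1,g} = PAF_g · N_g ;  base_{0,g} = N_g
    A_{t,g}   = AAF_g(c_t) · base_{t,g}
    avoided_{t,g} = A_{−1,g} − A_{t,g}          (cumulative vs year −1)
    base_{t+1,g}  = N_g − avoided_{t,g}

The base adjustment is applied within the band that generated the avoided
cases; on the packaged inputs this reproduces the published aggregate
narration (902 total cases, 74 avoided in year 0, 828 entering year 1) and
an aggregate-level adjustment agrees to within rounding. By construction
`avoided + attributable = A_{−1}` each year, and the final year's
attributable cases are exactly zero.

### Costing

Per year `t`: unavoidable cost `A_t · unit_cost`, avoidable cost
`avoided_t · unit_cost`, each discounted by division by `(1 + r)^t` (year 0
undiscounted). Defaults: unit cost 36 796.75 SEK per inpatient case, rate
r = 3 %/year. Totals sum years 0..horizon−1 (the year −1 row is context);
the avoidable share is discounted avoidable over total discounted cost.
Counting stops when `c_t` reaches 1 — the theoretical minimum risk — with an
optional `extra_years` flag that extrapolates additional years at full
avoidance for cross-horizon comparisons.

Horizons: 10 years (convention of earlier studies) and the patients'
expected remaining life years (24 for women, 21 for men, mean age 60),
counted *including* year 0 (women run years 0..23).

## Numerical choices

- All case counts, fractions and costs are carried at full double
  precision end to end; printed-style rounding (cases and SEK to integers,
  proportions to 2 d.p., shares to whole percents, half away from zero) is
  applied only at display/CSV time.
- The schedule's cumulative vector is clamped to 1 and its endpoint pinned
  to exactly 1.0, absorbing cumulative-sum float drift; this makes the
  terminal-year attributable count exactly zero.
- Validation is eager: domain types check their invariants on construction
  (parameter ranges, PAF < 1, one input mode per table, non-overlapping
  band labels), so the recursion itself never branches on bad input.
- Degenerate inputs: horizon 1 avoids everything in year 0; an all-zero-PAF
  table yields a zero-cost report whose avoidable share is 0 by convention
  (per-year shares, which divide by the baseline, raise instead).

## Reproduction accuracy

The published inputs carry PAFs at two decimals, which implies a baseline of
330.89 attributable cases against the publication's internal 328.06. All
derived *ratios* (avoidable shares, year-0 avoided counts after rounding,
RR grids) are insensitive to this ~0.9 % input perturbation and reproduce
the printed values; the *cumulative* avoided-case column drifts up to ~3
cases by year 9, and cost cells stay within ~1 % of the printed ones.
Rescaling to the internal baseline brings every year within ±1 case, so the
residual is input rounding, not algorithm. The year-0 avoidable proportion
computes to 22.4 % (printed: 23 %, from the unrounded internal inputs).

## Synthetic data

`SyntheticSpec`/`generate_population` emit population tables with the same
structure as the published one: by default 7 age bands, case counts uniform
on [1, 400] (the published bands span 2–359) and PAFs uniform on [0, 0.6]
(published: 0–0.52), bounded away from 1 where the excess ratio diverges.
Generation uses an explicit seeded `numpy` generator, never global state.
In prevalence mode, category prevalences are solved (random Dirichlet split
of the target excess ratio, shifted to the highest-risk category if the
population constraint binds) so the implied AAF equals the drawn PAF
exactly. The generator emulates table *structure* only — it does not sample
realistic consumption distributions, age gradients or sex differences — so
passing property tests demonstrates algebraic correctness (conservation,
mode equivalence, scale equivariance) on arbitrary well-formed inputs, not
epidemiological realism.

The men's published input table exists only in an appendix that is not
packaged; men's published totals are therefore documentation, not test
targets, and men are supported via user-supplied or synthetic tables.

## Known limitations

- Incident and prevalent cases at year 0 are not separated; all year-0
  cases are treated alike.
- Consumption is constant in the factual scenario and zero in the
  counterfactual; post-year-0 consumption trends are out of scope.
- One lag structure for all consumption levels (proportional-decline
  assumption); dose-specific decline shapes are not supported.
- Categorical relative risks only; no continuous dose-response.
- Health-care costs only — no crime, productivity or quality-of-life
  components, no currency conversion or inflation adjustment.
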