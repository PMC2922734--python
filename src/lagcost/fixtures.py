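"""Packaged worked-example inputs and seeded synthetic population tables.

The catalog holds the published Swedish 2002 inputs for women's inpatient
liver-cirrhosis care: the seven-age-band case/PAF table, the baseline
relative risks per drinking category, both lag-parameter sets, and the
costing configuration (36,796.75 SEK per case, 3% discounting).

The men's age-specific analogue was published only in an appendix that is
not packaged here; men are supported through user-supplied tables or the
synthetic generator below.  Synthetic tables are clearly labelled as such
and never masquerade as published data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attribution import AgeGroupRecord, PopulationTable
from .costing import CostConfig
from .lag_weights import (NORSTROM_PARAMS, SKOG_1984_PARAMS, LagParameters,
                          ValidationError)
from .risk_adjustment import RelativeRiskSet

#: Alcohol-attributable liver-cirrhosis inpatient cases, women, Sweden 2002.
WOMEN_TABLE1 = PopulationTable(
    sex="women",
    records=(
        AgeGroupRecord("0-14", 9, paf=0.0),
        AgeGroupRecord("15-17", 2, paf=0.46),
        AgeGroupRecord("18-29", 9, paf=0.52),
        AgeGroupRecord("30-49", 163, paf=0.47),
        AgeGroupRecord("50-64", 359, paf=0.44),
        AgeGroupRecord("65-79", 312, paf=0.26),
        AgeGroupRecord("80+", 48, paf=0.20),
    ),
)

#: Baseline (year -1) relative risks of liver cirrhosis, women.
BASELINE_RRS_WOMEN = RelativeRiskSet(
    {"abstinence": 1.00, "low": 1.30, "hazardous": 9.50, "harmful": 13.00})

#: Swedish costing assumptions: unit cost per inpatient case, discount rate.
SWEDISH_COST_CONFIG = CostConfig(unit_cost=36796.75, discount_rate=0.03)

_CATALOG = {
    "women_table1": WOMEN_TABLE1,
    "baseline_rrs": BASELINE_RRS_WOMEN,
    "norstrom_params": NORSTROM_PARAMS,
    "skog1984_params": SKOG_1984_PARAMS,
    "swedish_cost_config": SWEDISH_COST_CONFIG,
}


def load_fixture(name: str):
    """Return the packaged value for ``name`` (all values are immutable).

    Known names: women_table1, baseline_rrs, norstrom_params,
    skog1984_params, swedish_cost_config.
    """
    try:
        return _CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(_CATALOG)}") from None


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic population table.

    Case counts are drawn uniformly on ``cases_range`` and PAFs uniformly on
    ``paf_range`` (which must stay away from 1, where the excess ratio
    diverges).  The same seed always yields the same table.
    """

    n_bands: int = 7
    cases_range: tuple[float, float] = (1, 400)
    paf_range: tuple[float, float] = (0.0, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValidationError(f"n_bands must be >= 1, got {self.n_bands}")
        lo, hi = self.cases_range
        if not 0 <= lo <= hi:
            raise ValidationError(f"degenerate cases_range {self.cases_range}")
        plo, phi = self.paf_range
        if not 0.0 <= plo <= phi < 1.0:
            raise ValidationError(f"degenerate paf_range {self.paf_range}")


def _solve_prevalences(S: float, rrs: RelativeRiskSet,
                       rng: np.random.Generator) -> dict[str, float]:
    """Construct category prevalences whose excess ratio equals ``S`` exactly.

    Splits S across the exposed categories with random Dirichlet shares and
    sets P_i = share_i * S / (RR_i - 1); if the resulting fractions would
    exceed the population, mass is shifted to the highest-risk category.
    """
    exposed = [c for c in rrs.categories if rrs[c] > 1.0]
    if not exposed and S > 0:
        raise ValidationError("cannot realize S > 0 with all RRs equal to 1")
    if S == 0 or not exposed:
        return {c: 0.0 for c in exposed}
    shares = rng.dirichlet(np.ones(len(exposed)))
    prevs = {c: float(sh * S / (rrs[c] - 1.0))
             for c, sh in zip(exposed, shares)}
    if sum(prevs.values()) > 0.95:
        top = max(exposed, key=lambda c: rrs[c])
        prevs = {c: 0.0 for c in exposed}
        prevs[top] = S / (rrs[top] - 1.0)
        if prevs[top] > 1.0:
            raise ValidationError(
                f"S = {S} not realizable with max RR {rrs[top]}")
    return prevs


def generate_population(spec: SyntheticSpec, *, prevalence_mode: bool = False,
                        rrs: RelativeRiskSet | None = None) -> PopulationTable:
    """Generate a synthetic population table (labelled as such).

    In prevalence mode each band's category prevalences are solved so that
    the implied attributable fraction reproduces the drawn PAF exactly,
    making the two input modes interchangeable in tests.
    """
    rng = np.random.default_rng(spec.seed)
    cases = rng.uniform(*spec.cases_range, size=spec.n_bands)
    pafs = rng.uniform(*spec.paf_range, size=spec.n_bands)
    if prevalence_mode and rrs is None:
        rrs = BASELINE_RRS_WOMEN
    records = []
    for i, (n, paf) in enumerate(zip(cases, pafs)):
        band = f"band{i:02d}"
        if prevalence_mode:
            S = paf / (1.0 - paf)
            records.append(AgeGroupRecord(band, float(n),
                                          prevalences=_solve_prevalences(S, rrs, rng)))
        else:
            records.append(AgeGroupRecord(band, float(n), paf=float(paf)))
    return PopulationTable(sex="synthetic", records=records,
                           rrs=rrs if prevalence_mode else None)
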