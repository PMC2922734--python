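"""Avoidable and unavoidable inpatient costs, discounted to year-0 value.

Each year of the counterfactual splits the pre-cessation cost burden in
two: the cost of cases still occurring (*unavoidable due to prior
consumption*) and the cost of cases avoided (*avoidable*).  Undiscounted,
the two always sum to the baseline burden ``A_{-1} * unit_cost``.  Year-t
amounts are discounted by ``(1 + r)^t``; year 0 is undiscounted.

Counting stops when the cumulative risk decline reaches 1 (the theoretical
minimum risk).  Beyond that point every baseline case is avoidable each
year; ``cost_report`` can optionally extrapolate such years for exploratory
comparisons across horizons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import AttributionSeries
from .lag_weights import ValidationError

#: Table 4 / Table 7 column layout, after the year index.
REPORT_COLUMNS = (
    "cases",
    "cases_avoided",
    "unavoidable_cost_undisc",
    "avoidable_cost_undisc",
    "unavoidable_cost_disc",
    "avoidable_cost_disc",
)


@dataclass(frozen=True)
class CostConfig:
    """Unit cost per inpatient case (SEK) and annual discount rate.

    Defaults are the Swedish 2002 liver-cirrhosis values: 36,796.75 SEK per
    case and a 3% rate.
    """

    unit_cost: float = 36796.75
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValidationError(f"unit_cost must be >= 0, got {self.unit_cost}")
        if self.discount_rate <= -1:
            raise ValidationError(
                f"discount_rate must exceed -1, got {self.discount_rate}")


class UndefinedShareError(ZeroDivisionError):
    """Raised when a share is requested for a zero baseline."""


def discount(amount: float, rate: float, year: int):
    """Present (year-0) value of a year-``year`` amount: ``amount/(1+rate)^year``."""
    if rate <= -1:
        raise ValidationError(f"rate must exceed -1, got {rate}")
    year = np.asarray(year)
    if np.any(year < 0):
        raise ValidationError("year must be >= 0")
    result = np.asarray(amount) / (1.0 + rate) ** year
    return float(result) if result.ndim == 0 else result


@dataclass(frozen=True)
class CostReport:
    """Yearly cost split plus totals, mirroring the printed report tables.

    ``by_year`` carries full-precision values indexed by year, including the
    year -1 baseline row; ``totals`` sums years 0..horizon-1 only (the
    baseline row is context, not part of the counterfactual period).
    """

    by_year: pd.DataFrame
    baseline_cases: float
    unit_cost: float
    discount_rate: float

    @property
    def horizon(self) -> int:
        return int(self.by_year.index.max()) + 1

    @property
    def totals(self) -> pd.Series:
        return self.by_year.loc[0:].sum()

    @property
    def avoidable_share(self) -> float:
        """Share of total discounted cost that is avoidable, in [0, 1].

        A series with nothing avoided (and hence nothing attributable)
        has share 0 by convention.
        """
        t = self.totals
        denom = t["avoidable_cost_disc"] + t["unavoidable_cost_disc"]
        if denom == 0:
            return 0.0
        return float(t["avoidable_cost_disc"] / denom)


def cost_report(series: AttributionSeries, config: CostConfig,
                extra_years: int = 0) -> CostReport:
    """Price the counterfactual series and discount it.

    Per year t: unavoidable undiscounted cost is ``A_t * unit_cost``,
    avoidable is ``avoided_t * unit_cost``; discounted versions divide by
    ``(1 + rate)^t``.  ``extra_years`` appends years past the horizon at
    full avoidance (all baseline cases avoided, still discounted).
    """
    if extra_years < 0:
        raise ValidationError(f"extra_years must be >= 0, got {extra_years}")
    A0 = series.baseline_total
    cases = series.attributable_total
    avoided = series.avoided_total
    if extra_years:
        cases = np.concatenate([cases, np.zeros(extra_years)])
        avoided = np.concatenate([avoided, np.full(extra_years, A0)])
    years = np.arange(len(cases))

    unavoid = cases * config.unit_cost
    avoid = avoided * config.unit_cost
    body = pd.DataFrame(
        {
            "cases": cases,
            "cases_avoided": avoided,
            "unavoidable_cost_undisc": unavoid,
            "avoidable_cost_undisc": avoid,
            "unavoidable_cost_disc": discount(unavoid, config.discount_rate, years),
            "avoidable_cost_disc": discount(avoid, config.discount_rate, years),
        },
        index=pd.Index(years, name="year"),
    )
    baseline_cost = A0 * config.unit_cost
    baseline_row = pd.DataFrame(
        {
            "cases": [A0],
            "cases_avoided": [0.0],
            "unavoidable_cost_undisc": [baseline_cost],
            "avoidable_cost_undisc": [0.0],
            "unavoidable_cost_disc": [baseline_cost],
            "avoidable_cost_disc": [0.0],
        },
        index=pd.Index([-1], name="year"),
    )
    by_year = pd.concat([baseline_row, body])
    return CostReport(by_year=by_year, baseline_cases=A0,
                      unit_cost=config.unit_cost,
                      discount_rate=config.discount_rate)


def avoidable_share_by_year(report: CostReport) -> pd.Series:
    """Avoided share of the baseline burden per year: ``avoided_t / A_{-1}``.

    Nondecreasing, reaching 1.0 in the final schedule year.  Identical
    whether computed on cases or on (un)discounted costs, since every row
    scales the same baseline.
    """
    if report.baseline_cases == 0:
        raise UndefinedShareError("baseline attributable cases are zero")
    body = report.by_year.loc[0:]
    return body["cases_avoided"] / report.baseline_cases
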