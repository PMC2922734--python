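"""Named scenario runs and side-by-side comparisons.

A scenario fixes the lag-decline shape (two-component geometric, linear, or
immediate), the horizon (a fixed year count or the patients' expected
remaining life years) and the costing assumptions, then delegates to the
attribution recursion and the costing module.

Horizon conventions: the horizon counts years *including* year 0, so the
women's remaining-life scenario (24 expected remaining life years) runs
years 0..23.  "Immediate" is the degenerate one-year schedule in which the
entire risk decline — and hence the entire avoidable cost — lands in year 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .attribution import PopulationTable, run_counterfactual
from .costing import CostConfig, CostReport, cost_report
from .lag_weights import (LagParameters, LagSchedule, ValidationError,
                          build_schedule, linear_schedule)

LAG_KINDS = ("skog", "linear", "immediate")
HORIZON_MODES = ("fixed", "remaining_life")


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: lag shape + horizon + costing.

    ``horizon_mode`` is descriptive ("fixed" vs "remaining_life"); both
    interpret ``horizon`` as a year count including year 0.  ``params`` is
    only consulted for the "skog" lag kind.
    """

    label: str
    lag_kind: str = "skog"
    params: LagParameters = field(default_factory=LagParameters)
    horizon: int = 10
    horizon_mode: str = "fixed"
    costs: CostConfig = field(default_factory=CostConfig)

    def __post_init__(self) -> None:
        if self.lag_kind not in LAG_KINDS:
            raise ValidationError(f"lag_kind must be one of {LAG_KINDS}")
        if self.horizon_mode not in HORIZON_MODES:
            raise ValidationError(f"horizon_mode must be one of {HORIZON_MODES}")
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")
        if self.lag_kind == "immediate" and self.horizon != 1:
            raise ValidationError("immediate effect implies horizon 1")

    def schedule(self) -> LagSchedule:
        if self.lag_kind == "skog":
            return build_schedule(self.params, self.horizon)
        if self.lag_kind == "linear":
            return linear_schedule(self.horizon)
        return linear_schedule(1)  # immediate


#: Summary columns of the comparison tables (Tables 5/6/8/9 layout).
COMPARISON_COLUMNS = (
    "cases_unavoidable",
    "cases_avoidable",
    "costs_unavoidable_disc",
    "costs_avoidable_disc",
    "avoidable_share",
)


@dataclass(frozen=True)
class ScenarioComparison:
    """Per-scenario totals, one row per configured scenario."""

    table: pd.DataFrame

    def row(self, label: str) -> pd.Series:
        return self.table.loc[label]


def run_scenario(population: PopulationTable,
                 config: ScenarioConfig) -> CostReport:
    """Build the configured schedule and run attribution + costing."""
    series = run_counterfactual(population, config.schedule())
    return cost_report(series, config.costs)


def _summary_row(report: CostReport) -> dict:
    t = report.totals
    return {
        "cases_unavoidable": t["cases"],
        "cases_avoidable": t["cases_avoided"],
        "costs_unavoidable_disc": t["unavoidable_cost_disc"],
        "costs_avoidable_disc": t["avoidable_cost_disc"],
        "avoidable_share": report.avoidable_share,
    }


def compare_scenarios(population: PopulationTable,
                      configs: Sequence[ScenarioConfig]) -> ScenarioComparison:
    """Run each scenario and tabulate totals side by side."""
    if not configs:
        raise ValidationError("at least one scenario config required")
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate scenario labels: {labels}")
    rows = {c.label: _summary_row(run_scenario(population, c)) for c in configs}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(COMPARISON_COLUMNS))
    table.index.name = "scenario"
    return ScenarioComparison(table=table)


def sensitivity_run(population: PopulationTable,
                    parameter_sets: Sequence[LagParameters],
                    base: ScenarioConfig) -> ScenarioComparison:
    """Re-run ``base`` once per lag-parameter set, all else held fixed.

    Only meaningful for the "skog" lag kind (the other kinds ignore the
    parameters).  Labels are derived from the parameter values.
    """
    if not parameter_sets:
        raise ValidationError("at least one parameter set required")
    if base.lag_kind != "skog":
        raise ValidationError("sensitivity analysis varies skog parameters; "
                              f"base lag_kind is {base.lag_kind!r}")
    configs = [
        replace(base, params=ps,
                label=f"p={ps.p:g}, l1={ps.lambda_short:g}, l2={ps.lambda_long:g}")
        for ps in parameter_sets
    ]
    return compare_scenarios(population, configs)
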