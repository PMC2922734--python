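"""Attributable fractions and the year-by-year counterfactual case recursion.

The alcohol-attributable fraction (AAF) of cases in an age band is

    AAF = S / (1 + S),    S = sum_i P_i * (RR_i - 1)

summed over drinking categories (abstinence contributes nothing since its
RR is 1).  ``S`` — the *excess ratio* — is the ratio of attributable to
non-attributable cases.

Central enabling identity
-------------------------
After a fraction ``c`` of the post-cessation risk decline has accrued, every
category's excess risk is scaled by the same factor (RR_new - 1 =
(1 - c)(RR - 1); see :func:`lagcost.risk_adjustment.adjusted_rr`).  Hence
the post-decline excess ratio is simply ``(1 - c) * S``, and

    AAF(c) = (1 - c) * S / (1 + (1 - c) * S).

The post-decline AAF is therefore a function of the baseline excess ratio
alone — which equals ``PAF / (1 - PAF)`` — so the model runs from published
attributable fractions without knowing the underlying prevalences.  Both
input modes (printed PAF, or prevalences plus relative risks) are
first-class and provably equivalent.

Counterfactual recursion
------------------------
Consumption vanishes in year 0.  Avoided attributable cases shrink the pool
of total cases, so the year-t AAF is applied to a base adjusted for the
cases avoided in the year before, within each age band:

    A_{-1,g} = PAF_g * N_g           (pre-cessation attributable cases)
    base_{0,g} = N_g
    A_{t,g} = AAF_g(c_t) * base_{t,g}
    avoided_{t,g} = A_{-1,g} - A_{t,g}      (cumulative vs year -1)
    base_{t+1,g} = N_g - avoided_{t,g}

Fractional cases are carried unrounded throughout; integer display is a
formatting concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lag_weights import LagSchedule, ValidationError
from .risk_adjustment import RelativeRiskSet


def aaf_from_prevalence(prevalences: Mapping[str, float],
                        rrs: RelativeRiskSet) -> float:
    """Attributable fraction ``S / (1 + S)`` with ``S = sum P_i (RR_i - 1)``.

    ``prevalences`` maps drinking-category names to population fractions;
    the abstainer remainder is implicit and contributes nothing.
    """
    total = 0.0
    excess = 0.0
    for name, p in prevalences.items():
        if p < 0:
            raise ValidationError(f"negative prevalence for {name!r}: {p}")
        total += p
        excess += p * (rrs[name] - 1.0)
    if total > 1.0 + 1e-12:
        raise ValidationError(f"prevalences sum to {total} > 1")
    return excess / (1.0 + excess)


def excess_ratio_from_paf(paf: float) -> float:
    """Invert the attributable fraction: ``S = paf / (1 - paf)``."""
    if not 0.0 <= paf < 1.0:
        raise ValidationError(f"paf must be in [0, 1), got {paf}")
    return paf / (1.0 - paf)


def aaf_after_decline(S: float, decline_fraction: float) -> float:
    """Attributable fraction once a fraction ``c`` of the decline has accrued.

    ``(1 - c) S / (1 + (1 - c) S)``: the baseline AAF at c = 0, zero at
    c = 1.  Derivation in the module docstring.
    """
    if S < 0:
        raise ValidationError(f"excess ratio must be >= 0, got {S}")
    if not 0.0 <= decline_fraction <= 1.0:
        raise ValidationError(
            f"decline_fraction must be in [0, 1], got {decline_fraction}")
    scaled = (1.0 - decline_fraction) * S
    return scaled / (1.0 + scaled)


@dataclass(frozen=True)
class AgeGroupRecord:
    """One age band: total inpatient cases plus either a PAF or prevalences.

    Exactly one of ``paf`` and ``prevalences`` is set; a whole table uses one
    mode.  ``total_cases`` are persons in the pre-cessation year (-1).
    """

    age_band: str
    total_cases: float
    paf: float | None = None
    prevalences: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.total_cases < 0:
            raise ValidationError(
                f"{self.age_band}: total_cases must be >= 0, got {self.total_cases}")
        if (self.paf is None) == (self.prevalences is None):
            raise ValidationError(
                f"{self.age_band}: exactly one of paf / prevalences required")
        if self.paf is not None and not 0.0 <= self.paf < 1.0:
            raise ValidationError(
                f"{self.age_band}: paf must be in [0, 1), got {self.paf}")
        if self.prevalences is not None:
            object.__setattr__(self, "prevalences",
                               MappingProxyType(dict(self.prevalences)))


@dataclass(frozen=True)
class PopulationTable:
    """Per-age-band inputs for one sex.

    ``rrs`` is required when records are in prevalence mode (one baseline
    relative-risk set per sex, shared across bands).
    """

    sex: str
    records: Sequence[AgeGroupRecord]
    rrs: RelativeRiskSet | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("population table needs at least one record")
        bands = [r.age_band for r in self.records]
        if len(set(bands)) != len(bands):
            raise ValidationError(f"duplicate age bands: {bands}")
        modes = {r.paf is None for r in self.records}
        if len(modes) != 1:
            raise ValidationError("all records must use the same input mode")
        if self.prevalence_mode and self.rrs is None:
            raise ValidationError("prevalence-mode table requires an rrs set")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def prevalence_mode(self) -> bool:
        return self.records[0].paf is None

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(r.age_band for r in self.records)

    @property
    def total_cases(self) -> np.ndarray:
        return np.array([r.total_cases for r in self.records], dtype=float)

    def pafs(self) -> np.ndarray:
        """Per-band attributable fractions, resolved from either input mode."""
        if self.prevalence_mode:
            return np.array([aaf_from_prevalence(r.prevalences, self.rrs)
                             for r in self.records])
        return np.array([r.paf for r in self.records], dtype=float)

    def excess_ratios(self) -> np.ndarray:
        return np.array([excess_ratio_from_paf(p) for p in self.pafs()])


@dataclass(frozen=True)
class AttributionSeries:
    """Output of the counterfactual recursion, per band and year.

    ``attributable``/``avoided`` are (horizon, n_bands) arrays; ``avoided``
    is cumulative relative to year -1.  ``baseline`` holds the year -1
    attributable cases per band.
    """

    bands: tuple[str, ...]
    baseline: np.ndarray
    attributable: np.ndarray
    avoided: np.ndarray

    @property
    def horizon(self) -> int:
        return self.attributable.shape[0]

    @property
    def baseline_total(self) -> float:
        return float(self.baseline.sum())

    @property
    def attributable_total(self) -> np.ndarray:
        """Attributable cases per year, summed over bands."""
        return self.attributable.sum(axis=1)

    @property
    def avoided_total(self) -> np.ndarray:
        """Cumulative avoided cases per year, summed over bands."""
        return self.avoided.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Yearly totals with the year -1 baseline row prepended."""
        years = pd.Index(range(-1, self.horizon), name="year")
        cases = np.concatenate([[self.baseline_total], self.attributable_total])
        avoided = np.concatenate([[0.0], self.avoided_total])
        return pd.DataFrame({"cases": cases, "cases_avoided": avoided},
                            index=years)


def run_counterfactual(population: PopulationTable,
                       schedule: LagSchedule) -> AttributionSeries:
    """Run the avoided-case recursion over the schedule's horizon.

    Each band's base for year t reflects the cases avoided through year
    t - 1; totals are sums over bands at full precision.  By construction
    ``avoided + attributable`` equals the baseline exactly each year, and
    the final year's attributable cases are exactly zero (the schedule's
    cumulative decline ends at 1).
    """
    N = population.total_cases
    S = population.excess_ratios()
    baseline = population.pafs() * N

    n_years, n_bands = schedule.horizon, len(N)
    attributable = np.empty((n_years, n_bands))
    avoided = np.empty((n_years, n_bands))
    base = N.copy()
    for t, c_t in enumerate(schedule.cumulative):
        aaf_t = np.array([aaf_after_decline(s, float(c_t)) for s in S])
        attributable[t] = aaf_t * base
        avoided[t] = baseline - attributable[t]
        base = N - avoided[t]
    return AttributionSeries(bands=population.bands, baseline=baseline,
                             attributable=attributable, avoided=avoided)
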