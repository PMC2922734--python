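"""Relative-risk decay toward 1 as the cumulative risk decline accrues.

After cessation, the excess risk of a former drinker shrinks in proportion
to the realized share ``c`` of the total decline:

    RR_new = RR * (1 - c) + c  =  1 + (1 - c) * (RR - 1)

The second form makes the key identity explicit: the *excess* relative risk
``RR - 1`` is scaled by ``1 - c``.  This is what lets the attribution module
work from published attributable fractions alone, without knowing the
underlying prevalences (see :mod:`lagcost.attribution`).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .lag_weights import LagSchedule, ValidationError

#: Canonical drinking-category order (Global Burden of Disease convention).
CATEGORY_ORDER = ("abstinence", "low", "hazardous", "harmful")


class UnsupportedExposureError(ValueError):
    """Raised for protective exposures (RR < 1), which the model excludes."""


@dataclass(frozen=True)
class DrinkingCategory:
    """A consumption category with sex-specific daily-intake bounds.

    ``lower``/``upper`` are grams of pure alcohol per day; ``upper`` is
    exclusive (``None`` means unbounded).  Categories partition [0, inf).
    """

    name: str
    lower: float
    upper: float | None

    def __post_init__(self) -> None:
        if self.name not in CATEGORY_ORDER:
            raise ValidationError(f"unknown category name {self.name!r}")
        degenerate = self.upper == self.lower == 0.0  # abstinence: zero intake
        if self.lower < 0 or (self.upper is not None
                              and self.upper <= self.lower and not degenerate):
            raise ValidationError("category bounds must satisfy 0 <= lower < upper")


#: GBD category bounds, grams pure alcohol per day.  "abstinence" means no
#: alcohol within the last year; its nominal intake is zero.
CATEGORIES = {
    "women": (
        DrinkingCategory("abstinence", 0.0, 0.0),
        DrinkingCategory("low", 0.0, 20.0),
        DrinkingCategory("hazardous", 20.0, 40.0),
        DrinkingCategory("harmful", 40.0, None),
    ),
    "men": (
        DrinkingCategory("abstinence", 0.0, 0.0),
        DrinkingCategory("low", 0.0, 40.0),
        DrinkingCategory("hazardous", 40.0, 60.0),
        DrinkingCategory("harmful", 60.0, None),
    ),
}


@dataclass(frozen=True)
class RelativeRiskSet:
    """Baseline (pre-cessation, year -1) relative risks per drinking category.

    Abstinence is the reference (RR exactly 1); the model is stated for
    diseases where consumption elevates risk, so RR < 1 is rejected.
    """

    rrs: Mapping[str, float]

    def __post_init__(self) -> None:
        rrs = dict(self.rrs)
        unknown = set(rrs) - set(CATEGORY_ORDER)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        if rrs.setdefault("abstinence", 1.0) != 1.0:
            raise ValidationError("abstinence relative risk must be exactly 1")
        for name, rr in rrs.items():
            if rr < 1.0:
                raise UnsupportedExposureError(
                    f"RR({name}) = {rr} < 1: protective effects unsupported")
        object.__setattr__(self, "rrs", MappingProxyType(rrs))

    def __getitem__(self, name: str) -> float:
        return self.rrs[name]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c in CATEGORY_ORDER if c in self.rrs)


def adjusted_rr(rr: float, decline_fraction: float) -> float:
    """Relative risk after a fraction ``decline_fraction`` of the decline.

    Returns ``rr * (1 - c) + c`` with ``c = decline_fraction``; identically
    ``1 + (1 - c) * (rr - 1)``.  An affine contraction toward 1: the result
    lies in [1, rr], equals ``rr`` at c = 0 and 1 at c = 1.
    """
    if rr < 1.0:
        raise UnsupportedExposureError(f"rr = {rr} < 1 unsupported")
    if not 0.0 <= decline_fraction <= 1.0:
        raise ValidationError(
            f"decline_fraction must be in [0, 1], got {decline_fraction}")
    return rr * (1.0 - decline_fraction) + decline_fraction


def rr_decline_table(rrs: RelativeRiskSet, schedule: LagSchedule) -> pd.DataFrame:
    """Per-year relative risks after cessation, one column per category.

    The index runs from year -1 (the pre-cessation baseline row) through the
    last schedule year, where every category has returned to RR 1.  Uses the
    unrounded cumulative proportions; two-decimal display is a formatting
    concern.
    """
    cats = rrs.categories
    rows = [[rrs[c] for c in cats]]
    for c_t in schedule.cumulative:
        rows.append([adjusted_rr(rrs[cat], float(c_t)) for cat in cats])
    index = pd.Index(range(-1, schedule.horizon), name="year")
    return pd.DataFrame(rows, index=index, columns=list(cats))
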