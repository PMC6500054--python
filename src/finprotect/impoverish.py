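"""Impoverishment and poverty-gap measures due to out-of-pocket health payments.

A household is poor when its per-capita daily consumption falls strictly
below an international poverty line (US$3.1/person/day by default,
converted to survey currency and a daily basis). Comparing poverty before
and after netting out OOP health spending gives:

* the **impoverishment increment** — households above the line on gross
  expenditure pushed below it by OOP (equals the difference of head-count
  ratios when OOP is non-negative);
* the **poverty gap ratio** — average shortfall below the line as a
  percentage of the line, counting zero shortfall for the non-poor; the
  post-minus-pre difference is the gap attributable to OOP.

Averages are household-weighted by default; person-weighting
(weight x household size) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import SurveyDataset

__all__ = [
    "PovertyLine",
    "ImpoverishmentResult",
    "PovertyMeasure",
    "per_capita_daily",
    "poverty_status",
    "impoverishment",
    "poverty_gap",
]


@dataclass(frozen=True)
class PovertyLine:
    """Per-capita daily poverty line with currency/period conversions.

    ``exchange_rate`` is survey-currency units per USD and must be supplied
    by the analyst (surveys rarely document it alongside the microdata).
    """

    per_capita_daily_usd: float = 3.1
    exchange_rate: float = 1.0
    days_per_month: float = 30.0

    def __post_init__(self) -> None:
        for name in ("per_capita_daily_usd", "exchange_rate", "days_per_month"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ImpoverishmentResult:
    """Pre/post-OOP poverty head counts, the increment, and gap ratios (%)."""

    headcount_pre: float
    headcount_post: float
    impoverished_share: float
    gap_pre: float
    gap_post: float
    gap_due_to_oop: float
    stratum: str = "total"
    level: str = "total"
    n: int = 0
    weighted_n: float = 0.0


def _frame(ds) -> pd.DataFrame:
    return ds.frame if isinstance(ds, SurveyDataset) else ds


def _pc_daily_vector(df: pd.DataFrame, pl: PovertyLine, net_of_oop: bool) -> np.ndarray:
    total = df["total_expenditure"].to_numpy(dtype=float)
    if net_of_oop:
        # floor at 0 defensively; canonical data already satisfies oop <= total
        total = np.maximum(total - df["oop_health"].to_numpy(dtype=float), 0.0)
    size = df["household_size"].to_numpy(dtype=float)
    return total / size / pl.days_per_month / pl.exchange_rate


def per_capita_daily(h, pl: PovertyLine, net_of_oop: bool = False) -> float:
    """Per-capita daily consumption in USD for one household."""
    total = h["total_expenditure"] if not hasattr(h, "total_expenditure") else h.total_expenditure
    oop = h["oop_health"] if not hasattr(h, "oop_health") else h.oop_health
    size = h["household_size"] if not hasattr(h, "household_size") else h.household_size
    base = max(total - oop, 0.0) if net_of_oop else total
    return float(base) / float(size) / pl.days_per_month / pl.exchange_rate


def poverty_status(h, pl: PovertyLine, net_of_oop: bool = False) -> bool:
    """True when per-capita daily consumption lies strictly below the line."""
    return per_capita_daily(h, pl, net_of_oop) < pl.per_capita_daily_usd


class PovertyMeasure(BaseEstimator, TransformerMixin):
    """Stateless poverty transformer on survey frames.

    ``transform`` returns the boolean poverty status per household at the
    configured line; summary methods give weighted head counts, the
    impoverishment increment and poverty-gap ratios.
    """

    def __init__(
        self,
        per_capita_daily_usd: float = 3.1,
        exchange_rate: float = 1.0,
        days_per_month: float = 30.0,
        net_of_oop: bool = False,
        person_weighted: bool = False,
    ):
        self.per_capita_daily_usd = per_capita_daily_usd
        self.exchange_rate = exchange_rate
        self.days_per_month = days_per_month
        self.net_of_oop = net_of_oop
        self.person_weighted = person_weighted

    def _line(self) -> PovertyLine:
        return PovertyLine(self.per_capita_daily_usd, self.exchange_rate, self.days_per_month)

    def fit(self, X, y=None) -> "PovertyMeasure":
        self._line()  # validates parameters
        self.n_households_ = len(_frame(X))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_households_")
        df = _frame(X)
        pl = self._line()
        return _pc_daily_vector(df, pl, self.net_of_oop) < pl.per_capita_daily_usd

    def _weights(self, df: pd.DataFrame) -> np.ndarray:
        w = df["weight"].to_numpy(dtype=float)
        if self.person_weighted:
            w = w * df["household_size"].to_numpy(dtype=float)
        return w

    def headcount(self, X) -> float:
        """Weighted poverty head-count ratio at the configured line."""
        df = _frame(X)
        return float(np.average(self.transform(df), weights=self._weights(df)))

    def gap(self, X) -> float:
        """Weighted poverty-gap ratio in percent of the line."""
        df = _frame(X)
        pl = self._line()
        pc = _pc_daily_vector(df, pl, self.net_of_oop)
        shortfall = np.maximum(0.0, pl.per_capita_daily_usd - pc) / pl.per_capita_daily_usd
        return float(np.average(shortfall, weights=self._weights(df)) * 100.0)

    def summarise(self, X, stratum: str = "total", level: str = "total") -> ImpoverishmentResult:
        """Full pre/post comparison on one (sub)survey."""
        df = _frame(X)
        pl = self._line()
        w = self._weights(df)
        pre = _pc_daily_vector(df, pl, net_of_oop=False)
        post = _pc_daily_vector(df, pl, net_of_oop=True)
        poor_pre = pre < pl.per_capita_daily_usd
        poor_post = post < pl.per_capita_daily_usd
        hc_pre = float(np.average(poor_pre, weights=w))
        hc_post = float(np.average(poor_post, weights=w))
        pushed = float(np.average(~poor_pre & poor_post, weights=w))
        gap_pre = float(
            np.average(np.maximum(0.0, pl.per_capita_daily_usd - pre) / pl.per_capita_daily_usd, weights=w)
            * 100.0
        )
        gap_post = float(
            np.average(np.maximum(0.0, pl.per_capita_daily_usd - post) / pl.per_capita_daily_usd, weights=w)
            * 100.0
        )
        return ImpoverishmentResult(
            headcount_pre=hc_pre,
            headcount_post=hc_post,
            impoverished_share=pushed,
            gap_pre=gap_pre,
            gap_post=gap_post,
            gap_due_to_oop=gap_post - gap_pre,
            stratum=stratum,
            level=level,
            n=len(df),
            weighted_n=float(w.sum()),
        )


def impoverishment(
    ds, pl: PovertyLine, by: str | None = None, person_weighted: bool = False
) -> ImpoverishmentResult | list[ImpoverishmentResult]:
    """Impoverishment due to OOP, overall or stratified.

    ``by`` may name a categorical column of the survey frame (e.g.
    ``region`` or a precomputed ``quintile`` column); stratified results
    are returned alongside the overall one.
    """
    df = _frame(ds)
    measure = PovertyMeasure(
        per_capita_daily_usd=pl.per_capita_daily_usd,
        exchange_rate=pl.exchange_rate,
        days_per_month=pl.days_per_month,
        person_weighted=person_weighted,
    ).fit(df)
    if by is None:
        return measure.summarise(df)
    out = [measure.summarise(df)]
    for level, sub in df.groupby(by, observed=True, sort=True):
        out.append(measure.summarise(sub, stratum=by, level=str(level)))
    return out


def poverty_gap(ds, pl: PovertyLine, net_of_oop: bool = False, person_weighted: bool = False) -> float:
    """Weighted poverty-gap ratio (% of the line), pre or post OOP."""
    measure = PovertyMeasure(
        per_capita_daily_usd=pl.per_capita_daily_usd,
        exchange_rate=pl.exchange_rate,
        days_per_month=pl.days_per_month,
        net_of_oop=net_of_oop,
        person_weighted=person_weighted,
    ).fit(ds)
    return measure.gap(ds)
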