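"""Catastrophic health expenditure (CHE) flags, incidence and stratified tables.

Two standard constructions are implemented:

* **budget share** — a household is catastrophic when out-of-pocket (OOP)
  health spending exceeds a threshold fraction (10% / 25% by convention) of
  total consumption expenditure;
* **capacity to pay** — the denominator is household resources net of
  subsistence food needs; the conventional threshold is 40%. Subsistence is
  proxied by the weighted mean food expenditure of households whose food
  share lies in the 45th–55th weighted-percentile band of the food-share
  distribution.

The estimator :class:`CheFlagger` follows the scikit-learn protocol:
``fit`` learns the subsistence level from a survey, ``transform`` returns
per-household flags, and :meth:`CheFlagger.incidence` gives the weighted
proportion with a Wald confidence interval. Module-level functions mirror
the estimator for one-shot use.

Confidence intervals use the normal (Wald) approximation on the weighted
proportion with the unweighted stratum count as effective n, and are *not*
clamped to [0, 1] — small strata can print negative lower bounds, the
convention used in the source tables this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import (
    ACTIVITY_LEVELS,
    EDUCATION_LEVELS,
    MARITAL_LEVELS,
    REGIONS,
    SEXES,
    SurveyDataset,
)

__all__ = [
    "CheConfig",
    "IncidenceEstimate",
    "CheFlagger",
    "EstimationError",
    "food_share",
    "weighted_percentile",
    "subsistence_spending",
    "capacity_to_pay",
    "che_flag",
    "che_incidence",
    "assign_quintiles",
    "che_table",
    "STRATA",
]

#: Stratification variables of the incidence table, with their level domains.
STRATA = {
    "quintile": (1, 2, 3, 4, 5),
    "region": REGIONS,
    "gender": SEXES,
    "marital": MARITAL_LEVELS,
    "education": EDUCATION_LEVELS,
    "occupation": ACTIVITY_LEVELS,
}

_STRATUM_COLUMN = {
    "quintile": "quintile",
    "region": "region",
    "gender": "head_sex",
    "marital": "head_marital",
    "education": "head_education",
    "occupation": "head_activity",
}


class EstimationError(RuntimeError):
    """A required quantity could not be estimated from the data."""


@dataclass(frozen=True)
class CheConfig:
    """Method, threshold and conventions of one CHE definition."""

    method: str = "budget_share"  # "budget_share" | "capacity_to_pay"
    threshold: float = 0.10
    band: tuple[float, float] = (0.45, 0.55)
    strict: bool = True  # exceedance is ">" when set, ">=" otherwise
    eq_scale_beta: float = 0.0  # household_size**beta equivalisation; 0 = off
    literal_ctp_branches: bool = False  # literal (inconsistent) published branch rule

    def __post_init__(self) -> None:
        if self.method not in ("budget_share", "capacity_to_pay"):
            raise ValueError(f"unknown CHE method {self.method!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        lo, hi = self.band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("band must satisfy 0 <= low < high <= 1")

    @property
    def label(self) -> str:
        return f"{self.method}@{self.threshold:g}"


@dataclass(frozen=True)
class IncidenceEstimate:
    """Weighted proportion of catastrophic households with its Wald CI."""

    proportion: float
    ci_low: float
    ci_high: float
    n: int
    weighted_n: float
    config: CheConfig

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must lie in [0, 1]")
        if not self.ci_low <= self.proportion <= self.ci_high:
            raise ValueError("CI must bracket the proportion")


def _frame(ds) -> pd.DataFrame:
    return ds.frame if isinstance(ds, SurveyDataset) else ds


def food_share(h) -> float:
    """Food expenditure as a fraction of total expenditure for one household."""
    total = h["total_expenditure"] if not hasattr(h, "total_expenditure") else h.total_expenditure
    food = h["food_expenditure"] if not hasattr(h, "food_expenditure") else h.food_expenditure
    if total <= 0:
        raise EstimationError("food share undefined for zero total expenditure")
    return float(food) / float(total)


def weighted_percentile(values: np.ndarray, weights: np.ndarray, p: float) -> float:
    """Weighted percentile by cumulative-weight inversion, no interpolation.

    Returns the smallest observed value whose cumulative weight (values
    sorted ascending, stable for ties) reaches ``p`` of the total weight.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    target = p * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(idx, len(values) - 1)
    return float(values[order][idx])


def subsistence_spending(ds, cfg: CheConfig = CheConfig(method="capacity_to_pay", threshold=0.40)) -> float:
    """Subsistence food spending: weighted mean food expenditure of households
    whose food share lies in the closed band of weighted percentiles of the
    food-share distribution (default 45th–55th).

    With ``eq_scale_beta > 0`` food expenditures are equivalised by
    ``household_size**beta`` first, and the returned value is per
    equivalent adult (re-scaled per household downstream).
    """
    df = _frame(ds)
    if (df["total_expenditure"] <= 0).any():
        raise EstimationError("food shares undefined: zero total expenditure present")
    shares = (df["food_expenditure"] / df["total_expenditure"]).to_numpy()
    w = df["weight"].to_numpy(dtype=float)
    lo = weighted_percentile(shares, w, cfg.band[0])
    hi = weighted_percentile(shares, w, cfg.band[1])
    in_band = (shares >= lo) & (shares <= hi)
    if not in_band.any():
        raise EstimationError(f"no household inside the {cfg.band} food-share percentile band")
    food = df["food_expenditure"].to_numpy(dtype=float)
    if cfg.eq_scale_beta > 0:
        food = food / df["household_size"].to_numpy(dtype=float) ** cfg.eq_scale_beta
    return float(np.average(food[in_band], weights=w[in_band]))


def capacity_to_pay(h, se: float, literal: bool = False) -> float:
    """Household capacity to pay given subsistence spending ``se``.

    Canonical rule: non-food expenditure when observed food spending falls
    below subsistence, total minus subsistence otherwise. The ``literal``
    switch applies the published branch conditions verbatim (they swap the
    two branches; kept for sensitivity analysis).
    """
    total = h["total_expenditure"] if not hasattr(h, "total_expenditure") else h.total_expenditure
    food = h["food_expenditure"] if not hasattr(h, "food_expenditure") else h.food_expenditure
    if se < 0:
        raise ValueError("subsistence spending must be >= 0")
    if literal:
        return float(total - se) if food < se else float(total - food)
    if food >= se:
        return float(total - se)
    return float(total - food)


def _ctp_vector(df: pd.DataFrame, se_per_household: np.ndarray, literal: bool) -> np.ndarray:
    total = df["total_expenditure"].to_numpy(dtype=float)
    food = df["food_expenditure"].to_numpy(dtype=float)
    if literal:
        return np.where(food < se_per_household, total - se_per_household, total - food)
    return np.where(food >= se_per_household, total - se_per_household, total - food)


def _exceeds(share_num: np.ndarray, denom: np.ndarray, tau: float, strict: bool) -> np.ndarray:
    """Threshold comparison with the degenerate-denominator convention:
    zero denominator with zero OOP is not catastrophic; zero denominator
    with positive OOP is (the share is treated as infinite)."""
    share_num = np.asarray(share_num, dtype=float)
    denom = np.asarray(denom, dtype=float)
    out = np.zeros(share_num.shape, dtype=bool)
    ok = denom > 0
    if strict:
        out[ok] = share_num[ok] > tau * denom[ok]
    else:
        out[ok] = share_num[ok] >= tau * denom[ok]
    out[~ok] = share_num[~ok] > 0
    return out


def che_flag(h, cfg: CheConfig, se: float = 0.0) -> bool:
    """Catastrophic flag for a single household under ``cfg``."""
    oop = h["oop_health"] if not hasattr(h, "oop_health") else h.oop_health
    total = h["total_expenditure"] if not hasattr(h, "total_expenditure") else h.total_expenditure
    if cfg.method == "budget_share":
        denom = float(total)
    else:
        size = h["household_size"] if not hasattr(h, "household_size") else h.household_size
        se_h = se * float(size) ** cfg.eq_scale_beta if cfg.eq_scale_beta > 0 else se
        denom = capacity_to_pay(h, se_h, literal=cfg.literal_ctp_branches)
    return bool(_exceeds(np.array([oop]), np.array([denom]), cfg.threshold, cfg.strict)[0])


class CheFlagger(BaseEstimator, TransformerMixin):
    """Flag catastrophic health expenditure, scikit-learn style.

    Parameters
    ----------
    method : {"budget_share", "capacity_to_pay"}
        Denominator construction.
    threshold : float
        Fraction of the denominator OOP must exceed (0.10/0.25 budget
        share, 0.40 capacity to pay by convention).
    band : (float, float)
        Weighted food-share percentile band of the subsistence proxy.
    strict : bool
        ``>`` comparison when True, ``>=`` otherwise.
    eq_scale_beta : float
        Optional household-size equivalisation exponent for subsistence.
    literal_ctp_branches : bool
        Apply the literal published capacity-to-pay branch conditions.

    Attributes
    ----------
    subsistence_ : float
        Learned subsistence food spending (0.0 for budget share; per
        equivalent adult when ``eq_scale_beta > 0``).
    """

    def __init__(
        self,
        method: str = "budget_share",
        threshold: float = 0.10,
        band: tuple[float, float] = (0.45, 0.55),
        strict: bool = True,
        eq_scale_beta: float = 0.0,
        literal_ctp_branches: bool = False,
    ):
        self.method = method
        self.threshold = threshold
        self.band = band
        self.strict = strict
        self.eq_scale_beta = eq_scale_beta
        self.literal_ctp_branches = literal_ctp_branches

    def _config(self) -> CheConfig:
        return CheConfig(
            method=self.method,
            threshold=self.threshold,
            band=tuple(self.band),
            strict=self.strict,
            eq_scale_beta=self.eq_scale_beta,
            literal_ctp_branches=self.literal_ctp_branches,
        )

    def fit(self, X, y=None) -> "CheFlagger":
        cfg = self._config()  # validates parameters
        df = _frame(X)
        if len(df) == 0:
            raise ValueError("cannot fit on an empty survey")
        if cfg.method == "capacity_to_pay":
            self.subsistence_ = subsistence_spending(df, cfg)
        else:
            self.subsistence_ = 0.0
        self.n_households_ = len(df)
        return self

    def transform(self, X) -> np.ndarray:
        """Boolean catastrophic flag per household."""
        check_is_fitted(self, "subsistence_")
        cfg = self._config()
        df = _frame(X)
        oop = df["oop_health"].to_numpy(dtype=float)
        if cfg.method == "budget_share":
            denom = df["total_expenditure"].to_numpy(dtype=float)
        else:
            se_h = np.full(len(df), self.subsistence_)
            if cfg.eq_scale_beta > 0:
                se_h = se_h * df["household_size"].to_numpy(dtype=float) ** cfg.eq_scale_beta
            denom = _ctp_vector(df, se_h, cfg.literal_ctp_branches)
        return _exceeds(oop, denom, cfg.threshold, cfg.strict)

    def incidence(self, X, ci_level: float = 0.95, person_weighted: bool = False) -> IncidenceEstimate:
        """Weighted incidence of CHE with an (unclamped) Wald CI."""
        df = _frame(X)
        flags = self.transform(df)
        w = df["weight"].to_numpy(dtype=float)
        if person_weighted:
            w = w * df["household_size"].to_numpy(dtype=float)
        return _wald_incidence(flags, w, self._config(), ci_level)


def _wald_incidence(flags: np.ndarray, w: np.ndarray, cfg: CheConfig, ci_level: float) -> IncidenceEstimate:
    n = int(len(flags))
    wn = float(w.sum())
    p = float(np.sum(w * flags) / wn)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return IncidenceEstimate(
        proportion=p, ci_low=p - half, ci_high=p + half, n=n, weighted_n=wn, config=cfg
    )


def che_incidence(
    ds, cfg: CheConfig, ci_level: float = 0.95, person_weighted: bool = False
) -> IncidenceEstimate:
    """Weighted CHE incidence for one survey under one definition."""
    est = CheFlagger(**_cfg_kwargs(cfg)).fit(ds)
    return est.incidence(ds, ci_level=ci_level, person_weighted=person_weighted)


def _cfg_kwargs(cfg: CheConfig) -> dict:
    return dict(
        method=cfg.method,
        threshold=cfg.threshold,
        band=cfg.band,
        strict=cfg.strict,
        eq_scale_beta=cfg.eq_scale_beta,
        literal_ctp_branches=cfg.literal_ctp_branches,
    )


def assign_quintiles(ds) -> pd.Series:
    """Weighted quintile (1..5) of per-capita total expenditure.

    Boundaries follow cumulative weight in the sorted order; households
    with equal per-capita expenditure share the lowest applicable label,
    so a fully degenerate distribution is all quintile 1.
    """
    df = _frame(ds)
    pc = (df["total_expenditure"] / df["household_size"]).to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    order = np.argsort(pc, kind="stable")
    cum = np.cumsum(w[order])
    total = cum[-1]
    labels_sorted = np.minimum(5, np.ceil(5.0 * cum / total).astype(int))
    labels_sorted = np.maximum(labels_sorted, 1)
    labels = np.empty(len(df), dtype=int)
    labels[order] = labels_sorted
    out = pd.Series(labels, index=df.index, name="quintile")
    # ties take the lowest applicable label
    return out.groupby(pc).transform("min").astype(int).rename("quintile")


def che_table(
    ds,
    configs: Sequence[CheConfig],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Stratified incidence table: one row per (stratum, level, method, threshold).

    Subsistence is estimated once on the full survey per configuration;
    empty strata are emitted with NaN estimates (rendered "–" downstream).
    The ``total`` rows equal :func:`che_incidence` on the full dataset.
    """
    df = _frame(ds).copy()
    df["quintile"] = assign_quintiles(df)
    rows = []
    for cfg in configs:
        est = CheFlagger(**_cfg_kwargs(cfg)).fit(df)
        flags = est.transform(df)
        w = df["weight"].to_numpy(dtype=float)

        def emit(stratum: str, level, mask: np.ndarray) -> None:
            base = dict(
                stratum=stratum,
                level=str(level),
                method=cfg.method,
                threshold=cfg.threshold,
            )
            if mask.sum() == 0:
                rows.append(
                    base
                    | dict(proportion=np.nan, ci_low=np.nan, ci_high=np.nan, n=0, weighted_n=0.0)
                )
                return
            e = _wald_incidence(flags[mask], w[mask], cfg, ci_level)
            rows.append(
                base
                | dict(
                    proportion=e.proportion,
                    ci_low=e.ci_low,
                    ci_high=e.ci_high,
                    n=e.n,
                    weighted_n=e.weighted_n,
                )
            )

        for stratum, levels in STRATA.items():
            col = _STRATUM_COLUMN[stratum]
            values = df[col].to_numpy()
            for level in levels:
                emit(stratum, level, values == level)
        emit("total", "total", np.ones(len(df), dtype=bool))
    return pd.DataFrame(rows)
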