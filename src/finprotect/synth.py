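"""Synthetic household-budget-survey generator.

Emulates the statistical structure a financial-protection analysis relies
on, so every downstream stage (catastrophic-expenditure flags, poverty
measures, determinants model) can be exercised and verified without
restricted survey microdata:

* log-normal total monthly consumption expenditure, with a multiplicative
  urban premium;
* Engel behaviour — food shares generated from a logistic-transformed
  linear model in log expenditure, so shares stay inside (0, 1) and decline
  as households get richer;
* zero-inflated, heavy-tailed out-of-pocket (OOP) health spending whose
  log-scale location rises with elderly presence, a retired household head
  and (optionally) log expenditure, hard-capped at total expenditure so
  every generated record satisfies the data-model invariants;
* head-of-household demographics drawn from year-specific marginal
  prevalences;
* optional two-stage cluster design (probability-proportional-to-size
  cluster selection, then equal-size household samples) yielding
  inverse-inclusion-probability weights and a cluster effect on
  expenditure.

The generator is a test harness with known ground truth
(:func:`planted_truth`), not a replica of any real survey's joint
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    ACTIVITY_LEVELS,
    CANONICAL_COLUMNS,
    MARITAL_LEVELS,
    SurveyDataset,
)

__all__ = ["GeneratorParams", "default_params", "generate_survey", "planted_truth", "SURVEY_YEARS"]

SURVEY_YEARS = ("2001/02", "2006/07", "2012")

# Year-specific marginals used to parameterise the generator: mean household
# size, person-level shares of under-5s and over-60s (converted to
# household-presence probabilities below), and the head activity mix.
_YEAR_TARGETS = {
    "2001/02": dict(
        size=3.9,
        under5_person=0.078,
        over60_person=0.092,
        female=0.503,
        married=0.457,
        widowed=0.040,
        divorced=0.020,
        separated=0.019,
        activity=dict(
            employed=0.480, unemployed=0.046, homemaker=0.235, student=0.137, retired=0.070, other=0.032
        ),
    ),
    "2006/07": dict(
        size=3.7,
        under5_person=0.074,
        over60_person=0.104,
        female=0.506,
        married=0.466,
        widowed=0.044,
        divorced=0.022,
        separated=0.022,
        activity=dict(
            employed=0.468, unemployed=0.044, homemaker=0.229, student=0.151, retired=0.072, other=0.036
        ),
    ),
    "2012": dict(
        size=3.5,
        under5_person=0.054,
        over60_person=0.136,
        female=0.511,
        married=0.470,
        widowed=0.049,
        divorced=0.025,
        separated=0.024,
        activity=dict(
            employed=0.532, unemployed=0.044, homemaker=0.208, student=0.091, retired=0.099, other=0.026
        ),
    ),
}


@dataclass
class GeneratorParams:
    """Full parameterisation of one synthetic survey year.

    Money is in rupees per month on the log-e scale. ``oop_log_effects``
    are additive log-scale shifts of the OOP location and double as the
    planted ground truth for parameter-recovery experiments.
    """

    n_households: int = 6720
    seed: int = 0
    survey_year: str = "2012"
    urban_share: float = 0.42
    mean_household_size: float = 3.5
    log_mean_expenditure: float = 10.2
    log_sd_expenditure: float = 0.55
    engel_intercept: float = 3.15
    engel_slope: float = -0.40
    engel_noise_sd: float = 0.35
    oop_zero_prob: float = 0.35
    oop_log_mean: float = 6.5
    oop_log_sd: float = 1.2
    oop_expenditure_elasticity: float = 0.8
    oop_noise: str = "normal"  # "normal" | "logistic"
    covariate_prevalences: dict = field(default_factory=dict)
    oop_log_effects: dict = field(
        default_factory=lambda: {"elderly_over60": float(np.log(1.756)), "retired": float(np.log(3.389))}
    )
    urban_expenditure_premium: float = 1.2
    n_clusters: int = 0
    cluster_size: int = 0
    cluster_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        for name in ("urban_share", "oop_zero_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("log_sd_expenditure", "oop_log_sd", "urban_expenditure_premium"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mean_household_size < 1:
            raise ValueError("mean_household_size must be >= 1")
        if self.oop_noise not in ("normal", "logistic"):
            raise ValueError("oop_noise must be 'normal' or 'logistic'")
        for k, v in self.covariate_prevalences.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"covariate prevalence {k} must lie in [0, 1]")
        if (self.n_clusters > 0) != (self.cluster_size > 0):
            raise ValueError("n_clusters and cluster_size must be set together")


def _presence_probability(person_share: float, mean_size: float) -> float:
    """Probability a household contains at least one member of a class whose
    person-level share is ``person_share``, under random mixing."""
    return float(1.0 - (1.0 - person_share) ** mean_size)


def default_params(survey_year: str, n_households: int = 6720, seed: int = 0) -> GeneratorParams:
    """Year-specific defaults matched to the demographic marginals of the
    three Mauritian survey waves (2001/02, 2006/07, 2012)."""
    if survey_year not in _YEAR_TARGETS:
        raise ValueError(f"unknown survey year {survey_year!r}; expected one of {SURVEY_YEARS}")
    t = _YEAR_TARGETS[survey_year]
    prev = {
        "head_female": t["female"],
        "marital_married": t["married"],
        "marital_widowed": t["widowed"],
        "marital_divorced": t["divorced"],
        "marital_separated": t["separated"],
        "education_secondary_plus": 0.55,
        "child_under5": _presence_probability(t["under5_person"], t["size"]),
        "elderly_over60": _presence_probability(t["over60_person"], t["size"]),
    }
    prev.update({f"activity_{k}": v for k, v in t["activity"].items()})
    return GeneratorParams(
        n_households=n_households,
        seed=seed,
        survey_year=survey_year,
        mean_household_size=t["size"],
        covariate_prevalences=prev,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _draw_marital(rng: np.random.Generator, n: int, prev: dict) -> np.ndarray:
    p = np.array(
        [
            prev["marital_married"],
            prev["marital_widowed"],
            prev["marital_divorced"],
            prev["marital_separated"],
        ]
    )
    p = np.append(p, max(0.0, 1.0 - p.sum()))  # remainder -> single
    p = p / p.sum()
    idx = rng.choice(len(MARITAL_LEVELS), size=n, p=p)
    return np.asarray(MARITAL_LEVELS)[idx]


def _draw_activity(rng: np.random.Generator, n: int, prev: dict) -> np.ndarray:
    p = np.array([prev[f"activity_{lvl}"] for lvl in ACTIVITY_LEVELS], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(ACTIVITY_LEVELS), size=n, p=p)
    return np.asarray(ACTIVITY_LEVELS)[idx]


def generate_survey(params: GeneratorParams) -> SurveyDataset:
    """Generate one synthetic survey.

    Deterministic for a fixed ``(params, seed)``: all randomness is drawn
    from a single generator in a fixed stream order (design, region, size,
    head demographics, expenditure, food share, OOP). Every record
    satisfies the household invariants by construction.
    """
    rng = np.random.default_rng(params.seed)
    prev = dict(default_params(params.survey_year).covariate_prevalences)
    prev.update(params.covariate_prevalences)

    two_stage = params.n_clusters > 0
    if two_stage:
        n = params.n_clusters * params.cluster_size
        # PPS frame: a pool of clusters with log-normal household counts of
        # around 100 households each; selection probability proportional to
        # size, then an equal-size within-cluster sample.
        frame_size = max(params.n_clusters * 4, 20)
        cluster_counts = np.maximum(
            params.cluster_size,
            np.round(np.exp(rng.normal(np.log(100.0), 0.35, size=frame_size))).astype(int),
        )
        p_sel = cluster_counts / cluster_counts.sum()
        chosen = rng.choice(frame_size, size=params.n_clusters, replace=False, p=p_sel)
        chosen_counts = cluster_counts[chosen]
        pi_cluster = params.n_clusters * chosen_counts / cluster_counts.sum()
        pi_hh = np.clip(pi_cluster, None, 1.0) * (params.cluster_size / chosen_counts)
        cluster_of = np.repeat(np.arange(params.n_clusters), params.cluster_size)
        weight = np.repeat(1.0 / pi_hh, params.cluster_size)
        cluster_effect_per_cluster = rng.normal(0.0, params.cluster_log_sd, size=params.n_clusters)
        cluster_effect = cluster_effect_per_cluster[cluster_of]
    else:
        n = params.n_households
        weight = np.ones(n)
        cluster_effect = np.zeros(n)

    urban = rng.random(n) < params.urban_share
    size = 1 + rng.poisson(params.mean_household_size - 1.0, size=n)

    head_sex = np.where(rng.random(n) < prev["head_female"], "female", "male")
    head_marital = _draw_marital(rng, n, prev)
    head_education = np.where(
        rng.random(n) < prev["education_secondary_plus"], "secondary_plus", "primary"
    )
    head_activity = _draw_activity(rng, n, prev)
    child_under5 = rng.random(n) < prev["child_under5"]
    elderly_over60 = rng.random(n) < prev["elderly_over60"]

    log_total = (
        params.log_mean_expenditure
        + np.where(urban, np.log(params.urban_expenditure_premium), 0.0)
        + cluster_effect
        + rng.normal(0.0, params.log_sd_expenditure, size=n)
    )
    total = np.exp(log_total)

    share_logit = (
        params.engel_intercept
        + params.engel_slope * log_total
        + rng.normal(0.0, params.engel_noise_sd, size=n)
    )
    food = _sigmoid(share_logit) * total

    zero = rng.random(n) < params.oop_zero_prob
    loc = (
        params.oop_log_mean
        + params.oop_expenditure_elasticity * (log_total - params.log_mean_expenditure)
        + params.oop_log_effects.get("elderly_over60", 0.0) * elderly_over60
        + params.oop_log_effects.get("retired", 0.0) * (head_activity == "retired")
    )
    if params.oop_noise == "logistic":
        noise = rng.logistic(0.0, params.oop_log_sd, size=n)
    else:
        noise = rng.normal(0.0, params.oop_log_sd, size=n)
    oop = np.where(zero, 0.0, np.minimum(np.exp(loc + noise), total))

    year_tag = params.survey_year.replace("/", "")
    frame = pd.DataFrame(
        {
            "household_id": [f"H{year_tag}-{i:06d}" for i in range(n)],
            "weight": weight,
            "survey_year": params.survey_year,
            "region": np.where(urban, "urban", "rural"),
            "household_size": size.astype(int),
            "total_expenditure": total,
            "food_expenditure": food,
            "oop_health": oop,
            "head_sex": head_sex,
            "head_marital": head_marital,
            "head_education": head_education,
            "head_activity": head_activity,
            "has_child_under5": child_under5,
            "has_elderly_over60": elderly_over60,
        },
        columns=CANONICAL_COLUMNS,
    )
    return SurveyDataset(frame, currency="MUR", period="monthly")


def planted_truth(params: GeneratorParams) -> dict:
    """Generative ground truth for recovery experiments: the log-scale OOP
    effects actually applied plus the prevalence parameters in force."""
    prev = dict(default_params(params.survey_year).covariate_prevalences)
    prev.update(params.covariate_prevalences)
    return {
        "oop_log_effects": dict(params.oop_log_effects),
        "oop_zero_prob": params.oop_zero_prob,
        "oop_expenditure_elasticity": params.oop_expenditure_elasticity,
        "covariate_prevalences": prev,
        "urban_share": params.urban_share,
        "mean_household_size": params.mean_household_size,
    }
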