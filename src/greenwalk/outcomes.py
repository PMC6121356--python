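"""Simulated walking outcomes with known multilevel generating truth.

Walking is modelled at two levels.  Analysis 1: a binary walked/did-not-walk
decision for the full cohort from a random-intercept logistic model on
standardized exposures and covariates plus demographic contrasts.  Analysis
2: a (standardized) total-walking-time outcome for the subset who walked,
from a random-intercept linear model.  Because the survey data behind the
original analyses are confidential, the printed coefficient sets serve as
*generating truth* here: the package's recovery experiments simulate from
them and check that the fitted models give them back.

Demographic composition is drawn from the reference sample margins (age x
gender x household income drawn independently); the reference margins for
the full cohort and the walkers' subsample are shipped as defaults.

Gender enters the greenness interaction effect-coded (-1/2 male, +1/2
female), so the main greenness coefficient is the gender-averaged slope and
stratum slopes are main +/- interaction/2.  The gender main effect itself is
a conventional female dummy.  The logistic latent-scale residual variance is
fixed at pi^2/3 for intraclass-correlation bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .city import CityScene, place_dwellings
from .glmm import LOGISTIC_LATENT_VAR

__all__ = [
    "Table1Margins",
    "MAIN_SAMPLE_MARGINS",
    "WALKER_SAMPLE_MARGINS",
    "GeneratingModel",
    "reference_walk_model",
    "reference_time_model",
    "reference_posthoc_walk_model",
    "simulate_cohort",
    "simulate_walk_decision",
    "simulate_walk_time",
    "minutes_from_standardized",
    "sigma_u_for_icc",
    "AGE_BANDS",
    "INCOME_BANDS",
]

AGE_BANDS = ("5-17", "18-44", "45-64", "65+")
INCOME_BANDS = ("low", "medium_low", "medium_high", "high")
GENDERS = ("male", "female")


@dataclass(frozen=True)
class Table1Margins:
    """Marginal composition of a simulated cohort (probabilities sum to 1)."""

    age: tuple[float, float, float, float]
    gender: tuple[float, float]  # (male, female)
    income: tuple[float, float, float, float]

    def validate(self) -> None:
        for name, v in (("age", self.age), ("gender", self.gender), ("income", self.income)):
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} margins must be a probability vector")


#: Full-cohort composition (n = 24,773 survey): shares of the four age bands,
#: of male/female, and of the four household-income bands.
MAIN_SAMPLE_MARGINS = Table1Margins(
    age=(3770 / 24773, 9456 / 24773, 7905 / 24773, 3642 / 24773),
    gender=(11924 / 24773, 12849 / 24773),
    income=(6231 / 24773, 10471 / 24773, 5655 / 24773, 2416 / 24773),
)

#: Walkers' subsample composition (n = 1,994): the elderly and female are
#: oversampled relative to the full cohort, as walking propensity implies.
WALKER_SAMPLE_MARGINS = Table1Margins(
    age=(337 / 1958, 583 / 1958, 646 / 1958, 392 / 1958),
    gender=(852 / 1958, 1106 / 1958),
    income=(583 / 1958, 798 / 1958, 445 / 1958, 132 / 1958),
)


@dataclass
class GeneratingModel:
    """Coefficients that generate outcomes (log-odds or standardized-linear).

    ``coefs`` maps design-column names to effects; ``sigma_u`` is the block
    random-intercept SD on the logistic latent scale, ``sigma_b``/``sigma_e``
    the block/residual SDs of the linear model.
    """

    intercept: float
    coefs: dict[str, float]
    sigma_u: float = 0.0  # logistic
    sigma_b: float = 0.0  # linear
    sigma_e: float = 1.0  # linear

    def __post_init__(self):
        if min(self.sigma_u, self.sigma_b, self.sigma_e) < 0:
            raise ValueError("variance-component SDs must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratingModel":
        return cls(**json.loads(Path(path).read_text()))


def sigma_u_for_icc(target_icc: float) -> float:
    """Latent-scale random-intercept SD giving a target latent-threshold ICC."""
    if not 0 <= target_icc < 1:
        raise ValueError("ICC must be in [0, 1)")
    return float(np.sqrt(target_icc / (1 - target_icc) * LOGISTIC_LATENT_VAR))


#: Reference odds ratios (per SD of each standardized predictor; dummy
#: contrasts for the bands) used as generating truth for the walking-decision
#: recovery experiments, keyed by buffer radius.
REFERENCE_WALK_OR: dict[int, dict[str, float]] = {
    400: {
        "gvi": 1.149,
        "population_density": 1.050,
        "landuse_mix": 1.039,
        "intersection_density": 1.031,
        "n_shops": 1.056,
        "n_recreation": 1.008,
        "n_bus_stops": 0.997,
        "dist_mtr": 1.090,
        "age_18_44": 0.354,
        "age_45_64": 0.551,
        "age_65p": 1.763,
        "female": 1.585,
        "inc_medium_low": 0.806,
        "inc_medium_high": 0.675,
        "inc_high": 0.555,
        "gvi_x_gender": 1.070,
    },
    800: {
        "gvi": 1.193,
        "population_density": 1.047,
        "landuse_mix": 1.020,
        "intersection_density": 1.003,
        "n_shops": 1.191,
        "n_recreation": 1.000,
        "n_bus_stops": 0.948,
        "dist_mtr": 1.095,
        "age_18_44": 0.354,
        "age_45_64": 0.551,
        "age_65p": 1.760,
        "female": 1.585,
        "inc_medium_low": 0.806,
        "inc_medium_high": 0.675,
        "inc_high": 0.554,
        "gvi_x_gender": 1.091,
    },
}

#: Reference standardized betas for the walking-time recovery experiments.
REFERENCE_TIME_BETA: dict[int, dict[str, float]] = {
    400: {
        "gvi": 0.149,
        "population_density": 0.007,
        "landuse_mix": 0.048,
        "intersection_density": 0.055,
        "n_shops": -0.017,
        "n_recreation": 0.017,
        "n_bus_stops": 0.061,
        "dist_mtr": -0.004,
        "age_18_44": -0.021,
        "age_45_64": 0.097,
        "age_65p": 0.043,
        "female": 0.057,
        "inc_medium_low": -0.110,
        "inc_medium_high": -0.245,
        "inc_high": -0.365,
        "gvi_x_gender": 0.072,
    },
    800: {
        "gvi": 0.233,
        "population_density": -0.042,
        "landuse_mix": 0.006,
        "intersection_density": 0.133,
        "n_shops": 0.022,
        "n_recreation": -0.100,
        "n_bus_stops": 0.068,
        "dist_mtr": 0.012,
        "age_18_44": -0.022,
        "age_45_64": 0.101,
        "age_65p": 0.057,
        "female": 0.056,
        "inc_medium_low": -0.120,
        "inc_medium_high": -0.242,
        "inc_high": -0.376,
        "gvi_x_gender": 0.075,
    },
}

#: Reference gender-stratified greenness odds ratios (post-hoc simple slopes).
REFERENCE_STRATIFIED_WALK_OR: dict[int, dict[str, float]] = {
    400: {"female": 1.176, "male": 1.127},
    800: {"female": 1.235, "male": 1.181},
}

#: Null-model intraclass correlations of the two reference analyses.
REFERENCE_NULL_ICC = {"walk": 0.079, "time": 0.160}


def reference_walk_model(radius: int = 400, icc: float | None = None) -> GeneratingModel:
    """Walking-decision generating model from the reference odds ratios.

    Intercept 0 gives a ~50% marginal walking rate; the block SD is set so
    the latent-threshold ICC matches the reference null-model value (7.9%)
    unless overridden.
    """
    ors = REFERENCE_WALK_OR[radius]
    icc = REFERENCE_NULL_ICC["walk"] if icc is None else icc
    return GeneratingModel(
        intercept=0.0,
        coefs={k: float(np.log(v)) for k, v in ors.items()},
        sigma_u=sigma_u_for_icc(icc),
    )


def reference_time_model(
    radius: int = 400,
    icc: float | None = None,
    residual_total_var: float = 0.85,
) -> GeneratingModel:
    """Walking-time generating model on the standardized scale.

    Block and residual variances split ``residual_total_var`` in the ratio
    implied by the reference null-model ICC (16.0%); the default total keeps
    the simulated outcome variance near 1.
    """
    betas = REFERENCE_TIME_BETA[radius]
    icc = REFERENCE_NULL_ICC["time"] if icc is None else icc
    return GeneratingModel(
        intercept=0.0,
        coefs=dict(betas),
        sigma_b=float(np.sqrt(icc * residual_total_var)),
        sigma_e=float(np.sqrt((1 - icc) * residual_total_var)),
    )


def reference_posthoc_walk_model(radius: int = 800) -> GeneratingModel:
    """Walking-decision model whose greenness slopes are the reference
    gender-specific values: with effect-coded gender in the interaction, the
    main slope is the stratum mean log-OR and the interaction their
    difference (female minus male)."""
    strat = REFERENCE_STRATIFIED_WALK_OR[radius]
    lf, lm = np.log(strat["female"]), np.log(strat["male"])
    gm = reference_walk_model(radius)
    gm.coefs["gvi"] = float((lf + lm) / 2)
    gm.coefs["gvi_x_gender"] = float(lf - lm)
    return gm


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    city: CityScene,
    n: int,
    margins: Table1Margins = MAIN_SAMPLE_MARGINS,
    seed: int = 0,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Demographics plus dwelling/block assignment for n participants.

    Age, gender and income are drawn independently from the margins;
    dwellings come from :func:`greenwalk.city.place_dwellings`.
    """
    margins.validate()
    rng = np.random.default_rng(np.random.SeedSequence([city.seed, int(seed), 0xC0]))
    dwellings = place_dwellings(city, n, seed=int(seed), n_blocks=n_blocks)
    age = rng.choice(AGE_BANDS, size=n, p=margins.age)
    gender = rng.choice(GENDERS, size=n, p=margins.gender)
    income = rng.choice(INCOME_BANDS, size=n, p=margins.income)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "dwelling_id": [d.id for d in dwellings],
            "x": [d.x for d in dwellings],
            "y": [d.y for d in dwellings],
            "block_id": [d.block_id for d in dwellings],
            "estate_id": [d.estate_id for d in dwellings],
            "age_band": pd.Categorical(age, categories=AGE_BANDS),
            "gender": pd.Categorical(gender, categories=GENDERS),
            "income_band": pd.Categorical(income, categories=INCOME_BANDS),
        }
    )


def _linear_predictor(design: pd.DataFrame, gm: GeneratingModel) -> np.ndarray:
    missing = [k for k in gm.coefs if k not in design.columns]
    if missing:
        raise ValueError(f"design lacks generating-model predictors: {missing}")
    eta = np.full(len(design), gm.intercept, dtype=float)
    for name, coef in gm.coefs.items():
        eta += coef * design[name].to_numpy(dtype=float)
    return eta


def simulate_walk_decision(
    design: pd.DataFrame,
    blocks: Sequence[int],
    gm: GeneratingModel,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli walking decisions from the random-intercept logistic model.

    eta = intercept + sum(coef * x) + b_block with b ~ N(0, sigma_u^2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    codes, uniques = pd.factorize(np.asarray(blocks))
    b = rng.normal(0.0, gm.sigma_u, size=len(uniques))
    eta = _linear_predictor(design, gm) + b[codes]
    pr = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(design)) < pr).astype(int)


def simulate_walk_time(
    design: pd.DataFrame,
    blocks: Sequence[int],
    gm: GeneratingModel,
    seed: int = 0,
) -> np.ndarray:
    """Standardized walking-time outcomes from the random-intercept linear
    model: y = intercept + sum(coef * x) + u_block + eps."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x717]))
    codes, uniques = pd.factorize(np.asarray(blocks))
    u = rng.normal(0.0, gm.sigma_b, size=len(uniques))
    eps = rng.normal(0.0, gm.sigma_e, size=len(design))
    return _linear_predictor(design, gm) + u[codes] + eps


def minutes_from_standardized(
    y: np.ndarray, mean: float = 60.0, sd: float = 30.0, floor: float = 1.0
) -> tuple[np.ndarray, int]:
    """Affine back-transform of standardized walking time to minutes.

    Positivity is enforced by flooring at 1 minute; the number of floored
    values is returned for logging.  The analysis itself runs on the
    standardized scale; minutes are presentation only.
    """
    minutes = mean + sd * np.asarray(y, dtype=float)
    n_floored = int((minutes < floor).sum())
    return np.maximum(minutes, floor), n_floored
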