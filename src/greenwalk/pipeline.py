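"""End-to-end orchestration and parameter-recovery experiments.

``run_analysis1``/``run_analysis2`` execute the full chain — synthetic city,
cohort, exposures, covariates, simulated outcomes, random-intercept fits —
and emit formatted coefficient tables.  The ``*_recovery`` functions wrap
the same chain into replicated simulate-and-refit experiments whose averaged
estimates are compared to the generating truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .city import CityConfig, CityScene, generate_city
from .covariates import (
    CONTINUOUS_COVARIATES,
    compute_covariates,
    standardize,
    vif,
)
from .errors import DomainError
from .exposure import CityPointSampler, compute_exposures
from .glmm import FitResult, fit_linear_ri, fit_logistic_ri, simple_slopes
from .outcomes import (
    MAIN_SAMPLE_MARGINS,
    Table1Margins,
    WALKER_SAMPLE_MARGINS,
    reference_posthoc_walk_model,
    reference_time_model,
    reference_walk_model,
    simulate_cohort,
    simulate_walk_decision,
    simulate_walk_time,
    sigma_u_for_icc,
)

__all__ = [
    "RunConfig",
    "build_design",
    "assemble_analysis_frame",
    "run_analysis1",
    "run_analysis2",
    "walk_or_recovery",
    "time_beta_recovery",
    "icc_logistic_recovery",
    "icc_linear_recovery",
    "posthoc_female_or_recovery",
    "format_fit_table",
]

log = logging.getLogger("greenwalk")

DESIGN_COLUMNS = [
    "gvi",
    "population_density",
    "landuse_mix",
    "intersection_density",
    "n_shops",
    "n_recreation",
    "n_bus_stops",
    "dist_mtr",
    "age_18_44",
    "age_45_64",
    "age_65p",
    "female",
    "inc_medium_low",
    "inc_medium_high",
    "inc_high",
    "gvi_x_gender",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    city: CityConfig = field(default_factory=CityConfig)
    radii: tuple[float, ...] = (400.0, 800.0)
    n_participants: int = 24773
    n_walkers: int = 1994
    walker_blocks: int = 150
    exposure_mode: str = "field"  # "field" | "rendered"
    n_replicates: int = 1
    output_dir: str | None = None
    cache_dir: str | None = None


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {
            "seed": cfg.seed,
            "city": asdict(cfg.city),
            "radii": list(cfg.radii),
            "n": cfg.n_participants,
            "mode": cfg.exposure_mode,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_design(
    cohort: pd.DataFrame,
    exposure_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    radius: float,
) -> pd.DataFrame:
    """Assemble and z-score the analysis design for one buffer radius.

    Continuous predictors (mean green view index and the built-environment
    covariates) are z-scored on the analysis sample; demographic bands are
    dummy-coded against their reference levels (age 5-17, male, low income);
    the greenness x gender interaction multiplies z(gvi) by effect-coded
    gender (-1/2 male, +1/2 female).  Participants lacking exposure (empty
    buffers) are dropped; the caller can compare lengths to log exclusions.
    """
    exp_r = exposure_table[exposure_table["radius"] == radius][
        ["dwelling_id", "mean_gvi", "n_points"]
    ]
    cov_r = covariate_table[covariate_table["radius"] == radius].drop(columns="radius")
    df = cohort.merge(exp_r, on="dwelling_id").merge(cov_r, on="dwelling_id")
    n_before = len(df)
    df = df[df["n_points"] > 0].dropna(subset=["mean_gvi"]).reset_index(drop=True)
    if len(df) < n_before:
        log.info("dropped %d participants with empty buffers", n_before - len(df))

    out = pd.DataFrame(index=df.index)
    out["gvi"] = df["mean_gvi"]
    for c in CONTINUOUS_COVARIATES:
        out[c] = df[c]
    z = standardize(out, list(out.columns))
    out = z.frame

    out["age_18_44"] = (df["age_band"] == "18-44").astype(float)
    out["age_45_64"] = (df["age_band"] == "45-64").astype(float)
    out["age_65p"] = (df["age_band"] == "65+").astype(float)
    out["female"] = (df["gender"] == "female").astype(float)
    out["inc_medium_low"] = (df["income_band"] == "medium_low").astype(float)
    out["inc_medium_high"] = (df["income_band"] == "medium_high").astype(float)
    out["inc_high"] = (df["income_band"] == "high").astype(float)
    out["gvi_x_gender"] = out["gvi"] * (out["female"] - 0.5)
    out["block_id"] = df["block_id"].to_numpy()
    out["participant_id"] = df["id"].to_numpy()
    return out


def _with_intercept(design: pd.DataFrame) -> pd.DataFrame:
    X = design[DESIGN_COLUMNS].copy()
    X.insert(0, "intercept", 1.0)
    return X


def assemble_analysis_frame(
    city: CityScene,
    n: int,
    margins: Table1Margins,
    radii: Sequence[float],
    seed: int,
    n_blocks: int | None = None,
    exposure_mode: str = "field",
    sampler: CityPointSampler | None = None,
) -> dict[float, pd.DataFrame]:
    """City -> cohort -> exposures -> covariates -> per-radius design."""
    cohort = simulate_cohort(city, n, margins, seed=seed, n_blocks=n_blocks)
    dwellings = _cohort_dwellings(cohort)
    exposures = compute_exposures(
        city, dwellings, radii=radii, mode=exposure_mode, seed=seed, sampler=sampler
    )
    covs = compute_covariates(city, dwellings, radii=radii)
    return {
        r: build_design(cohort, exposures, covs, r) for r in radii
    }


def _cohort_dwellings(cohort: pd.DataFrame):
    from .city import Dwelling

    return [
        Dwelling(
            id=int(r.dwelling_id),
            x=float(r.x),
            y=float(r.y),
            block_id=int(r.block_id),
            estate_id=int(r.estate_id),
        )
        for r in cohort.itertuples()
    ]


def format_fit_table(fit: FitResult, title: str) -> str:
    """Human-readable coefficient table with an AIC/BIC/-2LL footer."""
    tab = fit.or_table() if fit.family == "binomial-logit" else fit.beta_table()
    footer = (
        f"AIC = {fit.aic:.0f}  BIC = {fit.bic:.0f}  "
        f"-2 Log Likelihood = {-2 * fit.loglik:.0f}  ICC = {fit.icc:.3f}"
    )
    return "\n".join(
        [title, tab.to_string(float_format=lambda v: f"{v:.3f}"), footer]
    )


def run_analysis1(cfg: RunConfig) -> dict[float, FitResult]:
    """Walking-decision analysis: random-intercept logistic fit per radius."""
    t0 = time.time()
    city = generate_city(cfg.city, seed=cfg.seed)
    designs = assemble_analysis_frame(
        city,
        cfg.n_participants,
        MAIN_SAMPLE_MARGINS,
        cfg.radii,
        seed=cfg.seed,
        exposure_mode=cfg.exposure_mode,
    )
    results = {}
    for radius, design in designs.items():
        gm = reference_walk_model(int(radius)) if int(radius) in (400, 800) else reference_walk_model(400)
        y = simulate_walk_decision(design, design["block_id"], gm, seed=cfg.seed)
        vifs = vif(design[CONTINUOUS_COVARIATES + ["gvi"]])
        log.info("radius %.0f: max VIF %.2f", radius, vifs.max())
        fit = fit_logistic_ri(_with_intercept(design), y, design["block_id"])
        results[radius] = fit
        log.info(
            "analysis1 radius=%.0f n=%d groups=%d elapsed=%.1fs",
            radius,
            fit.n_obs,
            fit.n_groups,
            time.time() - t0,
        )
        if cfg.output_dir:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"analysis1_{int(radius)}m.txt").write_text(
                format_fit_table(fit, f"Walking decision, {int(radius)} m buffer")
            )
    return results


def run_analysis2(cfg: RunConfig) -> dict[float, FitResult]:
    """Walking-time analysis on the walkers' subsample (linear RI fit)."""
    if cfg.n_walkers < 1:
        raise DomainError("no walkers to analyze")
    city = generate_city(cfg.city, seed=cfg.seed)
    designs = assemble_analysis_frame(
        city,
        cfg.n_walkers,
        WALKER_SAMPLE_MARGINS,
        cfg.radii,
        seed=cfg.seed + 1,
        n_blocks=cfg.walker_blocks,
        exposure_mode=cfg.exposure_mode,
    )
    results = {}
    for radius, design in designs.items():
        if design["block_id"].nunique() < 2:
            raise DomainError("fewer than 2 blocks among walkers")
        if len(design) == 0:
            raise DomainError("no walkers to analyze")
        gm = reference_time_model(int(radius)) if int(radius) in (400, 800) else reference_time_model(400)
        y = simulate_walk_time(design, design["block_id"], gm, seed=cfg.seed)
        fit = fit_linear_ri(_with_intercept(design), y, design["block_id"])
        results[radius] = fit
        if cfg.output_dir:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"analysis2_{int(radius)}m.txt").write_text(
                format_fit_table(fit, f"Walking time (standardized), {int(radius)} m buffer")
            )
    return results


# ---------------------------------------------------------------------------
# replicated parameter-recovery experiments
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), tag])
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class RecoveryResult:
    """Replicate-averaged estimate of one generating quantity."""

    estimates: np.ndarray
    truth: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def mc_se(self) -> float:
        return float(np.std(self.estimates, ddof=1) / np.sqrt(len(self.estimates)))


def walk_or_recovery(
    city: CityScene,
    radius: int = 400,
    n: int = 24773,
    n_replicates: int = 20,
    seed: int = 0,
    sampler: CityPointSampler | None = None,
    design: pd.DataFrame | None = None,
) -> RecoveryResult:
    """Mean fitted greenness odds ratio across replicated cohorts.

    One city and cohort design; each replicate redraws block effects and
    Bernoulli outcomes from the reference generating model and refits the
    random-intercept logistic model.
    """
    gm = reference_walk_model(radius)
    if design is None:
        design = assemble_analysis_frame(
            city, n, MAIN_SAMPLE_MARGINS, [float(radius)], seed=seed, sampler=sampler
        )[float(radius)]
    X = _with_intercept(design)
    ors = []
    for s in _spawn_seeds(seed, n_replicates, 0xB1 + radius):
        y = simulate_walk_decision(design, design["block_id"], gm, seed=s)
        fit = fit_logistic_ri(X, y, design["block_id"])
        ors.append(float(np.exp(fit.params["gvi"])))
    return RecoveryResult(np.array(ors), truth=float(np.exp(gm.coefs["gvi"])))


def time_beta_recovery(
    city: CityScene,
    radius: int = 400,
    n: int = 1994,
    n_blocks: int = 150,
    n_replicates: int = 20,
    seed: int = 0,
    sampler: CityPointSampler | None = None,
    design: pd.DataFrame | None = None,
) -> RecoveryResult:
    """Mean fitted standardized greenness coefficient for walking time."""
    gm = reference_time_model(radius)
    if design is None:
        design = assemble_analysis_frame(
            city,
            n,
            WALKER_SAMPLE_MARGINS,
            [float(radius)],
            seed=seed + 1,
            n_blocks=n_blocks,
            sampler=sampler,
        )[float(radius)]
    X = _with_intercept(design)
    betas = []
    for s in _spawn_seeds(seed, n_replicates, 0xB2 + radius):
        y = simulate_walk_time(design, design["block_id"], gm, seed=s)
        fit = fit_linear_ri(X, y, design["block_id"])
        betas.append(float(fit.params["gvi"]))
    return RecoveryResult(np.array(betas), truth=float(gm.coefs["gvi"]))


def icc_logistic_recovery(
    target_icc: float = 0.079,
    n: int = 24773,
    n_blocks: int = 200,
    n_replicates: int = 20,
    seed: int = 0,
) -> RecoveryResult:
    """Null-model latent-threshold ICC recovery for the binary outcome.

    Intercept-only data with block SD set from the target ICC; block sizes
    drawn from a Dirichlet-multinomial to mimic unequal estates.
    """
    sigma_u = sigma_u_for_icc(target_icc)
    iccs = []
    for s in _spawn_seeds(seed, n_replicates, 0xB5):
        rng = np.random.default_rng(s)
        sizes = rng.multinomial(n, rng.dirichlet(np.full(n_blocks, 4.0)))
        blocks = np.repeat(np.arange(n_blocks), sizes)
        b = rng.normal(0, sigma_u, size=n_blocks)
        pr = 1.0 / (1.0 + np.exp(-(b[blocks])))
        y = (rng.random(n) < pr).astype(int)
        X = pd.DataFrame({"intercept": np.ones(n)})
        fit = fit_logistic_ri(X, y, blocks)
        iccs.append(fit.icc)
    return RecoveryResult(np.array(iccs), truth=target_icc)


def icc_linear_recovery(
    target_icc: float = 0.160,
    n: int = 1994,
    n_blocks: int = 150,
    n_replicates: int = 20,
    seed: int = 0,
) -> RecoveryResult:
    """Null-model variance-ratio ICC recovery for the continuous outcome."""
    sigma_b = float(np.sqrt(target_icc))
    sigma_e = float(np.sqrt(1 - target_icc))
    iccs = []
    for s in _spawn_seeds(seed, n_replicates, 0xB6):
        rng = np.random.default_rng(s)
        sizes = rng.multinomial(n, rng.dirichlet(np.full(n_blocks, 4.0)))
        blocks = np.repeat(np.arange(n_blocks), sizes)
        y = rng.normal(0, sigma_b, size=n_blocks)[blocks] + rng.normal(0, sigma_e, size=n)
        X = pd.DataFrame({"intercept": np.ones(n)})
        fit = fit_linear_ri(X, y, blocks)
        iccs.append(fit.icc)
    return RecoveryResult(np.array(iccs), truth=target_icc)


def posthoc_female_or_recovery(
    city: CityScene,
    radius: int = 800,
    n: int = 24773,
    n_replicates: int = 20,
    seed: int = 0,
    sampler: CityPointSampler | None = None,
    design: pd.DataFrame | None = None,
) -> RecoveryResult:
    """Female-stratum greenness OR via simple slopes of the interaction model,
    on data generated with the reference gender-specific slopes."""
    gm = reference_posthoc_walk_model(radius)
    if design is None:
        design = assemble_analysis_frame(
            city, n, MAIN_SAMPLE_MARGINS, [float(radius)], seed=seed, sampler=sampler
        )[float(radius)]
    X = _with_intercept(design)
    truth_female = float(np.exp(gm.coefs["gvi"] + 0.5 * gm.coefs["gvi_x_gender"]))
    ors = []
    for s in _spawn_seeds(seed, n_replicates, 0xB8 + radius):
        y = simulate_walk_decision(design, design["block_id"], gm, seed=s)
        fit = fit_logistic_ri(X, y, design["block_id"])
        slopes = simple_slopes(fit, "gvi", "gvi_x_gender")
        ors.append(float(slopes.loc["female", "OR"]))
    return RecoveryResult(np.array(ors), truth=truth_female)
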