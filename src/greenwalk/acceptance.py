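"""Full-scale parameter-recovery suite.

Runs every headline recovery experiment at study scale — greenness odds
ratios for the walking decision (400/800 m), standardized greenness
coefficients for walking time (400/800 m), null-model intraclass
correlations for both families, segmentation validation, and the post-hoc
female-stratum odds ratio — and returns replicate-averaged values.  Used by
``greenwalk reproduce`` and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from .city import CityConfig, generate_city
from .exposure import CityPointSampler
from .outcomes import (
    MAIN_SAMPLE_MARGINS,
    WALKER_SAMPLE_MARGINS,
)
from .pipeline import (
    assemble_analysis_frame,
    icc_linear_recovery,
    icc_logistic_recovery,
    posthoc_female_or_recovery,
    time_beta_recovery,
    walk_or_recovery,
)
from .segment import validate_segmenter
from .streetscape import render_validation_corpus

N_MAIN = 24773
N_WALKERS = 1994
WALKER_BLOCKS = 150


def run_all(seed: int = 1, n_replicates: int = 20) -> dict:
    """Compute the full recovery summary.

    Returns ``{name: {"value": float, "n": int}}`` with odds ratios and betas
    on their natural scale and intraclass correlations in percent.
    """
    seed = int(seed)
    city = generate_city(CityConfig(), seed=seed)
    sampler = CityPointSampler(city)

    main_designs = assemble_analysis_frame(
        city, N_MAIN, MAIN_SAMPLE_MARGINS, [400.0, 800.0], seed=seed, sampler=sampler
    )
    walker_designs = assemble_analysis_frame(
        city,
        N_WALKERS,
        WALKER_SAMPLE_MARGINS,
        [400.0, 800.0],
        seed=seed + 1,
        n_blocks=WALKER_BLOCKS,
        sampler=sampler,
    )

    out = {}

    r = walk_or_recovery(
        city, 400, n_replicates=n_replicates, seed=seed, design=main_designs[400.0]
    )
    out["t1"] = {"value": round(r.mean, 4), "n": N_MAIN * n_replicates}

    r = walk_or_recovery(
        city, 800, n_replicates=n_replicates, seed=seed, design=main_designs[800.0]
    )
    out["t2"] = {"value": round(r.mean, 4), "n": N_MAIN * n_replicates}

    r = time_beta_recovery(
        city, 400, n_replicates=n_replicates, seed=seed, design=walker_designs[400.0]
    )
    out["t3"] = {"value": round(r.mean, 4), "n": N_WALKERS * n_replicates}

    r = time_beta_recovery(
        city, 800, n_replicates=n_replicates, seed=seed, design=walker_designs[800.0]
    )
    out["t4"] = {"value": round(r.mean, 4), "n": N_WALKERS * n_replicates}

    r = icc_logistic_recovery(n_replicates=n_replicates, seed=seed)
    out["t5"] = {"value": round(100 * r.mean, 3), "n": N_MAIN * n_replicates}

    r = icc_linear_recovery(n_replicates=n_replicates, seed=seed)
    out["t6"] = {"value": round(100 * r.mean, 3), "n": N_WALKERS * n_replicates}

    corpus = render_validation_corpus(n_images=50, seed=seed)
    report = validate_segmenter(corpus)
    out["t7"] = {"value": round(report.r, 4), "n": report.n_images}

    r = posthoc_female_or_recovery(
        city, 800, n_replicates=n_replicates, seed=seed, design=main_designs[800.0]
    )
    out["t8"] = {"value": round(r.mean, 4), "n": N_MAIN * n_replicates}

    return out
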