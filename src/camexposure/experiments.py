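"""Simulation experiments: recovery, CI calibration, test calibration.

Each function runs the full estimation path (generate -> segment ->
summarise -> design-based fit) on synthetic cohorts with known ground truth
and reports how well the estimators recover it. These are the package's own
verification experiments; the test suite and the acceptance script both call
them.
"""

from __future__ import annotations

import numpy as np

from .design import (
    SurveyDesign,
    estimate_margin_rates,
    fit_models,
    wald_interaction_test,
)
from .segmentation import segment, summarise_children
from .synthetic import GeneratorConfig, default_intensity_table, simulate_cohort

__all__ = [
    "NONCORE_TRUTH_RATE",
    "estimate_noncore_rate_once",
    "recovery_experiment",
    "coverage_experiment",
    "type1_experiment",
]

#: total non-core episode-start intensity of the default generator
#: (episodes per 10-h day), the calibration target of the margins.
NONCORE_TRUTH_RATE = 27.3

_ITAB = None


def _itab():
    global _ITAB
    if _ITAB is None:
        _ITAB = default_intensity_table()
    return _ITAB


def estimate_noncore_rate_once(seed: int, **config_kwargs) -> tuple:
    """One replicate: simulate, segment, intercept-only design-based fit.

    Returns ``(rate, ci_low, ci_high)`` for the overall non-core exposure
    rate per 10-h day. Marketing-free rows are not materialised (photo
    counts come from the wear windows), which leaves every estimate
    unchanged and keeps replicates fast.
    """
    cfg = GeneratorConfig(
        seed=seed,
        include_marketing_free=False,
        intensity_table=_itab(),
        **config_kwargs,
    )
    co = simulate_cohort(cfg)
    eps = segment(co.coded, permissive=True)
    summ = summarise_children(eps, co.children)
    svy = SurveyDesign.from_children(co.children)
    row = estimate_margin_rates(summ, svy, count_columns=["noncore_total"]).loc[
        "noncore_total"
    ]
    return float(row["rate"]), float(row["ci_low"]), float(row["ci_high"])


def recovery_experiment(seeds, **config_kwargs) -> dict:
    """Mean estimated overall non-core rate over study-size replicates.

    Default config: the full study design (9 strata, 28 schools, 168
    children, 4 x 10-h days). Returns the per-replicate estimates, their
    mean, and the Monte-Carlo standard error of the mean.
    """
    rates = np.array([estimate_noncore_rate_once(s, **config_kwargs)[0] for s in seeds])
    return {
        "rates": rates,
        "mean": float(rates.mean()),
        "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates))),
    }


def coverage_experiment(
    seeds,
    truth: float = NONCORE_TRUTH_RATE,
    schools_per_stratum: int = 3,
    children_per_school: int = 4,
    wear_days: int = 2,
) -> float:
    """Empirical coverage of the design-based CI for the overall rate.

    Reduced-size replicates (default 27 schools x 4 children x 2 days) keep
    the experiment fast while retaining the 9-stratum clustered design.
    Returns the fraction of replicates whose 95% CI covers the generator's
    non-core intensity.
    """
    hits = 0
    for s in seeds:
        _, lo, hi = estimate_noncore_rate_once(
            s,
            schools_per_stratum=schools_per_stratum,
            children_per_school=children_per_school,
            wear_days=wear_days,
        )
        hits += lo <= truth <= hi
    return hits / len(seeds)


def type1_experiment(
    seeds,
    alpha: float = 0.05,
    schools_per_stratum: int = 4,
    children_per_school: int = 4,
    wear_days: int = 2,
) -> float:
    """Type-I error of the ethnicity x decile adjusted Wald F test.

    The generator has no interaction (all stratum multipliers 1), so every
    rejection at level ``alpha`` is a false positive. Default design: 36
    schools x 4 children x 2 days — enough clusters for the F reference to
    be meaningful while keeping 400 replicates affordable.
    """
    rej = 0
    for s in seeds:
        cfg = GeneratorConfig(
            seed=s,
            include_marketing_free=False,
            intensity_table=_itab(),
            schools_per_stratum=schools_per_stratum,
            children_per_school=children_per_school,
            wear_days=wear_days,
        )
        co = simulate_cohort(cfg)
        eps = segment(co.coded, permissive=True)
        summ = summarise_children(eps, co.children)
        svy = SurveyDesign.from_children(co.children)
        fit3 = fit_models(summ, co.children, svy, outcome="noncore_total", models=(3,))[3]
        rej += wald_interaction_test(fit3).p_value < alpha
    return rej / len(seeds)
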