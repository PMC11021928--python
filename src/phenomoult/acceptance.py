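"""Recomputation of the headline quantities from scratch.

Each function runs the package's own machinery (generator, fitter,
schedule builder) on inputs defined only by published constants, and
returns the quantity on the scale the source reports (percentages as
percentages, days as days).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import moultfit, synchrony, synthdata

# published constants used as inputs
POP_MOULT_WINDOW_95 = 61.4     # days, population 95% moult window
IND_MOULT_DURATION = 7.3       # days, average individual moult duration
POP_HAULOUT_WINDOW_95 = 95.9   # days, population 95% presence window
IND_HAULOUT_DURATION = 43.8    # days, average individual haul-out duration
ADULT_MOULT_DURATION = 5.95    # days, adult reproductive females
ADULT_HAULOUT_DURATION = 42.0  # days, adult reproductive females
CATEGORY_DURATIONS = {         # days, per-category mean moult duration
    "adult": 5.95,
    "juvenile_female": 9.67,
    "juvenile_male": 10.29,
}
CATEGORY_COUNTS = {            # eligible moult cycles per model category
    "adult": 782,
    "juvenile_female": 232,
    "juvenile_male": 164,
}


def _peak_from_normal_starts(seed: int, n: int, window: float,
                             duration: float, which: str) -> float:
    """Peak single-day fraction for Normal event starts + fixed duration.

    The start s.d. is chosen so the population 95% window (lower 2.5%
    start quantile to upper 97.5% end quantile) equals ``window``:
    3.92 * sigma + duration = window.
    """
    sigma = (window - duration) / 3.92
    rng = np.random.default_rng(seed)
    starts = rng.normal(150.0, sigma, n)
    import pandas as pd

    events = pd.DataFrame({
        "arrival": starts,
        "moult_start": starts,
        "moult_end": starts + duration,
        "departure": starts + duration,
    })
    peaks = synchrony.peak_synchrony(synchrony.build_schedule(events))
    return 100.0 * peaks[which]["fraction"]


def peak_moulting_fraction(seed: int, n: int = 10000) -> float:
    """t1: % of the population moulting on the peak day (~20%)."""
    return _peak_from_normal_starts(
        seed, n, POP_MOULT_WINDOW_95, IND_MOULT_DURATION, "peak_moulting"
    )


def peak_presence_fraction(seed: int, n: int = 10000) -> float:
    """t2: % of the population ashore on the peak day (~90%)."""
    return _peak_from_normal_starts(
        seed + 1, n, POP_HAULOUT_WINDOW_95, IND_HAULOUT_DURATION, "peak_present"
    )


def moult_share_of_haulout() -> float:
    """t4: adult moult duration as a rounded % of haul-out duration."""
    return float(round(100.0 * ADULT_MOULT_DURATION / ADULT_HAULOUT_DURATION))


def weighted_mean_duration() -> float:
    """t5: cycle-count-weighted mean of category moult durations (1 dp)."""
    total = sum(CATEGORY_COUNTS.values())
    mean = sum(
        CATEGORY_COUNTS[c] * CATEGORY_DURATIONS[c] for c in CATEGORY_COUNTS
    ) / total
    return float(round(mean, 1))


def recover_category_duration(
    category: str,
    seed: int,
    n_individuals: int = 25,
    n_years: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    thin: int = 2,
) -> dict:
    """t6/t7: hierarchical-fit recovery of a category's mean moult duration.

    Generates a default synthetic colony for the category (n_individuals x
    n_years cycles), applies the inclusion filters, fits the hierarchical
    logistic model and returns the posterior mean/sd of the population
    mean 5-95% duration together with the generating value.
    """
    config = synthdata.default_config(
        n_individuals=n_individuals, categories=(category,),
        n_years=n_years, seed=seed,
    )
    _, _, records = synthdata.generate_colony(config)
    frame = synthdata.sightings_to_frame(records)
    cycles, report = moultfit.filter_cycles(moultfit.group_cycles(frame))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", moultfit.ConvergenceWarning)
        fit = moultfit.fit_hierarchical(
            cycles,
            moultfit.SamplerConfig(
                chains=2, draws=draws, warmup=warmup, thin=thin, seed=seed
            ),
        )
    draws_arr = fit.scalars["pop_mean_duration"].ravel()
    return {
        "posterior_mean": float(np.mean(draws_arr)),
        "posterior_sd": float(np.std(draws_arr, ddof=1)),
        "generating_value": config.categories[0].mean_duration,
        "n_cycles": len(cycles),
        "n_excluded": report.n_input - report.n_eligible,
        "converged": fit.converged,
    }
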