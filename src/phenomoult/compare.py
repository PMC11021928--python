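"""Category comparisons, variance partitioning and the annual-cycle chain.

Duration-like metrics (and start dates shifted to days since 1 March so
they are positive) are compared across age-sex categories with gamma
log-link mixed models (animal and year random intercepts).  Variance is
partitioned between the age-sex-category-by-year fixed structure, the
individual random effect and the residual; the phenological-compensation
regression quantifies how haul-out duration shrinks with arrival date.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import studentized_range

from ._glmm import GammaGLMM

__all__ = [
    "SEASON_ORIGIN_DAY",
    "BreedingConstants",
    "VariancePartition",
    "CategoryComparison",
    "compare_categories",
    "partition_variance",
    "compensation_regression",
    "annual_cycle_chain",
]

#: day-of-year of 1 March (non-leap): origin for positive start dates.
SEASON_ORIGIN_DAY = 60


# ---------------------------------------------------------------------------
# category comparison with grouping letters


@dataclass
class CategoryComparison:
    table: pd.DataFrame       # category, n, mean, se, letter
    contrasts: pd.DataFrame   # pair, estimate (link), se, p_adj, significant
    alpha: float
    model: object = field(repr=False, default=None)


def _grouping_letters(categories: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: maximal sets of mutually compatible levels."""
    compatible_sets = []
    for r in range(len(categories), 0, -1):
        for combo in itertools.combinations(categories, r):
            if any(
                (a, b) in different or (b, a) in different
                for a, b in itertools.combinations(combo, 2)
            ):
                continue
            if any(set(combo) <= s for s in compatible_sets):
                continue
            compatible_sets.append(set(combo))
    letters = {c: "" for c in categories}
    for letter, s in zip("abcdefghij", compatible_sets):
        for c in categories:
            if c in s:
                letters[c] += letter
    return letters


def compare_categories(
    values: np.ndarray,
    category: np.ndarray,
    animal_id: np.ndarray,
    year: np.ndarray,
    alpha: float = 0.05,
) -> CategoryComparison:
    """Gamma log-link mixed comparison of a positive metric across categories.

    Fits category as the fixed effect with animal and year random
    intercepts, then runs all-pairs contrasts with a Tukey-style
    studentized-range adjustment and assigns grouping letters (categories
    sharing a letter are not distinguishable at ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    cats = sorted(pd.unique(category))
    k = len(cats)
    cat_idx = pd.Categorical(category, categories=cats).codes
    X = np.zeros((values.size, k))
    X[np.arange(values.size), cat_idx] = 1.0  # cell-means coding

    model = GammaGLMM(
        values, X,
        {"animal": np.asarray(animal_id), "year": np.asarray(year)},
        fixed_names=list(cats),
    ).fit()

    df_resid = max(float(len(pd.unique(animal_id)) - k), 2.0)
    rows, different = [], set()
    for i, j in itertools.combinations(range(k), 2):
        diff = model.beta[i] - model.beta[j]
        se = float(np.sqrt(
            model.cov_beta[i, i] + model.cov_beta[j, j] - 2 * model.cov_beta[i, j]
        ))
        q = abs(diff) / se * np.sqrt(2.0)
        p_adj = float(studentized_range.sf(q, k, df_resid))
        sig = p_adj < alpha
        if sig:
            different.add((cats[i], cats[j]))
        rows.append({
            "pair": f"{cats[i]} - {cats[j]}",
            "estimate_link": float(diff),
            "se": se,
            "p_adj": p_adj,
            "significant": sig,
        })
    letters = _grouping_letters(cats, different)

    table = []
    for idx, c in enumerate(cats):
        sel = cat_idx == idx
        mean_link = model.beta[idx]
        se_link = float(np.sqrt(model.cov_beta[idx, idx]))
        table.append({
            "category": c,
            "n": int(sel.sum()),
            "mean": float(np.exp(mean_link)),
            "se": float(np.exp(mean_link) * se_link),  # delta method
            "letter": letters[c],
        })
    return CategoryComparison(
        table=pd.DataFrame(table),
        contrasts=pd.DataFrame(rows),
        alpha=alpha,
        model=model,
    )


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass
class VariancePartition:
    metric: str
    var_fixed: float
    var_individual: float
    var_residual: float
    flagged: bool = False
    family: str = "gamma"

    @property
    def share_individual(self) -> float:
        return self.var_individual / (
            self.var_fixed + self.var_individual + self.var_residual
        )

    @property
    def share_individual_excl_residual(self) -> float:
        return self.var_individual / (self.var_fixed + self.var_individual)

    def shares(self) -> dict[str, float]:
        total = self.var_fixed + self.var_individual + self.var_residual
        return {
            "fixed": self.var_fixed / total,
            "individual": self.var_individual / total,
            "residual": self.var_residual / total,
        }


def partition_variance(
    values: np.ndarray,
    category: np.ndarray,
    year: np.ndarray,
    animal_id: np.ndarray,
    metric: str = "metric",
    family: str = "gamma",
) -> VariancePartition:
    """Partition a metric's variance: category-by-year fixed structure vs
    individual random effect vs residual.

    The fixed component is the variance (across observations) of the
    fitted fixed-effect linear predictor; individual and residual
    components come from the mixed model.  ``family='gamma'`` partitions
    on the link (log) scale with residual variance trigamma(shape);
    ``family='gaussian'`` uses an identity-link linear mixed model.
    A single category or single year degenerates the interaction to the
    remaining main effect (flagged); at least two animals need repeat
    observations for the individual effect to be identifiable.
    """
    values = np.asarray(values, dtype=float)
    category = np.asarray(category)
    year = np.asarray(year)
    animal_id = np.asarray(animal_id)

    an_counts = pd.Series(animal_id).value_counts()
    if (an_counts > 1).sum() < 2:
        raise ValueError(
            "need >=2 animals with repeat observations to identify the individual effect"
        )

    n_cat = len(pd.unique(category))
    n_year = len(pd.unique(year))
    flagged = n_cat < 2 or n_year < 2
    if flagged:
        cell = category.astype(str) if n_year < 2 else year.astype(str)
        if n_cat < 2 and n_year < 2:
            cell = np.full(values.size, "all")
    else:
        cell = np.char.add(np.char.add(category.astype(str), "::"), year.astype(str))
    cell_codes, cell_levels = pd.factorize(cell)
    X = np.zeros((values.size, len(cell_levels)))
    X[np.arange(values.size), cell_codes] = 1.0

    if family == "gamma":
        res = GammaGLMM(values, X, {"animal": animal_id}).fit()
        fixed_pred = res.fixed_link
        var_individual = res.sigma["animal"] ** 2
        var_residual = float(polygamma(1, res.shape))
    elif family == "gaussian":
        import statsmodels.formula.api as smf

        frame = pd.DataFrame({"y": values, "cell": cell, "animal": animal_id})
        md = smf.mixedlm("y ~ 0 + C(cell)", frame, groups="animal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        fixed_pred = np.asarray(fit.predict(frame))
        var_individual = float(fit.cov_re.iloc[0, 0])
        var_residual = float(fit.scale)
    else:
        raise ValueError(f"unknown family: {family!r}")

    var_fixed = float(np.var(fixed_pred))
    return VariancePartition(
        metric=metric,
        var_fixed=var_fixed,
        var_individual=float(var_individual),
        var_residual=var_residual,
        flagged=flagged,
        family=family,
    )


# ---------------------------------------------------------------------------
# phenological compensation


@dataclass
class CompensationFit:
    category: str
    slope: float            # change in log duration per day of arrival delay
    slope_se: float
    ci_low: float
    ci_high: float
    p_value: float
    decile_ratio: float     # fitted earliest- vs latest-decile duration ratio
    n: int


def compensation_regression(
    duration: np.ndarray,
    arrival: np.ndarray,
    category: np.ndarray,
    animal_id: np.ndarray,
    min_cycles: int = 10,
) -> dict[str, CompensationFit]:
    """Per-category gamma log-link regression of haul-out duration on
    arrival date with an individual random intercept.

    Returns the per-day multiplicative slope with Wald CI and p-value,
    plus the fitted ratio of earliest-decile to latest-decile durations.
    Categories with fewer than ``min_cycles`` cycles are skipped with a
    warning.
    """
    from scipy.stats import norm

    duration = np.asarray(duration, dtype=float)
    arrival = np.asarray(arrival, dtype=float)
    category = np.asarray(category)
    animal_id = np.asarray(animal_id)

    out: dict[str, CompensationFit] = {}
    for cat in sorted(pd.unique(category)):
        sel = category == cat
        if sel.sum() < min_cycles:
            warnings.warn(
                f"category {cat!r} has {int(sel.sum())} cycles (<{min_cycles}); skipped"
            )
            continue
        arr = arrival[sel]
        arr_c = arr - arr.mean()
        X = np.column_stack([np.ones(arr_c.size), arr_c])
        res = GammaGLMM(
            duration[sel], X, {"animal": animal_id[sel]},
            fixed_names=["intercept", "arrival"],
        ).fit()
        slope, se = float(res.beta[1]), float(res.se_beta[1])
        z = slope / se
        deciles = np.quantile(arr, [0.1, 0.9])
        a_early = arr[arr <= deciles[0]].mean()
        a_late = arr[arr >= deciles[1]].mean()
        out[str(cat)] = CompensationFit(
            category=str(cat),
            slope=slope,
            slope_se=se,
            ci_low=slope - 1.96 * se,
            ci_high=slope + 1.96 * se,
            p_value=float(2.0 * norm.sf(abs(z))),
            decile_ratio=float(np.exp(slope * (a_early - a_late))),
            n=int(sel.sum()),
        )
    return out


# ---------------------------------------------------------------------------
# annual-cycle variance chain


@dataclass
class BreedingConstants:
    """External literature constants for the breeding season.

    These are configuration inputs with provenance labels, never computed
    by this pipeline.
    """

    breeding_arrival_mean: float = 15.0   # day-of-year, mid-January
    breeding_arrival_sd: float = 8.0
    birth_offset: float = 6.0             # birth = breeding arrival + 6 d
    birth_sd: float = 8.0
    lactation_days: float = 27.0          # weaning/departure = birth + 27 d
    weaning_departure_sd: float = 8.0
    provenance: str = "external-constant (published literature)"


_MOULT_EVENT_COLS = {
    "moult_arrival": "arrival",
    "moult_start": "moult_start",
    "moult_end": "moult_end",
    "moult_departure": "departure",
}


def annual_cycle_chain(
    events: pd.DataFrame,
    constants: BreedingConstants | None = None,
) -> pd.DataFrame:
    """Ordered table of annual-cycle event means and standard deviations.

    ``events`` holds per-individual moult-season dates (columns arrival,
    moult_start, moult_end, departure); breeding-season rows come from the
    literature constants.  The output reports, per event, the mean date,
    the across-individual sd and its source, and a boolean column
    ``sd_declines_from_prev`` tracking the variance chain across the
    moult-season events.
    """
    constants = constants or BreedingConstants()
    c = constants
    rows = [
        ("breeding_arrival", c.breeding_arrival_mean, c.breeding_arrival_sd, c.provenance),
        ("birth", c.breeding_arrival_mean + c.birth_offset, c.birth_sd, c.provenance),
        (
            "weaning_departure",
            c.breeding_arrival_mean + c.birth_offset + c.lactation_days,
            c.weaning_departure_sd,
            c.provenance,
        ),
    ]
    for name, col in _MOULT_EVENT_COLS.items():
        if col not in events.columns or events[col].dropna().empty:
            warnings.warn(f"annual-cycle event {name!r} missing from events; omitted")
            continue
        vals = events[col].dropna().astype(float)
        rows.append((name, float(vals.mean()), float(vals.std(ddof=1)), "this pipeline"))

    table = pd.DataFrame(rows, columns=["event", "mean_date", "sd", "source"])
    moult = table[table["source"] == "this pipeline"].reset_index(drop=True)
    decline = [np.nan] + [
        bool(moult["sd"].iloc[i] <= moult["sd"].iloc[i - 1])
        for i in range(1, len(moult))
    ]
    table["sd_declines_from_prev"] = np.nan
    table.loc[table["source"] == "this pipeline", "sd_declines_from_prev"] = decline
    return table
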