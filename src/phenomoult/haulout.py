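"""Detection-corrected arrival and departure estimation.

An animal's true arrival precedes its first sighting by however many
surveyed days it went undetected.  With per-survey-day detection
probability p, a latent arrival a <= f (first sighting) has likelihood
(1 - p)^k where k counts surveyed days in [a, f); non-surveyed days carry
no information.  The prior on a is uniform over a window before f.  The
departure side is the mirror image after the last sighting.

Detection probabilities are estimated separately for the arrival and the
departure boundary, hierarchically across years: each year's
detect/no-detect record on surveyed days strictly inside the sighting
window (when the animal was certainly ashore) is pooled through an
empirical-Bayes beta-binomial, and the posterior of each animal's latent
boundary day integrates over the year-level posterior of p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln

from .moultfit import summarize_draws

__all__ = [
    "DetectionConfig",
    "HaulOutEstimate",
    "select_subset",
    "estimate_detection",
    "fit_arrival_departure",
    "summarize_categories",
    "estimates_to_frame",
]


@dataclass
class DetectionConfig:
    window: int = 30          # days of uniform prior before first / after last sighting
    n_draws: int = 2000
    seed: int = 0
    prior_mu: float = 0.5     # hyper-prior centre for p when data are thin
    prior_kappa: float = 2.0
    fixed_p_arrival: float | None = None
    fixed_p_departure: float | None = None


@dataclass
class HaulOutEstimate:
    animal_id: str
    year: int
    category: str
    first_sighting: int
    last_sighting: int
    arrival: dict
    departure: dict
    duration: dict
    flagged: bool = False
    arrival_draws: np.ndarray | None = field(default=None, repr=False)
    departure_draws: np.ndarray | None = field(default=None, repr=False)


def select_subset(
    events: pd.DataFrame,
    ci_width_max: float = 6.0,
) -> tuple[pd.DataFrame, dict]:
    """Keep cycles whose moult-start 95% CI is strictly narrower than the cap."""
    width = events["start_q97.5"] - events["start_q2.5"]
    kept = events[width < ci_width_max].copy()
    report = {
        "n_input": int(len(events)),
        "n_kept": int(len(kept)),
        "n_dropped": int(len(events) - len(kept)),
        "ci_width_max": float(ci_width_max),
    }
    return kept, report


def _detection_counts(
    sightings: pd.DataFrame,
    calendar: dict[int, np.ndarray],
) -> dict[int, tuple[int, int]]:
    """Per-year (detections, misses) on surveyed days strictly inside each
    cycle's sighting window, when presence is certain."""
    counts: dict[int, list[int]] = {}
    for (_, year), grp in sightings.groupby(["animal_id", "year"]):
        year = int(year)
        days = np.sort(grp["date"].unique())
        if days.size < 2:
            continue
        f, l = days[0], days[-1]
        surveyed = calendar[year]
        inside = surveyed[(surveyed > f) & (surveyed < l)]
        hits = np.intersect1d(inside, days).size
        s, m = counts.setdefault(year, [0, 0])
        counts[year][0] = s + hits
        counts[year][1] = m + (inside.size - hits)
    return {y: (s, m) for y, (s, m) in counts.items()}


def estimate_detection(
    counts: dict[int, tuple[int, int]],
    config: DetectionConfig,
) -> dict[int, tuple[float, float]]:
    """Empirical-Bayes beta-binomial across years.

    Maximises the marginal likelihood over the hyper-parameters (mu,
    kappa) of a Beta(mu*kappa, (1-mu)*kappa) distribution of year-level
    detection probabilities, then returns each year's conjugate posterior
    Beta parameters.
    """
    ys = sorted(counts)
    s = np.array([counts[y][0] for y in ys], dtype=float)
    m = np.array([counts[y][1] for y in ys], dtype=float)

    def neg_marginal(theta):
        mu = 1.0 / (1.0 + np.exp(-theta[0]))
        kappa = np.exp(theta[1])
        a, b = mu * kappa, (1.0 - mu) * kappa
        ll = np.sum(betaln(a + s, b + m) - betaln(a, b))
        # weak regularisation toward the configured prior
        ll += -0.5 * ((theta[0] - np.log(0.5 / 0.5)) / 5.0) ** 2
        ll += -0.5 * ((theta[1] - np.log(2.0)) / 5.0) ** 2
        return -ll

    if len(ys) == 0:
        raise ValueError("no within-window detection data to estimate p from")
    res = minimize(neg_marginal, x0=np.array([0.0, np.log(5.0)]), method="Nelder-Mead")
    mu = 1.0 / (1.0 + np.exp(-res.x[0]))
    kappa = np.exp(res.x[1])
    return {
        y: (mu * kappa + counts[y][0], (1.0 - mu) * kappa + counts[y][1])
        for y in ys
    }


def _boundary_draws(
    rng: np.random.Generator,
    p_draws: np.ndarray,
    k_per_offset: np.ndarray,
) -> np.ndarray:
    """Sample latent offsets (days beyond the sighting) per posterior draw.

    k_per_offset[j] is the number of undetected surveyed days implied by
    offset j; the likelihood per draw is (1-p)^k over a uniform prior.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = np.log1p(-p_draws)[:, None] * k_per_offset[None, :]
    # p=1 with k=0 gives -inf*0: an offset with no missed surveys has weight 1
    logw = np.where(k_per_offset[None, :] == 0, 0.0, logw)
    logw = np.nan_to_num(logw, nan=-np.inf, neginf=-np.inf)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(p_draws.size)
    return (w.cumsum(axis=1) < u[:, None]).sum(axis=1)


def fit_arrival_departure(
    sightings: pd.DataFrame,
    calendar: dict[int, np.ndarray],
    config: DetectionConfig | None = None,
    subset: pd.DataFrame | None = None,
    keep_draws: bool = False,
) -> list[HaulOutEstimate]:
    """Estimate arrival/departure/duration per cycle.

    ``sightings`` is the standard sighting table; ``calendar`` maps year to
    the sorted array of surveyed days.  If ``subset`` (a frame with
    animal_id and year columns, e.g. from :func:`select_subset`) is given,
    only those cycles are estimated.  Duration draws are formed draw-wise
    as departure minus arrival.
    """
    config = config or DetectionConfig()
    if not calendar or all(len(v) == 0 for v in calendar.values()):
        raise ValueError("survey calendar is empty")
    rng = np.random.default_rng(config.seed)

    if subset is not None:
        keys = set(zip(subset["animal_id"].astype(str), subset["year"].astype(int)))
        mask = [
            (str(a), int(y)) in keys
            for a, y in zip(sightings["animal_id"], sightings["year"])
        ]
        sightings = sightings[np.array(mask, dtype=bool)]

    counts = _detection_counts(sightings, calendar)

    def p_sampler(fixed):
        if fixed is not None:
            return {y: np.full(config.n_draws, fixed) for y in calendar}
        post = estimate_detection(counts, config)
        out = {}
        for y in calendar:
            a, b = post.get(y, (config.prior_mu * config.prior_kappa,
                               (1 - config.prior_mu) * config.prior_kappa))
            out[y] = rng.beta(a, b, size=config.n_draws)
        return out

    p_arr = p_sampler(config.fixed_p_arrival)
    p_dep = p_sampler(config.fixed_p_departure)

    estimates = []
    for (animal, year), grp in sightings.groupby(["animal_id", "year"], sort=True):
        year = int(year)
        days = np.sort(grp["date"].unique())
        f, l = int(days[0]), int(days[-1])
        flagged = f == l
        window = config.window * (2 if flagged else 1)
        surveyed = calendar[year]

        # arrival: offsets j = f - a in [0, window]; k = surveyed days in [a, f)
        offs = np.arange(window + 1)
        k_arr = np.array([
            int(np.count_nonzero((surveyed >= f - j) & (surveyed < f)))
            for j in offs
        ])
        arr_draws = f - _boundary_draws(rng, p_arr[year], k_arr)

        # departure: offsets j = d - l in [0, window]; k = surveyed days in (l, d]
        k_dep = np.array([
            int(np.count_nonzero((surveyed > l) & (surveyed <= l + j)))
            for j in offs
        ])
        dep_draws = l + _boundary_draws(rng, p_dep[year], k_dep)

        dur_draws = dep_draws - arr_draws
        estimates.append(
            HaulOutEstimate(
                animal_id=str(animal),
                year=year,
                category=str(grp["category"].iloc[0]),
                first_sighting=f,
                last_sighting=l,
                arrival=summarize_draws(arr_draws.astype(float)),
                departure=summarize_draws(dep_draws.astype(float)),
                duration=summarize_draws(dur_draws.astype(float)),
                flagged=flagged,
                arrival_draws=arr_draws if keep_draws else None,
                departure_draws=dep_draws if keep_draws else None,
            )
        )
    return estimates


def estimates_to_frame(estimates: list[HaulOutEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {
            "animal_id": e.animal_id,
            "year": e.year,
            "category": e.category,
            "first_sighting": e.first_sighting,
            "last_sighting": e.last_sighting,
            "flagged": e.flagged,
        }
        for name, summ in (
            ("arrival", e.arrival),
            ("departure", e.departure),
            ("duration", e.duration),
        ):
            for stat, value in summ.items():
                row[f"{name}_{stat}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_categories(
    estimates: list[HaulOutEstimate],
    moult_events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Category-level means and standard errors.

    If per-cycle moult event summaries are supplied (from
    ``moultfit.derive_events``), the pre-moult gap (moult start - arrival)
    and post-moult gap (departure - moult end) are reported as well.
    Empty categories are simply absent from the output.
    """
    frame = estimates_to_frame(estimates)
    if moult_events is not None:
        frame = frame.merge(
            moult_events[["animal_id", "year", "start_mean", "end_mean"]],
            on=["animal_id", "year"],
            how="left",
        )
        frame["pre_gap"] = frame["start_mean"] - frame["arrival_mean"]
        frame["post_gap"] = frame["departure_mean"] - frame["end_mean"]

    rows = []
    for category, grp in frame.groupby("category"):
        n = len(grp)
        row = {"category": category, "n": n}
        metrics = ["arrival_mean", "departure_mean", "duration_mean"]
        if "pre_gap" in grp:
            metrics += ["pre_gap", "post_gap"]
        for m in metrics:
            vals = grp[m].dropna()
            label = m.replace("_mean", "")
            row[f"{label}_mean"] = float(vals.mean())
            row[f"{label}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
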