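"""Population-level occupancy and moulting curves.

Cumulative fractions of the population that have arrived, departed,
started and finished moulting are differenced to give the fraction
present / moulting each day; synchrony is the single-day peak of those
curves.  Day semantics are half-open: an individual counts on day t iff
start <= t < end, so cumulative differencing never double-counts a
boundary day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSchedule",
    "build_schedule",
    "peak_synchrony",
    "population_window",
]

_EVENT_COLS = ("arrival", "moult_start", "moult_end", "departure")


@dataclass
class PopulationSchedule:
    days: np.ndarray
    cum_arrived: np.ndarray
    cum_departed: np.ndarray
    cum_moult_started: np.ndarray
    cum_moult_ended: np.ndarray
    frac_present: np.ndarray
    frac_moulting: np.ndarray
    n_individuals: int
    n_rejected: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "cum_arrived": self.cum_arrived,
                "cum_departed": self.cum_departed,
                "cum_moult_started": self.cum_moult_started,
                "cum_moult_ended": self.cum_moult_ended,
                "frac_present": self.frac_present,
                "frac_moulting": self.frac_moulting,
            }
        )


def _cumulative_fraction(dates: np.ndarray, grid: np.ndarray, n: int) -> np.ndarray:
    """Fraction of the n individuals whose date is <= each grid day."""
    return np.searchsorted(np.sort(dates), grid, side="right") / n


def build_schedule(events: pd.DataFrame) -> PopulationSchedule:
    """Build daily cumulative/occupancy curves from per-individual dates.

    ``events`` needs columns arrival, moult_start, moult_end, departure
    (one row per individual; point estimates).  Rows violating the
    ordering arrival <= moult_start <= moult_end <= departure are rejected
    and counted.  Fractions use the retained individual count as
    denominator; the grid spans min(arrival)-1 to max(departure)+1.
    """
    for col in _EVENT_COLS:
        if col not in events.columns:
            raise ValueError(f"events frame is missing column {col!r}")
    ev = events[list(_EVENT_COLS)].astype(float)
    ok = (
        (ev["arrival"] <= ev["moult_start"])
        & (ev["moult_start"] <= ev["moult_end"])
        & (ev["moult_end"] <= ev["departure"])
    )
    n_rejected = int((~ok).sum())
    ev = ev[ok]
    if ev.empty:
        raise ValueError("no individuals with validly ordered event dates")
    n = len(ev)

    days = np.arange(int(np.floor(ev["arrival"].min())) - 1,
                     int(np.ceil(ev["departure"].max())) + 2)
    cum = {
        col: _cumulative_fraction(ev[col].to_numpy(), days, n)
        for col in _EVENT_COLS
    }
    return PopulationSchedule(
        days=days,
        cum_arrived=cum["arrival"],
        cum_departed=cum["departure"],
        cum_moult_started=cum["moult_start"],
        cum_moult_ended=cum["moult_end"],
        frac_present=cum["arrival"] - cum["departure"],
        frac_moulting=cum["moult_start"] - cum["moult_end"],
        n_individuals=n,
        n_rejected=n_rejected,
    )


def peak_synchrony(schedule: PopulationSchedule) -> dict:
    """Argmax day and value of the presence and moulting curves.

    Ties are broken by the earliest day (argmax convention).
    """
    ip = int(np.argmax(schedule.frac_present))
    im = int(np.argmax(schedule.frac_moulting))
    return {
        "peak_present": {
            "fraction": float(schedule.frac_present[ip]),
            "day": int(schedule.days[ip]),
        },
        "peak_moulting": {
            "fraction": float(schedule.frac_moulting[im]),
            "day": int(schedule.days[im]),
        },
    }


def population_window(
    start_dates: np.ndarray,
    end_dates: np.ndarray | None = None,
    coverage: float = 0.95,
) -> float:
    """Population-level event window length in days.

    The window runs from the (1-coverage)/2 empirical quantile of the
    start dates to the 1-(1-coverage)/2 quantile of the end dates, so a
    population where everyone shares the same dates collapses to the
    individual event duration (or to zero when only one date series is
    given).
    """
    start_dates = np.asarray(start_dates, dtype=float)
    if start_dates.size < 2:
        raise ValueError("need at least 2 dates")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    if end_dates is None:
        end_dates = start_dates
    end_dates = np.asarray(end_dates, dtype=float)
    alpha = (1.0 - coverage) / 2.0
    lo = np.quantile(start_dates, alpha)
    hi = np.quantile(end_dates, 1.0 - alpha)
    return float(hi - lo)
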