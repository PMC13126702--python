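"""Exogenous COVID-19 incidence, forced stay-home, and recovery sampling.

Infections are not transmitted between agents; each day's count is the
real municipal incidence M scaled to the simulated population,
``cases = round(n / N * M)``, and that many susceptible agents are chosen
uniformly at random (infection is independent of features and actions).
While infected, an agent's only possible action is staying at home.

Recovery is stochastic with two pathways fixed at infection time:

* standard (80%): duration = max(10, round(Gamma(shape=5, scale=3))) days;
* long COVID (20%): duration = max(35, round(Gamma(shape=9, scale=70/8)))
  days — the unclamped density peaks (mode) at (shape-1)*scale = 70 days.

Recovered agents are immune for the remainder of the run by default; a
flag returns them to the susceptible pool instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2


@dataclass(frozen=True)
class RecoveryDistribution:
    standard_shape: float = 5.0
    standard_scale: float = 3.0
    standard_minimum: int = 10
    long_shape: float = 9.0
    long_scale: float = 70.0 / 8.0  # 70/(shape-1): puts the gamma mode at 70 days
    long_minimum: int = 35
    long_fraction: float = 0.20

    def __post_init__(self) -> None:
        if min(self.standard_shape, self.standard_scale, self.long_shape,
               self.long_scale) <= 0:
            raise ValueError("gamma shapes and scales must be positive")
        if not 0.0 <= self.long_fraction <= 1.0:
            raise ValueError("long_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CaseSeries:
    """Daily new infections observed in a real population of size N."""

    dates: pd.DatetimeIndex
    new_cases: np.ndarray
    real_population_n: int

    def __post_init__(self) -> None:
        cases = np.asarray(self.new_cases, dtype=int)
        if len(cases) != len(self.dates):
            raise ValueError("dates and new_cases must have equal length")
        if np.any(cases < 0):
            raise ValueError("new_cases must be nonnegative")
        if self.real_population_n <= 0:
            raise ValueError("real population size must be positive")
        object.__setattr__(self, "new_cases", cases)

    def __len__(self) -> int:
        return len(self.dates)


def scale_cases(n: int, N: int, M: int) -> int:
    """Scale a real daily count M from population N to simulated size n.

    ``round(n / N * M)`` with half-up rounding; never negative.  Capping
    at the available susceptible pool is done at assignment time.
    """
    if N <= 0:
        raise ValueError("real population size N must be positive")
    if n <= 0:
        raise ValueError("simulated population size n must be positive")
    if M < 0:
        raise ValueError("daily case count M must be nonnegative")
    return int(math.floor(n / N * M + 0.5))


class InfectionStates:
    """Vectorized susceptible/infected/recovered state for a population."""

    def __init__(self, n: int):
        self.status = np.full(n, SUSCEPTIBLE, dtype=np.int8)
        self.days_remaining = np.zeros(n, dtype=int)
        self.long_covid = np.zeros(n, dtype=bool)
        self.total_duration = np.zeros(n, dtype=int)

    @property
    def n(self) -> int:
        return self.status.size

    @property
    def infected(self) -> np.ndarray:
        return self.status == INFECTED

    @property
    def susceptible(self) -> np.ndarray:
        return self.status == SUSCEPTIBLE

    @property
    def recovered(self) -> np.ndarray:
        return self.status == RECOVERED

    def counts(self) -> tuple[int, int, int]:
        return (
            int(self.susceptible.sum()),
            int(self.infected.sum()),
            int(self.recovered.sum()),
        )


def sample_recovery(
    long_covid,
    dist: RecoveryDistribution,
    rng: np.random.Generator,
) -> np.ndarray:
    """Whole-day recovery duration(s): rounded gamma draw, clamped at the minimum."""
    flags = np.atleast_1d(np.asarray(long_covid, dtype=bool))
    shape = np.where(flags, dist.long_shape, dist.standard_shape)
    scale = np.where(flags, dist.long_scale, dist.standard_scale)
    minimum = np.where(flags, dist.long_minimum, dist.standard_minimum)
    draws = np.rint(rng.gamma(shape, scale)).astype(int)
    out = np.maximum(draws, minimum)
    return out if np.asarray(long_covid).ndim >= 1 else int(out[0])


def assign_infections(
    states: InfectionStates,
    cases_today: int,
    rng: np.random.Generator,
    dist: RecoveryDistribution = RecoveryDistribution(),
) -> int:
    """Infect up to ``cases_today`` susceptible agents chosen uniformly.

    Each new infection receives a long-COVID flag (Bernoulli with the
    configured fraction) and a sampled recovery duration.  Returns the
    number actually infected (capped by the susceptible pool).
    """
    if cases_today < 0:
        raise ValueError("cases_today must be nonnegative")
    pool = np.flatnonzero(states.susceptible)
    k = min(cases_today, pool.size)
    if k == 0:
        return 0
    chosen = rng.choice(pool, size=k, replace=False)
    flags = rng.random(k) < dist.long_fraction
    durations = sample_recovery(flags, dist, rng)
    states.status[chosen] = INFECTED
    states.long_covid[chosen] = flags
    states.days_remaining[chosen] = durations
    states.total_duration[chosen] = durations
    return k


def step_recovery(states: InfectionStates, reinfection: bool = False) -> int:
    """End-of-day countdown: decrement infected agents; 0 days left -> recovered.

    With ``reinfection=True`` agents return to the susceptible pool
    instead of gaining immunity.  Returns the number who recovered.
    """
    inf = states.infected
    states.days_remaining[inf] -= 1
    done = inf & (states.days_remaining == 0)
    states.status[done] = SUSCEPTIBLE if reinfection else RECOVERED
    return int(done.sum())


# ---------------------------------------------------------------------------
# case-series loading (national public-health dashboard dialect)

def read_case_series(
    path: str | Path,
    real_population_n: int,
    start: str | pd.Timestamp | None = None,
    end: str | pd.Timestamp | None = None,
    municipality: str | None = None,
) -> CaseSeries:
    """Load a cumulative-positives CSV and difference it to daily incidence.

    Expected columns: ``date``, optional ``municipality``, and
    ``cumulative_positives`` (running total of reported positive tests).
    Day-over-day differences are taken after sorting by date; negative
    differences (reporting corrections) are clamped to 0.  ``start``/
    ``end`` select an inclusive date window after differencing, which must
    be fully covered by the file.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "cumulative_positives"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"case file missing columns: {sorted(missing)}")
    if municipality is not None:
        if "municipality" not in df.columns:
            raise ValueError("case file has no municipality column")
        df = df[df["municipality"] == municipality]
        if df.empty:
            raise ValueError(f"no rows for municipality {municipality!r}")
    df = df.sort_values("date").drop_duplicates("date", keep="last")
    daily = np.maximum(np.diff(df["cumulative_positives"].to_numpy(),
                               prepend=0), 0).astype(int)
    dates = pd.DatetimeIndex(df["date"])
    series = pd.Series(daily, index=dates)
    if start is not None or end is not None:
        window = pd.date_range(start or dates[0], end or dates[-1], freq="D")
        if not window.isin(dates).all():
            raise ValueError("case file does not cover the requested window")
        series = series.loc[window]
    return CaseSeries(
        dates=pd.DatetimeIndex(series.index),
        new_cases=series.to_numpy(),
        real_population_n=real_population_n,
    )


def write_case_series(series: CaseSeries, path: str | Path,
                      municipality: str | None = None) -> None:
    """Write daily incidence back out in the cumulative dialect."""
    df = pd.DataFrame(
        {
            "date": series.dates.strftime("%Y-%m-%d"),
            "cumulative_positives": np.cumsum(series.new_cases),
        }
    )
    if municipality is not None:
        df.insert(1, "municipality", municipality)
    df.to_csv(path, index=False)
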