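"""Grouped 5-year survival rate and the Kaplan-Meier product-limit curve."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BINS",
    "GroupedLengths",
    "SurvivalCurve",
    "grouped_survival_rate",
    "km_estimate",
    "survival_rate_at",
    "group_lengths",
]

#: Conventional survival-length bins in months: five closed year bins
#: below the 5-year mark and one open survivor bin.
DEFAULT_BINS = ("1-12", "13-24", "25-36", "37-48", "49-60", ">60")


@dataclass(frozen=True)
class GroupedLengths:
    """Ordered survival-length bins with counts; last bin is the survivors."""

    counts: tuple[int, ...]
    labels: tuple[str, ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.labels):
            raise ValueError("counts and labels must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("bin counts must be >= 0")
        if self.total < 1:
            raise ValueError("grouped table must cover >= 1 patient")

    @property
    def total(self) -> int:
        return sum(self.counts)


def group_lengths(
    survival_months: Sequence[int], labels: Sequence[str] = DEFAULT_BINS
) -> GroupedLengths:
    """Bin individual survival lengths into 12-month bins plus an open tail."""
    n_bins = len(labels)
    counts = [0] * n_bins
    upper = 12 * (n_bins - 1)  # start of the open survivor bin
    for months in survival_months:
        if months < 1:
            raise ValueError("survival months must be >= 1")
        if months > upper:
            counts[-1] += 1
        else:
            counts[(months - 1) // 12] += 1
    return GroupedLengths(tuple(counts), tuple(labels))


def grouped_survival_rate(grouped: GroupedLengths) -> float:
    """Proportion of patients in the final (survivor) bin."""
    return grouped.counts[-1] / grouped.total


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step estimate of the survival function.

    ``times`` are the distinct event times (strictly increasing);
    ``survival[i]`` is S(t) for times[i] <= t < times[i+1]; ``at_risk[i]``
    and ``events[i]`` are the risk-set size and death count at times[i].
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "survival", "at_risk", "events"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.times)
            == len(self.survival)
            == len(self.at_risk)
            == len(self.events)
        ):
            raise ValueError("curve arrays must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def km_estimate(
    times: Sequence[float], events: Sequence[bool]
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) is the product over event times t_i <= t of (1 - d_i / n_i) where
    d_i deaths occur among n_i at risk; censored observations leave the risk
    set just after their time (ties: deaths precede censorings).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = []
    at_risk = []
    deaths = []
    survival = []
    s = 1.0
    n = times.size
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(events[j])
            j += 1
        if d > 0:
            n_i = n - i
            s *= 1.0 - d / n_i
            event_times.append(t)
            at_risk.append(n_i)
            deaths.append(d)
            survival.append(s)
        i = j
    return SurvivalCurve(
        np.array(event_times),
        np.array(survival),
        np.array(at_risk, dtype=int),
        np.array(deaths, dtype=int),
    )


def survival_rate_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous evaluation of the step curve at time ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = int(np.searchsorted(curve.times, t, side="right"))
    if idx == 0:
        return 1.0
    return float(curve.survival[idx - 1])
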