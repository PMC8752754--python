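"""Kaplan-Meier estimation and multi-group log-rank testing.

Thin domain layer over lifelines: records enter as
:class:`~glycocode.io.ClinicalRecord` lists, curves come back as
:class:`KMCurve` tables (distinct event times, survival, numbers at
risk, censoring marks) and group comparisons as :class:`LogrankResult`.
Ties between events and censorings at the same time follow the standard
convention (events first; censored subjects still at risk at that time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalRecord

__all__ = ["KMCurve", "LogrankResult", "kaplan_meier", "logrank", "pairwise_logrank"]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t): survival probability just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def median(self) -> float:
        below = np.where(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else np.nan


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi-square statistic must be >= 0")


def _arrays(records: list[ClinicalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def kaplan_meier(records: list[ClinicalRecord]) -> KMCurve:
    """Product-limit survival estimate of one group of records."""
    if not records:
        raise ValueError("need >= 1 record")
    times, events = _arrays(records)
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = np.array([float(fitter.survival_function_at_times(t).iloc[0]) for t in event_times])
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    censor_times = np.sort(times[events == 0])
    return KMCurve(event_times, survival, at_risk, censor_times)


def logrank(records: list[ClinicalRecord], groups: dict[str, str]) -> LogrankResult:
    """Multi-group log-rank test; chi-square with (groups - 1) df."""
    labels = [groups[r.sample_id] for r in records]
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("need >= 2 groups")
    for g in unique:
        if labels.count(g) == 0:
            raise ValueError(f"group {g!r} is empty")
    times, events = _arrays(records)
    if events.sum() == 0:
        raise ValueError("no events")
    result = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        chi2=float(result.test_statistic), df=len(unique) - 1, p=float(result.p_value)
    )


def pairwise_logrank(
    records: list[ClinicalRecord], groups: dict[str, str]
) -> pd.DataFrame:
    """Unadjusted pairwise log-rank tests between all group pairs.

    Reported alongside the global test for three-group comparisons; the
    p-values are raw and flagged as such.
    """
    labels = sorted(set(groups[r.sample_id] for r in records))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sub = [r for r in records if groups[r.sample_id] in (a, b)]
            res = logrank(sub, groups)
            rows.append({"group_a": a, "group_b": b, "chi2": res.chi2, "p_unadjusted": res.p})
    return pd.DataFrame(rows)
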