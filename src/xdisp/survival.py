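"""Kaplan–Meier estimation and log-rank comparison of patient strata.

Strata come either from TP53 status (wild-type vs mutant) or from splitting a
cohort at the median expression of a chosen gene (bottom vs top half; values
exactly at the median go to the bottom stratum, deterministically). Follow-up
can be truncated at an administrative horizon before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "km_estimate",
    "logrank",
    "median_split",
    "truncate_followup",
    "tp53_strata",
]

DAYS_PER_YEAR = 365.25


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate: columns ``time`` and ``survival``.

    Censored subjects leave the risk set without producing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test (chi-squared, 1 df): returns (stat, p)."""
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("no events in either stratum")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def median_split(expression: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split patients at the median of an expression vector.

    Returns ``(bottom_ids, top_ids)``; values <= median go to the bottom
    stratum, so ties at the median are resolved deterministically and
    independently of input order. Constant vectors cannot be split.
    """
    expression = expression.dropna()
    if len(expression) < 2:
        raise ValueError("need at least two patients with expression values")
    if expression.nunique() == 1:
        raise ValueError("constant expression: no median split possible")
    med = expression.median()
    bottom = expression.index[expression <= med]
    top = expression.index[expression > med]
    if len(top) == 0:  # heavy ties: median equals the maximum
        raise ValueError("median equals maximum: no patients above the median")
    return bottom, top


def truncate_followup(
    clinical: pd.DataFrame, horizon_years: float
) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``horizon_years``."""
    horizon = horizon_years * DAYS_PER_YEAR
    out = clinical.copy()
    over = out["os_time"] > horizon
    out.loc[over, "os_time"] = horizon
    out.loc[over, "os_event"] = False
    return out


def tp53_strata(clinical: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Wild-type vs mutant TP53 strata (unknown status excluded)."""
    known = clinical[clinical["tp53_status"].isin(["wt", "mutant"])]
    return {
        status: sub.reset_index(drop=True)
        for status, sub in known.groupby("tp53_status")
    }
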