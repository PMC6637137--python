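"""Kaplan–Meier estimation and log-rank comparison of survival.

Thin, validated wrappers around lifelines.  The product-limit estimator uses
the standard tie convention (events precede censorings at equal times), and
the two-group log-rank statistic is χ² = (ΣO − ΣE)² / ΣV with one degree of
freedom, where O, E and V are the observed events, hypergeometric expectation
and variance at each distinct event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


@dataclass
class KMCurve:
    """Product-limit survival curve tabulated at distinct event times."""

    table: pd.DataFrame  # columns: time, n_risk, n_event, n_censor, survival

    def survival_at(self, t: float) -> float:
        """S(t): the estimate at the latest event time not exceeding t."""
        past = self.table[self.table["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    degenerate: bool = False


def _validate(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one sample")
    if (time < 0).any():
        raise ValueError("negative survival times are not allowed")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 (censored) or 1 (event)")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = Π (1 − d_i / n_i)."""
    time, event = _validate(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    rows = et[et["observed"] > 0]
    table = pd.DataFrame(
        {
            "time": rows.index.to_numpy(dtype=float),
            "n_risk": rows["at_risk"].to_numpy(dtype=int),
            "n_event": rows["observed"].to_numpy(dtype=int),
            "n_censor": rows["censored"].to_numpy(dtype=int),
            "survival": surv.loc[rows.index].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return KMCurve(table=table)


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test; returns χ² (df = 1) and its p-value.

    When no event time is shared between comparable risk sets the variance is
    zero and the test is undefined: p = 1 by convention, flagged degenerate.
    """
    time, event = _validate(time, event)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    in_a = group == labels[0]
    if event.sum() == 0:
        return LogrankResult(chi_square=0.0, p_value=1.0, degenerate=True)
    res = _lifelines_logrank(
        time[in_a], time[~in_a], event_observed_A=event[in_a], event_observed_B=event[~in_a]
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        return LogrankResult(chi_square=0.0, p_value=1.0, degenerate=True)
    return LogrankResult(chi_square=chi2, p_value=p)


def survival_by_group(clinical: pd.DataFrame, group_col: str,
                      time_col: str = "time", event_col: str = "event",
                      include: tuple[str, ...] | None = None) -> dict[str, KMCurve]:
    """KM curve per level of ``group_col`` (optionally restricted to ``include``)."""
    out: dict[str, KMCurve] = {}
    for label, grp in clinical.groupby(group_col):
        if include is not None and label not in include:
            continue
        out[str(label)] = km_estimate(grp[time_col], grp[event_col])
    return out
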