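"""Median-split Kaplan-Meier survival analysis with log-rank tests.

For each candidate lncRNA, patients are dichotomized at the median expression
(ties to the low group), the product-limit survival curve is estimated per
group, and the two curves are compared with the Mantel-Haenszel log-rank
test (1 df, no continuity correction).  The group with the smaller area under
its survival curve up to the last shared event time is reported as having the
worse survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .errors import DataError

logger = logging.getLogger(__name__)


def median_split(expressions) -> np.ndarray:
    """Labels ``low`` (value <= median) / ``high`` (value > median).

    Requires at least 4 patients and a non-degenerate split (identical values
    are an error).
    """
    values = np.asarray(expressions, dtype=float)
    if values.size < 4:
        raise DataError(f"need >= 4 patients for a median split, got {values.size}")
    median = float(np.median(values))
    labels = np.where(values <= median, "low", "high")
    if (labels == "low").all() or (labels == "high").all():
        raise DataError("median split impossible: all values on one side of the median")
    return labels


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times of one group."""

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimate at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def area_up_to(self, horizon: float) -> float:
        """Restricted mean survival time: area under the step curve on
        [0, horizon]."""
        grid = np.concatenate([[0.0], self.event_times[self.event_times <= horizon],
                               [horizon]])
        grid = np.unique(grid)
        area = 0.0
        for left, right in zip(grid[:-1], grid[1:]):
            area += self.survival_at(left) * (right - left)
        return area


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier curve: S(t) = prod over event times <= t of (1 - d_i/n_i).

    Censored observations leave the risk set without producing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("empty survival data")
    if (times < 0).any():
        raise DataError("negative survival times")
    if not np.isin(events, (0, 1)).all():
        raise DataError("events must be 0 (censored) or 1 (death)")

    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table
    steps = table[table["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    survival = np.array(
        [float(fitter.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMCurve(
        event_times=event_times,
        at_risk=steps["at_risk"].to_numpy(dtype=int),
        deaths=steps["observed"].to_numpy(dtype=int),
        survival=survival,
    )


def logrank_test(times_low, events_low, times_high, events_high) -> tuple[float, float]:
    """Mantel-Haenszel log-rank chi-square (1 df) and p-value.

    With no events in either group the test is undefined; (0, 1) is returned
    with a warning.
    """
    times_low = np.asarray(times_low, dtype=float)
    times_high = np.asarray(times_high, dtype=float)
    events_low = np.asarray(events_low, dtype=int)
    events_high = np.asarray(events_high, dtype=int)
    if times_low.size == 0 or times_high.size == 0:
        raise DataError("both groups must be nonempty")
    if events_low.sum() + events_high.sum() == 0:
        logger.warning("no events in either group; log-rank undefined, returning p=1")
        return 0.0, 1.0
    result = _lifelines_logrank(times_low, times_high, events_low, events_high)
    return float(result.test_statistic), float(result.p_value)


@dataclass
class SurvivalScreenRow:
    lncRNA: str
    chi2: float
    p: float
    worse_group: str  # "low" | "high"
    n_low: int
    n_high: int


def survival_screen(
    expression: pd.DataFrame,  # lncRNAs x patients
    clinical: pd.DataFrame,  # index patient id; columns time, event
    lncRNAs: list[str] | None = None,
) -> pd.DataFrame:
    """Median split + log-rank per lncRNA over the shared patients.

    ``worse_group`` is the arm with the smaller area under its KM curve up to
    the last event time shared by both arms.
    """
    if not {"time", "event"}.issubset(clinical.columns):
        raise DataError("clinical table needs 'time' and 'event' columns")
    shared = [p for p in expression.columns if p in clinical.index]
    if not shared:
        raise DataError(
            f"no shared patient ids between expression ({expression.shape[1]}) "
            f"and clinical ({len(clinical)}) tables"
        )
    if len(shared) < expression.shape[1]:
        logger.warning("%d expression patients lack clinical data",
                       expression.shape[1] - len(shared))
    if lncRNAs is None:
        lncRNAs = expression.index.tolist()

    rows = []
    times = clinical.loc[shared, "time"].to_numpy(dtype=float)
    events = clinical.loc[shared, "event"].to_numpy(dtype=int)
    for lnc in lncRNAs:
        if lnc not in expression.index:
            raise DataError(f"lncRNA {lnc!r} missing from expression table")
        labels = median_split(expression.loc[lnc, shared].to_numpy(dtype=float))
        low = labels == "low"
        chi2, p = logrank_test(times[low], events[low], times[~low], events[~low])
        if events.sum() == 0:
            worse = "none"
        else:
            curve_low = km_estimate(times[low], events[low])
            curve_high = km_estimate(times[~low], events[~low])
            if curve_low.event_times.size and curve_high.event_times.size:
                horizon = min(curve_low.event_times[-1], curve_high.event_times[-1])
            else:
                horizon = float(min(times[low].max(), times[~low].max()))
            worse = (
                "low"
                if curve_low.area_up_to(horizon) < curve_high.area_up_to(horizon)
                else "high"
            )
        rows.append(SurvivalScreenRow(lnc, chi2, p, worse, int(low.sum()),
                                      int((~low).sum())))
    return pd.DataFrame(
        [
            {"lncRNA": r.lncRNA, "chi2": r.chi2, "p": r.p, "worse_group": r.worse_group,
             "n_low": r.n_low, "n_high": r.n_high}
            for r in rows
        ]
    ).set_index("lncRNA")
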