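"""Readouts: bone area, event rates at 25-day intervals, arm comparisons.

Metrics rows (one per replicate × timepoint, as produced by
``Simulation.record``) carry: ``replicate_id``, ``day``, ``bone_area_um2``,
per-phenotype counts ``n_*`` (9 classes plus ``n_cancer``), clonal fractions
``frac_*`` and cumulative event counts ``cum_*``. Tumor burden is
operationalized as the total cancer-cell count across all four clones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EVENT_CLASSES
from .lattice import GridState

__all__ = [
    "bone_area", "interval_event_rates", "interval_rates_from_records",
    "compare_arms", "ArmComparison", "vicious_cycle_established",
    "established_day", "value_at_day",
]


def bone_area(grid: GridState) -> float:
    """Mineralized bone area in μm² (bone-site count × site area)."""
    return grid.bone_area_um2


def interval_event_rates(events: pd.DataFrame, interval_days: int = 25,
                         horizon_days: int = 250) -> pd.DataFrame:
    """Mean daily event counts per consecutive interval.

    ``events`` is a long-form log with columns ``day`` and ``event``; the
    result has one row per interval (10 for a 250-day horizon at 25-day
    intervals) and one column per event class present, in events/day.
    """
    if len(events) and events["day"].max() > horizon_days:
        raise ValueError("event log contains events beyond the horizon")
    n_int = int(np.ceil(horizon_days / interval_days))
    classes = sorted(set(events["event"])) if len(events) else []
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(n_int, name="interval"),
        columns=classes, dtype=float)
    if len(events):
        idx = np.minimum(((events["day"] - 1e-9) // interval_days).astype(int),
                         n_int - 1)
        for (i, ev), n in events.groupby([idx, "event"]).size().items():
            out.loc[i, ev] = n / interval_days
    return out


def interval_rates_from_records(records: pd.DataFrame,
                                interval_days: int = 25) -> pd.DataFrame:
    """Per-interval mean daily event rates from cumulative run records."""
    rec = records.sort_values("day")
    days = rec["day"].to_numpy()
    horizon = days.max()
    edges = np.arange(1.0, horizon + interval_days, interval_days)
    edges[-1] = min(edges[-1], horizon)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        a = rec[rec["day"] <= lo].iloc[-1]
        b = rec[rec["day"] <= hi].iloc[-1]
        span = b["day"] - a["day"]
        row = {"day_start": lo, "day_end": hi}
        for k in EVENT_CLASSES:
            row[k] = (b[f"cum_{k}"] - a[f"cum_{k}"]) / span if span else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def value_at_day(records: pd.DataFrame, metric: str, day: float) -> pd.Series:
    """Per-replicate value of a metric at (the last record up to) a day."""
    sel = records[records["day"] <= day + 1e-9].sort_values("day")
    out = sel.groupby("replicate_id").tail(1).set_index("replicate_id")
    return out[metric]


@dataclass(frozen=True)
class ArmComparison:
    metric: str
    day: float
    control_mean: float
    treated_mean: float
    control_sem: float
    treated_sem: float
    percent_change: float
    p_value: float
    n_control: int
    n_treated: int


def compare_arms(control: pd.DataFrame, treated: pd.DataFrame, metric: str,
                 day: float) -> ArmComparison:
    """Treated-vs-control percent change with SEM and a Welch t-test.

    Requires ≥ 3 replicates per arm. ``percent_change`` is
    ``100·(treated − control)/control`` on the replicate means at ``day``.
    """
    c = value_at_day(control, metric, day).to_numpy(dtype=float)
    t = value_at_day(treated, metric, day).to_numpy(dtype=float)
    if len(c) < 3 or len(t) < 3:
        raise ValueError("compare_arms needs >= 3 replicates per arm")
    cm, tm = c.mean(), t.mean()
    if cm == 0:
        raise ZeroDivisionError("control mean is zero")
    if np.allclose(c, c[0]) and np.allclose(t, t[0]) and np.isclose(cm, tm):
        p = 1.0   # degenerate identical arms
    else:
        p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
    return ArmComparison(
        metric=metric, day=day, control_mean=float(cm),
        treated_mean=float(tm),
        control_sem=float(stats.sem(c)) if len(c) > 1 else 0.0,
        treated_sem=float(stats.sem(t)) if len(t) > 1 else 0.0,
        percent_change=float(100.0 * (tm - cm) / cm),
        p_value=p, n_control=len(c), n_treated=len(t))


def established_day(daily_cancer: dict[int, int], initial: int,
                    factor: float = 10.0, window_days: int = 25) -> int | None:
    """First day the sustained-growth (vicious-cycle) criterion holds.

    The criterion: the cancer count reaches ``factor ×`` the seeded count
    and has not declined over the trailing ``window_days`` window.
    """
    if initial <= 0:
        return None
    for d in sorted(daily_cancer):
        prev = daily_cancer.get(d - window_days)
        if prev is None:
            continue
        if daily_cancer[d] >= factor * initial and daily_cancer[d] >= prev:
            return d
    return None


def vicious_cycle_established(daily_cancer: dict[int, int], initial: int,
                              factor: float = 10.0,
                              window_days: int = 25) -> bool:
    return established_day(daily_cancer, initial, factor, window_days) is not None
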