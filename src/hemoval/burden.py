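"""Hypotension-burden metrics: minutes below threshold, AUC-MAP, TWA-MAP.

For each threshold τ (65, 60, 55 mmHg by default):

* ``minutes_below`` — sample-and-hold time with MAP strictly below τ
  (each sub-threshold sample contributes one nominal dt, matching the
  episode-duration convention);
* ``auc`` — area between τ and the MAP curve while below τ, in
  mmHg·min, by the trapezoid rule with threshold crossings located by
  linear interpolation between adjacent samples, plus a dt-long hold
  of the last sample of each contiguous block;
* ``twa`` — AUC divided by the total monitored time.

Data gaps (inter-sample interval > 2×dt) and missing MAP split the
series into blocks; gap time contributes neither area nor monitored
time, so episodes of burden never span a recording interruption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from hemoval.io import HemoSeries

DEFAULT_THRESHOLDS = (65.0, 60.0, 55.0)
GAP_FACTOR = 2.0


def _blocks(series: HemoSeries, gap_factor: float = GAP_FACTOR):
    """Yield (t, map) arrays of maximal gap-free runs of present MAP samples."""
    t, m = series.t, series.map_mmHg
    n = len(t)
    max_gap = gap_factor * series.nominal_dt
    start = None
    for i in range(n):
        if np.isnan(m[i]):
            if start is not None:
                yield t[start:i], m[start:i]
                start = None
            continue
        if start is None:
            start = i
        elif (t[i] - t[i - 1]) > max_gap:
            yield t[start:i], m[start:i]
            start = i
    if start is not None:
        yield t[start:n], m[start:n]


def _trapezoid_deficit(t: np.ndarray, m: np.ndarray, tau: float, dt: float) -> float:
    """Integral of max(0, tau − MAP) over one block, in mmHg·seconds.

    Between samples MAP is linear, so the deficit is piecewise linear
    with a kink where MAP crosses tau; the crossing point is found
    exactly. The last sample holds its value for one dt.
    """
    area = 0.0
    for i in range(len(t) - 1):
        dt_i = t[i + 1] - t[i]
        d1 = tau - m[i]
        d2 = tau - m[i + 1]
        if d1 <= 0.0 and d2 <= 0.0:
            continue
        if d1 > 0.0 and d2 > 0.0:
            area += 0.5 * (d1 + d2) * dt_i
        else:
            # one-sided crossing: triangle on the sub-threshold side
            frac = d1 / (d1 - d2)  # location of MAP == tau from sample i
            if d1 > 0.0:
                area += 0.5 * d1 * frac * dt_i
            else:
                area += 0.5 * d2 * (1.0 - frac) * dt_i
    area += max(0.0, tau - m[-1]) * dt
    return area


def auc_below(series: HemoSeries, tau: float, gap_factor: float = GAP_FACTOR) -> float:
    """Area under the threshold tau and above the MAP curve, mmHg·min."""
    if len(series) < 2:
        warnings.warn(
            f"patient {series.patient_id!r}: fewer than 2 samples, AUC set to 0"
        )
        return 0.0
    total = sum(
        _trapezoid_deficit(bt, bm, tau, series.nominal_dt)
        for bt, bm in _blocks(series, gap_factor)
    )
    return total / 60.0


def monitored_minutes(series: HemoSeries, gap_factor: float = GAP_FACTOR) -> float:
    """Total monitored time in minutes: gap-free block spans + dt hold each."""
    total = 0.0
    for bt, _ in _blocks(series, gap_factor):
        total += (bt[-1] - bt[0]) + series.nominal_dt
    return total / 60.0


def minutes_below(series: HemoSeries, tau: float) -> float:
    """Sample-and-hold minutes with MAP strictly below tau."""
    with np.errstate(invalid="ignore"):
        k = int(np.sum(series.map_mmHg < tau))
    return k * series.nominal_dt / 60.0


@dataclass(frozen=True)
class BurdenSummary:
    """Per-patient burden at each threshold.

    ``per_threshold`` maps τ (mmHg) to a dict with ``minutes_below``
    (min), ``auc`` (mmHg·min) and ``twa`` (mmHg); ``total_time`` is
    monitored minutes (gap time excluded).
    """

    patient_id: str
    total_time: float
    per_threshold: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "total_time_min": self.total_time,
            "per_threshold": {
                str(k): dict(v) for k, v in self.per_threshold.items()
            },
        }


def burden_summary(
    series: HemoSeries, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> BurdenSummary:
    """Burden metrics for one patient at each threshold independently."""
    total = monitored_minutes(series) if len(series) else 0.0
    per = {}
    for tau in thresholds:
        auc = auc_below(series, tau) if len(series) >= 2 else 0.0
        per[float(tau)] = {
            "minutes_below": minutes_below(series, tau),
            "auc": auc,
            "twa": auc / total if total > 0 else 0.0,
        }
    return BurdenSummary(patient_id=series.patient_id, total_time=total, per_threshold=per)


def cohort_burden(
    series: Iterable[HemoSeries], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict:
    """Per-patient burden plus cohort median [Q1, Q3] per metric and threshold."""
    summaries = [burden_summary(s, thresholds) for s in series]
    out = {
        "patients": [b.to_dict() for b in summaries],
        "cohort": {},
    }
    for tau in thresholds:
        stats = {}
        for metric in ("minutes_below", "auc", "twa"):
            vals = np.array([b.per_threshold[float(tau)][metric] for b in summaries])
            if vals.size == 0:
                stats[metric] = None
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            stats[metric] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
        out["cohort"][str(float(tau))] = stats
    return out
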