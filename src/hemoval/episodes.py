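"""Hypotension / alert episode detection and event-based alert matching.

A *hypotension episode* is a maximal run of consecutive samples with
MAP < 65 mmHg lasting at least one minute; it starts at the first
sub-threshold sample and ends at the first sample with MAP ≥ 65 mmHg.
An *alert episode* is a maximal run of at least two consecutive samples
with HPI ≥ 85.

Matching follows an event-based rule anchored at alert onset: an alert
predicts hypotension if a hypotension episode starts within 15 minutes
of the alert's start. Long alerts are first *split* — at 15 minutes
when no hypotension occurred in the window, or at the end of the first
subsequent hypotension episode — and the resulting segments are then
classified in time order as true alerts (window contains a not-yet
claimed hypotension onset; the alert claims every unclaimed onset in
its window), ignored (window contains only onsets already claimed by an
earlier alert), or false alerts (no onset in window).

Durations use a sample-and-hold convention: each sample represents
[t, t + dt), so a run of k qualifying samples at 20-s spacing lasts
k·20 s and the one-minute rule means at least three samples. Data gaps
(inter-sample interval > 2×dt) and missing values break runs; a run
that ends at a gap or at the end of the series closes at the last
sample time + dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from hemoval.io import HemoSeries

MAP_THRESHOLD = 65.0
HPI_THRESHOLD = 85.0
MIN_HYPO_DURATION_S = 60.0
MIN_ALERT_SAMPLES = 2
WINDOW_S = 900.0  # 15-minute prediction window
GAP_FACTOR = 2.0

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Episode:
    """A closed run of qualifying samples, as the interval [start, end).

    ``end`` is the time of the first non-qualifying sample, or the last
    qualifying sample time + nominal dt when the run closes at a data
    gap or at the series end. ``sample_times`` retains the qualifying
    sample times when the episode came from a detector (None for
    hand-built episodes).
    """

    patient_id: str
    kind: Literal["hypotension", "alert"]
    start: float
    end: float
    n_samples: int
    sample_times: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"episode end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AlertSegment:
    """A post-splitting alert interval with its classification.

    ``classification`` is one of ``"true_alert"``, ``"false_alert"``,
    ``"ignored"`` (window contains only hypotension onsets already
    claimed by an earlier alert), or None before classification.
    ``predicted`` lists the hypotension episodes this segment claims;
    ``time_to_first`` is the lead time to the first of them, defined
    only for true alerts.
    """

    patient_id: str
    start: float
    end: float
    window_s: float = WINDOW_S
    raw_start: float = math.nan  # onset of the raw alert episode this came from
    classification: Optional[str] = None
    predicted: list = field(default_factory=list)
    time_to_first: Optional[float] = None
    starts_during_hypotension: bool = False

    @property
    def window_end(self) -> float:
        return self.start + self.window_s


@dataclass
class PredictionPerformance:
    """Episode-level alert performance: sensitivity, PPV, lead times.

    Sensitivity = predicted hypotension episodes / all hypotension
    episodes; PPV = true-alert segments / all alert segments (ignored
    and false segments stay in the denominator). 95% CIs are Wald
    intervals p ± 1.96·√(p(1−p)/n), clipped to [0, 1]. When a
    denominator is zero the estimate is None and ``flags`` explains.
    """

    n_hypotension: int
    n_predicted: int
    n_alerts: int
    n_true_alerts: int
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple]
    ppv: Optional[float]
    ppv_ci: Optional[tuple]
    times_to_hypotension: list = field(default_factory=list)
    n_false_alerts: int = 0
    n_ignored_alerts: int = 0
    flags: list = field(default_factory=list)

    @property
    def time_to_hypotension_median(self) -> Optional[float]:
        if not self.times_to_hypotension:
            return None
        return float(np.median(self.times_to_hypotension))

    @property
    def time_to_hypotension_quartiles(self) -> Optional[tuple]:
        if not self.times_to_hypotension:
            return None
        q1, q3 = np.percentile(self.times_to_hypotension, [25, 75])
        return (float(q1), float(q3))

    def to_dict(self) -> dict:
        q = self.time_to_hypotension_quartiles
        return {
            "n_hypotension": self.n_hypotension,
            "n_predicted": self.n_predicted,
            "n_alerts": self.n_alerts,
            "n_true_alerts": self.n_true_alerts,
            "n_false_alerts": self.n_false_alerts,
            "n_ignored_alerts": self.n_ignored_alerts,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci) if self.sensitivity_ci else None,
            "ppv": self.ppv,
            "ppv_ci": list(self.ppv_ci) if self.ppv_ci else None,
            "time_to_hypotension_median_s": self.time_to_hypotension_median,
            "time_to_hypotension_quartiles_s": list(q) if q else None,
            "n_times": len(self.times_to_hypotension),
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# Detection


def detect_episodes(
    series: HemoSeries,
    signal: Literal["map", "hpi"],
    threshold: float,
    direction: Literal["below", "above"],
    min_duration_s: float = 0.0,
    min_samples: int = 1,
    gap_factor: float = GAP_FACTOR,
) -> list[Episode]:
    """Find maximal runs of qualifying samples as ``[start, end)`` episodes.

    A sample qualifies when its value is present and strictly below the
    threshold (``direction="below"``) or at/above it
    (``direction="above"``). Missing MAP terminates runs of either
    signal (the pressure feed is the primary recording); missing HPI is
    simply non-qualifying. Runs shorter than ``min_duration_s`` or with
    fewer than ``min_samples`` samples are discarded.
    """
    n = len(series)
    if n == 0:
        return []
    t = series.t
    values = series.map_mmHg if signal == "map" else series.hpi
    with np.errstate(invalid="ignore"):
        if direction == "below":
            qual = ~np.isnan(values) & (values < threshold)
        elif direction == "above":
            qual = ~np.isnan(values) & (values >= threshold)
        else:
            raise ValueError(f"unknown direction {direction!r}")
    # missing MAP breaks runs regardless of signal
    qual &= ~np.isnan(series.map_mmHg)

    dt = series.nominal_dt
    max_gap = gap_factor * dt
    kind = "hypotension" if signal == "map" else "alert"

    episodes: list[Episode] = []
    run: list[int] = []

    def close(end_time: float) -> None:
        if not run:
            return
        start = float(t[run[0]])
        ep_end = float(end_time)
        if (ep_end - start) >= min_duration_s and len(run) >= min_samples:
            episodes.append(
                Episode(
                    patient_id=series.patient_id,
                    kind=kind,
                    start=start,
                    end=ep_end,
                    n_samples=len(run),
                    sample_times=tuple(float(t[i]) for i in run),
                )
            )
        run.clear()

    for i in range(n):
        if run and (t[i] - t[run[-1]]) > max_gap:
            close(t[run[-1]] + dt)  # run ends at the gap
        if qual[i]:
            run.append(i)
        else:
            close(t[i])
    close(t[n - 1] + dt) if run else None
    return episodes


def detect_hypotension_episodes(
    series: HemoSeries,
    threshold: float = MAP_THRESHOLD,
    min_duration_s: float = MIN_HYPO_DURATION_S,
) -> list[Episode]:
    """Hypotension episodes: MAP strictly below threshold for ≥ 1 minute."""
    return detect_episodes(
        series, "map", threshold, "below", min_duration_s=min_duration_s
    )


def detect_alert_episodes(
    series: HemoSeries,
    threshold: float = HPI_THRESHOLD,
    min_samples: int = MIN_ALERT_SAMPLES,
) -> list[Episode]:
    """Alert episodes: at least two continuous records with HPI ≥ threshold."""
    return detect_episodes(series, "hpi", threshold, "above", min_samples=min_samples)


# ---------------------------------------------------------------------------
# Splitting and classification


def split_alerts(
    alerts: Sequence[Episode],
    hypo: Sequence[Episode],
    window_s: float = WINDOW_S,
) -> list[AlertSegment]:
    """Split raw alert episodes into evaluation segments (unclassified).

    Working left to right inside each raw alert, a segment starting at
    ``s`` runs to ``min(raw_end, s + window)`` when no hypotension
    onset falls in ``(s, s + window]``, otherwise to ``min(raw_end,
    end of the first hypotension episode starting in that window)``.
    Any remainder containing at least one sample starts a new segment
    under the same rule.
    """
    hypo_sorted = sorted(hypo, key=lambda h: h.start)
    segments: list[AlertSegment] = []
    for ep in sorted(alerts, key=lambda a: a.start):
        s = ep.start
        while True:
            in_window = [h for h in hypo_sorted if s < h.start <= s + window_s]
            if in_window:
                cut = min(ep.end, in_window[0].end)
            else:
                cut = min(ep.end, s + window_s)
            if not cut > s:  # degenerate overlap; close out the remainder
                cut = ep.end
            segments.append(
                AlertSegment(
                    patient_id=ep.patient_id,
                    start=float(s),
                    end=float(cut),
                    window_s=window_s,
                    raw_start=ep.start,
                )
            )
            if cut >= ep.end:
                break
            if ep.sample_times is not None:
                if not any(st >= cut for st in ep.sample_times):
                    break
            s = cut
    segments.sort(key=lambda g: g.start)
    return segments


def classify_alerts(
    segments: Sequence[AlertSegment],
    hypo: Sequence[Episode],
    window_s: Optional[float] = None,
) -> list[AlertSegment]:
    """Classify segments in time order as true / false / ignored alerts.

    A segment whose window ``(start, start + window]`` contains at
    least one hypotension onset not claimed by an earlier true alert
    becomes a true alert and claims every unclaimed onset in its
    window; a segment whose window holds only already-claimed onsets is
    ignored; a segment with no onset in window is a false alert. Each
    hypotension onset is therefore claimed by at most one true alert.
    Onsets must fall strictly after the segment start (an alert
    beginning during ongoing hypotension does not claim that episode;
    ``starts_during_hypotension`` flags the situation).
    """
    hypo_sorted = sorted(hypo, key=lambda h: h.start)
    claimed: set[int] = set()
    out = sorted(segments, key=lambda g: (g.start, g.end))
    for seg in out:
        w = window_s if window_s is not None else seg.window_s
        seg.starts_during_hypotension = any(
            h.start <= seg.start < h.end for h in hypo_sorted
        )
        idx_in_window = [
            i for i, h in enumerate(hypo_sorted) if seg.start < h.start <= seg.start + w
        ]
        if not idx_in_window:
            seg.classification = "false_alert"
            seg.predicted = []
            seg.time_to_first = None
            continue
        unclaimed = [i for i in idx_in_window if i not in claimed]
        if not unclaimed:
            seg.classification = "ignored"
            seg.predicted = []
            seg.time_to_first = None
            continue
        seg.classification = "true_alert"
        seg.predicted = [hypo_sorted[i] for i in unclaimed]
        seg.time_to_first = seg.predicted[0].start - seg.start
        claimed.update(unclaimed)
    return out


# ---------------------------------------------------------------------------
# Scoring


def _wald_ci(p: float, n: int, z: float = Z_95) -> tuple:
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def performance_from_counts(
    n_hypotension: int,
    n_predicted: int,
    n_alerts: int,
    n_true_alerts: int,
    times_to_hypotension: Sequence[float] = (),
    n_false_alerts: int = 0,
    n_ignored_alerts: int = 0,
    flags: Sequence[str] = (),
) -> PredictionPerformance:
    """Assemble a :class:`PredictionPerformance` from episode counts.

    Sensitivity and PPV get Wald 95% confidence intervals with their
    respective denominators; a zero denominator yields a None estimate
    with an explanatory flag.
    """
    if not 0 <= n_predicted <= n_hypotension:
        raise ValueError("need 0 <= n_predicted <= n_hypotension")
    if not 0 <= n_true_alerts <= n_alerts:
        raise ValueError("need 0 <= n_true_alerts <= n_alerts")
    flags = list(flags)
    if n_hypotension > 0:
        sens = n_predicted / n_hypotension
        sens_ci = _wald_ci(sens, n_hypotension)
    else:
        sens, sens_ci = None, None
        flags.append("sensitivity undefined: no hypotension episodes")
    if n_alerts > 0:
        ppv = n_true_alerts / n_alerts
        ppv_ci = _wald_ci(ppv, n_alerts)
    else:
        ppv, ppv_ci = None, None
        flags.append("ppv undefined: no alert segments")
    return PredictionPerformance(
        n_hypotension=n_hypotension,
        n_predicted=n_predicted,
        n_alerts=n_alerts,
        n_true_alerts=n_true_alerts,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        ppv=ppv,
        ppv_ci=ppv_ci,
        times_to_hypotension=list(times_to_hypotension),
        n_false_alerts=n_false_alerts,
        n_ignored_alerts=n_ignored_alerts,
        flags=flags,
    )


def score_predictions(
    segments: Sequence[AlertSegment], hypo: Sequence[Episode]
) -> PredictionPerformance:
    """Score classified alert segments against hypotension episodes."""
    true_segments = [g for g in segments if g.classification == "true_alert"]
    n_predicted = sum(len(g.predicted) for g in true_segments)
    times = [g.time_to_first for g in true_segments if g.time_to_first is not None]
    flags = []
    n_during = sum(1 for g in segments if g.starts_during_hypotension)
    if n_during:
        flags.append(
            f"{n_during} alert segment(s) started during ongoing hypotension; "
            "ongoing episodes are not claimable"
        )
    return performance_from_counts(
        n_hypotension=len(hypo),
        n_predicted=n_predicted,
        n_alerts=len(segments),
        n_true_alerts=len(true_segments),
        times_to_hypotension=times,
        n_false_alerts=sum(1 for g in segments if g.classification == "false_alert"),
        n_ignored_alerts=sum(1 for g in segments if g.classification == "ignored"),
        flags=flags,
    )


def evaluate_prediction(
    series: Iterable[HemoSeries],
    map_threshold: float = MAP_THRESHOLD,
    hpi_threshold: float = HPI_THRESHOLD,
    window_s: float = WINDOW_S,
) -> tuple:
    """Run detection → splitting → classification → scoring over a cohort.

    Episodes are detected and matched within each patient; counts are
    pooled across patients for the cohort-level sensitivity and PPV.
    Returns ``(performance, detail)`` where ``detail`` maps patient id
    to its hypotension episodes and classified segments.
    """
    all_segments: list[AlertSegment] = []
    all_hypo: list[Episode] = []
    detail: dict[str, dict] = {}
    for s in series:
        hypo = detect_hypotension_episodes(s, threshold=map_threshold)
        alerts = detect_alert_episodes(s, threshold=hpi_threshold)
        segs = classify_alerts(split_alerts(alerts, hypo, window_s), hypo, window_s)
        all_segments.extend(segs)
        all_hypo.extend(hypo)
        detail[s.patient_id] = {"hypotension": hypo, "alerts": alerts, "segments": segs}
    return score_predictions(all_segments, all_hypo), detail


# ---------------------------------------------------------------------------
# Brute-force oracle (test use): exhaustive sample scan, no run-length tricks


def brute_force_matcher(
    series,
    map_threshold: float = MAP_THRESHOLD,
    hpi_threshold: float = HPI_THRESHOLD,
    window_s: float = WINDOW_S,
) -> PredictionPerformance:
    """Recompute alert performance by plain sample-by-sample scanning.

    Deliberately naive re-derivation of the whole chain (detection,
    splitting, classification, scoring) used as an equivalence oracle
    in tests; accepts one series or a list and pools counts.
    """
    if isinstance(series, HemoSeries):
        series = [series]

    total_hypo = 0
    total_pred = 0
    total_seg = 0
    total_true = 0
    total_false = 0
    total_ignored = 0
    times: list[float] = []

    for s in series:
        n = len(s)
        dt = s.nominal_dt
        hypo_iv: list[list[float]] = []  # [start, end]
        alert_iv: list[list] = []  # [start, end, sample_times]

        # -- find runs the slow way: walk every sample, restart on any break
        i = 0
        while i < n:
            m = s.map_mmHg[i]
            if not math.isnan(m) and m < map_threshold:
                j = i
                while True:
                    nxt = j + 1
                    if nxt >= n:
                        end = s.t[j] + dt
                        break
                    if (s.t[nxt] - s.t[j]) > 2.0 * dt:
                        end = s.t[j] + dt
                        break
                    mn = s.map_mmHg[nxt]
                    if math.isnan(mn) or not (mn < map_threshold):
                        end = s.t[nxt]
                        break
                    j = nxt
                if (end - s.t[i]) >= MIN_HYPO_DURATION_S:
                    hypo_iv.append([float(s.t[i]), float(end)])
                i = j + 1
            else:
                i += 1
        i = 0
        while i < n:
            h = s.hpi[i]
            m = s.map_mmHg[i]
            if not math.isnan(h) and h >= hpi_threshold and not math.isnan(m):
                j = i
                while True:
                    nxt = j + 1
                    if nxt >= n:
                        end = s.t[j] + dt
                        break
                    if (s.t[nxt] - s.t[j]) > 2.0 * dt:
                        end = s.t[j] + dt
                        break
                    hn = s.hpi[nxt]
                    mn = s.map_mmHg[nxt]
                    if math.isnan(hn) or math.isnan(mn) or not (hn >= hpi_threshold):
                        end = s.t[nxt]
                        break
                    j = nxt
                if (j - i + 1) >= MIN_ALERT_SAMPLES:
                    samp = [float(s.t[k]) for k in range(i, j + 1)]
                    alert_iv.append([float(s.t[i]), float(end), samp])
                i = j + 1
            else:
                i += 1

        # -- split each alert by repeated scanning
        segs: list[list[float]] = []
        for a0, a1, samp in alert_iv:
            s0 = a0
            while True:
                first_onset_end = None
                for h0, h1 in sorted(hypo_iv):
                    if s0 < h0 <= s0 + window_s:
                        first_onset_end = h1
                        break
                if first_onset_end is None:
                    cut = min(a1, s0 + window_s)
                else:
                    cut = min(a1, first_onset_end)
                if not cut > s0:
                    cut = a1
                segs.append([s0, cut])
                if cut >= a1:
                    break
                has_sample = False
                for st in samp:
                    if st >= cut:
                        has_sample = True
                if not has_sample:
                    break
                s0 = cut

        # -- classify in time order
        segs.sort()
        hypo_iv.sort()
        claimed = [False] * len(hypo_iv)
        for s0, s1 in segs:
            in_window = []
            for k, (h0, h1) in enumerate(hypo_iv):
                if s0 < h0 <= s0 + window_s:
                    in_window.append(k)
            if not in_window:
                total_false += 1
            else:
                new = [k for k in in_window if not claimed[k]]
                if not new:
                    total_ignored += 1
                else:
                    total_true += 1
                    total_pred += len(new)
                    times.append(hypo_iv[new[0]][0] - s0)
                    for k in new:
                        claimed[k] = True
        total_hypo += len(hypo_iv)
        total_seg += len(segs)

    return performance_from_counts(
        n_hypotension=total_hypo,
        n_predicted=total_pred,
        n_alerts=total_seg,
        n_true_alerts=total_true,
        times_to_hypotension=times,
        n_false_alerts=total_false,
        n_ignored_alerts=total_ignored,
    )
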