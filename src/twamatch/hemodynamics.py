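"""Per-patient hypotension endpoints from a fixed-interval MAP trace.

The central quantity is the time-weighted average (TWA) of hypotension:
the total area of the MAP deficit below a threshold divided by the total
monitoring time, i.e. severity x duration normalized to the case length,
in mmHg.  With a uniform sampling grid the area is the per-sample
rectangle rule (deficit x dt), so the TWA reduces to the mean per-sample
deficit; no interpolation is attempted at threshold crossings, which at
30-second sampling would be spurious precision.

Also provided: run-length episode segmentation with an optional minimum
duration and gap-merging rule, cumulative time below threshold, alarm
counting on an index channel (a run of samples at or above the alarm
threshold counts as one alarm), and the prevented-events arithmetic
(alarms minus realized events, floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from twamatch.cohort import VitalTrace
from twamatch.errors import AlarmSeriesMissingError, TraceValidationError


@dataclass(frozen=True)
class EventParams:
    """Episode-delimitation rule.

    ``min_duration_s``: merged runs shorter than this are discarded
    (default one minute, the common convention of the intraoperative
    hypotension literature).  ``merge_gap_s``: consecutive runs separated
    by at most this gap are treated as one episode.
    """

    min_duration_s: float = 60.0
    merge_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.min_duration_s < 0 or self.merge_gap_s < 0:
            raise ValueError("event parameters must be non-negative")


@dataclass
class HypotensionSummary:
    """Endpoint bundle for one patient."""

    patient_id: str
    twa_65: float
    twa_60: float
    twa_55: float
    n_events_65: int
    cum_duration_65_min: float
    monitoring_time_min: float
    n_alarms_ge85: Optional[int] = None


def _validated(trace: VitalTrace) -> VitalTrace:
    if not isinstance(trace, VitalTrace):
        raise TypeError("expected a VitalTrace")
    trace.validate()
    return trace


def twa_below(trace: VitalTrace, threshold: float) -> float:
    """Time-weighted average MAP deficit below ``threshold`` (mmHg).

    ``sum(max(0, threshold - MAP_i) * dt) / (N * dt)`` — the mean
    per-sample deficit; 0.0 when no sample is below the threshold.
    """
    _validated(trace)
    deficit = np.clip(threshold - trace.map_mmHg, 0.0, None)
    return float(deficit.mean())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index), inclusive."""
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.concatenate(([0], m))) == 1)
    ends = np.flatnonzero(np.diff(np.concatenate((m, [0]))) == -1)
    return list(zip(starts, ends))


def detect_episodes(
    trace: VitalTrace,
    threshold: float,
    min_duration_s: float = 60.0,
    merge_gap_s: float = 0.0,
) -> list[tuple[float, float]]:
    """Segment hypotensive episodes as (start_s, end_s) intervals.

    Episodes are maximal runs of consecutive samples with MAP strictly
    below ``threshold``; a sample at time t covers [t, t + dt).  Runs
    separated by at most ``merge_gap_s`` of above-threshold time are
    merged, then merged episodes shorter than ``min_duration_s`` are
    discarded.  The result is disjoint and ordered.
    """
    if min_duration_s < 0 or merge_gap_s < 0:
        raise ValueError("min_duration_s and merge_gap_s must be non-negative")
    _validated(trace)
    dt = trace.dt
    intervals = [
        (trace.t[i0], trace.t[i1] + dt) for i0, i1 in _runs(trace.map_mmHg < threshold)
    ]
    merged: list[list[float]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] <= merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [
        (float(s), float(e)) for s, e in merged if (e - s) >= min_duration_s
    ]


def cumulative_duration_below(trace: VitalTrace, threshold: float) -> float:
    """Total time with MAP below ``threshold`` in minutes (dt per sample),
    counting every below-threshold sample regardless of episode filtering."""
    _validated(trace)
    n_below = int((trace.map_mmHg < threshold).sum())
    return n_below * trace.dt / 60.0


def count_alarms(trace: VitalTrace, index_threshold: float = 85.0) -> int:
    """Number of alarms: maximal runs of index samples >= threshold.

    Raises :class:`AlarmSeriesMissingError` when the trace carries no
    index channel — an absent channel is not the same as zero alarms.
    """
    _validated(trace)
    if trace.hpi_index is None:
        raise AlarmSeriesMissingError(
            f"trace {trace.patient_id!r} has no alarm-index channel"
        )
    return len(_runs(trace.hpi_index >= index_threshold))


def prevented_events(n_alarms: int, n_events: int) -> int:
    """Alarms that were not followed by a realized event: max(0, alarms - events)."""
    if n_alarms < 0 or n_events < 0:
        raise ValueError("counts must be non-negative")
    return max(0, int(n_alarms) - int(n_events))


def summarize_patient(
    trace: VitalTrace,
    event_params: EventParams = EventParams(),
    alarm_threshold: float = 85.0,
) -> HypotensionSummary:
    """Compute the full endpoint bundle for one case.

    TWA at 65/60/55 mmHg, episode count and cumulative duration below
    65 mmHg, monitoring time, and — when an index channel is present —
    the alarm count.
    """
    _validated(trace)
    episodes = detect_episodes(
        trace, 65.0, event_params.min_duration_s, event_params.merge_gap_s
    )
    n_alarms = (
        count_alarms(trace, alarm_threshold) if trace.hpi_index is not None else None
    )
    return HypotensionSummary(
        patient_id=trace.patient_id,
        twa_65=twa_below(trace, 65.0),
        twa_60=twa_below(trace, 60.0),
        twa_55=twa_below(trace, 55.0),
        n_events_65=len(episodes),
        cum_duration_65_min=cumulative_duration_below(trace, 65.0),
        monitoring_time_min=trace.monitoring_time_min,
        n_alarms_ge85=n_alarms,
    )
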