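"""Per-session tallies and per-group aggregation of classified calls.

One session (a 5-minute recording of one animal) is reduced to counts
per call type, the percentage distribution over types, the cumulative
call duration (total and per type) and the mean peak frequency.  Group
aggregation produces the long-format (animal, group, call_type, count,
...) table the statistics layer consumes, plus mean +- SEM of calls per
call type by group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedCall
from .synth import CALL_TYPES

__all__ = ["SessionSummary", "summarize_session", "aggregate_group"]


@dataclass(frozen=True)
class SessionSummary:
    """Tallies of one animal's session.

    ``percent_by_type`` sums to 100 when any call was emitted;
    ``mean_peak_frequency_hz`` is the unweighted mean over calls and is
    None for an empty session (flagged rather than NaN-propagated).
    """

    animal_id: str
    group: str
    counts_by_type: dict[str, int]
    percent_by_type: dict[str, float]
    total_calls: int
    cumulative_duration_s: float
    cumulative_duration_by_type_s: dict[str, float]
    mean_peak_frequency_hz: float | None


def summarize_session(
    calls: list[ClassifiedCall], animal_id: str, group: str
) -> SessionSummary:
    """Exact tallies of one session's classified calls."""
    counts = {t: 0 for t in CALL_TYPES}
    durations = {t: 0.0 for t in CALL_TYPES}
    peaks = []
    for call in calls:
        counts[call.call_type] += 1
        durations[call.call_type] += call.duration_ms / 1e3
        if call.peak_frequency_hz is not None:
            peaks.append(call.peak_frequency_hz)
    total = sum(counts.values())
    percent = {
        t: (100.0 * c / total if total > 0 else 0.0) for t, c in counts.items()
    }
    return SessionSummary(
        animal_id=animal_id,
        group=group,
        counts_by_type=counts,
        percent_by_type=percent,
        total_calls=total,
        cumulative_duration_s=sum(durations.values()),
        cumulative_duration_by_type_s=durations,
        mean_peak_frequency_hz=float(np.mean(peaks)) if peaks else None,
    )


def aggregate_group(
    summaries: list[SessionSummary],
    known_groups: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-animal table plus per-group mean +- SEM.

    Returns ``(table, group_stats)``: ``table`` has one row per (animal,
    call type) with count, cumulative duration and session mean peak
    frequency; ``group_stats`` holds mean and SEM (n-1 denominator; NaN
    for a single animal) of calls per call type by group.

    Raises
    ------
    ValueError
        If a summary carries a group label outside ``known_groups``.
    """
    if not summaries:
        raise ValueError("need at least one session summary")
    if known_groups is not None:
        bad = {s.group for s in summaries} - set(known_groups)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
    rows = []
    for s in summaries:
        for t in CALL_TYPES:
            rows.append(
                {
                    "animal": s.animal_id,
                    "group": s.group,
                    "call_type": t,
                    "count": s.counts_by_type[t],
                    "cumulative_duration_s": s.cumulative_duration_by_type_s[t],
                    "peak_frequency_hz": s.mean_peak_frequency_hz,
                }
            )
    table = pd.DataFrame(rows)
    stats = (
        table.groupby(["group", "call_type"], sort=False)["count"]
        .agg(mean="mean", sem=lambda c: c.sem(ddof=1))
        .reset_index()
    )
    return table, stats
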