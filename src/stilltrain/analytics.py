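"""Training-progress measures computed from parsed session logs.

The measures mirror what a trainer tracks across sessions: the longest single
motionless period (with drinking pauses bridged, so licking and swallowing
during reward delivery do not cut a hold short), percent still time, the
number of discrete movements, and the average length of motionless intervals.
Sessions are optionally aggregated into consecutive 7-day weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .session_log import LogRecord, Status, parse_log

__all__ = [
    "SessionMetrics",
    "WeeklyMetrics",
    "session_metrics",
    "weekly_aggregate",
    "progress_report",
]

# How each status tick is classified when measuring time. MANUAL and TIMEOUT
# are drinking-window synonyms; REWARD ticks are still time (the tick that
# completed the criterion).
_STILL = frozenset({Status.STILL, Status.START, Status.REWARD})
_DRINK = frozenset({Status.DRINKING, Status.MANUAL, Status.TIMEOUT})


@dataclass(frozen=True)
class SessionMetrics:
    """Per-session performance measures."""

    best_still_s: float
    percent_still: float  # fraction of non-paused time
    n_movements: int  # discrete movement onsets
    n_rewards: int
    mean_still_interval_s: float
    total_still_s: float
    duration_s: float  # non-paused session time
    session_date: Optional[date] = None
    empty: bool = False  # warning flag: computed from zero records


@dataclass(frozen=True)
class WeeklyMetrics:
    """Arithmetic means of session metrics over one 7-day window."""

    week_index: int
    n_sessions: int
    best_still_s: float
    percent_still: float
    n_movements: float
    n_rewards: float
    mean_still_interval_s: float
    total_still_s: float


def _ms(seconds: float) -> int:
    return int(round(seconds * 1000))


def session_metrics(
    records: Sequence[LogRecord], session_date: date | None = None
) -> SessionMetrics:
    """Compute session measures from time-ordered log records.

    A *still interval* is a maximal run of motionless, non-paused time;
    drinking ticks neither break nor extend it (the bridging rule), while a
    sensed movement or a pause ends it. Movement flags recorded during
    drinking or pause are ignored, matching the controller's non-punishment
    semantics. All arithmetic is exact in integer-millisecond tick units.
    """
    if not records:
        return SessionMetrics(0.0, 0.0, 0, 0, 0.0, 0.0, 0.0, session_date, empty=True)
    still_ms = moving_ms = drink_ms = paused_ms = 0
    intervals: list[int] = []
    run_ms = 0
    n_movements = 0
    n_rewards = 0
    prev_elapsed = 0
    prev_status: Status | None = None
    for rec in records:
        elapsed = _ms(rec.elapsed_s)
        dt = elapsed - prev_elapsed
        prev_elapsed = elapsed
        if rec.juice_on_ms > 0:
            n_rewards += 1
        status = rec.status
        if status is Status.PAUSED:
            paused_ms += dt
            if run_ms > 0:
                intervals.append(run_ms)
                run_ms = 0
        elif status in _DRINK:
            drink_ms += dt  # bridged: run neither breaks nor grows
        elif status is Status.SENSED_MOVE:
            moving_ms += dt
            if prev_status is not Status.SENSED_MOVE:
                n_movements += 1
            if run_ms > 0:
                intervals.append(run_ms)
                run_ms = 0
        else:  # still tick
            still_ms += dt
            run_ms += dt
        prev_status = status
    if run_ms > 0:
        intervals.append(run_ms)
    train_ms = still_ms + moving_ms + drink_ms
    return SessionMetrics(
        best_still_s=max(intervals, default=0) / 1000,
        percent_still=(still_ms / train_ms) if train_ms > 0 else 0.0,
        n_movements=n_movements,
        n_rewards=n_rewards,
        mean_still_interval_s=(sum(intervals) / len(intervals) / 1000)
        if intervals
        else 0.0,
        total_still_s=still_ms / 1000,
        duration_s=train_ms / 1000,
        session_date=session_date,
    )


_MEAN_FIELDS = (
    "best_still_s",
    "percent_still",
    "n_movements",
    "n_rewards",
    "mean_still_interval_s",
    "total_still_s",
)


def weekly_aggregate(metrics: Sequence[SessionMetrics]) -> list[WeeklyMetrics]:
    """Bucket dated sessions into consecutive 7-day windows from the first
    session date and average each measure per bucket. Empty buckets are
    omitted; undated sessions are ignored."""
    dated = [m for m in metrics if m.session_date is not None]
    if not dated:
        return []
    dated.sort(key=lambda m: m.session_date)
    first = dated[0].session_date
    buckets: dict[int, list[SessionMetrics]] = {}
    for m in dated:
        buckets.setdefault((m.session_date - first).days // 7, []).append(m)
    out = []
    for week in sorted(buckets):
        group = buckets[week]
        means = {
            f: sum(getattr(m, f) for m in group) / len(group) for f in _MEAN_FIELDS
        }
        out.append(WeeklyMetrics(week_index=week, n_sessions=len(group), **means))
    return out


def progress_report(
    log_paths: Sequence[str | Path],
    out: str | Path | None = None,
    include_weekly: bool = True,
) -> pd.DataFrame:
    """Build a tabular report: one row per session plus weekly mean rows.

    Session dates are taken from each log's recorded session start, when
    present. Unparseable files yield a flagged row and the run continues.
    Output is deterministic for identical inputs.
    """
    rows = []
    sessions: list[SessionMetrics] = []
    for path in log_paths:
        path = Path(path)
        try:
            summary, records = parse_log(path)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            rows.append({"kind": "session", "file": path.name, "error": str(exc)})
            continue
        session_date = None
        if summary is not None and summary.session_start:
            try:
                session_date = date.fromisoformat(summary.session_start[:10])
            except ValueError:
                pass
        m = session_metrics(records, session_date=session_date)
        sessions.append(m)
        row = {"kind": "session", "file": path.name, "error": ""}
        for f in dc_fields(SessionMetrics):
            row[f.name] = getattr(m, f.name)
        rows.append(row)
    if include_weekly:
        for w in weekly_aggregate(sessions):
            row = {"kind": "week", "file": f"week{w.week_index}", "error": ""}
            for f in dc_fields(WeeklyMetrics):
                row[f.name] = getattr(w, f.name)
            rows.append(row)
    columns = (
        ["kind", "file", "error"]
        + [f.name for f in dc_fields(SessionMetrics)]
        + ["week_index", "n_sessions"]
    )
    df = pd.DataFrame(rows, columns=columns)
    if out is not None:
        df.to_csv(out, index=False)
    return df
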