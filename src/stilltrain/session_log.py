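"""ASCII session-log format: per-tick records, crash-safe checkpoints, and the
end-of-session summary block prepended to the final file.

Final log layout::

    Animal ID: m1
    Experimenter: ...
    Duration (Sec): 1800.0
    Percent Still: 0.845
    Rewards Given: 42
    Longest Still (Sec): 312.4
    Start Criterion (Sec): 5.0
    End Criterion (Sec): 20.0
    <blank line>
    Elapsed Time (Sec)\tMovement\tStatus\t...
    0.1\t0\tSTILL\t0\t2.0\t2.0\t5.0
    ...

Checkpoint (`.tmp`) files carry the column header and records only; a crash
therefore never loses more than the ticks since the last checkpoint and the
temp file always parses. Records print seconds at 0.1 s precision (integer
milliseconds for valve time); summary floats are printed at full precision so
parsing a finalized log reconstructs the summary exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import LogFormatError, LogParseError

__all__ = [
    "Status",
    "LogRecord",
    "SessionSummary",
    "COLUMN_HEADER",
    "write_record",
    "parse_record",
    "checkpoint",
    "finalize_log",
    "parse_log",
]


class Status(str, Enum):
    """Controller status vocabulary as written in the log's Status column."""

    START = "START"
    STILL = "STILL"
    SENSED_MOVE = "SENSED MOVE"
    REWARD = "REWARD"
    MANUAL = "MANUAL"
    DRINKING = "DRINKING"
    TIMEOUT = "TIMEOUT"
    PAUSED = "PAUSED"


_STATUS_BY_TOKEN = {s.value: s for s in Status}

COLUMN_HEADER = (
    "Elapsed Time (Sec)\tMovement\tStatus\tJuice On (mSec)\t"
    "Drink Time (Sec)\tTime Out (Sec)\tCriterion (Sec)"
)


@dataclass(frozen=True)
class LogRecord:
    """One sampled row of the session log."""

    elapsed_s: float
    movement: bool
    status: Status
    juice_on_ms: int
    drink_time_s: float
    time_out_s: float
    criterion_s: float


@dataclass(frozen=True)
class SessionSummary:
    """Performance summary prepended to the finalized log."""

    percent_still: float  # fraction in [0, 1]
    n_rewards: int
    duration_s: float
    longest_still_s: float
    start_criterion_s: float
    end_criterion_s: float
    animal_id: str = ""
    experimenter: str = ""
    session_start: str | None = None  # ISO wall-clock time, if recorded


def write_record(record: LogRecord) -> str:
    """Serialize one record to a tab-separated line (no trailing newline)."""
    status = record.status
    if not isinstance(status, Status):
        try:
            status = _STATUS_BY_TOKEN[str(status)]
        except KeyError:
            raise LogFormatError(f"unknown status {record.status!r}") from None
    return (
        f"{record.elapsed_s:.1f}\t{int(record.movement)}\t{status.value}\t"
        f"{record.juice_on_ms:d}\t{record.drink_time_s:.1f}\t"
        f"{record.time_out_s:.1f}\t{record.criterion_s:.1f}"
    )


def parse_record(line: str, lineno: int | None = None) -> LogRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 7:
        raise LogParseError(f"expected 7 columns, got {len(parts)}", lineno)
    try:
        status = _STATUS_BY_TOKEN[parts[2]]
    except KeyError:
        raise LogParseError(f"unknown status token {parts[2]!r}", lineno) from None
    try:
        return LogRecord(
            elapsed_s=float(parts[0]),
            movement=bool(int(parts[1])),
            status=status,
            juice_on_ms=int(parts[3]),
            drink_time_s=float(parts[4]),
            time_out_s=float(parts[5]),
            criterion_s=float(parts[6]),
        )
    except ValueError as exc:
        raise LogParseError(f"bad numeric field: {exc}", lineno) from None


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".new")
    tmp.write_text(text, encoding="ascii")
    os.replace(tmp, path)


def checkpoint(records: Sequence[LogRecord], temp_path: str | Path) -> None:
    """Write all records so far to the temp file, atomically.

    The temp file is header + records; an interrupted session can always be
    recovered by parsing it (the summary is simply absent).
    """
    temp_path = Path(temp_path)
    body = "".join(write_record(r) + "\n" for r in records)
    _atomic_write(temp_path, COLUMN_HEADER + "\n" + body)


_SUMMARY_FIELDS = [
    ("Animal ID", "animal_id"),
    ("Experimenter", "experimenter"),
    ("Session Start", "session_start"),
    ("Duration (Sec)", "duration_s"),
    ("Percent Still", "percent_still"),
    ("Rewards Given", "n_rewards"),
    ("Longest Still (Sec)", "longest_still_s"),
    ("Start Criterion (Sec)", "start_criterion_s"),
    ("End Criterion (Sec)", "end_criterion_s"),
]
_KEY_TO_FIELD = {k: f for k, f in _SUMMARY_FIELDS}


def _format_summary(summary: SessionSummary) -> str:
    lines = []
    for key, attr in _SUMMARY_FIELDS:
        value = getattr(summary, attr)
        if attr == "session_start" and value is None:
            continue
        if isinstance(value, float):
            value = repr(value)  # full precision: exact round trip
        lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"


def finalize_log(
    records: Sequence[LogRecord],
    summary: SessionSummary,
    path: str | Path,
    temp_path: str | Path | None = None,
) -> None:
    """Write the final log (summary block, blank line, header, records) and
    remove the checkpoint temp file, if any."""
    path = Path(path)
    body = "".join(write_record(r) + "\n" for r in records)
    _atomic_write(path, _format_summary(summary) + "\n" + COLUMN_HEADER + "\n" + body)
    if temp_path is None:
        temp_path = path.with_name(path.name + ".tmp")
    temp_path = Path(temp_path)
    if temp_path.exists():
        temp_path.unlink()


def parse_log(path: str | Path) -> tuple[Optional[SessionSummary], list[LogRecord]]:
    """Parse a finalized log or a headerless/summary-less checkpoint file.

    Returns ``(summary, records)``; summary is None for checkpoint files.
    Malformed lines raise :class:`LogParseError` naming the line number.
    """
    path = Path(path)
    lines = path.read_text(encoding="ascii").splitlines()
    i = 0
    summary = None
    if lines and not lines[0].startswith("Elapsed Time"):
        fields: dict[str, str] = {}
        while i < len(lines) and lines[i].strip():
            line = lines[i]
            if ": " not in line and not line.endswith(":"):
                raise LogParseError(f"malformed summary line {line!r}", i + 1)
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in _KEY_TO_FIELD:
                raise LogParseError(f"unknown summary key {key!r}", i + 1)
            fields[_KEY_TO_FIELD[key]] = value.strip()
            i += 1
        try:
            summary = SessionSummary(
                percent_still=float(fields["percent_still"]),
                n_rewards=int(fields["n_rewards"]),
                duration_s=float(fields["duration_s"]),
                longest_still_s=float(fields["longest_still_s"]),
                start_criterion_s=float(fields["start_criterion_s"]),
                end_criterion_s=float(fields["end_criterion_s"]),
                animal_id=fields.get("animal_id", ""),
                experimenter=fields.get("experimenter", ""),
                session_start=fields.get("session_start"),
            )
        except (KeyError, ValueError) as exc:
            raise LogParseError(f"incomplete or invalid summary block: {exc}") from None
        while i < len(lines) and not lines[i].strip():
            i += 1
    if i < len(lines) and lines[i].startswith("Elapsed Time"):
        i += 1  # column header
    records = []
    for lineno in range(i, len(lines)):
        if not lines[lineno].strip():
            continue
        records.append(parse_record(lines[lineno], lineno + 1))
    prev = float("-inf")
    for r in records:
        if r.elapsed_s < prev:
            raise LogParseError(
                f"elapsed time decreases at {r.elapsed_s}", None
            )
        prev = r.elapsed_s
    return summary, records
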