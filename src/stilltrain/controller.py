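"""Operant-conditioning controller: reward sustained stillness, adaptively.

The controller is a deterministic, discrete-time state machine. Each *tick*
(one sampling period of ``read_every_ms``) consumes a binary moved/still
observation plus any pending operator commands, and produces the cue state
(LED abstraction), at most one reward command, and exactly one log record.

Semantics, in brief:

* A flashing green cue asks the subject to hold still; any detected movement
  resets the live still timer (and the consecutive-reward count) and lights
  the red feedback cue for that tick.
* When the still timer reaches the current criterion, a liquid reward is
  dispensed and a drinking window of ``timeout_s`` begins during which
  movement is ignored entirely — drinking must not be punished.
* After every ``n_periods`` consecutive earned rewards the criterion moves by
  ``auto_delta_s`` seconds, clamped between the start and maximum intervals:
  the adaptive schedule that shapes the subject toward long motionless holds.
* Accumulated stillness additionally earns larger *bonus* rewards every
  ``bonus_period_s`` seconds of (cumulative) motionlessness.

All timing is held internally in integer milliseconds so identical inputs
yield identical trajectories and every conservation property is exact in tick
units; seconds appear only at the API and log boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import ConfigError, SessionStateError
from .session_log import LogRecord, SessionSummary, Status

__all__ = [
    "TrainingConfig",
    "ControllerState",
    "CueState",
    "RewardCommand",
    "OperatorCommand",
    "TickResult",
    "SessionResult",
    "init_session",
    "tick",
    "adapt_criterion",
    "apply_command",
    "finalize",
    "replay",
    "rewards_to_reach_max",
]


def _ms(seconds: float) -> int:
    return int(round(seconds * 1000))


# Config fields operators may change mid-session (via `set` commands).
MUTABLE_FIELDS = frozenset(
    {
        "timeout_s",
        "drinking_period_s",
        "n_periods",
        "auto_delta_s",
        "set_max_s",
        "bonus_period_s",
        "bonus_multiplier",
        "reward_duration_ms",
    }
)


@dataclass
class TrainingConfig:
    """Operator-settable training parameters (the control-panel state).

    Defaults mirror a typical early training session: a 5 s starting
    criterion stepped up by 5 s after every 2 consecutive rewards toward a
    95 s maximum, a 2 s drinking time-out, 100 ms sampling.
    """

    set_start_s: float = 5.0
    set_max_s: float = 95.0
    n_periods: int = 2
    auto_delta_s: float = 5.0
    timeout_s: float = 2.0
    drinking_period_s: float | None = None  # defaults to timeout_s
    bonus_period_s: float = 60.0  # 0 disables bonus rewards
    bonus_multiplier: float = 2.0
    reward_duration_ms: int = 500
    read_every_ms: int = 100
    bonus_mode: str = "cumulative"  # or "continuous"
    animal_id: str = ""
    experimenter: str = ""

    def __post_init__(self) -> None:
        if self.drinking_period_s is None:
            self.drinking_period_s = self.timeout_s

    def validate(self) -> "TrainingConfig":
        bad = []
        if not self.set_start_s > 0:
            bad.append("set_start_s must be > 0")
        if self.set_start_s > self.set_max_s:
            bad.append("set_start_s must be <= set_max_s")
        if self.n_periods < 1:
            bad.append("n_periods must be >= 1")
        if not self.reward_duration_ms > 0:
            bad.append("reward_duration_ms must be > 0")
        if not self.read_every_ms > 0:
            bad.append("read_every_ms must be > 0")
        if self.timeout_s < 0:
            bad.append("timeout_s must be >= 0")
        if self.drinking_period_s is not None and self.drinking_period_s < 0:
            bad.append("drinking_period_s must be >= 0")
        if self.bonus_multiplier < 1:
            bad.append("bonus_multiplier must be >= 1")
        if self.bonus_period_s < 0:
            bad.append("bonus_period_s must be >= 0")
        if self.bonus_mode not in ("cumulative", "continuous"):
            bad.append("bonus_mode must be 'cumulative' or 'continuous'")
        if bad:
            raise ConfigError("invalid training config: " + "; ".join(bad))
        return self


@dataclass(frozen=True)
class CueState:
    """LED abstraction: flashing green = hold still; red = movement sensed;
    solid green (red off) = drinking window."""

    green_flashing: bool
    green_solid: bool
    red_on: bool


@dataclass(frozen=True)
class RewardCommand:
    """A valve-open command. kind is one of normal/bonus/manual/continuous."""

    onset_s: float
    duration_ms: int
    kind: str


@dataclass(frozen=True)
class OperatorCommand:
    """A timestamped front-panel action.

    kind: pause | restart | manual_reward | continuous_reward_start |
    continuous_reward_stop | save_stop | save_quit | set
    For ``set``, ``field``/``value`` name a mutable config parameter.
    """

    kind: str
    at_s: float = 0.0
    field: str | None = None
    value: float | None = None


@dataclass
class ControllerState:
    """Live session state. All *_ms fields are exact integer milliseconds."""

    status: Status = Status.START
    criterion_ms: int = 0
    elapsed_ms: int = 0
    current_still_ms: int = 0  # live timer toward the criterion
    run_still_ms: int = 0  # bridged still run (drinking neither breaks nor extends)
    best_still_ms: int = 0
    bonus_accum_ms: int = 0
    drink_remaining_ms: int = 0
    consecutive_rewards: int = 0
    # totals
    still_ms: int = 0
    moving_ms: int = 0
    drinking_ms: int = 0
    paused_ms: int = 0
    movement_count: int = 0
    reward_count: int = 0
    juice_ms: int = 0
    # bookkeeping
    resume_status: Status = Status.STILL
    continuous_start_ms: int | None = None
    terminal: bool = False
    warnings: list = field(default_factory=list)

    # -- second-valued views -------------------------------------------------
    @property
    def elapsed_s(self) -> float:
        return self.elapsed_ms / 1000

    @property
    def current_criterion_s(self) -> float:
        return self.criterion_ms / 1000

    @property
    def current_still_s(self) -> float:
        return self.current_still_ms / 1000

    @property
    def best_still_s(self) -> float:
        return self.best_still_ms / 1000

    @property
    def total_still_s(self) -> float:
        return self.still_ms / 1000


@dataclass(frozen=True)
class TickResult:
    state: ControllerState
    cue: CueState
    reward: Optional[RewardCommand]
    record: LogRecord


@dataclass(frozen=True)
class SessionResult:
    records: list[LogRecord]
    summary: SessionSummary
    state: ControllerState
    rewards: list[RewardCommand]


def init_session(cfg: TrainingConfig) -> ControllerState:
    """Start a session: criterion at set_start_s, all timers and totals zero."""
    cfg.validate()
    return ControllerState(status=Status.START, criterion_ms=_ms(cfg.set_start_s))


def adapt_criterion(
    consecutive_rewards: int, current_criterion_s: float, cfg: TrainingConfig
) -> float:
    """Adaptive schedule: after each block of n_periods consecutive rewards the
    criterion moves by auto_delta_s, clamped between set_start_s and set_max_s
    (whichever order those lie in)."""
    return (
        _adapt_ms(consecutive_rewards, _ms(current_criterion_s), cfg) / 1000
    )


def _adapt_ms(consecutive: int, cur_ms: int, cfg: TrainingConfig) -> int:
    if consecutive > 0 and consecutive % cfg.n_periods == 0:
        lo, hi = sorted((_ms(cfg.set_start_s), _ms(cfg.set_max_s)))
        return min(max(cur_ms + _ms(cfg.auto_delta_s), lo), hi)
    return cur_ms


def cue_for(status: Status) -> CueState:
    if status in (Status.DRINKING, Status.MANUAL, Status.TIMEOUT):
        return CueState(green_flashing=False, green_solid=True, red_on=False)
    if status is Status.PAUSED:
        return CueState(green_flashing=False, green_solid=False, red_on=False)
    return CueState(
        green_flashing=True,
        green_solid=False,
        red_on=status is Status.SENSED_MOVE,
    )


def apply_command(
    state: ControllerState, cfg: TrainingConfig, cmd: OperatorCommand
) -> tuple[ControllerState, Optional[RewardCommand]]:
    """Apply one operator command, mutating ``state`` (and ``cfg`` for `set`).

    Returns the state and the reward the command produced, if any. Restarting
    when not paused is a recorded no-op warning, not an error.
    """
    reward: Optional[RewardCommand] = None
    kind = cmd.kind
    if kind == "pause":
        if state.status is not Status.PAUSED:
            state.resume_status = state.status
            state.status = Status.PAUSED
    elif kind == "restart":
        if state.status is Status.PAUSED:
            state.status = state.resume_status
        else:
            state.warnings.append(
                f"restart at {cmd.at_s:g}s ignored: session not paused"
            )
    elif kind == "manual_reward":
        reward = RewardCommand(
            onset_s=state.elapsed_ms / 1000,
            duration_ms=cfg.reward_duration_ms,
            kind="manual",
        )
        state.reward_count += 1
        state.juice_ms += reward.duration_ms
        if state.status is not Status.PAUSED:
            # manual rewards get the same non-punishment drinking window;
            # the live still timer is frozen, never reset.
            state.drink_remaining_ms = _ms(cfg.timeout_s)
            state.status = Status.MANUAL
    elif kind == "continuous_reward_start":
        state.continuous_start_ms = state.elapsed_ms
    elif kind == "continuous_reward_stop":
        if state.continuous_start_ms is None:
            state.warnings.append(
                f"continuous stop at {cmd.at_s:g}s ignored: no start pending"
            )
        else:
            dur = state.elapsed_ms - state.continuous_start_ms
            reward = RewardCommand(
                onset_s=state.continuous_start_ms / 1000,
                duration_ms=dur,
                kind="continuous",
            )
            state.reward_count += 1
            state.juice_ms += dur
            state.continuous_start_ms = None
    elif kind == "set":
        if cmd.field not in MUTABLE_FIELDS:
            state.warnings.append(f"set {cmd.field!r} ignored: not adjustable")
        else:
            value = cmd.value
            if cmd.field in ("n_periods", "reward_duration_ms"):
                value = int(value)
            setattr(cfg, cmd.field, value)
            cfg.validate()
    elif kind in ("save_stop", "save_quit"):
        state.terminal = True
    else:
        raise ConfigError(f"unknown operator command {kind!r}")
    return state, reward


def tick(
    state: ControllerState,
    cfg: TrainingConfig,
    moved: bool,
    pending: Sequence[OperatorCommand] = (),
) -> TickResult:
    """Advance the session by one sampling period.

    Order of effects: operator commands first, then the motion sample. During
    the drinking window movement is ignored completely (no timer reset, no
    movement count, no red cue). Paused ticks advance only the wall clock.
    At most one RewardCommand is emitted per tick.
    """
    if state.terminal:
        raise SessionStateError("tick on a terminated session")
    dt = cfg.read_every_ms
    reward: Optional[RewardCommand] = None
    for cmd in pending:
        _, r = apply_command(state, cfg, cmd)
        if r is not None and reward is None:
            reward = r
    if state.terminal:
        # save-and-stop landed on this tick: no time advances, final record.
        record = _make_record(state, cfg, moved=False, juice=0)
        return TickResult(state, cue_for(state.status), reward, record)

    state.elapsed_ms += dt

    if state.status is Status.PAUSED:
        state.paused_ms += dt
        state.run_still_ms = 0  # a pause breaks the motionless run
        record = _make_record(state, cfg, moved=moved, juice=_dur(reward))
        return TickResult(state, cue_for(Status.PAUSED), reward, record)

    if state.drink_remaining_ms > 0:
        rec_status = (
            Status.MANUAL if state.status is Status.MANUAL else Status.DRINKING
        )
        state.drinking_ms += dt
        state.drink_remaining_ms = max(0, state.drink_remaining_ms - dt)
        state.status = Status.DRINKING if state.drink_remaining_ms > 0 else Status.STILL
        record = _make_record(
            state, cfg, moved=moved, juice=_dur(reward), status=rec_status
        )
        return TickResult(state, cue_for(rec_status), reward, record)

    if moved:
        state.status = Status.SENSED_MOVE
        state.moving_ms += dt
        state.movement_count += 1
        state.current_still_ms = 0
        state.consecutive_rewards = 0
        state.run_still_ms = 0
        if cfg.bonus_mode == "continuous":
            state.bonus_accum_ms = 0
        record = _make_record(state, cfg, moved=True, juice=_dur(reward))
        return TickResult(state, cue_for(Status.SENSED_MOVE), reward, record)

    # still tick
    state.status = Status.STILL
    state.still_ms += dt
    state.current_still_ms += dt
    state.run_still_ms += dt
    state.bonus_accum_ms += dt
    if state.run_still_ms > state.best_still_ms:
        state.best_still_ms = state.run_still_ms

    if reward is None and state.current_still_ms >= state.criterion_ms:
        state.status = Status.REWARD
        reward = RewardCommand(
            onset_s=state.elapsed_ms / 1000,
            duration_ms=cfg.reward_duration_ms,
            kind="normal",
        )
        state.reward_count += 1
        state.juice_ms += reward.duration_ms
        state.consecutive_rewards += 1
        state.criterion_ms = _adapt_ms(
            state.consecutive_rewards, state.criterion_ms, cfg
        )
        state.current_still_ms = 0
        state.drink_remaining_ms = _ms(cfg.timeout_s)
    elif (
        reward is None
        and cfg.bonus_period_s > 0
        and state.bonus_accum_ms >= _ms(cfg.bonus_period_s)
    ):
        reward = RewardCommand(
            onset_s=state.elapsed_ms / 1000,
            duration_ms=int(round(cfg.bonus_multiplier * cfg.reward_duration_ms)),
            kind="bonus",
        )
        state.reward_count += 1
        state.juice_ms += reward.duration_ms
        state.bonus_accum_ms = 0

    record = _make_record(state, cfg, moved=False, juice=_dur(reward))
    return TickResult(state, cue_for(state.status), reward, record)


def _dur(reward: Optional[RewardCommand]) -> int:
    return 0 if reward is None else reward.duration_ms


def _make_record(
    state: ControllerState,
    cfg: TrainingConfig,
    moved: bool,
    juice: int,
    status: Status | None = None,
) -> LogRecord:
    return LogRecord(
        elapsed_s=state.elapsed_ms / 1000,
        movement=moved,
        status=status if status is not None else state.status,
        juice_on_ms=juice,
        drink_time_s=float(cfg.drinking_period_s),
        time_out_s=float(cfg.timeout_s),
        criterion_s=state.criterion_ms / 1000,
    )


def finalize(
    state: ControllerState,
    cfg: TrainingConfig,
    session_start: str | None = None,
) -> SessionSummary:
    """Compute the end-of-session summary that is prepended to the log file.

    Percent still uses non-paused session time as the denominator; a
    zero-duration session yields 0% and zero counts.
    """
    train_ms = state.elapsed_ms - state.paused_ms
    return SessionSummary(
        percent_still=(state.still_ms / train_ms) if train_ms > 0 else 0.0,
        n_rewards=state.reward_count,
        duration_s=train_ms / 1000,
        longest_still_s=state.best_still_ms / 1000,
        start_criterion_s=float(cfg.set_start_s),
        end_criterion_s=state.criterion_ms / 1000,
        animal_id=cfg.animal_id,
        experimenter=cfg.experimenter,
        session_start=session_start,
    )


def replay(
    cfg: TrainingConfig,
    moved_stream: Iterable[bool],
    commands: Sequence[OperatorCommand] = (),
    session_start: str | None = None,
) -> SessionResult:
    """Run a full session over a recorded moved/still stream.

    Commands are applied on the first tick whose end time reaches their
    timestamp. The stream ends either when exhausted or at a save_stop /
    save_quit command. Deterministic: identical inputs give identical output,
    byte for byte once written.
    """
    cfg = replace(cfg).validate()
    state = init_session(cfg)
    queue = sorted(commands, key=lambda c: c.at_s)
    qi = 0
    records: list[LogRecord] = []
    rewards: list[RewardCommand] = []
    dt = cfg.read_every_ms
    for moved in moved_stream:
        pending = []
        horizon = state.elapsed_ms + dt
        while qi < len(queue) and _ms(queue[qi].at_s) <= horizon:
            pending.append(queue[qi])
            qi += 1
        res = tick(state, cfg, moved, pending)
        records.append(res.record)
        if res.reward is not None:
            rewards.append(res.reward)
        if state.terminal:
            break
    summary = finalize(state, cfg, session_start=session_start)
    return SessionResult(records=records, summary=summary, state=state, rewards=rewards)


def rewards_to_reach_max(cfg: TrainingConfig) -> int:
    """Closed form: consecutive rewards a never-moving subject needs before the
    criterion first equals set_max_s (positive auto_delta_s only)."""
    if cfg.auto_delta_s <= 0:
        raise ConfigError("closed form requires auto_delta_s > 0")
    steps = math.ceil((cfg.set_max_s - cfg.set_start_s) / cfg.auto_delta_s)
    return cfg.n_periods * steps
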