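"""Simulated subject, synthetic scene rendering, and closed-loop sessions.

The subject is a two-state (idle/moving) discrete-time renewal process: while
idle it starts a movement each tick with probability ``hazard * dt`` (a
thinned Bernoulli approximation of a Poisson process with the given rate);
movement episodes end each tick with probability ``dt / move_duration_s``, so
episode lengths are geometric with the requested mean. An optional
reward-contingent learning factor multiplies the hazard by
``learning_factor ** rewards_so_far``, producing the declining movement rate a
training system exists to induce. ``drink_motion`` injects movement during the
controller's drinking window — movement the controller must ignore.

The scene renderer produces a mostly static, optionally noisy grayscale
background in which a rectangular blob shifts intensity on moved ticks, so
``detect_sequence(render_frames(samples))`` recovers the moved flags (exactly,
at zero noise).

All randomness flows from a single seed split into named sub-streams
(subject, scene) so components can be re-run independently and every run is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .controller import (
    ControllerState,
    OperatorCommand,
    SessionResult,
    TrainingConfig,
    finalize,
    init_session,
    tick,
)
from .errors import BoundsError, ConfigError, InputError
from .motion import Frame, MotionSample
from .session_log import LogRecord, SessionSummary, Status, finalize_log

__all__ = [
    "SubjectParams",
    "SceneParams",
    "simulate_subject",
    "render_frames",
    "run_closed_loop",
    "estimate_move_hazard",
]


@dataclass
class SubjectParams:
    """Stochastic movement model of a simulated subject.

    move_hazard_per_s
        Rate of initiating a movement while idle (events per second).
    move_duration_s
        Mean movement-episode length in seconds.
    drink_motion
        Whether the subject visibly moves (licks/swallows) while drinking.
    learning_factor
        Hazard multiplier applied per earned reward; 1 = no learning.
    """

    move_hazard_per_s: float = 0.05
    move_duration_s: float = 0.5
    drink_motion: bool = True
    learning_factor: float = 1.0
    seed: int | None = None

    def validate(self) -> "SubjectParams":
        bad = []
        if self.move_hazard_per_s < 0:
            bad.append("move_hazard_per_s must be >= 0")
        if not self.move_duration_s > 0:
            bad.append("move_duration_s must be > 0")
        if not 0 < self.learning_factor <= 1:
            bad.append("learning_factor must be in (0, 1]")
        if bad:
            raise ConfigError("invalid subject params: " + "; ".join(bad))
        return self


@dataclass
class SceneParams:
    """Synthetic camera scene: static background plus a movement blob.

    Emulates a fixed surveillance view of a restrained subject: uniform
    background with optional per-pixel Gaussian noise, and a rectangular
    region (the body part that moves) whose intensity shifts by
    ``blob_delta`` during movement ticks.
    """

    width: int = 64
    height: int = 48
    background: int = 120
    noise_sd: float = 0.0
    blob: tuple[int, int, int, int] = (24, 16, 40, 32)  # (x0, y0, x1, y1)
    blob_delta: int = 60
    seed: int | None = None

    def validate(self) -> "SceneParams":
        if self.width < 1 or self.height < 1:
            raise ConfigError("scene dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        x0, y0, x1, y1 = self.blob
        if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
            raise BoundsError(
                f"blob {self.blob} outside {self.width}x{self.height} frame"
            )
        return self


@dataclass(frozen=True)
class ClosedLoopResult:
    """Everything one simulated session produced."""

    samples: list[MotionSample]
    records: list[LogRecord]
    summary: SessionSummary
    state: ControllerState
    n_move_onsets: int  # subject-initiated movement onsets (ground truth)


def _subject_rng(params: SubjectParams, seed: int | None) -> np.random.Generator:
    root = params.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    return np.random.default_rng(ss.spawn(2)[0])


def run_closed_loop(
    subject: SubjectParams,
    cfg: TrainingConfig,
    duration_s: float,
    seed: int | None = None,
    commands: Sequence[OperatorCommand] = (),
    log_path: str | Path | None = None,
    session_start: str | None = None,
) -> ClosedLoopResult:
    """Run a full closed-loop session: subject -> controller -> log.

    The subject reacts to the controller (drinking windows, reward-contingent
    learning); the controller sees only the per-tick moved flag. Fully
    deterministic given the seed.
    """
    subject.validate()
    cfg = TrainingConfig(**{k: getattr(cfg, k) for k in cfg.__dataclass_fields__})
    cfg.validate()
    if not duration_s > 0:
        raise InputError("duration_s must be > 0")
    rng = _subject_rng(subject, seed)
    state = init_session(cfg)
    dt_s = cfg.read_every_ms / 1000
    n_ticks = int(round(duration_s / dt_s))
    queue = sorted(commands, key=lambda c: c.at_s)
    qi = 0
    moving = False
    p_end = min(1.0, dt_s / subject.move_duration_s)
    samples: list[MotionSample] = []
    records: list[LogRecord] = []
    n_onsets = 0
    for _ in range(n_ticks):
        u = rng.random()  # one draw per tick keeps streams aligned
        if moving:
            if u < p_end:
                moving = False
        else:
            p_move = min(
                1.0,
                subject.move_hazard_per_s
                * dt_s
                * subject.learning_factor**state.reward_count,
            )
            if u < p_move:
                moving = True
                n_onsets += 1
        drinking = state.drink_remaining_ms > 0 and state.status is not Status.PAUSED
        moved = moving or (drinking and subject.drink_motion)
        pending = []
        horizon = state.elapsed_ms + cfg.read_every_ms
        while qi < len(queue) and int(round(queue[qi].at_s * 1000)) <= horizon:
            pending.append(queue[qi])
            qi += 1
        res = tick(state, cfg, moved, pending)
        samples.append(
            MotionSample(
                timestamp=state.elapsed_ms / 1000,
                moved=moved,
                magnitude=1.0 if moved else 0.0,
            )
        )
        records.append(res.record)
        if state.terminal:
            break
    summary = finalize(state, cfg, session_start=session_start)
    if log_path is not None:
        finalize_log(records, summary, log_path)
    return ClosedLoopResult(
        samples=samples,
        records=records,
        summary=summary,
        state=state,
        n_move_onsets=n_onsets,
    )


def simulate_subject(
    params: SubjectParams,
    cfg: TrainingConfig,
    duration_s: float,
    seed: int | None = None,
) -> list[MotionSample]:
    """Generate the per-tick motion samples of a simulated subject running
    closed-loop against a controller with ``cfg``."""
    return run_closed_loop(params, cfg, duration_s, seed=seed).samples


def render_frames(
    samples: Sequence[MotionSample], scene: SceneParams, seed: int | None = None
) -> list[Frame]:
    """Render a motion-sample stream as a synthetic grayscale frame sequence.

    Produces ``len(samples) + 1`` frames; the blob toggles its intensity
    shift on every moved sample so each moved pair differs in exactly the
    blob region, and still pairs are identical at zero noise.
    """
    scene.validate()
    samples = list(samples)
    if not samples:
        raise InputError("need at least one sample to render")
    for a, b in zip(samples, samples[1:]):
        if b.timestamp <= a.timestamp:
            raise InputError("samples must be strictly time-ordered")
    root = scene.seed if seed is None else seed
    ss = np.random.SeedSequence(0 if root is None else root)
    rng = np.random.default_rng(ss.spawn(2)[1])
    x0, y0, x1, y1 = scene.blob
    dt = samples[1].timestamp - samples[0].timestamp if len(samples) > 1 else 0.1

    def base() -> np.ndarray:
        img = np.full((scene.height, scene.width), scene.background, dtype=float)
        if scene.noise_sd > 0:
            img += rng.normal(0.0, scene.noise_sd, img.shape)
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    frames: list[Frame] = []
    phase = False
    t0 = samples[0].timestamp - dt
    if scene.noise_sd > 0:
        frames.append(Frame(base(), timestamp=t0))
    else:
        quiet = base()
        frames.append(Frame(quiet, timestamp=t0))
    for s in samples:
        if s.moved:
            phase = not phase
        if scene.noise_sd > 0:
            img = base()
        else:
            img = quiet.copy()
        if phase:
            region = img[y0:y1, x0:x1].astype(int) + scene.blob_delta
            img[y0:y1, x0:x1] = np.clip(region, 0, 255).astype(np.uint8)
        frames.append(Frame(img, timestamp=s.timestamp))
    return frames


def estimate_move_hazard(records: Sequence[LogRecord]) -> float:
    """Estimate the subject's movement-initiation rate from a session log:
    movement onsets per second of observed still (idle, non-drinking) time."""
    still_ms = 0
    onsets = 0
    prev: Status | None = None
    prev_elapsed = 0
    for rec in records:
        elapsed = int(round(rec.elapsed_s * 1000))
        dt = elapsed - prev_elapsed
        prev_elapsed = elapsed
        if rec.status in (Status.STILL, Status.START, Status.REWARD):
            still_ms += dt
        elif rec.status is Status.SENSED_MOVE and prev is not Status.SENSED_MOVE:
            onsets += 1
        prev = rec.status
    if still_ms == 0:
        return float("nan")
    return onsets / (still_ms / 1000)
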