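"""Independent brute-force oracles and random input generators.

The replay oracle is a deliberately flat, straight-line reimplementation of
the controller contract (no shared code with the package): it walks the tick
stream with plain integer counters and returns reward times, the criterion
trajectory, and the time/count totals. The pixel oracle is a naive double
loop. Both exist only to cross-check the real implementations.
"""

from __future__ import annotations

import numpy as np

from stilltrain import OperatorCommand, TrainingConfig


def naive_magnitude(prev, cur, excluded, threshold):
    """Double-loop changed-pixel fraction over unmasked pixels."""
    h = len(prev)
    w = len(prev[0])
    changed = 0
    visible = 0
    for y in range(h):
        for x in range(w):
            if excluded[y][x]:
                continue
            visible += 1
            if abs(int(cur[y][x]) - int(prev[y][x])) >= threshold:
                changed += 1
    return changed / visible


def replay_oracle(cfg: TrainingConfig, moved_stream, commands=()):
    """Straight-line replay of the controller contract.

    Returns a dict with reward (time_ms, kind) pairs, the criterion value
    after each normal reward, and all totals in integer milliseconds/counts.
    """

    def ms(s):
        return int(round(s * 1000))

    dt = cfg.read_every_ms
    lo, hi = sorted((ms(cfg.set_start_s), ms(cfg.set_max_s)))
    crit = ms(cfg.set_start_s)
    elapsed = 0
    cur_still = 0
    run = 0
    best = 0
    bonus = 0
    drink = 0
    consec = 0
    still_t = moving_t = drinking_t = paused_t = 0
    n_move = n_rew = juice = 0
    paused = False
    rewards = []
    crit_traj = []
    cmds = sorted(commands, key=lambda c: c.at_s)
    ci = 0
    for mv in moved_stream:
        cmd_rewarded = False  # at most one reward command per tick
        while ci < len(cmds) and ms(cmds[ci].at_s) <= elapsed + dt:
            c = cmds[ci]
            ci += 1
            if c.kind == "pause":
                paused = True
            elif c.kind == "restart":
                paused = False
            elif c.kind == "manual_reward":
                n_rew += 1
                juice += cfg.reward_duration_ms
                rewards.append((elapsed, "manual"))
                cmd_rewarded = True
                if not paused:
                    drink = ms(cfg.timeout_s)
        elapsed += dt
        if paused:
            paused_t += dt
            run = 0
            continue
        if drink > 0:
            drinking_t += dt
            drink -= dt
            continue
        if mv:
            moving_t += dt
            n_move += 1
            cur_still = 0
            consec = 0
            run = 0
            if cfg.bonus_mode == "continuous":
                bonus = 0
            continue
        still_t += dt
        cur_still += dt
        run += dt
        bonus += dt
        if run > best:
            best = run
        if cmd_rewarded:
            continue
        if cur_still >= crit:
            n_rew += 1
            juice += cfg.reward_duration_ms
            rewards.append((elapsed, "normal"))
            consec += 1
            if consec % cfg.n_periods == 0:
                crit = min(max(crit + ms(cfg.auto_delta_s), lo), hi)
            crit_traj.append(crit)
            cur_still = 0
            drink = ms(cfg.timeout_s)
        elif cfg.bonus_period_s > 0 and bonus >= ms(cfg.bonus_period_s):
            dur = int(round(cfg.bonus_multiplier * cfg.reward_duration_ms))
            n_rew += 1
            juice += dur
            rewards.append((elapsed, "bonus"))
            bonus = 0
    return {
        "rewards": rewards,
        "criterion_traj": crit_traj,
        "final_criterion_ms": crit,
        "best_ms": best,
        "totals": {
            "still_ms": still_t,
            "moving_ms": moving_t,
            "drinking_ms": drinking_t,
            "paused_ms": paused_t,
            "movement_count": n_move,
            "reward_count": n_rew,
            "juice_ms": juice,
        },
    }


def result_fingerprint(result):
    """The same quantities extracted from a package SessionResult."""
    st = result.state
    return {
        "rewards": [
            (int(round(r.onset_s * 1000)), r.kind) for r in result.rewards
        ],
        "final_criterion_ms": st.criterion_ms,
        "best_ms": st.best_still_ms,
        "totals": {
            "still_ms": st.still_ms,
            "moving_ms": st.moving_ms,
            "drinking_ms": st.drinking_ms,
            "paused_ms": st.paused_ms,
            "movement_count": st.movement_count,
            "reward_count": st.reward_count,
            "juice_ms": st.juice_ms,
        },
    }


def random_config(rng: np.random.Generator) -> TrainingConfig:
    """A random but valid training configuration (0.1 s-grained values)."""
    start = rng.integers(10, 101) / 10  # 1.0 .. 10.0 s
    span = rng.integers(0, 201) / 10
    return TrainingConfig(
        set_start_s=float(start),
        set_max_s=float(start + span),
        n_periods=int(rng.integers(1, 6)),
        auto_delta_s=float(rng.integers(-30, 51) / 10),
        timeout_s=float(rng.integers(0, 31) / 10),
        bonus_period_s=float(rng.choice([0.0, 5.0, 12.0, 30.0])),
        bonus_multiplier=float(rng.integers(10, 31) / 10),
        reward_duration_ms=int(rng.integers(1, 11) * 100),
        read_every_ms=100,
        bonus_mode=str(rng.choice(["cumulative", "continuous"])),
    )


def random_moved_stream(rng: np.random.Generator, n_ticks: int) -> list[bool]:
    """Two-state moved/still stream with random switching rates."""
    p_start = rng.uniform(0.002, 0.08)
    p_stop = rng.uniform(0.1, 0.6)
    moving = False
    out = []
    for _ in range(n_ticks):
        u = rng.random()
        moving = (u >= p_stop) if moving else (u < p_start)
        out.append(moving)
    return out


def random_commands(
    rng: np.random.Generator, n_ticks: int, dt_ms: int
) -> list[OperatorCommand]:
    """Occasional pause/restart pairs and manual rewards within the session."""
    cmds = []
    horizon_s = n_ticks * dt_ms / 1000
    if rng.random() < 0.3 and horizon_s > 2:
        t0 = float(rng.uniform(0, horizon_s * 0.6))
        t1 = float(rng.uniform(t0, horizon_s * 0.9))
        cmds.append(OperatorCommand("pause", at_s=t0))
        cmds.append(OperatorCommand("restart", at_s=t1))
    n_manual = int(rng.integers(0, 3))
    if n_manual and n_ticks > n_manual:
        # distinct ticks so each manual reward lands on its own sample
        ticks = rng.choice(n_ticks, size=n_manual, replace=False)
        for t in ticks:
            cmds.append(
                OperatorCommand("manual_reward", at_s=float(t * dt_ms / 1000))
            )
    return cmds
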