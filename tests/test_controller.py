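"""Controller state machine: reward timing, drinking immunity, adaptation,
operator commands, conservation, and equivalence with the replay oracle."""

import pytest
from hypothesis import given
from hypothesis import strategies as hs

import numpy as np

from stilltrain import (
    ConfigError,
    OperatorCommand,
    SessionStateError,
    Status,
    TrainingConfig,
    adapt_criterion,
    init_session,
    replay,
    rewards_to_reach_max,
    tick,
)

from _oracle import (
    random_commands,
    random_config,
    random_moved_stream,
    replay_oracle,
    result_fingerprint,
)


class TestInitAndValidation:
    def test_initial_state(self, cfg):
        state = init_session(cfg)
        assert state.status is Status.START
        assert state.current_criterion_s == 5.0
        assert state.current_still_s == 0.0
        assert state.elapsed_s == 0.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"set_start_s": 0.0},
            {"set_start_s": 10.0, "set_max_s": 5.0},
            {"n_periods": 0},
            {"reward_duration_ms": 0},
            {"timeout_s": -1.0},
            {"bonus_multiplier": 0.5},
        ],
    )
    def test_invalid_configs_rejected_with_field_name(self, bad):
        with pytest.raises(ConfigError) as err:
            TrainingConfig(**bad).validate()
        assert next(iter(bad)) in str(err.value)


class TestAdaptCriterion:
    def test_advances_at_block_boundary(self):
        cfg = TrainingConfig(set_start_s=5, set_max_s=95, n_periods=2, auto_delta_s=5)
        assert adapt_criterion(2, 5.0, cfg) == 10.0

    def test_unchanged_below_trigger(self):
        cfg = TrainingConfig(set_start_s=5, set_max_s=95, n_periods=2, auto_delta_s=5)
        assert adapt_criterion(1, 5.0, cfg) == 5.0

    def test_clamped_to_set_max(self):
        cfg = TrainingConfig(set_start_s=5, set_max_s=95, n_periods=2, auto_delta_s=5)
        assert adapt_criterion(2, 92.0, cfg) == 95.0

    def test_negative_delta_clamped_to_set_start(self):
        cfg = TrainingConfig(set_start_s=5, set_max_s=95, n_periods=1, auto_delta_s=-3)
        assert adapt_criterion(1, 6.0, cfg) == 5.0


class TestRewardTiming:
    def test_first_reward_after_criterion_of_stillness(self, cfg):
        res = replay(cfg, [False] * 60)
        assert res.rewards[0].kind == "normal"
        assert res.rewards[0].onset_s == 5.0
        assert res.records[49].status is Status.REWARD

    def test_movement_resets_still_timer(self, cfg):
        # still 4.9 s, move once, then still: reward 5 s after the movement
        stream = [False] * 49 + [True] + [False] * 60
        res = replay(cfg, stream)
        assert res.rewards[0].onset_s == 10.0
        assert res.state.movement_count == 1
        assert res.records[49].status is Status.SENSED_MOVE

    def test_scripted_stream_matches_oracle(self, rng):
        cfg = TrainingConfig(
            set_start_s=5, set_max_s=20, n_periods=2, auto_delta_s=5,
            bonus_period_s=0,
        )
        stream = random_moved_stream(rng, 6000)  # 10 min at 100 ms
        res = replay(cfg, stream)
        oracle = replay_oracle(cfg, stream)
        got = result_fingerprint(res)
        assert got["rewards"] == oracle["rewards"]
        assert got["final_criterion_ms"] == oracle["final_criterion_ms"]
        assert got["totals"] == oracle["totals"]


class TestDrinkingImmunity:
    def test_motion_during_drinking_is_ignored(self, cfg):
        # reward at tick 50; movement one tick later, inside the 2 s window
        stream = [False] * 50 + [True] + [False] * 60
        res = replay(cfg, stream)
        assert res.state.movement_count == 0
        assert all(r.status is not Status.SENSED_MOVE for r in res.records)
        # second reward arrives exactly as if no motion had been injected
        quiet = replay(cfg, [False] * 111)
        assert [r.onset_s for r in res.rewards] == [r.onset_s for r in quiet.rewards]

    def test_drinking_window_length_in_ticks(self, cfg):
        res = replay(cfg, [False] * 80)
        statuses = [r.status for r in res.records[50:70]]
        assert all(s is Status.DRINKING for s in statuses)
        assert res.records[70].status is Status.STILL

    def test_red_cue_only_on_sensed_move(self, cfg):
        state = init_session(cfg)
        cues = []
        for moved in [False, True, False]:
            cues.append(tick(state, cfg, moved).cue)
        assert [c.red_on for c in cues] == [False, True, False]
        assert cues[0].green_flashing and cues[1].green_flashing


class TestOperatorCommands:
    def test_manual_reward_keeps_still_timer(self, cfg):
        stream = [False] * 40
        cmds = [OperatorCommand("manual_reward", at_s=2.0)]
        res = replay(cfg, stream, cmds)
        assert res.rewards[0].kind == "manual"
        assert res.rewards[0].duration_ms == 500
        manual = [r for r in res.records if r.status is Status.MANUAL]
        assert len(manual) == 1 and manual[0].juice_on_ms == 500

    def test_pause_freezes_training_timers(self, cfg):
        stream = [False] * 200
        cmds = [OperatorCommand("pause", at_s=2.0), OperatorCommand("restart", at_s=12.0)]
        res = replay(cfg, stream, cmds)
        assert res.state.paused_ms == 10_000
        # summary duration excludes the frozen period
        assert res.summary.duration_s == 10.0
        # the reward still needs 5 s of stillness, paid across the pause
        assert res.rewards[0].onset_s == pytest.approx(15.0)

    def test_restart_when_not_paused_warns(self, cfg):
        res = replay(cfg, [False] * 5, [OperatorCommand("restart", at_s=0.2)])
        assert any("not paused" in w for w in res.state.warnings)

    def test_continuous_reward_spans_interval(self, cfg):
        cmds = [
            OperatorCommand("continuous_reward_start", at_s=1.0),
            OperatorCommand("continuous_reward_stop", at_s=4.0),
        ]
        res = replay(cfg, [False] * 45, cmds)
        cont = [r for r in res.rewards if r.kind == "continuous"]
        assert len(cont) == 1 and cont[0].duration_ms == 3000

    def test_save_stop_terminates(self, cfg):
        res = replay(cfg, [False] * 100, [OperatorCommand("save_stop", at_s=3.0)])
        assert res.state.terminal
        # the terminating tick writes its record without advancing the clock
        assert res.state.elapsed_ms == 2900
        assert len(res.records) == 30
        with pytest.raises(SessionStateError):
            tick(res.state, cfg, False)

    def test_mid_session_set_changes_reward_size(self, cfg):
        cmds = [OperatorCommand("set", at_s=2.0, field="reward_duration_ms", value=750)]
        res = replay(cfg, [False] * 60, cmds)
        assert res.rewards[0].duration_ms == 750


class TestBonusRewards:
    def test_cumulative_bonus_survives_movements(self):
        cfg = TrainingConfig(
            set_start_s=50, set_max_s=50, n_periods=1, auto_delta_s=0,
            bonus_period_s=3.0, bonus_multiplier=2.0, timeout_s=2.0,
        )
        # 2 s still, move, 1 s still: cumulative still time reaches 3 s
        stream = [False] * 20 + [True] + [False] * 10
        res = replay(cfg, stream)
        bonus = [r for r in res.rewards if r.kind == "bonus"]
        assert len(bonus) == 1
        assert bonus[0].duration_ms == 1000

    def test_continuous_bonus_resets_on_movement(self):
        cfg = TrainingConfig(
            set_start_s=50, set_max_s=50, n_periods=1, auto_delta_s=0,
            bonus_period_s=3.0, bonus_mode="continuous",
        )
        stream = [False] * 20 + [True] + [False] * 10
        res = replay(cfg, stream)
        assert not [r for r in res.rewards if r.kind == "bonus"]


class TestInvariantsAndOracle:
    def test_conservation_of_time(self, rng):
        for _ in range(20):
            cfg = random_config(rng)
            n = int(rng.integers(50, 2000))
            stream = random_moved_stream(rng, n)
            cmds = random_commands(rng, n, cfg.read_every_ms)
            st = replay(cfg, stream, cmds).state
            assert (
                st.still_ms + st.moving_ms + st.drinking_ms + st.paused_ms
                == st.elapsed_ms
            )

    def test_criterion_stays_within_bounds(self, rng):
        for _ in range(20):
            cfg = random_config(rng)
            if cfg.auto_delta_s < 0:
                continue
            stream = random_moved_stream(rng, 3000)
            res = replay(cfg, stream)
            lo, hi = cfg.set_start_s, cfg.set_max_s
            for rec in res.records:
                assert lo - 1e-9 <= rec.criterion_s <= hi + 1e-9

    def test_current_still_never_exceeds_best(self, cfg, rng):
        state = init_session(cfg)
        for moved in random_moved_stream(rng, 500):
            tick(state, cfg, moved)
            assert state.current_still_ms <= max(state.best_still_ms, 0)

    def test_oracle_equivalence_on_random_streams(self, rng):
        for _ in range(100):
            cfg = random_config(rng)
            n = int(rng.integers(100, 2000))
            stream = random_moved_stream(rng, n)
            cmds = random_commands(rng, n, cfg.read_every_ms)
            res = replay(cfg, stream, cmds)
            oracle = replay_oracle(cfg, stream, cmds)
            got = result_fingerprint(res)
            assert got["rewards"] == oracle["rewards"]
            assert got["final_criterion_ms"] == oracle["final_criterion_ms"]
            assert got["best_ms"] == oracle["best_ms"]
            assert got["totals"] == oracle["totals"]

    @given(hs.integers(0, 2**31 - 1))
    def test_replay_is_deterministic(self, seed):
        r = np.random.default_rng(seed)
        cfg = random_config(r)
        stream = random_moved_stream(r, 300)
        a = replay(cfg, stream)
        b = replay(cfg, stream)
        assert a.records == b.records
        assert a.summary == b.summary


class TestBridgedBestStill:
    def test_long_hold_at_high_criterion_bridges_rewards(self):
        # at a 95 s criterion a subject holding still for ~11.5 min earns
        # several rewards; the longest motionless period bridges the 2 s
        # drinking breaks and exceeds 10 minutes
        cfg = TrainingConfig(
            set_start_s=95.0, set_max_s=95.0, n_periods=1, auto_delta_s=0.0,
            timeout_s=2.0, bonus_period_s=0.0,
        )
        res = replay(cfg, [False] * 7000)
        assert res.summary.n_rewards >= 6
        assert res.summary.longest_still_s > 600.0


class TestSchedule:
    def test_never_moving_subject_walks_the_schedule(self):
        cfg = TrainingConfig(
            set_start_s=5, set_max_s=20, n_periods=1, auto_delta_s=5,
            timeout_s=2, bonus_period_s=0,
        )
        res = replay(cfg, [False] * 1200)
        traj = []
        for rec in res.records:
            if rec.status is Status.REWARD:
                traj.append(rec.criterion_s)
        assert traj[:5] == [10.0, 15.0, 20.0, 20.0, 20.0]
        assert rewards_to_reach_max(cfg) == 3
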