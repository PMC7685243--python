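"""Tensor coding of behavior: pulses, targets, dataset splitting, batching."""

import numpy as np
import pytest

from corticostriatal import behavior_synth, signal_coding, task_env, value_model
from corticostriatal.signal_coding import (CodingConfig, build_dataset,
                                           decode_actions, encode_block,
                                           encode_session, sample_batch)

CFG = CodingConfig.scaled(10)


@pytest.fixture(scope="module")
def session():
    log = behavior_synth.simulate_session(40, value_model.QParams(), rng=5)
    traces = value_model.generate_value_traces(log, value_model.QParams())
    return log, traces


@pytest.fixture(scope="module")
def perfect_block():
    profile = behavior_synth.ErrorProfile(np.ones(8))
    log = behavior_synth.simulate_session(1, profile, rng=1)
    traces = value_model.generate_value_traces(log, value_model.QParams())
    return encode_block(log, traces, CFG), log


class TestCodingConfig:
    def test_reward_pulse_is_fifth_of_action_pulse(self):
        assert CodingConfig(50, 10, 10).reward_pulse_len == 10
        with pytest.raises(ValueError):
            CodingConfig(50, 25, 10)
        assert CodingConfig.scaled(10).reward_pulse_len == 2

    def test_dimensions(self):
        assert signal_coding.N_STRIATAL_IN == 15
        assert signal_coding.N_PREFRONTAL_IN == 20
        assert signal_coding.N_ACTION_OUT == 11


class TestEncodeBlock:
    def test_empty_block_gives_zero_length_tensors(self):
        t = encode_block(task_env.empty_log(),
                         np.zeros((0, 10)), CFG)
        assert t.T == 0 and t.u_s.shape == (0, 15)

    def test_perfect_trial_pulses(self, perfect_block):
        """Each correct decision puts one action pulse and one reward pulse."""
        t, log = perfect_block
        seq = task_env.sequence(t.sequence_id)
        n = len(log)
        acts = t.u_s[:, :10]
        rews = t.u_s[:, 10:]
        # one action pulse per decision, on the executed direction
        assert np.array_equal(decode_actions(t), log["action_id"].to_numpy())
        assert acts.sum() == n * CFG.action_pulse_len
        # rewards per trial = rewarded decisions of the trial (3 for perfect)
        assert rews.sum() == n * CFG.reward_pulse_len
        for stage, direction in enumerate(seq.moves):
            assert acts[:, direction].sum() == 8 * CFG.action_pulse_len

    def test_reward_pulse_begins_where_action_pulse_ends(self, perfect_block):
        t, _ = perfect_block
        L, P, R = CFG.window_len, CFG.action_pulse_len, CFG.reward_pulse_len
        for j in range(1, t.n_windows):
            win = t.u_s[j * L:(j + 1) * L]
            assert win[:P, :10].any() and not win[P:, :10].any()
            assert win[P:P + R, 10:].any() and not win[:P, 10:].any()
            assert not win[P + R:, 10:].any()

    def test_error_decision_has_no_reward_pulse(self, session):
        log, traces = session
        blocks = encode_session(log, traces, CFG)
        b = next(b for b in blocks if not b.decisions["correct"].all())
        L, P, R = CFG.window_len, CFG.action_pulse_len, CFG.reward_pulse_len
        rewarded = b.decisions["reward"].to_numpy(dtype=bool)
        for j, r in enumerate(rewarded):
            win = b.u_s[(j + 1) * L:(j + 2) * L]
            assert win[:P, :10].any()  # the action pulse is always present
            assert win[P:P + R, 10:].any() == r

    def test_value_target_steps_after_reward(self, perfect_block):
        t, log = perfect_block
        L, P, R = CFG.window_len, CFG.action_pulse_len, CFG.reward_pulse_len
        a0 = int(log["action_id"].iloc[0])
        # before the first feedback window the target is flat at the carry-in
        assert np.allclose(t.y_v[:L + P + R, a0], t.y_v[0, a0])
        jump = t.y_v[L + P + R, a0] - t.y_v[L + P + R - 1, a0]
        assert jump > 0  # rewarded: value steps up right after the reward

    def test_hemifield_unit_constant(self, session):
        log, traces = session
        for b in encode_session(log, traces, CFG):
            expected = 1.0 if b.sequence_id in task_env.UPPER_SEQUENCE_IDS else -1.0
            assert np.all(b.y_a[:, 10] == expected)

    def test_choice_targets_match_executed_actions(self, session):
        log, traces = session
        b = encode_session(log, traces, CFG)[0]
        L, CP = CFG.window_len, CFG.choice_offset
        for j, a in enumerate(b.decisions["action_id"]):
            seg = b.y_a[j * L + CP:(j + 1) * L, :10]
            assert np.array_equal(np.unique(np.nonzero(seg)[1]), [a])

    def test_instructions_never_reveal_the_updown_answer(self, session):
        """At the up/down stage both candidate decision points are cued."""
        log, traces = session
        b = encode_session(log, traces, CFG)[0]
        L, CP = CFG.window_len, CFG.choice_offset
        stages = b.decisions["stage"].to_numpy()
        up, down = 1, 2
        for j, s in enumerate(stages):
            mh = b.u_ins[j * L + CP:(j + 1) * L, 1::2]
            active = set(np.unique(np.nonzero(mh)[1]))
            if s == 1:
                assert active == {up, down}
            else:
                assert len(active) == 1

    def test_bad_action_id_rejected(self):
        log = behavior_synth.simulate_session(
            1, behavior_synth.ErrorProfile(np.ones(8)), rng=0)
        log.loc[0, "action_id"] = 99
        with pytest.raises(ValueError):
            encode_block(log, np.zeros((len(log), 10)), CFG)


class TestDatasetOps:
    def test_split_sizes_and_disjointness(self, session):
        log, traces = session
        train, test = build_dataset(log, traces, CFG, test_blocks=10, rng=0)
        assert len(train) == 30 and len(test) == 10
        assert not ({b.block_id for b in train} & {b.block_id for b in test})

    def test_augmentation_grows_train_only(self, session):
        log, traces = session
        aug_log = behavior_synth.simulate_session(
            5, value_model.QParams(), rng=99)
        aug_tr = value_model.generate_value_traces(aug_log, value_model.QParams())
        tr0, te0 = build_dataset(log, traces, CFG, test_blocks=10, rng=0)
        tr1, te1 = build_dataset(log, traces, CFG, test_blocks=10, rng=0,
                                 augment=(aug_log, aug_tr))
        assert len(tr1) == len(tr0) + 5 and len(te1) == len(te0)

    def test_split_deterministic_under_seed(self, session):
        log, traces = session
        _, te1 = build_dataset(log, traces, CFG, test_blocks=10, rng=4)
        _, te2 = build_dataset(log, traces, CFG, test_blocks=10, rng=4)
        assert [b.block_id for b in te1] == [b.block_id for b in te2]

    def test_too_few_blocks_rejected(self, session):
        log, traces = session
        with pytest.raises(ValueError):
            build_dataset(log, traces, CFG, test_blocks=40)

    def test_sample_batch_uniform_with_replacement(self, session):
        log, traces = session
        train, _ = build_dataset(log, traces, CFG, test_blocks=10, rng=0)
        rng = np.random.default_rng(0)
        assert len(sample_batch(train, 10, rng)) == 10
        only = [train[0]]
        assert sample_batch(only, 1, rng)[0] is train[0]
        counts = np.zeros(len(train))
        for b in sample_batch(train, 10_000, rng):
            counts[[t.block_id for t in train].index(b.block_id)] += 1
        freqs = counts / counts.sum()
        assert np.abs(freqs - 1 / len(train)).max() < 4 * np.sqrt(
            (1 / len(train)) * (1 - 1 / len(train)) / 10_000)

    def test_hdf5_round_trip(self, session, tmp_path):
        log, traces = session
        train, _ = build_dataset(log, traces, CFG, test_blocks=10, rng=0)
        path = tmp_path / "ds.h5"
        signal_coding.save_dataset(path, train[:3])
        back = signal_coding.load_dataset(path)
        assert len(back) == 3
        for a, b in zip(train[:3], back):
            assert np.array_equal(a.u_s, b.u_s)
            assert np.array_equal(a.y_a, b.y_a)
            assert a.cfg == b.cfg
            assert a.decisions["action_id"].tolist() == \
                b.decisions["action_id"].tolist()
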