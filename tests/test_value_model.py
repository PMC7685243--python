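"""Q-learning updates, softmax choice, decay, traces and likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from corticostriatal import behavior_synth, task_env, value_model
from corticostriatal.task_env import TaskState, sequence
from corticostriatal.value_model import (QParams, choice_probs, decay,
                                         generate_value_traces, new_qtable,
                                         q_update)


class TestQUpdate:
    def test_full_step_update(self):
        state = TaskState(block_sequence=sequence(1))
        q = q_update(new_qtable(), state, sequence(1).moves[0], 1,
                     QParams(alpha=1.0, gamma=0.0))
        assert q[sequence(1).moves[0]] == pytest.approx(1.0)

    def test_fitted_parameter_update_from_zero(self):
        # alpha*(r + gamma*max(0) - 0) = 0.81 with the fitted parameters
        state = TaskState(block_sequence=sequence(1))
        a = sequence(1).moves[0]
        q = q_update(new_qtable(), state, a, 1, QParams())
        assert q[a] == pytest.approx(0.81)
        assert np.count_nonzero(q) == 1

    def test_zero_learning_rate_changes_nothing(self):
        state = TaskState(block_sequence=sequence(2))
        q0 = np.arange(10.0) / 10
        with pytest.raises(ValueError):
            QParams(alpha=0.0).validate()
        q = q_update(q0, state, 0, 1, QParams(alpha=1e-12))
        assert np.allclose(q, q0, atol=1e-10)

    def test_bootstrap_uses_next_stage_options(self):
        # center choice bootstraps on the stage-1 branch values
        seq = sequence(5)  # center-R -> right-up
        q0 = new_qtable()
        q0[4] = 0.5  # right-up has value
        state = TaskState(block_sequence=seq)
        params = QParams(alpha=1.0, gamma=0.5)
        q = q_update(q0, state, 1, 1, params)
        assert q[1] == pytest.approx(1 + 0.5 * 0.5)

    def test_invalid_params_rejected(self):
        state = TaskState(block_sequence=sequence(1))
        for bad in (QParams(alpha=1.5), QParams(gamma=1.0),
                    QParams(beta=-1), QParams(tau_q=0.0)):
            with pytest.raises(ValueError):
                q_update(new_qtable(), state, 0, 1, bad)


class TestDecay:
    def test_single_and_iterated_decay(self):
        params = QParams()
        q = np.ones(10)
        assert decay(q, params)[0] == pytest.approx(0.95)
        qn = q.copy()
        for _ in range(10):
            qn = decay(qn, params)
        assert np.allclose(qn, 0.95 ** 10)

    def test_unit_decay_is_identity(self):
        q = np.linspace(0, 1, 10)
        assert np.array_equal(decay(q, QParams(tau_q=1.0)), q)


class TestChoiceProbs:
    def test_symmetry_and_normalization(self):
        p = choice_probs(new_qtable(), {0, 1}, QParams())
        assert p[0] == pytest.approx(0.5) and p[1] == pytest.approx(0.5)

    def test_fitted_beta_scalar_evaluation(self):
        q = new_qtable()
        q[0] = 0.81
        p = choice_probs(q, {0, 1}, QParams(beta=3.05))
        # logistic of 3.05 * 0.81 = 2.4705
        assert p[0] == pytest.approx(1 / (1 + np.exp(-2.4705)), abs=1e-12)
        assert p[0] == pytest.approx(0.922, abs=1e-3)

    def test_beta_to_zero_limit_is_uniform(self):
        q = np.arange(10.0)
        p = choice_probs(q, {2, 5, 9}, QParams(beta=1e-9))
        assert all(abs(v - 1 / 3) < 1e-6 for v in p.values())

    def test_invariance_to_constant_shift(self):
        q = np.arange(10.0) / 5
        p1 = choice_probs(q, {1, 4, 7}, QParams())
        p2 = choice_probs(q + 3.7, {1, 4, 7}, QParams())
        for a in p1:
            assert p1[a] == pytest.approx(p2[a], rel=1e-9)

    def test_empty_available_set_errors(self):
        with pytest.raises(ValueError):
            choice_probs(new_qtable(), set(), QParams())


class TestValueTraces:
    def test_empty_log_gives_empty_trace(self):
        traces = generate_value_traces(task_env.empty_log(), QParams())
        assert traces.shape == (0, 10)

    def test_values_grow_over_rewarded_repetitions(self):
        """Perfect block: each correct direction's value rises across trials."""
        profile = behavior_synth.ErrorProfile(np.ones(8))
        log = behavior_synth.simulate_session(1, profile, rng=0)
        traces = generate_value_traces(log, QParams())
        seq = sequence(int(log["sequence_id"].iloc[0]))
        for stage, direction in enumerate(seq.moves):
            vals = traces[log["stage"] == stage][:, direction]
            assert np.all(np.diff(vals[:4]) > 0)

    def test_unrewarded_action_decays_toward_zero(self, qagent_log):
        traces = generate_value_traces(qagent_log, QParams())
        errs = np.flatnonzero(~qagent_log["correct"].to_numpy(dtype=bool))
        k = errs[10]
        a = int(qagent_log["action_id"].iloc[k])
        assert traces[k, a] <= traces[k - 1, a] + 1e-12

    def test_replay_is_deterministic(self, qagent_log):
        sub = qagent_log[qagent_log["block_id"] < 20]
        t1 = generate_value_traces(sub, QParams())
        t2 = generate_value_traces(sub, QParams())
        assert np.array_equal(t1, t2)

    def test_values_bounded_by_discounted_reward_sum(self, qagent_log):
        params = QParams()
        traces = generate_value_traces(qagent_log, params)
        assert traces.min() >= 0.0
        assert traces.max() <= 1 / (1 - params.gamma) + 1e-9

    def test_traces_hdf5_round_trip(self, qagent_log, tmp_path):
        sub = qagent_log[qagent_log["block_id"] < 5]
        traces = generate_value_traces(sub, QParams())
        path = tmp_path / "traces.h5"
        value_model.save_traces(path, traces, tau_q=0.95)
        assert np.array_equal(value_model.load_traces(path), traces)

    def test_inconsistent_log_rejected(self, qagent_log):
        bad = qagent_log.copy().reset_index(drop=True)
        bad.loc[3, "stage"] = (bad.loc[3, "stage"] + 1) % 3
        with pytest.raises(ValueError):
            generate_value_traces(bad, QParams())


class TestLikelihoodAndFit:
    def test_log_likelihood_matches_direct_computation(self):
        """Compiled replay agrees with an explicit softmax/update replay."""
        log = behavior_synth.simulate_session(10, QParams(), rng=42)
        params = QParams(alpha=0.6, gamma=0.3, beta=2.0, tau_q=0.9)
        q = new_qtable()
        state, prev_block, ll = None, None, 0.0
        for row in log.itertuples(index=False):
            if row.block_id != prev_block:
                state = TaskState(block_sequence=sequence(int(row.sequence_id)))
                prev_block = row.block_id
            avail = sorted(task_env.available_actions(state))
            z = params.beta * q[avail]
            ll += z[avail.index(int(row.action_id))] - logsumexp(z)
            q = decay(q_update(q, state, int(row.action_id), int(row.reward),
                               params, correct=bool(row.correct)), params)
            state, _ = task_env.step(state, int(row.action_id))
        assert value_model.log_likelihood(log, params) == pytest.approx(ll)

    def test_fit_rejects_short_logs(self):
        with pytest.raises(ValueError):
            value_model.fit_params(task_env.empty_log())

    def test_fitted_params_locally_optimal(self, qagent_log):
        """The simplex optimum beats 100 random perturbations around it."""
        sub = qagent_log[qagent_log["block_id"] < 60]
        fitted, nll0, _ = value_model.fit_params(sub, init=QParams(),
                                                 n_restarts=1, seed=3)
        rng = np.random.default_rng(1)
        for _ in range(100):
            pert = QParams(
                alpha=float(np.clip(fitted.alpha + rng.normal(0, 0.1), 0.05, 1.0)),
                gamma=float(np.clip(fitted.gamma + rng.normal(0, 0.1), 0.0, 0.9)),
                beta=float(np.clip(fitted.beta + rng.normal(0, 0.5), 0.1, 20)),
                tau_q=fitted.tau_q)
            assert -value_model.log_likelihood(sub, pert) >= nll0 - 1e-4

    def test_parameter_recovery_small(self):
        """alpha/beta recovered from a 120-block log (coarse bound)."""
        true = QParams(alpha=0.8, gamma=0.2, beta=3.0, tau_q=0.95)
        log = behavior_synth.simulate_session(120, true, rng=9)
        fitted, nll, _ = value_model.fit_params(log, init=QParams(),
                                                n_restarts=2, seed=0)
        assert abs(fitted.alpha - true.alpha) < 0.2
        assert abs(fitted.beta - true.beta) < 0.8
        assert nll <= -value_model.log_likelihood(log, true) + 1e-6
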