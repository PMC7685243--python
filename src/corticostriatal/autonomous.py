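"""Closed-loop (autonomous) execution of the trained system.

After training all weights stay frozen and the system performs whole
blocks on its own: for each decision the striatal network receives the
previously executed action pulse and its reward pulse (white noise on the
action channels at block start, and on the reward channels after errors),
its value readout drives the prefrontal network together with the current
stage's instruction channels, and the next action is decoded
probabilistically — a softmax over the time-averaged prefrontal action
outputs restricted to the currently available options.  Wrong actions are
unrewarded and force a repeat of the stage, exactly as in the task; the
block ends after eight error-free trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior_synth, task_env
from .rnn_model import NetworkParams, NetworkState, initial_state, rollout
from .signal_coding import (CodingConfig, N_DIRECTIONS, N_STRIATAL_IN,
                            N_INSTRUCTION, _visible_points)
from .task_env import DECISION_POINTS, TaskState
from .value_model import FITTED_BETA

#: default decoding temperature: the decoder reuses the sharpness of the
#: fitted behavioral softmax (inverse temperature beta = 3.050), so a
#: perfectly trained network with unit-amplitude choice pulses selects the
#: correct option with roughly the animals' asymptotic (~90%) accuracy.
DECODE_TEMPERATURE = 1.0 / FITTED_BETA


def decode_action(
    u_a: np.ndarray,
    available: set[int] | list[int],
    rng: np.random.Generator,
    temperature: float = DECODE_TEMPERATURE,
) -> int:
    """Sample an action from softmax of the output vector over available options."""
    avail = sorted(available)
    if not avail:
        raise ValueError("empty set of available actions")
    z = np.asarray(u_a, float)[avail] / temperature
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(avail, p=p))


@dataclass
class BlockResult:
    """Traces and decisions of one autonomously executed block."""

    log: pd.DataFrame
    u_v: np.ndarray            # (T, 10) striatal value readout
    u_a: np.ndarray            # (T, 11) prefrontal action readout
    sequence_id: int
    cfg: CodingConfig
    u_s_in: np.ndarray | None = field(default=None, repr=False)   # (T, 15)
    u_ins_in: np.ndarray | None = field(default=None, repr=False)  # (T, 10)
    X_s: np.ndarray | None = field(default=None, repr=False)
    X_p: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_decisions(self) -> int:
        return len(self.log)

    def value_trace(self) -> np.ndarray:
        """(n_decisions, 10) mean value readout over each post-reward segment."""
        L, CP = self.cfg.window_len, self.cfg.choice_offset
        rows = []
        for j in range(1, self.n_decisions + 1):
            rows.append(self.u_v[j * L + CP - self.cfg.inter_event_gap:
                                 (j + 1) * L - self.cfg.action_pulse_len].mean(axis=0))
        return np.array(rows)


def _window_inputs(
    cfg: CodingConfig,
    prev: tuple[int, int, str] | None,   # (action, reward, decision_point)
    stage_info: tuple[task_env.SequenceSpec, int] | None,
    rng: np.random.Generator,
    input_noise_sd: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Striatal and instruction inputs for one window of the closed loop."""
    L, P, R, CP = (cfg.window_len, cfg.action_pulse_len,
                   cfg.reward_pulse_len, cfg.choice_offset)
    u_s = np.zeros((L, N_STRIATAL_IN))
    u_ins = np.zeros((L, N_INSTRUCTION))
    if prev is None:
        # block start: the action vector is reset to white noise
        u_s[:P, :N_DIRECTIONS] = rng.standard_normal((P, N_DIRECTIONS)) * input_noise_sd
    else:
        action, reward, dp = prev
        u_s[:P, action] = 1.0
        if reward:
            u_s[P:P + R, N_DIRECTIONS + DECISION_POINTS.index(dp)] = 1.0
        else:
            # unrewarded: the reward vector is set to white noise
            u_s[P:P + R, N_DIRECTIONS:] = (
                rng.standard_normal((R, len(DECISION_POINTS))) * input_noise_sd)
    if stage_info is not None:
        seq, stage = stage_info
        for p in _visible_points(seq, stage):
            u_ins[CP:L, 2 * p + 1] = 1.0
            u_ins[:CP, 2 * p] = 1.0
    return u_s, u_ins


def run_block(
    params: NetworkParams,
    cfg: CodingConfig,
    rng: np.random.Generator,
    state: NetworkState | None = None,
    prev_seq: task_env.SequenceSpec | None = None,
    forced_sequence: int | None = None,
    exclude_prev: bool = False,
    temperature: float = DECODE_TEMPERATURE,
    max_repeats: int = 50,
    dyn_noise: bool = True,
    record_states: bool = False,
    block_id: int = 0,
    dt: float | None = None,
) -> tuple[BlockResult, NetworkState]:
    """Run one closed-loop block; returns the result and the carried state.

    ``forced_sequence`` pins the block's correct sequence (useful for
    building balanced analysis datasets); otherwise it is drawn as in the
    task.  ``dyn_noise`` toggles the networks' white state noise.
    """
    dt = cfg.dt if dt is None else dt
    if state is None:
        state = initial_state(params)
    if forced_sequence is not None:
        env = TaskState(block_sequence=task_env.sequence(forced_sequence))
    else:
        env = task_env.new_block(rng, prev=prev_seq, exclude_prev=exclude_prev)
    seq = env.block_sequence
    noise_rng = rng if dyn_noise else None

    L, CP = cfg.window_len, cfg.choice_offset
    rows, u_v_all, u_a_all, xs_all, xp_all = [], [], [], [], []
    us_all, uins_all = [], []
    prev = None
    done = False
    while not done:
        stage_info = (seq, env.stage)
        u_s, u_ins = _window_inputs(cfg, prev, stage_info, rng)
        us_all.append(u_s)
        uins_all.append(u_ins)
        out = rollout(params, u_s, u_ins, state=state, rng=noise_rng,
                      dt=dt, record_states=record_states)
        if record_states:
            u_v, u_a, state, X_s, X_p = out
            xs_all.append(X_s)
            xp_all.append(X_p)
        else:
            u_v, u_a, state = out
        u_v_all.append(u_v)
        u_a_all.append(u_a)
        avail = task_env.available_actions(env)
        logits = u_a[CP:, :N_DIRECTIONS].mean(axis=0)
        action = decode_action(logits, avail, rng, temperature=temperature)
        repeat_flag, trial_index, stage = env.pending_repeat, env.trial_index, env.stage
        env, outcome = task_env.step(env, action, max_repeats=max_repeats)
        rows.append((block_id, trial_index, stage, seq.id, action,
                     outcome.reward, outcome.correct, repeat_flag))
        prev = (action, outcome.reward, outcome.decision_point)
        done = outcome.block_done
    # terminal window: deliver the last decision's feedback
    u_s, u_ins = _window_inputs(cfg, prev, None, rng)
    us_all.append(u_s)
    uins_all.append(u_ins)
    out = rollout(params, u_s, u_ins, state=state, rng=noise_rng,
                  dt=dt, record_states=record_states)
    if record_states:
        u_v, u_a, state, X_s, X_p = out
        xs_all.append(X_s)
        xp_all.append(X_p)
    else:
        u_v, u_a, state = out
    u_v_all.append(u_v)
    u_a_all.append(u_a)

    log = pd.DataFrame(rows, columns=list(task_env.LOG_COLUMNS))
    result = BlockResult(
        log=log, u_v=np.concatenate(u_v_all), u_a=np.concatenate(u_a_all),
        sequence_id=seq.id, cfg=cfg,
        u_s_in=np.concatenate(us_all), u_ins_in=np.concatenate(uins_all),
        X_s=np.concatenate(xs_all) if record_states else None,
        X_p=np.concatenate(xp_all) if record_states else None)
    return result, state


def run_session(
    params: NetworkParams,
    cfg: CodingConfig,
    n_blocks: int,
    rng: np.random.Generator | int | None = None,
    forced_sequences: list[int] | None = None,
    record_states: bool = False,
    **block_kw,
) -> list[BlockResult]:
    """Run several closed-loop blocks, carrying network state across blocks.

    ``forced_sequences`` balances the session over the listed sequences:
    the list is replayed as a freshly shuffled deck each cycle, so every
    sequence appears equally often while its predecessor varies (a fixed
    cyclic order would give every block a deterministic predecessor and
    imprint systematic block-start structure on the analyses).
    """
    rng = np.random.default_rng(rng)
    state = initial_state(params)
    results = []
    prev_seq = None
    deck: list[int] = []
    for b in range(n_blocks):
        if forced_sequences:
            if not deck:
                deck = [forced_sequences[i]
                        for i in rng.permutation(len(forced_sequences))]
            forced = deck.pop()
        else:
            forced = None
        res, state = run_block(params, cfg, rng, state=state, prev_seq=prev_seq,
                               forced_sequence=forced, record_states=record_states,
                               block_id=b, **block_kw)
        prev_seq = task_env.sequence(res.sequence_id)
        results.append(res)
    return results


def session_log(results: list[BlockResult]) -> pd.DataFrame:
    return pd.concat([r.log for r in results], ignore_index=True)


def behavioral_curve(results: list[BlockResult]) -> pd.DataFrame:
    """Fraction of first-attempt-correct decisions vs trial-in-block."""
    if len(results) < 10:
        raise ValueError("need at least 10 blocks for a behavioral curve")
    _, curve = behavior_synth.error_profile(session_log(results))
    return curve
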