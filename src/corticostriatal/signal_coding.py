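"""Conversion of behavior logs and value traces into network tensors.

Each attempted decision occupies one *window* on the network timeline.
Window j is laid out so that all feedback about decision j-1 arrives
before the choice pulse for decision j:

    [0, P)            action pulse of the previous decision (striatal input)
    [P, P+R)          its reward pulse (striatal input; reward pulses begin
                      at the end of their action pulse and are absent for
                      unrewarded decisions)
    [P+R, P+R+G)      gap
    [P+R+G, L)        choice segment: the prefrontal target pulses the
                      action of decision j (L = 2P + R + G)

The striatal value target is a step function that jumps to the post-update
Q table at the end of each reward pulse, so values rise right after reward
delivery and the target never anticipates unseen feedback.  A final
terminal window carries the last decision's feedback with a silent choice
segment.  The 10 instruction channels pair a Fixate and a Move+Hold unit
for each of the five decision points: the Move+Hold units of the visible
targets are active during the choice segment, the matching Fixate units
during the preceding fixation.  The hemifield unit of the prefrontal
target is +1/-1 throughout a block for upper/lower terminating sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import task_env
from .task_env import DECISION_POINTS, N_DIRECTIONS, N_DECISION_POINTS

N_STRIATAL_IN = N_DIRECTIONS + N_DECISION_POINTS  # 15
N_INSTRUCTION = 2 * N_DECISION_POINTS             # 10
N_PREFRONTAL_IN = N_DIRECTIONS + N_INSTRUCTION    # 20
N_VALUE_OUT = N_DIRECTIONS                        # 10
N_ACTION_OUT = N_DIRECTIONS + 1                   # 11 (10 actions + hemifield)


@dataclass(frozen=True)
class CodingConfig:
    """Pulse geometry of the task coding.

    ``dt`` is the integration step in ms (1 ms by default, so with the
    10 ms neural time constant the Euler factor is 0.1).  The reward pulse
    is 2/10 as long as the action pulse.
    """

    action_pulse_len: int = 50
    reward_pulse_len: int = 10
    inter_event_gap: int = 10
    dt: float = 1.0

    def __post_init__(self):
        if min(self.action_pulse_len, self.reward_pulse_len,
               self.inter_event_gap) < 1:
            raise ValueError("pulse lengths and gap must be >= 1")
        if self.reward_pulse_len != round(0.2 * self.action_pulse_len):
            raise ValueError("reward pulse must be 2/10 of the action pulse")

    @property
    def window_len(self) -> int:
        return 2 * self.action_pulse_len + self.reward_pulse_len + self.inter_event_gap

    @property
    def choice_offset(self) -> int:
        """Start of the choice segment within a window."""
        return self.action_pulse_len + self.reward_pulse_len + self.inter_event_gap

    @classmethod
    def scaled(cls, action_pulse_len: int = 10, dt: float = 1.0) -> "CodingConfig":
        """A shorter pulse geometry for small, fast simulations."""
        return cls(action_pulse_len=action_pulse_len,
                   reward_pulse_len=round(0.2 * action_pulse_len),
                   inter_event_gap=max(round(0.2 * action_pulse_len), 1),
                   dt=dt)


def _visible_points(seq: task_env.SequenceSpec, stage: int) -> list[int]:
    """Decision-point channels whose targets are on display at a stage.

    Never reveals the correct choice: at the up/down stage both candidate
    points are shown; the final stage's hemifield is fixed by the branch
    already reached.
    """
    if stage == 0:
        return [DECISION_POINTS.index("center")]
    if stage == 1:
        return [DECISION_POINTS.index("upwards"), DECISION_POINTS.index("downwards")]
    return [DECISION_POINTS.index(seq.hemifield)]


@dataclass
class TrialTensors:
    """Time-resolved inputs and targets for one block."""

    u_s: np.ndarray    # (T, 15) striatal input: 10 action + 5 reward channels
    u_ins: np.ndarray  # (T, 10) prefrontal instruction channels
    y_v: np.ndarray    # (T, 10) striatal value target
    y_a: np.ndarray    # (T, 11) prefrontal target: 10 actions + hemifield unit
    block_id: int
    sequence_id: int
    cfg: CodingConfig
    decisions: pd.DataFrame = field(repr=False)

    @property
    def T(self) -> int:
        return self.u_s.shape[0]

    @property
    def n_windows(self) -> int:
        return self.T // self.cfg.window_len

    @property
    def u_p(self) -> np.ndarray:
        """(T, 20) teacher-forced prefrontal input [value target, instructions]."""
        return np.concatenate([self.y_v, self.u_ins], axis=1)


def encode_block(
    block_log: pd.DataFrame,
    value_traces: np.ndarray,
    cfg: CodingConfig,
    q_prev: np.ndarray | None = None,
) -> TrialTensors:
    """Encode one block of decisions into network tensors.

    ``value_traces`` holds the post-update Q table per decision of the
    block (rows aligned with ``block_log``); ``q_prev`` is the table
    carried in from before the block (zeros by default).
    """
    M = len(block_log)
    actions = block_log["action_id"].to_numpy(dtype=int)
    rewards = block_log["reward"].to_numpy(dtype=int)
    stages = block_log["stage"].to_numpy(dtype=int)
    if np.any(actions < 0) or np.any(actions >= N_DIRECTIONS):
        raise ValueError("action id outside the 10-direction vocabulary")
    if value_traces.shape != (M, N_DIRECTIONS):
        raise ValueError("value traces not aligned with the block log")
    seq = task_env.sequence(int(block_log["sequence_id"].iloc[0])) if M else None

    L, P, R = cfg.window_len, cfg.action_pulse_len, cfg.reward_pulse_len
    CP = cfg.choice_offset
    n_win = M + 1 if M else 0
    T = n_win * L
    u_s = np.zeros((T, N_STRIATAL_IN))
    u_ins = np.zeros((T, N_INSTRUCTION))
    y_v = np.zeros((T, N_VALUE_OUT))
    y_a = np.zeros((T, N_ACTION_OUT))

    q = np.zeros(N_DIRECTIONS) if q_prev is None else np.asarray(q_prev, float)
    for j in range(n_win):
        b = j * L
        # feedback segment: previous decision's action and reward
        if j > 0:
            d = j - 1
            u_s[b:b + P, actions[d]] = 1.0
            if rewards[d]:
                dp = task_env.decision_point(seq, int(stages[d]))
                u_s[b + P:b + P + R, N_DIRECTIONS + DECISION_POINTS.index(dp)] = 1.0
        # value target: step to the updated table at the end of the reward pulse
        y_v[b:b + P + R] = q
        if j > 0:
            q = value_traces[j - 1]
        y_v[b + P + R:b + L] = q
        # choice segment and instructions for decision j
        if j < M:
            y_a[b + CP:b + L, actions[j]] = 1.0
            for p in _visible_points(seq, int(stages[j])):
                u_ins[b + CP:b + L, 2 * p + 1] = 1.0       # Move + Hold
                u_ins[b:b + CP, 2 * p] = 1.0               # Fixate
        if seq is not None:
            y_a[b:b + L, N_DIRECTIONS] = 1.0 if seq.hemifield == "upper" else -1.0

    return TrialTensors(u_s=u_s, u_ins=u_ins, y_v=y_v, y_a=y_a,
                        block_id=int(block_log["block_id"].iloc[0]) if M else -1,
                        sequence_id=seq.id if seq else -1,
                        cfg=cfg, decisions=block_log.reset_index(drop=True))


def decode_actions(tensors: TrialTensors) -> np.ndarray:
    """Recover the executed action sequence from the striatal input pulses."""
    L, P = tensors.cfg.window_len, tensors.cfg.action_pulse_len
    out = []
    for j in range(1, tensors.n_windows):
        seg = tensors.u_s[j * L:j * L + P, :N_DIRECTIONS]
        out.append(int(np.argmax(seg.sum(axis=0))))
    return np.array(out, dtype=int)


def encode_session(
    log: pd.DataFrame, value_traces: np.ndarray, cfg: CodingConfig
) -> list[TrialTensors]:
    """Encode every block of a session, carrying the value table across blocks."""
    blocks = []
    q_prev = np.zeros(N_DIRECTIONS)
    for _, block in log.groupby("block_id", sort=True):
        tr = value_traces[block.index.to_numpy()]
        blocks.append(encode_block(block, tr, cfg, q_prev=q_prev))
        q_prev = tr[-1]
    return blocks


def build_dataset(
    log: pd.DataFrame,
    value_traces: np.ndarray,
    cfg: CodingConfig,
    test_blocks: int = 25,
    augment: tuple[pd.DataFrame, np.ndarray] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TrialTensors], list[TrialTensors]]:
    """Split a session into train/test block tensors at block granularity.

    ``test_blocks`` blocks are held out (sampled without replacement);
    augmentation blocks, if given, are appended to the training set only.
    """
    blocks = encode_session(log, value_traces, cfg)
    if len(blocks) < test_blocks + 1:
        raise ValueError(f"need more than {test_blocks} blocks, got {len(blocks)}")
    rng = np.random.default_rng(rng)
    test_idx = set(rng.choice(len(blocks), size=test_blocks, replace=False).tolist())
    train = [b for i, b in enumerate(blocks) if i not in test_idx]
    test = [b for i, b in enumerate(blocks) if i in test_idx]
    if augment is not None:
        train.extend(encode_session(augment[0], augment[1], cfg))
    return train, test


def sample_batch(
    train: list[TrialTensors], k: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[TrialTensors]:
    """Sample k blocks uniformly with replacement from the training set."""
    if not train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(rng)
    return [train[int(i)] for i in rng.integers(len(train), size=k)]


# ---------------------------------------------------------------------------
# HDF5 storage

_ARRAYS = ("u_s", "u_ins", "y_v", "y_a")
_DEC_COLS = list(task_env.LOG_COLUMNS)


def save_dataset(path, blocks: list[TrialTensors]) -> None:
    with h5py.File(path, "w") as fh:
        for i, b in enumerate(blocks):
            g = fh.create_group(f"block{i:04d}")
            for name in _ARRAYS:
                g.create_dataset(name, data=getattr(b, name))
            g.create_dataset("decisions",
                             data=b.decisions[_DEC_COLS].to_numpy(dtype=np.int64))
            g.attrs.update(block_id=b.block_id, sequence_id=b.sequence_id,
                           action_pulse_len=b.cfg.action_pulse_len,
                           reward_pulse_len=b.cfg.reward_pulse_len,
                           inter_event_gap=b.cfg.inter_event_gap, dt=b.cfg.dt)


def load_dataset(path) -> list[TrialTensors]:
    blocks = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            cfg = CodingConfig(int(g.attrs["action_pulse_len"]),
                               int(g.attrs["reward_pulse_len"]),
                               int(g.attrs["inter_event_gap"]),
                               float(g.attrs["dt"]))
            dec = pd.DataFrame(g["decisions"][()], columns=_DEC_COLS)
            blocks.append(TrialTensors(
                *(g[name][()] for name in _ARRAYS),
                block_id=int(g.attrs["block_id"]),
                sequence_id=int(g.attrs["sequence_id"]),
                cfg=cfg, decisions=dec))
    return blocks
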