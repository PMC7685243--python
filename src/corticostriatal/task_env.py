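"""Deterministic state machine for the oculomotor sequence task.

The task is a chain of three binary saccade decisions.  From central
fixation the subject chooses left or right, then (from the reached lateral
position) up or down, then (within the reached visual hemifield) a final
left or right target.  Eight movement sequences S1-S8 exhaust the 2x2x2
branch structure; four terminate in the upper visual hemifield (S1, S2,
S5, S6) and four in the lower (S3, S4, S7, S8).

One *trial* is a complete traversal of the three decision stages.  A wrong
choice at any stage is unrewarded and forces a repeat of that stage, so a
trial always ends with three correct decisions.  A *block* keeps one
sequence fixed until eight trials have been executed without any error,
after which the sequence switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

# Canonical ordering of the 10 movement directions; every 10-D action or
# value vector in the package is indexed this way.
DIRECTIONS = (
    "center-L", "center-R",
    "left-up", "left-down", "right-up", "right-down",
    "upper-L", "upper-R", "lower-L", "lower-R",
)
N_DIRECTIONS = len(DIRECTIONS)

# The five reward-delivery / decision points, in canonical order: the 5-D
# reward vector is indexed this way.
DECISION_POINTS = ("center", "upwards", "downwards", "upper", "lower")
N_DECISION_POINTS = len(DECISION_POINTS)

N_SEQUENCES = 8
N_STAGES = 3
TRIALS_PER_BLOCK = 8  # error-free trials needed to finish a block

#: columns of a behavior log (one row per attempted decision)
LOG_COLUMNS = (
    "block_id", "trial_index", "stage", "sequence_id",
    "action_id", "reward", "correct", "repeat_flag",
)

_UP_MOVES = frozenset({2, 4})      # left-up, right-up
_UPPER_TARGETS = (6, 7)            # upper-L, upper-R
_LOWER_TARGETS = (8, 9)            # lower-L, lower-R


@dataclass(frozen=True)
class SequenceSpec:
    """One of the eight movement sequences: an ordered triple of directions."""

    id: int
    moves: tuple[int, int, int]
    hemifield: str  # "upper" or "lower"

    def __post_init__(self):
        if len(self.moves) != N_STAGES:
            raise ValueError("a sequence has exactly three moves")
        if self.hemifield not in ("upper", "lower"):
            raise ValueError(f"unknown hemifield {self.hemifield!r}")


def _load_sequences() -> tuple[SequenceSpec, ...]:
    with resources.files("corticostriatal").joinpath("data/sequences.json").open() as fh:
        table = json.load(fh)
    assert tuple(table["directions"]) == DIRECTIONS
    specs = tuple(
        SequenceSpec(id=e["id"], moves=tuple(e["moves"]), hemifield=e["hemifield"])
        for e in table["sequences"]
    )
    assert len(specs) == N_SEQUENCES
    return specs


SEQUENCES: tuple[SequenceSpec, ...] = _load_sequences()
UPPER_SEQUENCE_IDS = frozenset(s.id for s in SEQUENCES if s.hemifield == "upper")
LOWER_SEQUENCE_IDS = frozenset(s.id for s in SEQUENCES if s.hemifield == "lower")


def sequence(seq_id: int) -> SequenceSpec:
    """Look up a sequence by its 1-based id."""
    if not 1 <= seq_id <= N_SEQUENCES:
        raise ValueError(f"sequence id must be in 1..{N_SEQUENCES}, got {seq_id}")
    return SEQUENCES[seq_id - 1]


@dataclass
class TaskState:
    """Mutable-in-spirit task state; ``step`` returns an updated copy."""

    block_sequence: SequenceSpec
    stage: int = 0
    correct_trials_in_block: int = 0
    pending_repeat: bool = False
    trial_index: int = 1
    trial_had_error: bool = False
    repeat_count: int = 0  # consecutive repeats of the current stage

    def __post_init__(self):
        if not 0 <= self.stage < N_STAGES:
            raise ValueError(f"stage must be 0..{N_STAGES - 1}, got {self.stage}")


@dataclass(frozen=True)
class StepOutcome:
    reward: int
    correct: bool
    block_done: bool
    decision_point: str


def new_block(
    rng: np.random.Generator,
    prev: SequenceSpec | None = None,
    exclude_prev: bool = False,
) -> TaskState:
    """Start a fresh block with a randomly drawn sequence.

    By default the draw is uniform over all eight sequences, matching the
    chance (50%) first-decision statistics of the task: because the first
    moves split 4/4 between center-L and center-R, a uniform draw makes the
    first decision of a block uncorrelated with any previously learned
    action.  Set ``exclude_prev=True`` to forbid immediate repeats of the
    previous block's sequence.
    """
    candidates = list(SEQUENCES)
    if exclude_prev and prev is not None:
        candidates = [s for s in candidates if s.id != prev.id]
    seq = candidates[int(rng.integers(len(candidates)))]
    return TaskState(block_sequence=seq)


def decision_point(seq: SequenceSpec, stage: int) -> str:
    """The reward-delivery point of the given stage of a sequence."""
    if stage == 0:
        return "center"
    if stage == 1:
        return "upwards" if seq.moves[1] in _UP_MOVES else "downwards"
    if stage == 2:
        return seq.hemifield
    raise ValueError(f"invalid stage {stage}")


def available_actions(state: TaskState) -> set[int]:
    """The two choice targets offered at the current stage.

    Availability depends only on the branch reached by prior correct moves
    (which the forced-repeat rule makes identical to the block sequence's
    prefix), never on the yet-unknown correct choice.
    """
    stage = state.stage
    moves = state.block_sequence.moves
    if stage == 0:
        return {0, 1}
    if stage == 1:
        return {2, 3} if moves[0] == 0 else {4, 5}
    if stage == 2:
        return set(_UPPER_TARGETS) if moves[1] in _UP_MOVES else set(_LOWER_TARGETS)
    raise ValueError(f"invalid stage {stage}")


def step(
    state: TaskState, action: int, max_repeats: int = 50
) -> tuple[TaskState, StepOutcome]:
    """Execute one attempted decision.

    A correct action is rewarded and advances the stage (completing the
    trial after stage 2); a wrong action is unrewarded and the same stage
    is offered again.  The block ends when eight error-free trials have
    accumulated.  ``max_repeats`` bounds consecutive forced repeats of one
    stage to keep pathological policies finite.
    """
    avail = available_actions(state)
    if action not in avail:
        raise ValueError(
            f"action {action} not available at stage {state.stage} "
            f"of sequence S{state.block_sequence.id} (available: {sorted(avail)})"
        )
    seq = state.block_sequence
    correct = action == seq.moves[state.stage]
    dp = decision_point(seq, state.stage)
    if correct:
        if state.stage == N_STAGES - 1:
            # trial complete
            counted = not state.trial_had_error
            n_correct = state.correct_trials_in_block + int(counted)
            done = n_correct >= TRIALS_PER_BLOCK
            new_state = replace(
                state,
                stage=0,
                correct_trials_in_block=n_correct,
                pending_repeat=False,
                trial_index=state.trial_index + 1,
                trial_had_error=False,
                repeat_count=0,
            )
            return new_state, StepOutcome(1, True, done, dp)
        new_state = replace(
            state, stage=state.stage + 1, pending_repeat=False, repeat_count=0
        )
        return new_state, StepOutcome(1, True, False, dp)
    # wrong choice: forced repeat of the same stage
    if state.repeat_count + 1 > max_repeats:
        raise RuntimeError(
            f"exceeded {max_repeats} forced repeats at stage {state.stage}"
        )
    new_state = replace(
        state,
        pending_repeat=True,
        trial_had_error=True,
        repeat_count=state.repeat_count + 1,
    )
    return new_state, StepOutcome(0, False, False, dp)


# ---------------------------------------------------------------------------
# Behavior logs


def empty_log() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=int) for c in LOG_COLUMNS})


def write_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


def read_log(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(log.columns)
    if missing:
        raise ValueError(f"behavior log missing columns: {sorted(missing)}")
    return log


def validate_log(log: pd.DataFrame) -> None:
    """Replay a behavior log through the task rules; raise on any violation."""
    for block_id, block in log.groupby("block_id", sort=True):
        seq_ids = block["sequence_id"].unique()
        if len(seq_ids) != 1:
            raise ValueError(f"block {block_id} mixes sequence ids {seq_ids}")
        state = TaskState(block_sequence=sequence(int(seq_ids[0])))
        done = False
        for row in block.itertuples(index=False):
            if done:
                raise ValueError(f"block {block_id} continues past completion")
            if row.trial_index != state.trial_index or row.stage != state.stage:
                raise ValueError(
                    f"block {block_id}: log position (trial {row.trial_index}, "
                    f"stage {row.stage}) does not match replay "
                    f"(trial {state.trial_index}, stage {state.stage})"
                )
            if bool(row.repeat_flag) != state.pending_repeat:
                raise ValueError(f"block {block_id}: repeat flag mismatch")
            state, out = step(state, int(row.action_id), max_repeats=10**9)
            if int(row.reward) != out.reward or bool(row.correct) != out.correct:
                raise ValueError(f"block {block_id}: outcome mismatch in replay")
            done = out.block_done
        if not done:
            raise ValueError(f"block {block_id} is truncated")
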