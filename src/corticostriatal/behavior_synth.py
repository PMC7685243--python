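"""Synthetic behavior generator emulating the animals' learning statistics.

Real sessions of the sequence task are not publicly deposited, so every
analysis in this package can be driven by synthetic choice logs.  The
default generator is a Q-learning agent (the fitted behavioral model)
playing the task environment: its per-trial error profile reproduces the
animals' learning curve — chance on the first decision of a block, rising
to roughly 90% correct by the fifth trial.  A parametric mode draws
decision correctness directly from a per-trial Bernoulli profile so
analyses can be stress-tested at arbitrary learning rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task_env, value_model
from .task_env import TRIALS_PER_BLOCK, TaskState
from .value_model import QParams

#: the certainty levels used in the latent analyses, with their nominal
#: fraction-correct centers: block start (chance), mid-block, late block.
CERTAINTY_LEVELS = ("50%", "76%", "88-91%")
CERTAINTY_CENTERS = np.array([0.50, 0.76, 0.895])


@dataclass(frozen=True)
class ErrorProfile:
    """Per-trial-in-block probability that a decision is first-attempt correct."""

    p_correct_by_trial: np.ndarray  # length 8
    mode: str = "parametric"  # "q_agent" or "parametric"

    def validate(self) -> "ErrorProfile":
        p = np.asarray(self.p_correct_by_trial, dtype=float)
        if p.shape != (TRIALS_PER_BLOCK,):
            raise ValueError(f"profile must have {TRIALS_PER_BLOCK} entries")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("profile entries must be probabilities")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"p_correct_by_trial": list(map(float, self.p_correct_by_trial)),
                       "mode": self.mode}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ErrorProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["p_correct_by_trial"]), d["mode"]).validate()


def simulate_session(
    n_blocks: int,
    profile_or_params: ErrorProfile | QParams = None,
    rng: np.random.Generator | int | None = None,
    exclude_prev: bool = False,
    max_repeats: int = 50,
) -> pd.DataFrame:
    """Simulate a session of ``n_blocks`` blocks; returns a behavior log.

    With ``QParams`` (the default, at the fitted behavioral parameters) the
    choices come from the softmax Q-learning agent interacting with the
    task, the action-value table carried across blocks.  With an
    ``ErrorProfile`` the first attempt at each decision is correct with the
    profile's per-trial probability, the wrong option being the other
    available action; a forced repeat of a binary choice is always correct
    (the error reveals the alternative).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if profile_or_params is None:
        profile_or_params = QParams()
    rng = np.random.default_rng(rng)

    q_mode = isinstance(profile_or_params, QParams)
    if q_mode:
        params = profile_or_params.validate()
        q = value_model.new_qtable()
    else:
        profile = profile_or_params.validate()
        p_by_trial = np.asarray(profile.p_correct_by_trial, dtype=float)

    rows = []
    prev_seq = None
    for block_id in range(n_blocks):
        state = task_env.new_block(rng, prev=prev_seq, exclude_prev=exclude_prev)
        prev_seq = state.block_sequence
        done = False
        while not done:
            avail = sorted(task_env.available_actions(state))
            correct_action = state.block_sequence.moves[state.stage]
            if q_mode:
                probs = value_model.choice_probs(q, avail, params)
                action = int(rng.choice(avail, p=[probs[a] for a in avail]))
            else:
                if state.pending_repeat:
                    action = correct_action
                else:
                    idx = min(state.trial_index, TRIALS_PER_BLOCK) - 1
                    if rng.random() < p_by_trial[idx]:
                        action = correct_action
                    else:
                        action = next(a for a in avail if a != correct_action)
            repeat_flag = state.pending_repeat
            trial_index, stage = state.trial_index, state.stage
            state, out = task_env.step(state, action, max_repeats=max_repeats)
            if q_mode:
                # replay-state for the update is the pre-step state
                pre = TaskState(block_sequence=prev_seq, stage=stage,
                                trial_index=trial_index,
                                pending_repeat=repeat_flag)
                q = value_model.decay(
                    value_model.q_update(q, pre, action, out.reward, params,
                                         correct=out.correct),
                    params)
            rows.append((block_id, trial_index, stage, prev_seq.id,
                         action, out.reward, out.correct, repeat_flag))
            done = out.block_done
    return pd.DataFrame(rows, columns=list(task_env.LOG_COLUMNS))


def error_profile(
    log: pd.DataFrame, n_trials: int = TRIALS_PER_BLOCK
) -> tuple[ErrorProfile, pd.DataFrame]:
    """Fraction of first-attempt-correct decisions per trial-in-block.

    Pools all blocks; forced-repeat attempts are excluded (the statistic is
    first-attempt accuracy, as in the behavioral learning curve).  Returns
    the profile plus a curve table with normal-approximation binomial CIs.
    """
    if len(log) == 0:
        raise ValueError("empty log")
    first = log[~log["repeat_flag"].astype(bool)]
    recs = []
    for t in range(1, n_trials + 1):
        sel = first[first["trial_index"].clip(upper=n_trials) == t] if t == n_trials \
            else first[first["trial_index"] == t]
        n = len(sel)
        frac = float(sel["correct"].mean()) if n else np.nan
        se = np.sqrt(frac * (1 - frac) / n) if n else np.nan
        recs.append((t, n, frac, max(frac - 1.96 * se, 0.0) if n else np.nan,
                     min(frac + 1.96 * se, 1.0) if n else np.nan))
    curve = pd.DataFrame(recs, columns=["trial", "n", "frac_correct",
                                        "ci_lo", "ci_hi"])
    prof = ErrorProfile(curve["frac_correct"].to_numpy(), mode="q_agent")
    return prof, curve


def certainty_of_trial(frac_correct: float) -> str:
    """Bin an empirical fraction-correct onto the analysis certainty levels."""
    return CERTAINTY_LEVELS[int(np.argmin(np.abs(CERTAINTY_CENTERS - frac_correct)))]


def level_map_from_curve(curve: pd.DataFrame) -> dict[int, str]:
    """Trial-in-block -> certainty level, from a behavioral learning curve.

    This is the calibration used to stratify model analyses: the labels
    come from the behavior the system was trained to reproduce, so a
    trial's certainty reflects task position rather than any particular
    closed-loop run.
    """
    return {int(t): certainty_of_trial(f)
            for t, f in zip(curve["trial"], curve["frac_correct"])
            if np.isfinite(f)}


def assign_certainty(log: pd.DataFrame) -> pd.DataFrame:
    """Label every trial with its certainty level.

    A trial's certainty is the empirical first-attempt fraction-correct of
    its trial-in-block index (pooled over the whole log), binned to the
    analysis levels 50% / 76% / 88-91%.  Returns one row per trial with
    columns block_id, trial_index, frac_correct, level.
    """
    profile, curve = error_profile(log)
    by_trial = dict(zip(curve["trial"], curve["frac_correct"]))
    trials = log[["block_id", "trial_index"]].drop_duplicates()
    fc = trials["trial_index"].clip(upper=TRIALS_PER_BLOCK).map(by_trial)
    out = trials.assign(frac_correct=fc.to_numpy())
    out["level"] = [certainty_of_trial(f) for f in out["frac_correct"]]
    return out.reset_index(drop=True)
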