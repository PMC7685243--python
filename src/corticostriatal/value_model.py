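"""Q-learning action values, softmax choice, decay, and likelihood fitting.

The behavioral/value model maintains one action value per movement
direction (10 values); the task's stage/branch structure enters through
the availability mask, so the 10 direction slots double as the
state-action table.  After each attempted decision the chosen entry is
updated by the temporal-difference rule

    Q(a) <- Q(a) + alpha * (r + gamma * max_a' Q(a') - Q(a))

with the max taken over the actions available at the next decision point
(0 after the final stage of a trial), and the whole table then decays
multiplicatively by tau_q.  Choices are softmax(beta * Q) restricted to
the available options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from . import task_env
from .task_env import N_DIRECTIONS, TaskState

#: parameters fitted to monkey behavior (session-level maximum likelihood)
FITTED_ALPHA = 0.8100
FITTED_GAMMA = 0.2010
FITTED_BETA = 3.050
FITTED_TAU_Q = 0.95


@dataclass(frozen=True)
class QParams:
    """Learning rate, discount, inverse temperature and per-decision decay."""

    alpha: float = FITTED_ALPHA
    gamma: float = FITTED_GAMMA
    beta: float = FITTED_BETA
    tau_q: float = FITTED_TAU_Q

    def validate(self) -> "QParams":
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 <= self.gamma < 1):
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0 < self.tau_q <= 1):
            raise ValueError(f"tau_q must be in (0, 1], got {self.tau_q}")
        return self

    def to_json(self, path, nll: float | None = None) -> None:
        payload = {"alpha": self.alpha, "gamma": self.gamma,
                   "beta": self.beta, "tau_q": self.tau_q}
        if nll is not None:
            payload["nll"] = nll
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["alpha"], d["gamma"], d["beta"], d["tau_q"])


def new_qtable() -> np.ndarray:
    """All-zero 10-vector of action values."""
    return np.zeros(N_DIRECTIONS)


def _next_max(q: np.ndarray, state: TaskState, action: int, correct: bool) -> float:
    """max over the next decision point's available actions (0 if terminal)."""
    if correct and state.stage == task_env.N_STAGES - 1:
        return 0.0  # trial ends: no bootstrap past the third correct decision
    if correct:
        nxt = replace(state, stage=state.stage + 1)
    else:
        nxt = state  # forced repeat of the same stage
    return float(max(q[a] for a in task_env.available_actions(nxt)))


def q_update(
    q: np.ndarray,
    state: TaskState,
    action: int,
    reward: int,
    params: QParams,
    correct: bool | None = None,
) -> np.ndarray:
    """One temporal-difference update of the chosen entry (returns a copy)."""
    params.validate()
    if action not in task_env.available_actions(state):
        raise ValueError(f"action {action} not available at stage {state.stage}")
    if correct is None:
        correct = action == state.block_sequence.moves[state.stage]
    q = q.copy()
    target = reward + params.gamma * _next_max(q, state, action, correct)
    q[action] += params.alpha * (target - q[action])
    return q


def decay(q: np.ndarray, params: QParams) -> np.ndarray:
    """Multiplicative per-decision decay of the whole table."""
    return q * params.tau_q


def choice_probs(
    q: np.ndarray, available: set[int] | list[int], params: QParams
) -> dict[int, float]:
    """Softmax(beta * Q) restricted to the available actions."""
    avail = sorted(available)
    if not avail:
        raise ValueError("empty set of available actions")
    z = params.beta * q[avail]
    p = np.exp(z - logsumexp(z))
    return dict(zip(avail, p))


def generate_value_traces(log: pd.DataFrame, params: QParams) -> np.ndarray:
    """Replay a behavior log and emit the post-update value table per decision.

    Row k of the returned (n_decisions, 10) array is the Q table after the
    update and decay triggered by decision k.  The table is carried across
    blocks (values learned in one block decay into the next), matching the
    continual-session structure of the task.
    """
    params.validate()
    q = new_qtable()
    traces = np.empty((len(log), N_DIRECTIONS))
    state: TaskState | None = None
    prev_block = None
    for k, row in enumerate(log.itertuples(index=False)):
        if row.block_id != prev_block:
            state = TaskState(block_sequence=task_env.sequence(int(row.sequence_id)))
            prev_block = row.block_id
        if row.stage != state.stage or row.trial_index != state.trial_index:
            raise ValueError("log inconsistent with task rules "
                             f"(block {row.block_id}, trial {row.trial_index})")
        action = int(row.action_id)
        q = q_update(q, state, action, int(row.reward), params,
                     correct=bool(row.correct))
        q = decay(q, params)
        traces[k] = q
        state, out = task_env.step(state, action, max_repeats=10**9)
        if out.correct != bool(row.correct):
            raise ValueError("log outcome inconsistent with task rules")
    return traces


def compile_log(log: pd.DataFrame) -> list[tuple]:
    """Pre-resolve the task structure of a log for fast repeated replay.

    Returns one tuple per decision: (action, reward, available-actions,
    next-decision available actions or () when the trial ends).  The
    compiled form lets the likelihood be evaluated many times (as the
    simplex fit requires) without re-deriving task states.
    """
    rows = []
    state: TaskState | None = None
    prev_block = None
    for row in log.itertuples(index=False):
        if row.block_id != prev_block:
            state = TaskState(block_sequence=task_env.sequence(int(row.sequence_id)))
            prev_block = row.block_id
        action = int(row.action_id)
        avail = tuple(sorted(task_env.available_actions(state)))
        correct = bool(row.correct)
        if correct and state.stage == task_env.N_STAGES - 1:
            next_avail: tuple[int, ...] = ()
        elif correct:
            next_avail = tuple(sorted(task_env.available_actions(
                replace(state, stage=state.stage + 1))))
        else:
            next_avail = avail
        rows.append((action, int(row.reward), avail, next_avail))
        state, out = task_env.step(state, action, max_repeats=10**9)
        if out.correct != correct:
            raise ValueError("log outcome inconsistent with task rules")
    return rows


def _replay_nll(compiled: list[tuple], params: QParams) -> float:
    alpha, gamma, beta, tau = params.alpha, params.gamma, params.beta, params.tau_q
    q = [0.0] * N_DIRECTIONS
    nll = 0.0
    for action, reward, avail, next_avail in compiled:
        z = [beta * q[a] for a in avail]
        zmax = max(z)
        nll -= z[avail.index(action)] - zmax - np.log(
            sum(np.exp(v - zmax) for v in z))
        boot = max(q[a] for a in next_avail) if next_avail else 0.0
        q[action] += alpha * (reward + gamma * boot - q[action])
        for a in range(N_DIRECTIONS):
            q[a] *= tau
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite log-likelihood")
    return nll


def log_likelihood(log: pd.DataFrame, params: QParams) -> float:
    """Total log-likelihood of the logged choices under the softmax policy."""
    params.validate()
    return -_replay_nll(compile_log(log), params)


def save_traces(path, traces: np.ndarray, **attrs) -> None:
    """Store a (decisions x 10) value-trace array as an HDF5 dataset."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("value_traces", data=traces)
        ds.attrs.update(attrs)


def load_traces(path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["value_traces"][()]


def fit_params(
    log: pd.DataFrame,
    init: QParams | None = None,
    fixed_tau: bool = True,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[QParams, float, bool]:
    """Maximum-likelihood fit of (alpha, gamma, beta[, tau_q]) to a choice log.

    Derivative-free Nelder-Mead simplex on the negative log-likelihood, in
    an unconstrained reparametrization (logit for the unit-interval
    parameters, log for beta), restarted from ``n_restarts`` random points;
    the best optimum wins.  With ``fixed_tau`` the decay is held at the
    initial value (the behavioral fit held tau_q = 0.95 fixed).

    Returns (params, nll, converged).
    """
    if len(log) < 50:
        raise ValueError(f"need >= 50 decisions to fit, got {len(log)}")
    init = (init or QParams()).validate()
    rng = np.random.default_rng(seed)
    compiled = compile_log(log)

    def logit(p):  # (0,1) -> R
        return np.log(p / (1 - p))

    def pack(p: QParams):
        v = [logit(p.alpha), logit(p.gamma), np.log(p.beta)]
        if not fixed_tau:
            v.append(logit(p.tau_q))
        return np.array(v)

    def unpack(v) -> QParams:
        expit = lambda z: 1 / (1 + np.exp(-z))
        tau = expit(v[3]) if not fixed_tau else init.tau_q
        return QParams(alpha=float(np.clip(expit(v[0]), 1e-6, 1.0)),
                       gamma=float(np.clip(expit(v[1]), 0.0, 1 - 1e-9)),
                       beta=float(np.exp(v[2])), tau_q=float(tau))

    def nll(v) -> float:
        try:
            return _replay_nll(compiled, unpack(v))
        except FloatingPointError:
            return np.inf

    starts = [pack(init)]
    for _ in range(n_restarts - 1):
        starts.append(pack(QParams(
            alpha=float(rng.uniform(0.1, 0.95)),
            gamma=float(rng.uniform(0.02, 0.8)),
            beta=float(rng.uniform(0.5, 8.0)),
            tau_q=init.tau_q if fixed_tau else float(rng.uniform(0.7, 0.99)),
        )))
    best, converged = None, False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-5,
                                         "fatol": 1e-7})
        if best is None or res.fun < best.fun:
            best, converged = res, bool(res.success)
    return unpack(best.x), float(best.fun), converged
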