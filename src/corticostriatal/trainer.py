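"""Joint supervised training of the coupled networks.

All six weight matrices are updated with the gradient of a combined
squared-error loss over batches of blocks,

    l = 2 * sum_k sum_t sum_i (u_v - y_v)^2  +  sum_k sum_t sum_i (u_a - y_a)^2

with the striatal term carrying double weight.  Gradients are obtained by
backpropagation through time through the unrolled Euler dynamics of both
networks, including the value-readout coupling from the striatal into the
prefrontal network; the implementation is hand-derived and is checked
against central finite differences in the test suite.  The schedule is
the published one: initial learning rate 1e-3 for 10 outer steps of 1000
iterations each, the rate multiplied by 2/3 at every outer step.  The
optimizer is Adam by default (plain SGD available); the additive state
noise is treated as a constant during differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import signal_coding
from .rnn_model import WEIGHT_NAMES, NetworkParams
from .signal_coding import TrialTensors, sample_batch


@dataclass
class TrainConfig:
    lr0: float = 0.001
    n_outer: int = 10
    iters_per_outer: int = 1000
    lr_decay: float = 2.0 / 3.0
    batch_k: int = 10
    striatal_weight: float = 2.0
    dt: float = 1.0
    optimizer: str = "adam"  # or "sgd"
    train_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def lr_at(self, outer: int) -> float:
        return self.lr0 * self.lr_decay ** outer


def loss(
    u_v: np.ndarray, u_a: np.ndarray, y_v: np.ndarray, y_a: np.ndarray,
    w_str: float = 2.0, mask: np.ndarray | None = None,
) -> float:
    """Combined squared-error loss with double-weighted striatal term."""
    if u_v.shape != y_v.shape or u_a.shape != y_a.shape:
        raise ValueError("output/target shape mismatch")
    ev = (u_v - y_v) ** 2
    ea = (u_a - y_a) ** 2
    if mask is not None:
        ev = ev * mask[..., None]
        ea = ea * mask[..., None]
    return float(w_str * ev.sum() + ea.sum())


def pack_batch(blocks: list[TrialTensors]):
    """Zero-pad a batch of blocks to a common length; mask marks valid steps."""
    K = len(blocks)
    T = max(b.T for b in blocks)
    u_s = np.zeros((K, T, signal_coding.N_STRIATAL_IN))
    u_ins = np.zeros((K, T, signal_coding.N_INSTRUCTION))
    y_v = np.zeros((K, T, signal_coding.N_VALUE_OUT))
    y_a = np.zeros((K, T, signal_coding.N_ACTION_OUT))
    mask = np.zeros((K, T))
    for k, b in enumerate(blocks):
        u_s[k, :b.T] = b.u_s
        u_ins[k, :b.T] = b.u_ins
        y_v[k, :b.T] = b.y_v
        y_a[k, :b.T] = b.y_a
        mask[k, :b.T] = 1.0
    return u_s, u_ins, y_v, y_a, mask


def forward(
    params: NetworkParams,
    u_s: np.ndarray, u_ins: np.ndarray,
    dt: float = 1.0,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Unrolled forward pass storing the current trajectories for BPTT.

    Inputs are (K, T, dim); returns u_v, u_a and the stacked currents
    x_s, x_p of shape (K, T+1, N) (index 0 is the zero initial state).
    """
    K, T, _ = u_s.shape
    kappa = dt / params.tau
    n_s, n_p = params.n_s, params.n_p
    x_s = np.zeros((K, T + 1, n_s))
    x_p = np.zeros((K, T + 1, n_p))
    u_v = np.empty((K, T, signal_coding.N_VALUE_OUT))
    u_a = np.empty((K, T, signal_coding.N_ACTION_OUT))
    eta_s, eta_p = noise if noise is not None else (None, None)
    for t in range(T):
        drive_s = np.tanh(x_s[:, t]) @ params.W_rr_s.T + u_s[:, t] @ params.W_ir_s.T
        if eta_s is not None:
            drive_s = drive_s + eta_s[:, t]
        x_s[:, t + 1] = (1 - kappa) * x_s[:, t] + kappa * drive_s
        u_v[:, t] = x_s[:, t + 1] @ params.W_ro_s.T
        pin = np.concatenate([u_v[:, t], u_ins[:, t]], axis=1)
        drive_p = np.tanh(x_p[:, t]) @ params.W_rr_p.T + pin @ params.W_ir_p.T
        if eta_p is not None:
            drive_p = drive_p + eta_p[:, t]
        x_p[:, t + 1] = (1 - kappa) * x_p[:, t] + kappa * drive_p
        u_a[:, t] = x_p[:, t + 1] @ params.W_ro_p.T
    if not (np.all(np.isfinite(x_s)) and np.all(np.isfinite(x_p))):
        raise FloatingPointError("non-finite state during training rollout")
    return u_v, u_a, x_s, x_p


def forward_backward(
    params: NetworkParams,
    u_s: np.ndarray, u_ins: np.ndarray,
    y_v: np.ndarray, y_a: np.ndarray,
    mask: np.ndarray,
    w_str: float = 2.0,
    dt: float = 1.0,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and its gradient w.r.t. all six weight matrices (BPTT)."""
    K, T, _ = u_s.shape
    kappa = dt / params.tau
    u_v, u_a, x_s, x_p = forward(params, u_s, u_ins, dt=dt, noise=noise)
    m = mask[..., None]
    e_v = 2.0 * w_str * (u_v - y_v) * m   # dL/du_v (direct term)
    e_a = 2.0 * (u_a - y_a) * m           # dL/du_a
    total = loss(u_v, u_a, y_v, y_a, w_str=w_str, mask=mask)

    g = {k: np.zeros_like(getattr(params, k)) for k in WEIGHT_NAMES}
    W_ir_p_v = params.W_ir_p[:, :signal_coding.N_VALUE_OUT]  # value part of PFC input
    lam_s = np.zeros((K, params.n_s))  # dL/dx_s[t+1], future contributions
    lam_p = np.zeros((K, params.n_p))
    for t in range(T - 1, -1, -1):
        g_xp1 = lam_p + e_a[:, t] @ params.W_ro_p          # dL/dx_p[t+1]
        g_uv = e_v[:, t] + kappa * (g_xp1 @ W_ir_p_v)      # dL/du_v[t]
        g_xs1 = lam_s + g_uv @ params.W_ro_s               # dL/dx_s[t+1]

        r_s_t = np.tanh(x_s[:, t])
        r_p_t = np.tanh(x_p[:, t])
        pin_t = np.concatenate([u_v[:, t], u_ins[:, t]], axis=1)
        g["W_ro_p"] += e_a[:, t].T @ x_p[:, t + 1]
        g["W_ro_s"] += g_uv.T @ x_s[:, t + 1]
        g["W_rr_p"] += kappa * g_xp1.T @ r_p_t
        g["W_ir_p"] += kappa * g_xp1.T @ pin_t
        g["W_rr_s"] += kappa * g_xs1.T @ r_s_t
        g["W_ir_s"] += kappa * g_xs1.T @ u_s[:, t]

        lam_p = (1 - kappa) * g_xp1 + kappa * (g_xp1 @ params.W_rr_p) * (1 - r_p_t ** 2)
        lam_s = (1 - kappa) * g_xs1 + kappa * (g_xs1 @ params.W_rr_s) * (1 - r_s_t ** 2)
    return total, g


def numerical_gradient(
    params: NetworkParams, name: str, index: tuple[int, int],
    u_s, u_ins, y_v, y_a, mask,
    w_str: float = 2.0, dt: float = 1.0,
    noise=None, h: float = 1e-6,
) -> float:
    """Central finite difference of the loss w.r.t. one weight entry."""
    p = params.copy()
    W = getattr(p, name)
    vals = []
    for sign in (+1, -1):
        W[index] += sign * h
        u_v, u_a, _, _ = forward(p, u_s, u_ins, dt=dt, noise=noise)
        vals.append(loss(u_v, u_a, y_v, y_a, w_str=w_str, mask=mask))
        W[index] -= sign * h
    return (vals[0] - vals[1]) / (2 * h)


class _Adam:
    def __init__(self, keys, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}

    def step(self, params: NetworkParams, grads: dict) -> None:
        self.t += 1
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            getattr(params, k)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, keys, lr):
        self.lr = lr

    def step(self, params: NetworkParams, grads: dict) -> None:
        for k, gk in grads.items():
            getattr(params, k)[...] -= self.lr * gk


def train(
    params: NetworkParams,
    train_blocks: list[TrialTensors],
    cfg: TrainConfig = TrainConfig(),
    callback=None,
    checkpoint_dir=None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Train both networks jointly; returns updated params and loss history.

    Each iteration samples a batch of ``batch_k`` blocks with replacement,
    rolls the system out over each block from rest, and applies one
    optimizer step on the BPTT gradient of the combined loss.  The input
    weights are trained along with the recurrent and readout matrices.
    With ``checkpoint_dir`` the weights are written to HDF5 after every
    outer step (outer index and iteration stored as attributes).
    """
    if not train_blocks:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = params.copy()
    opt_cls = _Adam if cfg.optimizer == "adam" else _SGD
    history = []
    it_total = 0
    for outer in range(cfg.n_outer):
        opt = opt_cls(WEIGHT_NAMES, lr=cfg.lr_at(outer))
        for it in range(cfg.iters_per_outer):
            batch = sample_batch(train_blocks, k=cfg.batch_k, rng=rng)
            u_s, u_ins, y_v, y_a, mask = pack_batch(batch)
            noise = None
            if cfg.train_noise and params.noise_sd > 0:
                K, T, _ = u_s.shape
                noise = (rng.standard_normal((K, T, params.n_s)) * params.noise_sd,
                         rng.standard_normal((K, T, params.n_p)) * params.noise_sd)
            val, grads = forward_backward(params, u_s, u_ins, y_v, y_a, mask,
                                          w_str=cfg.striatal_weight, dt=cfg.dt,
                                          noise=noise)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"training diverged (loss={val}) at outer {outer} iter {it}")
            opt.step(params, grads)
            history.append((it_total, outer, cfg.lr_at(outer), val))
            it_total += 1
            if callback is not None:
                callback(it_total, outer, val)
        if checkpoint_dir is not None:
            from pathlib import Path

            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            params.save(ckpt / f"checkpoint_outer{outer:02d}.h5",
                        outer=outer, iteration=it_total, seed=cfg.seed)
    return params, pd.DataFrame(history, columns=["iteration", "outer", "lr", "loss"])


def evaluate_mse_by_trial(
    params: NetworkParams,
    blocks: list[TrialTensors],
    dt: float = 1.0,
    n_trials: int = 8,
) -> pd.DataFrame:
    """Teacher-forced test error per trial-in-block (the block-learning curve).

    Rolls each block through the trained system noise-free with the
    recorded inputs, and averages the squared output-target error of both
    networks within each trial's windows.  A decreasing curve over trials
    reproduces the within-block learning pattern: the error is largest on
    the first trial after a sequence switch, when the correct sequence is
    still unknown.
    """
    per_trial: dict[int, list[float]] = {t: [] for t in range(1, n_trials + 1)}
    for b in blocks:
        u_v, u_a, _, _ = forward(params, b.u_s[None], b.u_ins[None], dt=dt)
        err = np.concatenate([((u_v[0] - b.y_v) ** 2), ((u_a[0] - b.y_a) ** 2)],
                             axis=1).mean(axis=1)
        L = b.cfg.window_len
        trials = b.decisions["trial_index"].to_numpy()
        for j in range(b.n_windows):
            d = min(j, len(trials) - 1)  # terminal window joins the last trial
            t_idx = min(int(trials[d]), n_trials)
            per_trial[t_idx].append(err[j * L:(j + 1) * L].mean())
    recs = [(t, float(np.mean(v)) if v else np.nan, len(v))
            for t, v in per_trial.items()]
    return pd.DataFrame(recs, columns=["trial", "mse", "n_windows"])
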