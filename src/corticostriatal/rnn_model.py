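"""Coupled striatal / prefrontal rate networks.

Two tanh rate networks with leaky continuous-time dynamics, integrated by
explicit Euler:

    tau dx/dt = -x + W_rr r + W_ir u + eta,   r = tanh(x)

The striatal network receives the 15-D action/reward input and reads a
10-D action-value vector u_v linearly from its synaptic currents; u_v is
concatenated with the 10 instruction channels to form the prefrontal
input, and the prefrontal network reads out the 11-D action vector
(10 actions + hemifield unit), again from currents.  The two networks are
coupled through these readouts only and have separate weight matrices.
Each unit receives independent white noise (SD 0.01 by default) inside
the Euler update.

Full-scale sizes are N_s=1300 and N_p=1000 units; a 5x reduced model
(N_s=260, N_p=200) is the default for desk-scale simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .signal_coding import (N_ACTION_OUT, N_INSTRUCTION, N_PREFRONTAL_IN,
                            N_STRIATAL_IN, N_VALUE_OUT)

#: full-scale network sizes
N_STRIATAL_FULL = 1300
N_PREFRONTAL_FULL = 1000
#: 5x reduced sizes used for desk-scale runs
N_STRIATAL_SCALED = 260
N_PREFRONTAL_SCALED = 200

DEFAULT_TAU = 10.0       # ms
DEFAULT_NOISE_SD = 0.01
WEIGHT_NAMES = ("W_rr_s", "W_ir_s", "W_ro_s", "W_rr_p", "W_ir_p", "W_ro_p")


@dataclass
class NetworkParams:
    W_rr_s: np.ndarray  # (N_s, N_s)
    W_ir_s: np.ndarray  # (N_s, 15)
    W_ro_s: np.ndarray  # (10, N_s)
    W_rr_p: np.ndarray  # (N_p, N_p)
    W_ir_p: np.ndarray  # (N_p, 20)
    W_ro_p: np.ndarray  # (11, N_p)
    g: float = 1.0
    tau: float = DEFAULT_TAU
    noise_sd: float = DEFAULT_NOISE_SD

    @property
    def n_s(self) -> int:
        return self.W_rr_s.shape[0]

    @property
    def n_p(self) -> int:
        return self.W_rr_p.shape[0]

    def copy(self) -> "NetworkParams":
        return replace(self, **{k: getattr(self, k).copy() for k in WEIGHT_NAMES})

    def save(self, path, **attrs) -> None:
        with h5py.File(path, "w") as fh:
            for k in WEIGHT_NAMES:
                fh.create_dataset(k, data=getattr(self, k))
            fh.attrs.update(g=self.g, tau=self.tau, noise_sd=self.noise_sd, **attrs)

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with h5py.File(path, "r") as fh:
            mats = {k: fh[k][()] for k in WEIGHT_NAMES}
            return cls(**mats, g=float(fh.attrs["g"]), tau=float(fh.attrs["tau"]),
                       noise_sd=float(fh.attrs["noise_sd"]))


@dataclass
class NetworkState:
    """Synaptic currents of both networks; rates are tanh of currents."""

    x_s: np.ndarray
    x_p: np.ndarray

    @property
    def r_s(self) -> np.ndarray:
        return np.tanh(self.x_s)

    @property
    def r_p(self) -> np.ndarray:
        return np.tanh(self.x_p)


def init_params(
    n_s: int = N_STRIATAL_SCALED,
    n_p: int = N_PREFRONTAL_SCALED,
    g: float = 1.0,
    rng: np.random.Generator | int | None = None,
    tau: float = DEFAULT_TAU,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> NetworkParams:
    """Random initial weights.

    Recurrent weights are standard normal scaled by g/sqrt(N); input and
    readout weights standard normal scaled by 1/sqrt(fan-in).
    """
    if min(n_s, n_p) < 2:
        raise ValueError("network sizes must be >= 2")
    rng = np.random.default_rng(rng)
    sn = rng.standard_normal
    return NetworkParams(
        W_rr_s=sn((n_s, n_s)) * g / np.sqrt(n_s),
        W_ir_s=sn((n_s, N_STRIATAL_IN)) / np.sqrt(N_STRIATAL_IN),
        W_ro_s=sn((N_VALUE_OUT, n_s)) / np.sqrt(n_s),
        W_rr_p=sn((n_p, n_p)) * g / np.sqrt(n_p),
        W_ir_p=sn((n_p, N_PREFRONTAL_IN)) / np.sqrt(N_PREFRONTAL_IN),
        W_ro_p=sn((N_ACTION_OUT, n_p)) / np.sqrt(n_p),
        g=g, tau=tau, noise_sd=noise_sd,
    )


def initial_state(
    params: NetworkParams, batch_shape: tuple[int, ...] = (),
    rng: np.random.Generator | int | None = None, scale: float = 0.0,
) -> NetworkState:
    """Zero (default) or small random initial currents."""
    if scale > 0:
        rng = np.random.default_rng(rng)
        return NetworkState(rng.standard_normal(batch_shape + (params.n_s,)) * scale,
                            rng.standard_normal(batch_shape + (params.n_p,)) * scale)
    return NetworkState(np.zeros(batch_shape + (params.n_s,)),
                        np.zeros(batch_shape + (params.n_p,)))


def step(
    state: NetworkState,
    u_s: np.ndarray,
    u_ins: np.ndarray,
    params: NetworkParams,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkState, np.ndarray, np.ndarray]:
    """One Euler step of the coupled system.

    Updates the striatal currents first; its fresh value readout u_v joins
    the instruction channels as the prefrontal input of the same step.
    Noise is i.i.d. N(0, noise_sd^2) per unit, added inside the Euler
    bracket; pass ``rng=None`` for noise-free dynamics.  Leading batch
    dimensions on the state and inputs broadcast.
    """
    if dt > params.tau:
        raise ValueError("dt must not exceed the time constant tau")
    kappa = dt / params.tau
    eta_s = eta_p = 0.0
    if rng is not None and params.noise_sd > 0:
        eta_s = rng.standard_normal(state.x_s.shape) * params.noise_sd
        eta_p = rng.standard_normal(state.x_p.shape) * params.noise_sd
    x_s = state.x_s + kappa * (-state.x_s + np.tanh(state.x_s) @ params.W_rr_s.T
                               + u_s @ params.W_ir_s.T + eta_s)
    if np.any(~np.isfinite(x_s)):
        raise FloatingPointError("non-finite striatal state")
    u_v = x_s @ params.W_ro_s.T
    u_p = np.concatenate([u_v, u_ins], axis=-1)
    x_p = state.x_p + kappa * (-state.x_p + np.tanh(state.x_p) @ params.W_rr_p.T
                               + u_p @ params.W_ir_p.T + eta_p)
    if np.any(~np.isfinite(x_p)):
        raise FloatingPointError("non-finite prefrontal state")
    u_a = x_p @ params.W_ro_p.T
    return NetworkState(x_s, x_p), u_v, u_a


def rollout(
    params: NetworkParams,
    u_s_seq: np.ndarray,
    u_ins_seq: np.ndarray,
    state: NetworkState | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
    record_states: bool = False,
):
    """Iterate ``step`` over a (..., T, dim) input sequence.

    Returns (u_v, u_a, final_state) and, with ``record_states``, also the
    current traces (X_s, X_p) with time on the -2 axis.
    """
    if u_s_seq.shape[-1] != N_STRIATAL_IN or u_ins_seq.shape[-1] != N_INSTRUCTION:
        raise ValueError("input dimension mismatch")
    if u_s_seq.shape[:-1] != u_ins_seq.shape[:-1]:
        raise ValueError("striatal and instruction sequences disagree in shape")
    T = u_s_seq.shape[-2]
    batch = u_s_seq.shape[:-2]
    if state is None:
        state = initial_state(params, batch_shape=batch)
    u_v = np.empty(batch + (T, N_VALUE_OUT))
    u_a = np.empty(batch + (T, N_ACTION_OUT))
    X_s = np.empty(batch + (T, params.n_s)) if record_states else None
    X_p = np.empty(batch + (T, params.n_p)) if record_states else None
    for t in range(T):
        state, v, a = step(state, u_s_seq[..., t, :], u_ins_seq[..., t, :],
                           params, dt=dt, rng=rng)
        u_v[..., t, :] = v
        u_a[..., t, :] = a
        if record_states:
            X_s[..., t, :] = state.x_s
            X_p[..., t, :] = state.x_p
    if record_states:
        return u_v, u_a, state, X_s, X_p
    return u_v, u_a, state


def eig_spectrum(W: np.ndarray) -> np.ndarray:
    """Eigenvalues of a weight matrix, sorted by descending modulus."""
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square matrix")
    ev = np.linalg.eigvals(W)
    return ev[np.argsort(-np.abs(ev))]


def plot_spectrum(W: np.ndarray, ax=None, **scatter_kw):
    """Scatter the eigenvalues of W in the complex plane."""
    import matplotlib.pyplot as plt

    ev = eig_spectrum(W)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ev.real, ev.imag, s=6, **scatter_kw)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("Re")
    ax.set_ylabel("Im")
    ax.set_aspect("equal")
    return ax
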