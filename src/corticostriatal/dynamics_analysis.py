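"""Potential surfaces, fixed points and minimal paths between attractors.

The potential surface of a network at a chosen moment is obtained by
meshing a region of the 2-D sequence-dPC plane, lifting each mesh point
into unit space through the sequence encoder (as an initial vector of
firing rates), iterating the network one noise-free Euler step with the
input frozen at the chosen time point, and recording the magnitude of the
resulting state change.  Troughs of this surface are candidate fixed
points; a trough is verified by iterating the network for several more
steps and requiring its latent projection to stay put.  The joint surface
of two sequences is the pointwise minimum of their surfaces, and the
minimal path length between their fixed points is the Dijkstra shortest
path on the 8-connected mesh graph with Euclidean edge lengths in
(latent-1, latent-2, value) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter

from .latent_analysis import DPCAModel, PopulationTensor
from .rnn_model import NetworkParams

_CLIP = 1.0 - 1e-6


def _network_mats(params: NetworkParams, region: str):
    if region == "prefrontal":
        return params.W_rr_p, params.W_ir_p
    if region == "striatal":
        return params.W_rr_s, params.W_ir_s
    raise ValueError("region must be 'prefrontal' or 'striatal'")


def _single_step(W_rr, W_ir, x: np.ndarray, u: np.ndarray, kappa: float):
    return x + kappa * (-x + np.tanh(x) @ W_rr.T + u @ W_ir.T)


@dataclass
class PotentialSurface:
    """Gradient-magnitude values over a 2-D latent mesh at a frozen input."""

    xs: np.ndarray                 # (G,) latent-1 mesh coordinates
    ys: np.ndarray                 # (G,) latent-2 mesh coordinates
    values: np.ndarray             # (G, G) one-step state-change magnitude
    fixed_points: list[tuple[int, int]] = field(default_factory=list)
    context: dict = field(default_factory=dict)

    def minimum(self) -> tuple[int, int]:
        """Grid index of the global trough."""
        return tuple(np.unravel_index(np.argmin(self.values), self.values.shape))


def mesh_extent(latent_trajs: list[np.ndarray], pad: float = 0.25):
    """Bounding box of (2, T) latent trajectories padded by a fraction."""
    pts = np.concatenate(latent_trajs, axis=1)
    lo, hi = pts.min(axis=1), pts.max(axis=1)
    span = np.maximum(hi - lo, 1e-6)
    return (lo[0] - pad * span[0], hi[0] + pad * span[0],
            lo[1] - pad * span[1], hi[1] + pad * span[1])


def _lift(mesh_pts: np.ndarray, encoder: np.ndarray, mean: np.ndarray):
    """Latent mesh points -> unit-space currents via the encoder (as rates)."""
    r = mesh_pts @ encoder.T + mean
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def potential_surface(
    params: NetworkParams,
    region: str,
    model: DPCAModel,
    extent: tuple[float, float, float, float],
    frozen_input: np.ndarray,
    grid: int = 60,
    dt: float = 1.0,
    n_iter_check: int = 10,
    fp_eps: float = 1e-3,
    context: dict | None = None,
) -> PotentialSurface:
    """Compute the gradient-magnitude surface over a latent mesh.

    Mesh points are lifted through the first two columns of the sequence
    encoder, iterated one noise-free step at the frozen input, and scored
    by the Euclidean magnitude of the current change.  Local minima of the
    surface are kept as fixed points when the verification iteration
    confirms their latent projection stays within ``fp_eps``.
    """
    F = model.encoders["s"][:, :2]
    D = model.decoders["s"][:2]
    mean = model.mean
    if np.linalg.matrix_rank(F) < 2:
        warnings.warn("sequence encoder is rank deficient; mesh points "
                      "cannot be lifted faithfully")
    W_rr, W_ir = _network_mats(params, region)
    kappa = dt / params.tau
    xs = np.linspace(extent[0], extent[1], grid)
    ys = np.linspace(extent[2], extent[3], grid)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel()], axis=1)           # (G*G, 2)
    x0 = _lift(pts, F, mean)
    x1 = _single_step(W_rr, W_ir, x0, frozen_input, kappa)
    values = np.linalg.norm(x1 - x0, axis=1).reshape(grid, grid)

    surf = PotentialSurface(xs=xs, ys=ys, values=values,
                            context=dict(context or {}, region=region))
    is_min = values <= minimum_filter(values, size=3, mode="nearest")
    for i, j in zip(*np.where(is_min)):
        x_start = _lift(np.array([[xs[i], ys[j]]]), F, mean)[0]
        if verify_fixed_point(params, region, x_start, frozen_input,
                              decoder=D, mean=mean, n_iter=n_iter_check,
                              eps=fp_eps, dt=dt):
            surf.fixed_points.append((int(i), int(j)))
    return surf


def verify_fixed_point(
    params: NetworkParams,
    region: str,
    x0: np.ndarray,
    frozen_input: np.ndarray,
    decoder: np.ndarray,
    mean: np.ndarray,
    n_iter: int = 10,
    eps: float = 1e-3,
    dt: float = 1.0,
) -> bool:
    """True iff the latent projection stays within eps over n_iter steps.

    The network is iterated noise-free from unit-space currents ``x0``
    with the input held fixed (the length of the check corresponds to a
    fixation period); the displacement of the decoded latent position
    from its start must remain below ``eps`` throughout.
    """
    if not np.isfinite(eps):
        return True
    W_rr, W_ir = _network_mats(params, region)
    kappa = dt / params.tau
    x = x0.copy()
    z0 = decoder @ (np.tanh(x) - mean)
    for _ in range(n_iter):
        x = _single_step(W_rr, W_ir, x, frozen_input, kappa)
        if np.linalg.norm(decoder @ (np.tanh(x) - mean) - z0) >= eps:
            return False
    return True


def joint_surface(A: PotentialSurface, B: PotentialSurface) -> PotentialSurface:
    """Pointwise minimum of two surfaces on the same mesh."""
    if not (np.array_equal(A.xs, B.xs) and np.array_equal(A.ys, B.ys)):
        raise ValueError("surfaces must share the same mesh")
    return PotentialSurface(
        xs=A.xs, ys=A.ys, values=np.minimum(A.values, B.values),
        fixed_points=sorted(set(A.fixed_points) | set(B.fixed_points)),
        context={"joint": (A.context, B.context)})


def _surface_graph(surface: PotentialSurface,
                   edge_weight: str = "euclidean") -> nx.Graph:
    G = surface.values.shape[0]
    xs, ys, V = surface.xs, surface.ys, surface.values
    g = nx.Graph()
    for i in range(G):
        for j in range(V.shape[1]):
            for di, dj in ((1, 0), (0, 1), (1, 1), (1, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < G and 0 <= nj < V.shape[1]:
                    planar = np.hypot(xs[ni] - xs[i], ys[nj] - ys[j])
                    if edge_weight == "euclidean":
                        w = np.sqrt(planar ** 2 + (V[ni, nj] - V[i, j]) ** 2)
                    elif edge_weight == "cost":
                        w = 0.5 * (V[ni, nj] + V[i, j]) * planar
                    else:
                        raise ValueError(f"unknown edge weight {edge_weight!r}")
                    g.add_edge((i, j), (ni, nj), weight=float(w))
    return g


def min_path_length(
    surface: PotentialSurface, p: tuple[int, int], q: tuple[int, int],
    edge_weight: str = "euclidean",
) -> float:
    """Dijkstra shortest-path length between two mesh points.

    Edges connect 8-neighbors.  The default edge length is the Euclidean
    step in (latent-1, latent-2, value) space, so climbing the ridge
    between two troughs lengthens the path; ``edge_weight="cost"``
    instead weights each planar step by the mean endpoint surface value.
    """
    G = surface.values.shape
    for pt in (p, q):
        if not (0 <= pt[0] < G[0] and 0 <= pt[1] < G[1]):
            raise ValueError(f"point {pt} is off the mesh")
    if p == q:
        return 0.0
    g = _surface_graph(surface, edge_weight=edge_weight)
    return float(nx.dijkstra_path_length(g, tuple(p), tuple(q)))


# ---------------------------------------------------------------------------
# Certainty-resolved path lengths


def frozen_inputs_from_results(
    results,
    region: str,
    level_of_trial: dict[int, str],
    at_fraction: float = 0.5,
) -> dict[tuple[int, str], np.ndarray]:
    """Session-averaged network input at a chosen moment, per (sequence, level).

    The chosen moment is anchored to the first movement of a trial: for
    the prefrontal network it is the middle of that movement's choice
    pulse (instruction channels plus the live value readout), and for the
    striatal network the middle of that movement's action-feedback pulse
    in the following window (the action/reward channels are silent during
    the choice segment, so only the feedback moment carries
    sequence-specific striatal input).  ``at_fraction`` shifts the moment
    within the respective pulse.
    """
    from .task_env import TRIALS_PER_BLOCK

    acc: dict[tuple[int, str], list[np.ndarray]] = {}
    for res in results:
        cfg = res.cfg
        L, CP = cfg.window_len, cfg.choice_offset
        dec = res.log.reset_index(drop=True)
        n_win = res.u_v.shape[0] // L
        for t_idx, trial in dec.groupby("trial_index"):
            level = level_of_trial.get(min(int(t_idx), TRIALS_PER_BLOCK))
            if level is None:
                continue
            w = int(trial.index[0])  # first movement's choice window
            if region == "striatal":
                if w + 1 >= n_win:
                    continue
                tp = (w + 1) * L + int(at_fraction * cfg.action_pulse_len)
                u = res.u_s_in[tp]
            else:
                tp = w * L + CP + int(at_fraction * cfg.action_pulse_len)
                u = np.concatenate([res.u_v[tp], res.u_ins_in[tp]])
            acc.setdefault((res.sequence_id, level), []).append(u)
    return {k: np.mean(v, axis=0) for k, v in acc.items()}


def path_length_by_certainty(
    params: NetworkParams,
    region: str,
    pt: PopulationTensor,
    model: DPCAModel,
    frozen_inputs: dict[tuple[int, str], np.ndarray],
    pairs: list[tuple[int, int]] | None = None,
    grid: int = 40,
    dt: float = 1.0,
    fp_eps: float = 1e-3,
    require_verified: bool = False,
) -> pd.DataFrame:
    """Minimal path length between sequence fixed points, per certainty level.

    For every sequence pair and level, both sequences' surfaces are
    computed on the shared mesh spanning the pair's latent trajectories,
    their troughs located (skipping the pair with a warning if a trough
    fails fixed-point verification and ``require_verified`` is set), and
    the Dijkstra length along the joint surface between the troughs
    recorded.
    """
    D2 = model.decoders["s"][:2]
    A = pt.activity - model.mean[:, None, None, None]
    latent = np.einsum("dn,nsct->sctd", D2, A)  # (S, C, T, 2) via transpose
    seq_index = {sid: i for i, sid in enumerate(pt.sequence_ids)}
    pairs = pairs or list(combinations(pt.sequence_ids, 2))
    rows = []
    for ci, level in enumerate(pt.levels):
        for sa, sb in pairs:
            try:
                ta = latent[seq_index[sa], ci].T  # (2, T)
                tb = latent[seq_index[sb], ci].T
            except KeyError as e:
                raise ValueError(f"sequence {e} not in tensor") from e
            extent = mesh_extent([ta, tb])
            surfs = {}
            ok = True
            for sid in (sa, sb):
                key = (sid, level)
                if key not in frozen_inputs:
                    warnings.warn(f"no frozen input for sequence {sid} at {level};"
                                  " pair skipped")
                    ok = False
                    break
                surfs[sid] = potential_surface(
                    params, region, model, extent, frozen_inputs[key],
                    grid=grid, dt=dt, fp_eps=fp_eps,
                    context={"sequence": sid, "level": level})
                if require_verified and not surfs[sid].fixed_points:
                    warnings.warn(f"no verified fixed point for sequence {sid}"
                                  f" at {level}; pair skipped")
                    ok = False
                    break
            if not ok:
                continue
            joint = joint_surface(surfs[sa], surfs[sb])
            length = min_path_length(joint, surfs[sa].minimum(),
                                     surfs[sb].minimum())
            rows.append((level, sa, sb, length))
    return pd.DataFrame(rows, columns=["level", "seq_a", "seq_b", "path_length"])
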