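"""Demixed PCA and distance statistics on population activity.

The population tensor is organized as units x sequences x certainty x
time.  Demixed PCA decomposes the centered tensor into ANOVA-style
marginalizations over time (t), sequence (s), certainty (c) and their
pairwise interactions, leaving the three-way interaction as the noise
term, and then finds a per-marginalization encoder/decoder pair by
ridge-regularized reduced-rank regression; decoder rows are the demixed
principal components.  Trajectory statistics (inter-sequence distance
within hemifield clusters, distance-to-centroid compactness, hemifield
separation) operate either in full unit space or in a low-dimensional
sequence dPC subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from . import behavior_synth, task_env

#: marginalization labels: subsets of the task parameters
MARGINALIZATIONS = ("t", "s", "c", "st", "sc", "ct")
_AXES = {"s": 1, "c": 2, "t": 3}


@dataclass
class PopulationTensor:
    """Trial-averaged activity, units x sequences x certainty levels x time."""

    activity: np.ndarray
    sequence_ids: list[int]
    levels: list[str]
    dt: float = 1.0

    def __post_init__(self):
        if self.activity.ndim != 4:
            raise ValueError("activity must be units x sequences x certainty x time")
        if self.activity.shape[1] != len(self.sequence_ids):
            raise ValueError("sequence axis does not match sequence_ids")
        if self.activity.shape[2] != len(self.levels):
            raise ValueError("certainty axis does not match levels")
        if np.any(~np.isfinite(self.activity)):
            raise ValueError("tensor has missing cells (design not balanced)")

    @property
    def n_units(self) -> int:
        return self.activity.shape[0]

    def hemifield_labels(self) -> list[str]:
        return ["upper" if s in task_env.UPPER_SEQUENCE_IDS else "lower"
                for s in self.sequence_ids]


def population_tensor(
    results,
    region: str = "prefrontal",
    level_of_trial: dict[int, str] | None = None,
    levels: list[str] | None = None,
    use_rates: bool = True,
    n_per_cell: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> PopulationTensor:
    """Build a trial-aligned population tensor from closed-loop block results.

    Each trial contributes the hidden-unit traces of its three correct
    decisions' choice windows (3 windows of length L), so trials of
    different error counts align exactly.  Trials are binned by certainty
    level via ``level_of_trial`` (trial-in-block -> level; defaults to the
    behavioral-curve binning of the pooled session log) and averaged per
    (sequence, level) cell; an empty cell raises.

    ``n_per_cell`` subsamples every cell to the same number of trials
    (without replacement) before averaging.  Cell means carry sampling
    noise that inflates distance estimates by an amount shrinking with
    the trial count, so level-wise distance comparisons should equalize
    counts across cells; pass ``n_per_cell="min"`` to use the smallest
    cell's count.
    """
    if region not in ("prefrontal", "striatal"):
        raise ValueError("region must be 'prefrontal' or 'striatal'")
    from .autonomous import session_log

    log = session_log(results)
    if level_of_trial is None:
        lab = behavior_synth.assign_certainty(log)
        level_of_trial = dict(
            lab.groupby("trial_index")["level"].agg(lambda s: s.mode().iloc[0]))
    levels = levels or [l for l in behavior_synth.CERTAINTY_LEVELS
                        if l in set(level_of_trial.values())]
    seq_ids = sorted(log["sequence_id"].unique())

    cells: dict[tuple[int, str], list[np.ndarray]] = {}
    for res in results:
        X = res.X_p if region == "prefrontal" else res.X_s
        if X is None:
            raise ValueError("block results must be recorded with record_states=True")
        if use_rates:
            X = np.tanh(X)
        L = res.cfg.window_len
        dec = res.log.reset_index(drop=True)
        for t_idx, trial in dec.groupby("trial_index"):
            wins = trial.index[trial["correct"].astype(bool)].to_numpy()
            if len(wins) != 3:
                continue
            level = level_of_trial.get(
                min(int(t_idx), task_env.TRIALS_PER_BLOCK))
            if level not in levels:
                continue
            segs = [X[w * L:(w + 1) * L] for w in wins]
            cells.setdefault((res.sequence_id, level), []).append(
                np.concatenate(segs, axis=0).T)  # (units, 3L)
    if n_per_cell is not None:
        if not cells:
            raise ValueError("no complete trials found")
        k = (min(len(v) for v in cells.values()) if n_per_cell == "min"
             else int(n_per_cell))
        short = [c for c, v in cells.items() if len(v) < k]
        if short:
            raise ValueError(f"cells {short} have fewer than {k} trials")
        rng = np.random.default_rng(rng)
        cells = {c: [v[i] for i in rng.choice(len(v), size=k, replace=False)]
                 for c, v in cells.items()}
    n_units = next(iter(cells.values()))[0].shape[0]
    T = next(iter(cells.values()))[0].shape[1]
    act = np.full((n_units, len(seq_ids), len(levels), T), np.nan)
    for (sid, level), traces in cells.items():
        act[:, seq_ids.index(sid), levels.index(level), :] = np.mean(traces, axis=0)
    return PopulationTensor(act, sequence_ids=list(seq_ids), levels=list(levels))


# ---------------------------------------------------------------------------
# dPCA


def marginalize(X: np.ndarray | PopulationTensor) -> dict[str, np.ndarray]:
    """ANOVA-style decomposition of the centered tensor.

    Returns full-shape arrays for each marginalization plus the residual
    (three-way interaction) under key "noise"; their sum reconstructs the
    centered tensor exactly.
    """
    A = X.activity if isinstance(X, PopulationTensor) else np.asarray(X, float)
    if A.ndim != 4:
        raise ValueError("expected a units x sequences x certainty x time tensor")
    if np.any(~np.isfinite(A)):
        raise ValueError("unbalanced tensor: missing cells")
    grand = A.mean(axis=(1, 2, 3), keepdims=True)
    Ac = A - grand
    out: dict[str, np.ndarray] = {}
    for phi in MARGINALIZATIONS:
        keep = [_AXES[f] for f in phi]
        avg_axes = tuple(ax for ax in (1, 2, 3) if ax not in keep)
        term = Ac.mean(axis=avg_axes, keepdims=True)
        for sub in MARGINALIZATIONS:
            if sub != phi and set(sub) < set(phi):
                term = term - out[sub].mean(
                    axis=tuple(ax for ax in (1, 2, 3) if ax not in keep),
                    keepdims=True)
        out[phi] = np.broadcast_to(term, A.shape).copy()
    out["noise"] = Ac - sum(out[phi] for phi in MARGINALIZATIONS)
    return out


@dataclass
class DPCAModel:
    """Per-marginalization encoder (F) and decoder (D) pairs."""

    encoders: dict[str, np.ndarray]   # phi -> (N, d)
    decoders: dict[str, np.ndarray]   # phi -> (d, N)
    explained: pd.DataFrame = field(repr=False)
    reg: float = 0.0
    mean: np.ndarray | None = None    # (N,) grand mean removed before fitting


def fit_dpca(
    X: np.ndarray | PopulationTensor,
    n_components: int | dict[str, int] = 10,
    reg: float | None = None,
) -> DPCAModel:
    """Fit demixed PCA by reduced-rank ridge regression per marginalization.

    For each marginalization phi the pair (F_phi, D_phi) minimizes
    ``||X_phi - F_phi D_phi X||^2`` at the requested rank: the ridge
    regression solution is rank-reduced through the SVD of its fitted
    values.  ``reg=None`` uses 1e-6 * ||X||_F^2; pass 0 for plain least
    squares.
    """
    A = X.activity if isinstance(X, PopulationTensor) else np.asarray(X, float)
    margs = marginalize(A)
    N = A.shape[0]
    mean = A.mean(axis=(1, 2, 3))
    Xf = (A - mean[:, None, None, None]).reshape(N, -1)
    if reg is None:
        reg = 1e-6 * float(np.sum(Xf ** 2))
    G = Xf @ Xf.T + reg * np.eye(N)
    Ginv = np.linalg.inv(G)
    encoders, decoders, rows = {}, {}, []
    for phi in MARGINALIZATIONS:
        d = n_components[phi] if isinstance(n_components, dict) else n_components
        if d > min(Xf.shape):
            raise ValueError(f"rank {d} exceeds data dimensions for '{phi}'")
        Yf = margs[phi].reshape(N, -1)
        B = Yf @ Xf.T @ Ginv
        if d == 0:
            encoders[phi] = np.zeros((N, 0))
            decoders[phi] = np.zeros((0, N))
            continue
        U, S, _ = np.linalg.svd(B @ Xf, full_matrices=False)
        Ud = U[:, :d]
        F, D = Ud, Ud.T @ B
        encoders[phi], decoders[phi] = F, D
        fitted = F @ (D @ Xf)
        tot = float(np.sum(Yf ** 2))
        for i in range(d):
            comp = np.outer(F[:, i], D[i] @ Xf)
            rows.append((phi, i, float(np.sum(comp ** 2)) / tot if tot else 0.0))
        rows.append((phi, -1, float(np.sum(fitted ** 2)) / tot if tot else 0.0))
    explained = pd.DataFrame(rows, columns=["marginalization", "component",
                                            "explained_var"])
    return DPCAModel(encoders=encoders, decoders=decoders, explained=explained,
                     reg=reg, mean=mean)


def project(
    X_raw: np.ndarray,
    model: DPCAModel,
    phi: str = "s",
    d: int = 3,
    smoothing_sigma: float = 2.0,
) -> np.ndarray:
    """Project unit x time traces onto the first d demixed components of phi.

    Traces are Gaussian-smoothed along time (sigma in time bins; 0 skips
    smoothing) and centered with the model's stored mean before applying
    the decoder rows.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing sigma must be >= 0")
    X = np.asarray(X_raw, float)
    if smoothing_sigma > 0:
        X = gaussian_filter1d(X, smoothing_sigma, axis=-1)
    if model.mean is not None:
        X = X - model.mean[:, None]
    D = model.decoders[phi]
    if d > D.shape[0]:
        raise ValueError(f"model has only {D.shape[0]} '{phi}' components")
    return D[:d] @ X


# ---------------------------------------------------------------------------
# Distance statistics


def _level_trajectories(
    pt: PopulationTensor, subspace: DPCAModel | None, d_sub: int
) -> np.ndarray:
    """(S, C, dims, T) trajectories, optionally in the sequence dPC subspace."""
    A = pt.activity
    if subspace is not None:
        D = subspace.decoders["s"][:d_sub]
        A = A - subspace.mean[:, None, None, None]
        A = np.einsum("dn,nsct->dsct", D, A)
    return np.moveaxis(A, 0, 2)


def inter_sequence_distance(
    pt: PopulationTensor,
    clusters: dict[int, str] | None = None,
    subspace: DPCAModel | None = None,
    d_sub: int = 10,
) -> pd.DataFrame:
    """Mean Euclidean distance between sequence trajectories per certainty level.

    For every sequence pair (restricted to pairs within the same cluster
    when ``clusters`` maps sequence id -> cluster label) the pointwise
    Euclidean distance between the two trajectories is averaged across
    time.  Returns one row per (level, pair).
    """
    traj = _level_trajectories(pt, subspace, d_sub)
    rows = []
    for ci, level in enumerate(pt.levels):
        for i, j in combinations(range(len(pt.sequence_ids)), 2):
            si, sj = pt.sequence_ids[i], pt.sequence_ids[j]
            if clusters is not None and clusters.get(si) != clusters.get(sj):
                continue
            dist = float(np.linalg.norm(traj[i, ci] - traj[j, ci], axis=0).mean())
            rows.append((level, si, sj, dist))
    return pd.DataFrame(rows, columns=["level", "seq_a", "seq_b", "distance"])


def hemifield_clusters(pt: PopulationTensor) -> dict[int, str]:
    return dict(zip(pt.sequence_ids, pt.hemifield_labels()))


def centroid_compactness(
    pt: PopulationTensor,
    subspace: DPCAModel | None = None,
    d_sub: int = 10,
) -> pd.DataFrame:
    """Mean distance of each trajectory to its own time-centroid, per level."""
    traj = _level_trajectories(pt, subspace, d_sub)
    if traj.shape[-1] < 2:
        raise ValueError("trajectories must have at least 2 time points")
    rows = []
    for ci, level in enumerate(pt.levels):
        for i, sid in enumerate(pt.sequence_ids):
            tr = traj[i, ci]
            centroid = tr.mean(axis=1, keepdims=True)
            rows.append((level, sid,
                         float(np.linalg.norm(tr - centroid, axis=0).mean())))
    return pd.DataFrame(rows, columns=["level", "sequence", "compactness"])


def paired_level_test(
    df: pd.DataFrame,
    low: str | list[str],
    high: str,
    value: str,
    alternative: str = "greater",
    n_comparisons: int = 1,
) -> dict:
    """Paired t-test of a per-item statistic between certainty levels.

    Items (sequence pairs or sequences) are matched across levels; the
    default alternative tests for an increase at the high level.  The
    returned p is Bonferroni-multiplied by ``n_comparisons``.
    """
    lows = [low] if isinstance(low, str) else list(low)
    keys = [c for c in df.columns if c not in ("level", value)]
    lo = (df[df["level"].isin(lows)].groupby(keys)[value].mean())
    hi = df[df["level"] == high].set_index(keys)[value]
    lo, hi = lo.align(hi, join="inner")
    if len(lo) < 2:
        raise ValueError("need at least 2 matched items for a paired test")
    t, p = stats.ttest_rel(hi, lo, alternative=alternative)
    return {"t": float(t), "p": float(min(p * n_comparisons, 1.0)),
            "n_items": int(len(lo)),
            "mean_low": float(lo.mean()), "mean_high": float(hi.mean())}


def hemifield_separation_test(
    pt: PopulationTensor,
    subspace: DPCAModel | None = None,
    d_sub: int = 10,
) -> pd.DataFrame:
    """Within- vs between-hemifield trajectory distances, per certainty level.

    For each sequence, its mean distance to same-hemifield sequences is
    paired with its mean distance to opposite-hemifield sequences; a
    paired t-test per level (Bonferroni corrected over levels) checks that
    between-hemifield distances exceed within-hemifield ones.
    """
    labels = pt.hemifield_labels()
    if len(set(labels)) < 2:
        raise ValueError("both hemifields must be represented")
    dists = inter_sequence_distance(pt, clusters=None, subspace=subspace,
                                    d_sub=d_sub)
    hemis = dict(zip(pt.sequence_ids, labels))
    rows = []
    n_levels = len(pt.levels)
    for level in pt.levels:
        sub = dists[dists["level"] == level]
        within, between = [], []
        for sid in pt.sequence_ids:
            mask = (sub["seq_a"] == sid) | (sub["seq_b"] == sid)
            other = np.where(sub.loc[mask, "seq_a"] == sid,
                             sub.loc[mask, "seq_b"], sub.loc[mask, "seq_a"])
            same = np.array([hemis[o] == hemis[sid] for o in other])
            d = sub.loc[mask, "distance"].to_numpy()
            within.append(d[same].mean())
            between.append(d[~same].mean())
        t, p = stats.ttest_rel(between, within, alternative="greater")
        rows.append((level, float(t), float(p), float(min(p * n_levels, 1.0))))
    return pd.DataFrame(rows, columns=["level", "t", "p", "p_bonferroni"])
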