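"""Canonical correlation analysis between population datasets.

Model activity is compared with a reference population (another model run,
a surrogate dataset, or real recordings supplied as a units x time array)
by trial-averaging, Gaussian smoothing, reducing each dataset to 15
dimensions, and computing the first 10 canonical correlation
coefficients.  The CCA itself is solved through the SVD of the whitened
cross-covariance with a small ridge for numerical stability.  Joint
significance of the coefficient spectrum uses Bartlett's chi-square
approximation of the sequential Wilks-lambda statistic; two coefficient
spectra (e.g. trained vs untrained model) are compared per coefficient by
Fisher z-transformation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.ndimage import gaussian_filter1d

from . import trainer
from .rnn_model import NetworkParams
from .signal_coding import TrialTensors


def _reduce(X: np.ndarray, d: int) -> np.ndarray:
    """Center over time and project onto the top-d principal components."""
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(Xc) < d:
        raise ValueError(f"data rank below the requested {d} dimensions")
    U, _, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :d].T @ Xc


def cca_compare(
    X: np.ndarray,
    Y: np.ndarray,
    d_reduce: int = 15,
    n_cc: int = 10,
    smoothing_sigma: float = 2.0,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Canonical correlations between two units x time datasets.

    Both datasets are smoothed along time, reduced to ``d_reduce``
    dimensions, and whitened; the singular values of the whitened
    cross-covariance are the canonical correlation coefficients (sorted
    non-increasing, in [0, 1]).  Also returns the paired canonical
    variable time series, each (n_cc, T).
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("datasets must share the time axis")
    if min(X.shape[0], Y.shape[0]) < d_reduce:
        raise ValueError("fewer units than reduction dimensions")
    if smoothing_sigma > 0:
        X = gaussian_filter1d(X, smoothing_sigma, axis=1)
        Y = gaussian_filter1d(Y, smoothing_sigma, axis=1)
    Xr, Yr = _reduce(X, d_reduce), _reduce(Y, d_reduce)
    T = Xr.shape[1]
    Cxx = Xr @ Xr.T / T + ridge * np.eye(d_reduce)
    Cyy = Yr @ Yr.T / T + ridge * np.eye(d_reduce)
    Cxy = Xr @ Yr.T / T
    Wx = linalg.inv(linalg.sqrtm(Cxx).real)
    Wy = linalg.inv(linalg.sqrtm(Cyy).real)
    U, S, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    n_cc = min(n_cc, len(S))
    coeffs = np.clip(S[:n_cc], 0.0, 1.0)
    A = (Wx @ U[:, :n_cc]).T @ Xr
    B = (Wy @ Vt.T[:, :n_cc]).T @ Yr
    return coeffs, (A, B)


def cca_significance(
    coefficients: np.ndarray, n_samples: int, p: int = 15, q: int = 15
) -> pd.DataFrame:
    """Sequential Wilks-lambda tests of the canonical correlation spectrum.

    Row k tests the joint significance of coefficients k..m-1 after
    removing the first k, via Bartlett's chi-square approximation.  Small
    ``n_samples`` (below the dimensionalities involved) makes the
    asymptotics unreliable; a warning column flags this.
    """
    r = np.asarray(coefficients, float)
    m = len(r)
    small = n_samples < p + q + 2
    rows = []
    for k in range(m):
        lam = float(np.prod(1.0 - r[k:] ** 2))
        dof = (p - k) * (q - k)
        factor = n_samples - 1 - (p + q + 1) / 2.0
        chi2 = -factor * np.log(max(lam, np.finfo(float).tiny))
        pval = float(stats.chi2.sf(chi2, dof)) if factor > 0 else np.nan
        rows.append((k, lam, chi2, dof, pval, small or factor <= 0))
    return pd.DataFrame(rows, columns=["k", "wilks_lambda", "chi2", "dof",
                                       "p", "asymptotics_warning"])


def fisher_z_compare(
    c1: np.ndarray, c2: np.ndarray, n_samples: int
) -> pd.DataFrame:
    """Per-coefficient Fisher z comparison of two correlation spectra."""
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    if c1.shape != c2.shape:
        raise ValueError("coefficient sets must have equal length")
    cap = 1.0 - 1e-12
    z = (np.arctanh(np.clip(c1, -cap, cap)) - np.arctanh(np.clip(c2, -cap, cap)))
    se = np.sqrt(2.0 / max(n_samples - 3, 1))
    zstat = z / se
    p = 2 * stats.norm.sf(np.abs(zstat))
    return pd.DataFrame({"k": np.arange(len(c1)), "c1": c1, "c2": c2,
                         "z": zstat, "p": p})


def trial_averaged_activity(
    params: NetworkParams,
    blocks: list[TrialTensors],
    region: str = "prefrontal",
    sequence_id: int | None = None,
    dt: float = 1.0,
    use_rates: bool = True,
) -> np.ndarray:
    """Teacher-forced, trial-averaged unit activity over one sequence's trials.

    Each block is rolled through the coupled system noise-free with its
    recorded inputs; every error-free traversal (the three correct
    decisions' choice windows) contributes one trial, and trials are
    averaged to a (units, 3L) array.
    """
    segs = []
    for b in blocks:
        if sequence_id is not None and b.sequence_id != sequence_id:
            continue
        _, _, x_s, x_p = trainer.forward(params, b.u_s[None], b.u_ins[None], dt=dt)
        X = (x_p if region == "prefrontal" else x_s)[0, 1:]  # (T, N)
        if use_rates:
            X = np.tanh(X)
        L = b.cfg.window_len
        dec = b.decisions.reset_index(drop=True)
        for _, trial in dec.groupby("trial_index"):
            wins = trial.index[trial["correct"].astype(bool)].to_numpy()
            if len(wins) != 3:
                continue
            segs.append(np.concatenate([X[w * L:(w + 1) * L] for w in wins]).T)
    if not segs:
        raise ValueError("no complete trials found for the requested sequence")
    return np.mean(segs, axis=0)


def trained_vs_untrained(
    trained: NetworkParams,
    untrained: NetworkParams,
    reference: np.ndarray,
    blocks: list[TrialTensors],
    region: str = "prefrontal",
    sequence_id: int | None = None,
    d_reduce: int = 15,
    n_cc: int = 10,
    dt: float = 1.0,
) -> pd.DataFrame:
    """CCA coefficient spectra of trained and untrained models vs a reference.

    Both models receive identical inputs (the same test blocks); each is
    compared with the reference dataset, and the per-coefficient spectra
    plus their means are returned together with the Fisher z comparison.
    """
    if trained.n_s != untrained.n_s or trained.n_p != untrained.n_p:
        raise ValueError("trained and untrained architectures must match")
    rows = {}
    for label, params in (("trained", trained), ("untrained", untrained)):
        act = trial_averaged_activity(params, blocks, region=region,
                                      sequence_id=sequence_id, dt=dt)
        coeffs, _ = cca_compare(act, reference, d_reduce=d_reduce, n_cc=n_cc)
        rows[label] = coeffs
    n = reference.shape[1]
    fz = fisher_z_compare(rows["trained"], rows["untrained"], n)
    out = pd.DataFrame({"k": np.arange(len(rows["trained"])),
                        "trained": rows["trained"],
                        "untrained": rows["untrained"],
                        "fisher_z": fz["z"], "fisher_p": fz["p"]})
    out.attrs["mean_trained"] = float(np.mean(rows["trained"]))
    out.attrs["mean_untrained"] = float(np.mean(rows["untrained"]))
    return out
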