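"""Time-lagged independent component analysis (tICA).

Solves the generalized eigenproblem C(tau) v = lambda C(0) v, where C(tau)
is the time-lagged covariance of the mean-centered collective-variable time
series and C(0) the instantaneous covariance.  The leading eigenvectors are
the slowest linearly-decorrelating coordinates; eigenvalue lambda_i at lag
tau corresponds to an implied relaxation timescale -tau/ln(lambda_i).

Lagged pairs are formed within independent segments only, C(tau) is
symmetrized to guarantee a real spectrum, and C(0) receives a small ridge
for numerical safety with nearly collinear CV sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = ["TICAModel", "fit_tica", "kinetic_content", "project", "implied_timescale"]


@dataclass
class TICAModel:
    mean: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, normalized v^T C0 v = 1
    lag_frames: int
    epsilon: float
    c0: np.ndarray
    c0_reg: np.ndarray
    ctau: np.ndarray

    @property
    def n_cv(self) -> int:
        return self.mean.shape[0]


def _as_segments(data: Sequence[np.ndarray] | np.ndarray) -> list[np.ndarray]:
    if isinstance(data, np.ndarray):
        data = [data]
    return [np.asarray(seg, dtype=float) for seg in data]


def fit_tica(
    segments: Sequence[np.ndarray] | np.ndarray,
    lag_frames: int = 25,
    epsilon: float | None = None,
) -> TICAModel:
    """Fit tICA on one or more CV segments (each frames x n_cv).

    The mean is pooled over all frames; C(0) and C(tau) are pooled over
    segments and C(tau) symmetrized before the generalized eigensolve.
    ``epsilon`` (default 1e-10) sets a diagonal ridge on C(0) proportional
    to each CV's own variance, so the regularization is invariant under
    rescaling of individual CVs.
    """
    segs = _as_segments(segments)
    if not segs:
        raise ValueError("no data segments")
    n_cv = segs[0].shape[1]
    if n_cv < 2:
        raise ValueError("need at least 2 collective variables")
    for seg in segs:
        if seg.ndim != 2 or seg.shape[1] != n_cv:
            raise ValueError("all segments must be 2-D with the same CV count")
        if seg.shape[0] <= lag_frames:
            raise ValueError(
                f"segment of {seg.shape[0]} frames is not longer than lag {lag_frames}"
            )
    mean = np.concatenate(segs, axis=0).mean(axis=0)

    c0 = np.zeros((n_cv, n_cv))
    ctau = np.zeros((n_cv, n_cv))
    n0 = 0
    ntau = 0
    for seg in segs:
        x = seg - mean
        c0 += x.T @ x
        n0 += x.shape[0]
        a = x[:-lag_frames]
        b = x[lag_frames:]
        ctau += a.T @ b
        ntau += a.shape[0]
    c0 /= n0
    ctau /= ntau
    ctau = 0.5 * (ctau + ctau.T)

    if epsilon is None:
        epsilon = 1e-10
    c0_reg = c0 + epsilon * np.diag(np.diag(c0))
    try:
        eigvals, eigvecs = scipy.linalg.eigh(ctau, c0_reg)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"C(0) is singular even after regularization: {exc}") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading positive
    for i in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, i]))
        if eigvecs[j, i] < 0:
            eigvecs[:, i] = -eigvecs[:, i]
    return TICAModel(
        mean=mean,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        lag_frames=lag_frames,
        epsilon=float(epsilon),
        c0=c0,
        c0_reg=c0_reg,
        ctau=ctau,
    )


def kinetic_content(model: TICAModel, k: int) -> float:
    """Fraction of the positive-eigenvalue sum captured by the first k modes."""
    if not 1 <= k <= model.n_cv:
        raise ValueError(f"k must be in [1, {model.n_cv}]")
    pos = np.maximum(model.eigenvalues, 0.0)
    total = pos.sum()
    if total == 0:
        return 0.0
    return float(pos[:k].sum() / total)


def project(model: TICAModel, cv_matrix: np.ndarray, k: int = 3) -> np.ndarray:
    """Project mean-centered data on the first k tICA eigenvectors."""
    x = np.asarray(cv_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_cv:
        raise ValueError(
            f"CV matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, model expects {model.n_cv}"
        )
    if not 1 <= k <= model.n_cv:
        raise ValueError(f"k must be in [1, {model.n_cv}]")
    return (x - model.mean) @ model.eigenvectors[:, :k]


def implied_timescale(model: TICAModel, i: int = 0) -> float:
    """Implied timescale (in frames) of the i-th tICA mode, -tau/ln(lambda_i)."""
    lam = model.eigenvalues[i]
    if lam <= 0:
        return float("nan")
    if lam >= 1:
        return float("inf")
    return float(-model.lag_frames / np.log(lam))
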