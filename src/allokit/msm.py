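"""Markov state models over clustered reduced coordinates.

Microstates come from k-means in the tICA (or any reduced) space.  The
transition count matrix at lag tau' is accumulated with a sliding window
within each independent segment, symmetrized by averaging with its transpose
to enforce detailed balance, restricted to the largest connected set of
states, and row-normalized into the transition probability matrix (TPM).
The stationary distribution is proportional to the symmetrized row sums.

Model quality is assessed by the implied-timescale test (t_i = -tau'/ln
lambda_i should be flat in tau' for a Markovian discretization) and by
GMRQ cross-validation (how well training-set eigenvectors diagonalize the
test-set TPM).  Kinetically metastable macrostates are obtained with PCCA+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "Clustering",
    "MarkovModel",
    "MacrostateModel",
    "cluster_microstates",
    "assign_to_centers",
    "build_tpm",
    "implied_timescales",
    "timescales_from_tpm",
    "gmrq_score",
    "reversible_eigs",
    "pcca_macrostates",
    "macrostate_populations",
]


@dataclass
class Clustering:
    centers: np.ndarray  # k x d
    assignments: list[np.ndarray]  # per segment
    inertia: float
    seed: int | None

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]


@dataclass
class MarkovModel:
    counts: np.ndarray  # over active states (symmetrized if requested)
    tpm: np.ndarray  # row-stochastic
    stationary: np.ndarray
    lag_frames: int
    active_states: np.ndarray  # original microstate labels of retained states
    symmetrized: bool

    @property
    def n_states(self) -> int:
        return self.tpm.shape[0]


@dataclass
class MacrostateModel:
    memberships: np.ndarray  # k x m, rows sum to 1
    crisp_map: np.ndarray  # microstate -> macrostate
    populations: np.ndarray  # per macrostate, sums to 1
    macro_tpm: np.ndarray

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]


def _as_segments(data: Sequence[np.ndarray] | np.ndarray) -> list[np.ndarray]:
    if isinstance(data, np.ndarray):
        data = [data]
    return [np.asarray(seg) for seg in data]


def cluster_microstates(
    segments: Sequence[np.ndarray] | np.ndarray, k: int = 200, seed: int | None = None
) -> Clustering:
    """k-means discretization (k-means++ seeding, deterministic for a seed)."""
    segs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in _as_segments(segments)]
    stacked = np.concatenate(segs, axis=0)
    if stacked.shape[0] < k:
        raise ValueError(f"{stacked.shape[0]} frames < {k} requested microstates")
    km = KMeans(n_clusters=k, init="k-means++", n_init=5, random_state=seed)
    km.fit(stacked)
    assignments = []
    start = 0
    for seg in segs:
        assignments.append(km.labels_[start : start + seg.shape[0]].copy())
        start += seg.shape[0]
    return Clustering(
        centers=km.cluster_centers_,
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
    )


def assign_to_centers(
    segments: Sequence[np.ndarray] | np.ndarray, centers: np.ndarray
) -> list[np.ndarray]:
    """Nearest-center state assignment for new data."""
    out = []
    for seg in _as_segments(segments):
        seg = np.atleast_2d(np.asarray(seg, dtype=float))
        d2 = ((seg[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        out.append(np.argmin(d2, axis=1))
    return out


def _count_transitions(
    assignments: Sequence[np.ndarray], lag: int, n_states: int
) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    for seg in assignments:
        seg = np.asarray(seg, dtype=int)
        if seg.shape[0] <= lag:
            raise ValueError(f"segment of {seg.shape[0]} frames not longer than lag {lag}")
        np.add.at(counts, (seg[:-lag], seg[lag:]), 1.0)
    return counts


def build_tpm(
    assignments: Sequence[np.ndarray] | np.ndarray,
    lag_frames: int,
    n_states: int | None = None,
    symmetrize: bool = True,
) -> MarkovModel:
    """Sliding-window transition counts at the given lag, within segments only.

    With ``symmetrize`` the count matrix is averaged with its transpose
    (detailed balance holds exactly afterwards).  States outside the largest
    connected set are dropped with a warning; the TPM is the row-normalized
    count matrix and the stationary distribution is proportional to the
    symmetrized row sums.
    """
    segs = _as_segments(assignments)
    if n_states is None:
        n_states = int(max(int(np.max(s)) for s in segs)) + 1
    counts = _count_transitions(segs, lag_frames, n_states)
    if counts.sum() == 0:
        raise ValueError("empty count matrix")
    if symmetrize:
        counts = 0.5 * (counts + counts.T)
    # ergodic trimming to the largest (strongly) connected component
    graph = csr_matrix(counts > 0)
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    if n_comp > 1:
        sizes = np.bincount(labels, weights=counts.sum(axis=1))
        keep_label = int(np.argmax(sizes))
        active = np.where(labels == keep_label)[0]
        warnings.warn(
            f"dropped {n_states - active.size} state(s) outside the largest connected set",
            stacklevel=2,
        )
    else:
        active = np.arange(n_states)
    # also drop states with zero visits
    visited = counts[np.ix_(active, active)].sum(axis=1) > 0
    active = active[visited]
    c = counts[np.ix_(active, active)]
    rowsum = c.sum(axis=1)
    tpm = c / rowsum[:, None]
    if symmetrize:
        pi = rowsum / rowsum.sum()
    else:
        # left Perron eigenvector
        vals, vecs = np.linalg.eig(tpm.T)
        i = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, i].real)
        pi = pi / pi.sum()
    return MarkovModel(
        counts=c,
        tpm=tpm,
        stationary=pi,
        lag_frames=lag_frames,
        active_states=active,
        symmetrized=symmetrize,
    )


def reversible_eigs(tpm: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real eigenvalues (descending) and right eigenvectors of a reversible TPM.

    Uses the symmetric similarity transform D^{1/2} T D^{-1/2} with
    D = diag(pi), which is symmetric exactly when detailed balance holds.
    """
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * tpm) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    right = vecs[:, order] / sqrt_pi[:, None]
    # normalize so the Perron eigenvector is exactly 1
    right = right / right[np.argmax(np.abs(right[:, 0])), 0]
    return vals, right


def implied_timescales(
    assignments: Sequence[np.ndarray] | np.ndarray,
    lags: Sequence[int],
    n_timescales: int = 5,
    n_states: int | None = None,
) -> pd.DataFrame:
    """Implied timescales t_i = -tau'/ln(lambda_i) per lag (frames).

    Non-positive eigenvalues yield NaN with a warning; lambda = 1 beyond the
    Perron mode (disconnected dynamics) yields +inf.
    """
    rows = []
    for lag in lags:
        mm = build_tpm(assignments, lag_frames=lag, n_states=n_states, symmetrize=True)
        vals, _ = reversible_eigs(mm.tpm, mm.stationary)
        row = {"lag": lag}
        ts = []
        for lam in vals[1:]:  # skip the Perron eigenvalue
            if lam <= 0:
                ts.append(np.nan)
            elif lam >= 1:
                ts.append(np.inf)
            else:
                ts.append(-lag / np.log(lam))
        if any(np.isnan(t) for t in ts[:n_timescales]):
            warnings.warn(
                f"non-positive TPM eigenvalue at lag {lag}: timescale undefined",
                stacklevel=2,
            )
        for i in range(n_timescales):
            row[f"t{i + 2}"] = ts[i] if i < len(ts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def timescales_from_tpm(tpm: np.ndarray, pi: np.ndarray, lag_frames: int) -> np.ndarray:
    """Implied timescales -tau'/ln(lambda_i) from an analytic reversible TPM.

    Returns one value per non-Perron eigenvalue, descending; non-positive
    eigenvalues map to NaN, unit eigenvalues to +inf.
    """
    vals, _ = reversible_eigs(np.asarray(tpm, dtype=float), np.asarray(pi, dtype=float))
    out = []
    for lam in vals[1:]:
        if lam <= 0:
            out.append(np.nan)
        elif lam >= 1:
            out.append(np.inf)
        else:
            out.append(-lag_frames / np.log(lam))
    return np.asarray(out)


def gmrq_score(
    train_segments: Sequence[np.ndarray],
    test_segments: Sequence[np.ndarray],
    n_states: int,
    lag_frames: int,
    n_eigenvectors: int,
    seed: int | None = None,
) -> float:
    """Generalized matrix Rayleigh quotient cross-validation score.

    The microstate definition (k-means centers) and the eigenvectors V are
    fit on the training segments only; test frames are assigned to the
    training centers.  With S = diag(test stationary distribution) and T the
    test TPM, the score is Tr[(V^T S T V)(V^T S V)^-1].  With train = test
    it reduces to the sum of the top-n eigenvalues of that TPM.
    """
    if not train_segments or not test_segments:
        raise ValueError("train and test sets must be non-empty")
    clustering = cluster_microstates(train_segments, k=n_states, seed=seed)
    train_mm = build_tpm(clustering.assignments, lag_frames, n_states=n_states)
    test_assign = assign_to_centers(test_segments, clustering.centers)
    test_counts = _count_transitions(test_assign, lag_frames, n_states)
    test_counts = 0.5 * (test_counts + test_counts.T)
    c = test_counts[np.ix_(train_mm.active_states, train_mm.active_states)]
    rowsum = c.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("test set does not visit every training state")
    test_tpm = c / rowsum[:, None]
    s = np.diag(rowsum / rowsum.sum())
    _, right = reversible_eigs(train_mm.tpm, train_mm.stationary)
    v = right[:, :n_eigenvectors]
    vsv = v.T @ s @ v
    try:
        inv_vsv = np.linalg.inv(vsv)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"V^T S V is singular: {exc}") from exc
    return float(np.trace(v.T @ s @ test_tpm @ v @ inv_vsv))


def pcca_macrostates(mm: MarkovModel, m: int = 9) -> MacrostateModel:
    """PCCA+ metastable decomposition into m macrostates.

    Uses the inner-simplex construction on the first m right eigenvectors of
    the reversible TPM: the m most linearly independent microstates span a
    simplex, and memberships are the barycentric coordinates of every state
    in that simplex (small negative values from sampling noise are clipped
    and rows renormalized).  The crisp map is the argmax membership.
    """
    if not mm.symmetrized:
        raise ValueError("PCCA+ requires a reversible (symmetrized) TPM")
    if m > mm.n_states:
        raise ValueError(f"m = {m} exceeds the {mm.n_states} microstates")
    vals, right = reversible_eigs(mm.tpm, mm.stationary)
    if m >= 2 and vals[m - 1] <= 0:
        warnings.warn(
            f"eigenvalue {m} is non-positive ({vals[m - 1]:.3f}); "
            "the spectral gap does not support this many macrostates",
            stacklevel=2,
        )
    x = right[:, :m].copy()
    x[:, 0] = 1.0  # Perron eigenvector, exact
    vertices = _inner_simplex_vertices(x)
    a = np.linalg.inv(x[vertices])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    if len(np.unique(crisp)) < m:
        warnings.warn("some macrostates are empty under the crisp map", stacklevel=2)
    populations = macrostate_populations(mm.stationary, crisp, m)
    macro_tpm = _coarse_grain_tpm(mm.tpm, mm.stationary, crisp, m)
    return MacrostateModel(
        memberships=chi, crisp_map=crisp, populations=populations, macro_tpm=macro_tpm
    )


def _inner_simplex_vertices(x: np.ndarray) -> np.ndarray:
    """Indices of the m rows of x spanning the largest simplex (ISA search)."""
    n, m = x.shape
    vertices = np.empty(m, dtype=int)
    work = x.copy()
    vertices[0] = int(np.argmax(np.linalg.norm(work, axis=1)))
    work = work - work[vertices[0]]
    for j in range(1, m):
        norms = np.linalg.norm(work, axis=1)
        vertices[j] = int(np.argmax(norms))
        v = work[vertices[j]] / norms[vertices[j]]
        work = work - np.outer(work @ v, v)
    return vertices


def macrostate_populations(
    pi: np.ndarray, crisp_map: np.ndarray, n_macrostates: int | None = None
) -> np.ndarray:
    """Macrostate population = sum of stationary weights of member microstates."""
    crisp_map = np.asarray(crisp_map, dtype=int)
    if n_macrostates is None:
        n_macrostates = int(crisp_map.max()) + 1
    return np.bincount(crisp_map, weights=pi, minlength=n_macrostates)


def _coarse_grain_tpm(
    tpm: np.ndarray, pi: np.ndarray, crisp_map: np.ndarray, m: int
) -> np.ndarray:
    """Population-weighted coarse-grained transition matrix between macrostates."""
    flux = pi[:, None] * tpm
    macro = np.zeros((m, m))
    for a in range(m):
        ia = crisp_map == a
        for b in range(m):
            macro[a, b] = flux[np.ix_(ia, crisp_map == b)].sum()
    rowsum = macro.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return macro / rowsum
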