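"""Transition path theory on a Markov state model.

Given a row-stochastic transition matrix T and its stationary distribution
pi, the committor q_i is the probability of reaching the target set before
the source set starting from state i.  The reactive (gross) flux is

    J_ij = pi_i (1 - q_i) T_ij q_j

and the net flux J+_ij = max(0, J_ij - J_ji).  The total source->target flux
is decomposed into individual pathways by repeatedly extracting the widest
(maximum-bottleneck) path through the net-flux network and subtracting its
bottleneck flux along the path.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FluxResult", "Pathway", "committor", "flux_matrix", "decompose_pathways", "tpt_analysis"]


@dataclass
class Pathway:
    states: tuple[int, ...]
    flux: float
    normalized_flux: float
    cumulative_flux: float


@dataclass
class FluxResult:
    committor: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    source: tuple[int, ...]
    target: tuple[int, ...]
    pathways: list[Pathway] = field(default_factory=list)

    def pathway_table(self) -> pd.DataFrame:
        """Table mirroring the usual pathway report: path, normalized, cumulative."""
        return pd.DataFrame(
            {
                "path": ["->".join(map(str, p.states)) for p in self.pathways],
                "flux": [p.flux for p in self.pathways],
                "normalized_flux": [p.normalized_flux for p in self.pathways],
                "cumulative_flux": [p.cumulative_flux for p in self.pathways],
            }
        )


def _check_sets(n: int, source, target) -> tuple[tuple[int, ...], tuple[int, ...]]:
    source = tuple(sorted(int(s) for s in np.atleast_1d(source)))
    target = tuple(sorted(int(t) for t in np.atleast_1d(target)))
    if not source or not target:
        raise ValueError("source and target sets must be non-empty")
    if set(source) & set(target):
        raise ValueError("source and target sets overlap")
    for s in source + target:
        if not 0 <= s < n:
            raise ValueError(f"state {s} out of range")
    return source, target


def committor(tpm: np.ndarray, source, target) -> np.ndarray:
    """Forward committor toward the target set (0 on source, 1 on target).

    Solves the harmonic system q_i = sum_j T_ij q_j on intermediate states
    with the boundary conditions by a direct linear solve.
    """
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[0]
    source, target = _check_sets(n, source, target)
    q = np.zeros(n)
    q[list(target)] = 1.0
    inter = np.array([i for i in range(n) if i not in source and i not in target], dtype=int)
    if inter.size:
        a = np.eye(inter.size) - tpm[np.ix_(inter, inter)]
        b = tpm[np.ix_(inter, list(target))].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular committor system (disconnected intermediates {inter.tolist()}): {exc}"
            ) from exc
    return q


def flux_matrix(
    tpm: np.ndarray, pi: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gross flux J_ij = pi_i (1-q_i) T_ij q_j and net flux max(0, J - J^T)."""
    tpm = np.asarray(tpm, dtype=float)
    pi = np.asarray(pi, dtype=float)
    q = np.asarray(q, dtype=float)
    gross = pi[:, None] * (1.0 - q)[:, None] * tpm * q[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(gross - gross.T, 0.0)
    return gross, net


def _widest_path(
    flux: np.ndarray, source: tuple[int, ...], target: tuple[int, ...]
) -> tuple[list[int], float]:
    """Maximum-bottleneck path via a Dijkstra-style search.

    Ties between equally wide paths are broken by lexicographic state order
    (smaller predecessor state wins), which makes the decomposition
    deterministic.
    """
    n = flux.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=int)
    heap: list[tuple[float, int, int]] = []
    for s in source:
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, s, -1))
    visited = np.zeros(n, dtype=bool)
    while heap:
        neg_w, u, _ = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in target:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            path.reverse()
            return path, float(width[u])
        for v in range(n):
            if visited[v] or flux[u, v] <= 0:
                continue
            w = min(width[u], flux[u, v])
            if w > width[v] or (w == width[v] and prev[v] > u):
                width[v] = w
                prev[v] = u
                heapq.heappush(heap, (-w, v, u))
    return [], 0.0


def decompose_pathways(
    net_flux: np.ndarray,
    source,
    target,
    total_flux: float | None = None,
    coverage: float = 0.95,
    n_paths: int | None = None,
) -> list[Pathway]:
    """Iterative widest-path decomposition of the net flux.

    Repeatedly finds the maximum-bottleneck source->target path, records it
    with its bottleneck flux, subtracts that flux along the path, and stops
    once the recorded paths cover ``coverage`` of the total flux (or after
    ``n_paths`` paths).
    """
    flux = np.array(net_flux, dtype=float)
    n = flux.shape[0]
    source, target = _check_sets(n, source, target)
    if total_flux is None:
        total_flux = float(flux[list(source), :].sum() - flux[:, list(source)].sum())
    if total_flux <= 0:
        warnings.warn("no source->target flux; nothing to decompose", stacklevel=2)
        return []
    pathways: list[Pathway] = []
    carried = 0.0
    while True:
        path, bottleneck = _widest_path(flux, source, target)
        if not path or bottleneck <= 0:
            if not pathways:
                warnings.warn("target unreachable from source in the flux network", stacklevel=2)
            break
        carried += bottleneck
        pathways.append(
            Pathway(
                states=tuple(path),
                flux=bottleneck,
                normalized_flux=bottleneck / total_flux,
                cumulative_flux=carried / total_flux,
            )
        )
        for a, b in zip(path[:-1], path[1:]):
            flux[a, b] -= bottleneck
        if n_paths is not None and len(pathways) >= n_paths:
            break
        if carried >= coverage * total_flux - 1e-15:
            break
    return pathways


def tpt_analysis(
    tpm: np.ndarray,
    pi: np.ndarray,
    source,
    target,
    coverage: float = 0.95,
    n_paths: int | None = None,
    decompose_gross: bool = False,
) -> FluxResult:
    """Full TPT analysis: committor, fluxes, total flux, pathway decomposition.

    ``decompose_gross`` switches the pathway search from the net to the gross
    flux network.
    """
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[0]
    source, target = _check_sets(n, source, target)
    q = committor(tpm, source, target)
    gross, net = flux_matrix(tpm, pi, q)
    total = float(gross[list(source), :].sum() - gross[:, list(source)].sum())
    pathways = decompose_pathways(
        gross if decompose_gross else net,
        source,
        target,
        total_flux=total,
        coverage=coverage,
        n_paths=n_paths,
    )
    return FluxResult(
        committor=q,
        gross_flux=gross,
        net_flux=net,
        total_flux=total,
        source=source,
        target=target,
        pathways=pathways,
    )
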