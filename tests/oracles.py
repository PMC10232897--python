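"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most direct formulation available (explicit
sub-determinants, exhaustive enumeration, Monte-Carlo simulation) and share
no code with the package's computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))


# ---------------------------------------------------------------------------
# Gaussian information measures straight from a covariance matrix


def entropy_cov(cov: np.ndarray, idx: np.ndarray) -> float:
    """Differential entropy of the variables ``idx`` via the sub-determinant."""
    sub = np.atleast_2d(np.asarray(cov)[np.ix_(idx, idx)])
    sign, logdet = np.linalg.slogdet(sub)
    assert sign > 0, "sub-covariance must be positive definite"
    return 0.5 * (len(idx) * _LN_2PIE + logdet)


def tc_cov(cov: np.ndarray, blocks: list[np.ndarray]) -> float:
    joint = np.concatenate(blocks)
    return sum(entropy_cov(cov, b) for b in blocks) - entropy_cov(cov, joint)


def ctc_cov(cov: np.ndarray, blocks: list[np.ndarray], cond: np.ndarray) -> float:
    h_m = entropy_cov(cov, cond)
    total = sum(
        entropy_cov(cov, np.concatenate([b, cond])) - h_m for b in blocks
    )
    joint = np.concatenate(list(blocks) + [cond])
    return total - (entropy_cov(cov, joint) - h_m)


def ci_cov(cov: np.ndarray, blocks: list[np.ndarray], trans: np.ndarray) -> float:
    return tc_cov(cov, blocks) - ctc_cov(cov, blocks, trans)


def nci_cov(cov: np.ndarray, blocks: list[np.ndarray], trans: np.ndarray) -> float:
    return 100.0 * ci_cov(cov, blocks, trans) / tc_cov(cov, blocks)


def mci_cov(
    cov: np.ndarray,
    blocks: list[np.ndarray],
    trans: np.ndarray,
    chan: np.ndarray,
) -> float:
    union = np.concatenate([trans, chan])
    return (
        ci_cov(cov, blocks, trans)
        + ci_cov(cov, blocks, chan)
        - ci_cov(cov, blocks, union)
    )


def nmci_cov(
    cov: np.ndarray,
    blocks: list[np.ndarray],
    trans: np.ndarray,
    chan: np.ndarray,
) -> float:
    return 100.0 * mci_cov(cov, blocks, trans, chan) / ci_cov(cov, blocks, trans)


# ---------------------------------------------------------------------------
# geometry / contacts


def brute_force_min_distance(coords: np.ndarray, atoms_a, atoms_b) -> np.ndarray:
    """Per-frame min distance by an explicit double loop over atom pairs."""
    n_frames = coords.shape[0]
    out = np.full(n_frames, np.inf)
    for f in range(n_frames):
        for i in atoms_a:
            for j in atoms_b:
                d = np.sqrt(np.sum((coords[f, i] - coords[f, j]) ** 2))
                out[f] = min(out[f], d)
    return out


def windowed_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Direct centered truncated-window mean of a 1-D series."""
    n = len(x)
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    out = np.empty(n)
    for t in range(n):
        lo = max(t - half_lo, 0)
        hi = min(t + half_hi + 1, n)
        out[t] = np.mean(x[lo:hi])
    return out


# ---------------------------------------------------------------------------
# Markov chains / TPT


def mc_committor(
    tpm: np.ndarray, source, target, n_walkers: int, rng: np.random.Generator
) -> np.ndarray:
    """Committor by direct simulation: fraction of walkers absorbed at target.

    All walkers starting from each state are stepped in parallel until every
    one hits the source or target set.
    """
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[0]
    cum = np.cumsum(tpm, axis=1)
    source = set(np.atleast_1d(source).tolist())
    target = set(np.atleast_1d(target).tolist())
    absorbing = np.zeros(n, dtype=bool)
    hit_target = np.zeros(n, dtype=bool)
    for s in source:
        absorbing[s] = True
    for t in target:
        absorbing[t] = True
        hit_target[t] = True
    q = np.zeros(n)
    for start in range(n):
        if start in target:
            q[start] = 1.0
            continue
        if start in source:
            continue
        state = np.full(n_walkers, start, dtype=np.int64)
        active = np.ones(n_walkers, dtype=bool)
        reached = np.zeros(n_walkers, dtype=bool)
        while active.any():
            idx = np.where(active)[0]
            u = rng.random(idx.size)
            nxt = np.empty(idx.size, dtype=np.int64)
            for s_val in np.unique(state[idx]):
                mask = state[idx] == s_val
                nxt[mask] = np.searchsorted(cum[s_val], u[mask])
            state[idx] = nxt
            done = absorbing[nxt]
            reached[idx[done]] = hit_target[nxt[done]]
            active[idx[done]] = False
        q[start] = reached.mean()
    return q


def greedy_bottleneck_paths(
    flux: np.ndarray, source: int, target: int
) -> list[tuple[tuple[int, ...], float]]:
    """Pathway decomposition by exhaustively enumerating simple paths.

    At each round, every simple source->target path is scored by its
    bottleneck edge; the widest (ties broken lexicographically) is recorded
    and its bottleneck subtracted along the path.
    """
    flux = np.array(flux, dtype=float)
    n = flux.shape[0]
    results = []
    while True:
        best: tuple[float, tuple[int, ...]] | None = None
        for k in range(n):
            for mid in itertools.permutations(
                [s for s in range(n) if s not in (source, target)], k
            ):
                path = (source, *mid, target)
                width = min(flux[a, b] for a, b in zip(path[:-1], path[1:]))
                if width <= 0:
                    continue
                if best is None or width > best[0] or (width == best[0] and path < best[1]):
                    best = (width, path)
        if best is None:
            return results
        width, path = best
        results.append((path, width))
        for a, b in zip(path[:-1], path[1:]):
            flux[a, b] -= width


def simulate_chain(tpm: np.ndarray, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Plain sequential chain sampler (oracle-side duplicate on purpose)."""
    tpm = np.asarray(tpm, dtype=float)
    cum = np.cumsum(tpm, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = 0
    u = rng.random(n_steps)
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t]))
        states[t] = s
    return states
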