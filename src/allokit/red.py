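"""Rare-event detection (RED) by non-negative matrix factorization of contact maps.

The smoothed, trimmed contact time series I (frames x pairs) is factorized as
I ~ W H with W (frames x c) the temporal weights and H (c x pairs) the spatial
components.  Each spatial row is a contact pattern; its temporal column says
when that pattern dominates.  Components are made comparable by dividing each
spatial row by the mean value of the "constitutive" pairs (contacts present
with similar weight in every component) and multiplying the matching temporal
column by the same factor, which leaves the reconstruction unchanged.
Differences between two normalized spatial rows highlight the structure-
differentiating contact pairs (SDCPs) that form or break during the event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .contacts import ContactTimeSeries

__all__ = [
    "REDModel",
    "fit_red",
    "identify_constitutive_pairs",
    "normalize_components",
    "extract_sdcps",
    "dominance_timeline",
    "match_components",
]


@dataclass
class REDModel:
    spatial: np.ndarray  # c x n_pairs, non-negative
    temporal: np.ndarray  # t x c, non-negative
    pair_index: list[tuple[int, int]]
    reconstruction_error: float
    seed: int | None
    iterations: int
    normalization_factors: np.ndarray | None = None  # length c, set by normalize
    constitutive_pairs: list[tuple[int, int]] = field(default_factory=list)
    segment_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if (self.spatial < 0).any() or (self.temporal < 0).any():
            raise ValueError("NMF factors must be non-negative")
        if self.spatial.shape[0] != self.temporal.shape[1]:
            raise ValueError("component count mismatch between spatial and temporal")
        if self.spatial.shape[1] != len(self.pair_index):
            raise ValueError("pair_index does not match spatial columns")

    @property
    def n_components(self) -> int:
        return self.spatial.shape[0]

    @property
    def is_normalized(self) -> bool:
        return self.normalization_factors is not None

    def reconstruction(self) -> np.ndarray:
        return self.temporal @ self.spatial


def fit_red(
    cts: ContactTimeSeries,
    c: int = 5,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-9,
    init: str | None = None,
) -> REDModel:
    """Factorize the contact series into ``c`` non-negative components.

    Initialization defaults to the deterministic non-negative double-SVD
    ('nndsvda'); pass ``init='random'`` with a seed for randomized restarts.
    Minimizes the Frobenius loss by coordinate descent.
    """
    if c < 2:
        raise ValueError("need at least 2 components")
    if cts.n_frames <= c:
        raise ValueError("more components than frames")
    X = cts.values
    if (X < 0).any():
        raise ValueError("negative input values")
    if init is None:
        init = "nndsvda"
    model = NMF(
        n_components=c,
        init=init,
        solver="cd",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning handled below
        W = model.fit_transform(X)
    if model.n_iter_ >= max_iter:
        warnings.warn(
            f"NMF did not converge in {max_iter} iterations "
            f"(residual {model.reconstruction_err_:.3e})",
            stacklevel=2,
        )
    return REDModel(
        spatial=model.components_,
        temporal=W,
        pair_index=list(cts.pair_index),
        reconstruction_error=float(model.reconstruction_err_),
        seed=seed,
        iterations=int(model.n_iter_),
        segment_boundaries=list(cts.segment_boundaries),
    )


def identify_constitutive_pairs(
    model: REDModel, cv_max: float = 0.15, mean_min: float = 0.5
) -> list[tuple[int, int]]:
    """Pairs contributing similarly to every component (the 'horizontal lines').

    The NMF scale split between temporal and spatial factors is arbitrary
    per component, so each spatial row is first rescaled to unit mean; a pair
    is selected when the coefficient of variation of its rescaled values
    across components is below ``cv_max`` and its rescaled mean exceeds
    ``mean_min`` relative to the largest pair mean.
    """
    row_scale = model.spatial.mean(axis=1, keepdims=True)
    if (row_scale <= 0).any():
        raise ValueError("a spatial component is identically zero")
    rescaled = model.spatial / row_scale
    mean = rescaled.mean(axis=0)
    std = rescaled.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, std / mean, np.inf)
    scale = mean.max() if mean.size else 0.0
    mask = (cv < cv_max) & (mean > mean_min * scale)
    pairs = [p for p, m in zip(model.pair_index, mask) if m]
    if not pairs:
        raise ValueError(
            "no constitutive pairs found; relax cv_max/mean_min or inspect the spatial arrays"
        )
    return pairs


def normalize_components(
    model: REDModel, constitutive: Sequence[tuple[int, int]]
) -> REDModel:
    """Scale each component so constitutive pairs average 1 in its spatial row.

    The temporal column is multiplied by the same factor, so the product
    (the reconstruction of I) is unchanged.
    """
    if not constitutive:
        raise ValueError("constitutive set must be non-empty")
    col = {p: i for i, p in enumerate(model.pair_index)}
    try:
        cols = [col[p] for p in constitutive]
    except KeyError as exc:
        raise ValueError(f"constitutive pair {exc} not in model") from exc
    factors = model.spatial[:, cols].mean(axis=1)
    if (factors <= 0).any():
        raise ValueError("non-positive normalization factor; constitutive set unsuitable")
    return REDModel(
        spatial=model.spatial / factors[:, None],
        temporal=model.temporal * factors[None, :],
        pair_index=list(model.pair_index),
        reconstruction_error=model.reconstruction_error,
        seed=model.seed,
        iterations=model.iterations,
        normalization_factors=factors,
        constitutive_pairs=list(constitutive),
        segment_boundaries=list(model.segment_boundaries),
    )


def extract_sdcps(
    model: REDModel,
    comp_from: int,
    comp_to: int,
    k_sigma: float = 4.0,
    groups: dict[tuple[int, int], str] | None = None,
) -> pd.DataFrame:
    """Structure-differentiating contact pairs between two normalized components.

    delta = spatial[comp_to] - spatial[comp_from]; rows whose |delta| exceeds
    ``k_sigma`` times the plain standard deviation of delta over all pairs are
    reported, positive deltas as contacts formed in the from->to event and
    negative as broken.  ``groups`` optionally annotates pairs with motif
    labels.
    """
    if not model.is_normalized:
        raise ValueError("extract_sdcps requires a normalized model")
    for comp in (comp_from, comp_to):
        if not 0 <= comp < model.n_components:
            raise ValueError(f"component {comp} out of range")
    delta = model.spatial[comp_to] - model.spatial[comp_from]
    threshold = k_sigma * float(delta.std())
    rows = []
    for pair, d in zip(model.pair_index, delta):
        if abs(d) > threshold:
            rows.append(
                {
                    "res_i": pair[0],
                    "res_j": pair[1],
                    "component_from": comp_from,
                    "component_to": comp_to,
                    "delta": float(d),
                    "direction": "formed" if d > 0 else "broken",
                    "group": (groups or {}).get(pair, ""),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "res_i",
            "res_j",
            "component_from",
            "component_to",
            "delta",
            "direction",
            "group",
        ],
    )
    return table.sort_values("delta", key=np.abs, ascending=False, ignore_index=True)


def dominance_timeline(
    model: REDModel,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-frame component weights, dominant component, and transition frames.

    Returns ``(weights, labels, transitions)`` where ``weights`` is the t x c
    temporal matrix (suitable for stacked-area plots), ``labels[t]`` the
    argmax component at frame t, and ``transitions`` the frames where the
    dominant label changes (excluding replica joins).
    """
    if not model.is_normalized:
        raise ValueError("dominance_timeline requires a normalized model")
    weights = model.temporal
    labels = np.argmax(weights, axis=1)
    joins = set(model.segment_boundaries)
    transitions = [
        t for t in range(1, len(labels)) if labels[t] != labels[t - 1] and t not in joins
    ]
    return weights, labels, transitions


def match_components(model_a: REDModel, model_b: REDModel) -> list[int]:
    """Greedy cosine matching of spatial rows: index i of a -> returned[i] of b."""
    a = model_a.spatial
    b = model_b.spatial
    if a.shape[1] != b.shape[1]:
        raise ValueError("models have different pair spaces")
    na = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-300)
    nb = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-300)
    sim = na @ nb.T
    mapping = [-1] * a.shape[0]
    used: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-sim, axis=None), sim.shape))[0]
    for i, j in order:
        if mapping[i] == -1 and j not in used:
            mapping[i] = int(j)
            used.add(int(j))
    return mapping
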