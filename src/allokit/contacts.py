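"""Residue-residue contact time series: the input matrix for rare-event detection.

A contact between two residues in a frame means at least one interatomic
distance below the cutoff (3.5 A by default).  The raw series is binary; the
analysis pipeline trims pairs that never change, smooths each column with a
sliding mean, and concatenates independent replicas along the time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .traj_io import Trajectory

__all__ = [
    "ContactTimeSeries",
    "compute_contact_series",
    "trim_invariant_pairs",
    "smooth",
    "concatenate",
]


@dataclass
class ContactTimeSeries:
    """frames x pairs occupancy matrix with a residue-pair index.

    Raw series hold {0,1}; smoothed series hold window means in [0,1].
    """

    values: np.ndarray
    pair_index: list[tuple[int, int]]
    segment_boundaries: list[int] = field(default_factory=lambda: [0])
    smoothed: bool = False
    window_frames: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames, pairs)")
        if self.values.shape[1] != len(self.pair_index):
            raise ValueError("pair_index length does not match number of columns")
        if len(set(self.pair_index)) != len(self.pair_index):
            raise ValueError("duplicate pairs in pair_index")
        for i, j in self.pair_index:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) must have res_i < res_j")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("contact values must lie in [0, 1]")
        if not self.smoothed and self.values.size:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("raw (unsmoothed) contact values must be 0/1")
        if not self.segment_boundaries or self.segment_boundaries[0] != 0:
            raise ValueError("segment_boundaries must start with 0")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def segment_slices(self) -> list[slice]:
        bounds = list(self.segment_boundaries) + [self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def min_residue_distances(
    traj: Trajectory, res_i: int, res_j: int, heavy_only: bool = True
) -> np.ndarray:
    """Per-frame minimum interatomic distance between two residues (A)."""
    top = traj.topology
    ia = _atom_ids(traj, res_i, heavy_only)
    ja = _atom_ids(traj, res_j, heavy_only)
    # frames x len(ia) x len(ja)
    diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ja, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return d.reshape(traj.n_frames, -1).min(axis=1)


def _atom_ids(traj: Trajectory, residue_id: int, heavy_only: bool) -> np.ndarray:
    ids = traj.topology.residue_atoms[residue_id]
    if heavy_only:
        ids = np.asarray([i for i in ids if traj.topology.atoms[int(i)].is_heavy], dtype=int)
        if ids.size == 0:  # hydrogen-only residue: fall back to all atoms
            ids = traj.topology.residue_atoms[residue_id]
    return ids


def compute_contact_series(
    traj: Trajectory, cutoff: float = 3.5, heavy_only: bool = True
) -> ContactTimeSeries:
    """Binary contact series over all unordered residue pairs."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    residues = traj.topology.residue_ids
    if len(residues) < 2:
        raise ValueError("need at least two residues to compute contacts")
    pairs = [(residues[a], residues[b]) for a in range(len(residues)) for b in range(a + 1, len(residues))]
    values = np.empty((traj.n_frames, len(pairs)))
    for col, (ri, rj) in enumerate(pairs):
        values[:, col] = min_residue_distances(traj, ri, rj, heavy_only) < cutoff
    return ContactTimeSeries(
        values, pairs, segment_boundaries=list(traj.segment_boundaries)
    )


def trim_invariant_pairs(cts: ContactTimeSeries) -> ContactTimeSeries:
    """Drop columns that never change over the full series."""
    if cts.smoothed:
        raise ValueError("trim operates on the raw (binary) series")
    dynamic = (cts.values != cts.values[0]).any(axis=0)
    if not dynamic.any():
        raise ValueError("no dynamic contacts: every pair is invariant")
    removed = [p for p, d in zip(cts.pair_index, dynamic) if not d]
    if removed:
        warnings.warn(f"trimmed {len(removed)} invariant pair(s)", stacklevel=2)
    return replace(
        cts,
        values=cts.values[:, dynamic],
        pair_index=[p for p, d in zip(cts.pair_index, dynamic) if d],
    )


def smooth(cts: ContactTimeSeries, window_frames: int = 25) -> ContactTimeSeries:
    """Centered sliding-mean smoothing, truncated at segment boundaries.

    The window never averages across replica joins; near edges it shrinks to
    the available frames.
    """
    if window_frames < 1:
        raise ValueError("window must be >= 1")
    shortest = min(s.stop - s.start for s in cts.segment_slices())
    if window_frames > shortest:
        raise ValueError(
            f"window ({window_frames}) exceeds shortest segment ({shortest} frames)"
        )
    if window_frames == 1:
        return replace(cts, smoothed=True, window_frames=1)
    half_lo = (window_frames - 1) // 2
    half_hi = window_frames - 1 - half_lo
    out = np.empty_like(cts.values)
    for seg in cts.segment_slices():
        block = cts.values[seg]
        n = block.shape[0]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        lo = np.maximum(np.arange(n) - half_lo, 0)
        hi = np.minimum(np.arange(n) + half_hi + 1, n)
        out[seg] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return replace(cts, values=out, smoothed=True, window_frames=window_frames)


def concatenate(
    series: Sequence[ContactTimeSeries], mode: str = "strict"
) -> ContactTimeSeries:
    """Stack contact series along the time axis.

    ``mode='strict'`` requires identical pair indices; ``mode='intersect'``
    keeps the common pairs (order of the first input) with a warning.
    """
    if not series:
        raise ValueError("nothing to concatenate")
    if len(series) == 1:
        return series[0]
    first = series[0]
    common = list(first.pair_index)
    for cts in series[1:]:
        if cts.pair_index != first.pair_index:
            if mode == "strict":
                raise ValueError("pair indices differ; use mode='intersect' to take the overlap")
            keep = set(cts.pair_index)
            common = [p for p in common if p in keep]
    if not common:
        raise ValueError("no pairs in common")
    if common != first.pair_index:
        warnings.warn(
            f"intersected pair sets: keeping {len(common)} common pair(s)", stacklevel=2
        )
    blocks = []
    boundaries: list[int] = []
    total = 0
    for cts in series:
        cols = [cts.pair_index.index(p) for p in common]
        blocks.append(cts.values[:, cols])
        boundaries.extend(b + total for b in cts.segment_boundaries)
        total += cts.n_frames
    smoothed = any(c.smoothed for c in series)
    return ContactTimeSeries(
        np.concatenate(blocks, axis=0),
        common,
        segment_boundaries=boundaries,
        smoothed=smoothed,
        window_frames=max(c.window_frames for c in series),
    )
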