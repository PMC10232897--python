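"""Collective variables and ligand binding-mode observables.

Provides center-of-mass distances, a scalar "cavity coordinate" describing
the ligand position along the binding pocket, distance-threshold
classification of the two pocket binding modes (hydroxyl near the serine
pair vs near the tryptophan/arginine/tyrosine site at the exit gate), and
contact probability between residue pairs as a percentage of frames.

All observables are pure functions of interatomic geometry and are invariant
under global rotation and translation of the input coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import min_residue_distances
from .traj_io import AtomSelection, Trajectory

__all__ = [
    "CVMatrix",
    "BindingModeSeries",
    "com_series",
    "com_distance",
    "cavity_coordinate",
    "classify_binding_mode",
    "contact_probability",
    "build_cv_matrix",
]

SER_MODE = "SER"
TRP_MODE = "TRP"
OTHER_MODE = "OTHER"


@dataclass
class CVMatrix:
    """frames x n_cv matrix of collective variables (distances in Angstrom)."""

    values: np.ndarray
    cv_names: list[str]
    definitions: list[dict] = field(default_factory=list)
    segment_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.cv_names):
            raise ValueError("values shape does not match cv_names")
        if len(set(self.cv_names)) != len(self.cv_names):
            raise ValueError("cv names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("CV values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.cv_names)


@dataclass
class BindingModeSeries:
    labels: np.ndarray  # of SER/TRP/OTHER strings
    channels: dict[str, np.ndarray]
    threshold: float


def com_series(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    """Per-frame mass-weighted center of mass of a selection (frames x 3)."""
    ids = sel.resolve(traj.topology)
    masses = traj.topology.masses(ids)
    total = masses.sum()
    return np.einsum("fad,a->fd", traj.coords[:, ids, :], masses) / total


def com_distance(
    traj: Trajectory, group_a: AtomSelection, group_b: AtomSelection
) -> np.ndarray:
    """Per-frame distance between the mass-weighted centers of two groups (A)."""
    ca = com_series(traj, group_a)
    cb = com_series(traj, group_b)
    return np.linalg.norm(ca - cb, axis=1)


def cavity_coordinate(
    traj: Trajectory,
    h4_sel: AtomSelection,
    ser_sel: AtomSelection,
    probe_sel: AtomSelection,
    protein_sel: AtomSelection | None = None,
) -> np.ndarray:
    """Scalar ligand-position coordinate along the pocket axis.

    Per frame the complex is (conceptually) rotated so that the long axis of
    the gate helix lies along x and the protein center of mass sits directly
    above the helix center of mass (+z); the origin is placed at the center
    of mass of the serine-pair selection and the probe displacement is
    projected on the bisector of the x and z axes, (x+z)/sqrt(2).

    The rotation is built from the coordinates themselves (helix principal
    axis oriented N->C, protein-offset direction), so the value is invariant
    under any global rigid-body motion of the input.
    """
    h4_ids = h4_sel.resolve(traj.topology)
    h4_res = sorted({traj.topology.atoms[int(i)].residue_id for i in h4_ids})
    if len(h4_res) < 2:
        raise ValueError("helix selection must span at least 2 residues")
    h4_com = com_series(traj, h4_sel)
    if protein_sel is None:
        # the orienting body is the protein: exclude the probe (ligand) atoms
        probe_res = {
            traj.topology.atoms[int(i)].residue_id
            for i in probe_sel.resolve(traj.topology)
        }
        protein_sel = AtomSelection.make(
            residue_ids=[r for r in traj.topology.residue_ids if r not in probe_res]
        )
    prot_com = com_series(traj, protein_sel)
    origin = com_series(traj, ser_sel)
    probe = com_series(traj, probe_sel)

    # per-residue helix anchor points, ordered N->C, for the long axis
    anchors = []
    masses_by_res = {}
    for rid in h4_res:
        ids = [int(i) for i in h4_ids if traj.topology.atoms[int(i)].residue_id == rid]
        m = traj.topology.masses(ids)
        anchors.append(np.einsum("fad,a->fd", traj.coords[:, ids, :], m) / m.sum())
        masses_by_res[rid] = m.sum()
    anchor_arr = np.stack(anchors, axis=1)  # frames x n_res x 3

    bisector = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = anchor_arr[f] - anchor_arr[f].mean(axis=0)
        u, s, vt = np.linalg.svd(pts, full_matrices=False)
        if s[0] < 1e-10:
            raise ValueError("degenerate helix axis: anchor points coincide")
        e1 = vt[0]
        # orient N-terminus -> C-terminus
        if np.dot(anchor_arr[f, -1] - anchor_arr[f, 0], e1) < 0:
            e1 = -e1
        v = prot_com[f] - h4_com[f]
        v_perp = v - np.dot(v, e1) * e1
        norm = np.linalg.norm(v_perp)
        if norm < 1e-10:
            raise ValueError(
                "degenerate geometry: protein center of mass lies on the helix axis"
            )
        e3 = v_perp / norm  # +z: protein sits above the helix
        e2 = np.cross(e3, e1)  # right-handed x,y,z
        rot = np.stack([e1, e2, e3])  # rows: lab->pocket frame
        disp = rot @ (probe[f] - origin[f])
        out[f] = float(np.dot(disp, bisector))
    return out


def classify_binding_mode(
    channels: Mapping[str, np.ndarray],
    ser_channel: str = "ser_dist",
    trp_channel: str = "trp_dist",
    d_site: float = 6.0,
) -> BindingModeSeries:
    """Label frames SER / TRP / OTHER from probe-to-site distances.

    SER when the serine-site distance is below ``d_site`` and smaller than
    the tryptophan-site distance; TRP symmetrically; OTHER when neither site
    is within ``d_site``.  The default 6 A accommodates water-bridged
    variants of each mode, which are collapsed into their parent mode.
    """
    for name in (ser_channel, trp_channel):
        if name not in channels:
            raise ValueError(f"missing distance channel {name!r}")
    ser = np.asarray(channels[ser_channel], dtype=float)
    trp = np.asarray(channels[trp_channel], dtype=float)
    if ser.shape != trp.shape:
        raise ValueError("distance channels have different lengths")
    labels = np.full(ser.shape, OTHER_MODE, dtype=object)
    labels[(ser < d_site) & (ser <= trp)] = SER_MODE
    labels[(trp < d_site) & (trp < ser)] = TRP_MODE
    return BindingModeSeries(
        labels=labels,
        channels={ser_channel: ser, trp_channel: trp},
        threshold=d_site,
    )


def contact_probability(
    traj: Trajectory,
    res_a: int,
    res_b: int,
    cutoff: float = 3.5,
    heavy_only: bool = True,
) -> float:
    """Percent of frames with any interatomic distance below the cutoff."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    d = min_residue_distances(traj, min(res_a, res_b), max(res_a, res_b), heavy_only)
    return 100.0 * float(np.mean(d < cutoff))


def build_cv_matrix(traj: Trajectory, cv_config: Sequence[dict]) -> CVMatrix:
    """Evaluate a list of CV definitions (in order) into a CVMatrix.

    Each definition is a dict with ``name``, ``type`` and type-specific keys:

    - ``com_distance``: ``group_a``, ``group_b`` (selection dicts)
    - ``cavity_coordinate``: ``h4``, ``ser``, ``probe`` (selection dicts)

    Selection dicts accept ``residue_ids``, ``atom_names``, ``heavy_only``.
    """
    if not cv_config:
        raise ValueError("empty CV configuration")
    columns = []
    names = []
    for cv in cv_config:
        name = cv.get("name")
        kind = cv.get("type")
        if not name:
            raise ValueError(f"CV definition missing 'name': {cv}")
        if kind == "com_distance":
            col = com_distance(traj, _sel(cv["group_a"]), _sel(cv["group_b"]))
        elif kind == "cavity_coordinate":
            col = cavity_coordinate(traj, _sel(cv["h4"]), _sel(cv["ser"]), _sel(cv["probe"]))
        else:
            raise ValueError(f"unknown CV type {kind!r} in {name!r}")
        names.append(name)
        columns.append(col)
    return CVMatrix(
        np.column_stack(columns),
        names,
        definitions=list(cv_config),
        segment_boundaries=list(traj.segment_boundaries),
    )


def _sel(spec: Mapping) -> AtomSelection:
    return AtomSelection.make(
        residue_ids=spec.get("residue_ids"),
        atom_names=spec.get("atom_names"),
        heavy_only=bool(spec.get("heavy_only", False)),
    )
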