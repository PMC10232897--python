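"""Small construction helpers for hand-built test systems."""

from __future__ import annotations

import numpy as np

from allokit.traj_io import Atom, Topology, Trajectory


def bead_topology(atoms_per_residue: list[int], element: str = "C") -> Topology:
    """One chain of bead residues with the given atom counts."""
    atoms = []
    for r, n in enumerate(atoms_per_residue, start=1):
        for k in range(n):
            atoms.append(Atom(len(atoms), f"C{k + 1}" if k else "CA", element, r, "BEA", "A"))
    return Topology(atoms)


def make_traj(coords: np.ndarray, atoms_per_residue: list[int] | None = None, **kw) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if atoms_per_residue is None:
        atoms_per_residue = [1] * coords.shape[1]
    return Trajectory(bead_topology(atoms_per_residue), coords, **kw)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
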