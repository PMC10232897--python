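"""Structure/trajectory input-output, atom selections, and superposition.

Coordinates are in Angstrom throughout, residue numbering is 1-based (PDB
convention), frame indices are 0-based.  A :class:`Trajectory` may be the
concatenation of several independent replicas; ``segment_boundaries`` records
where each replica starts so that time-lagged estimators never correlate
frames across a join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "superpose",
    "rmsd",
]

_HYDROGEN = {"H", "D"}


class PDBParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN

    @property
    def mass(self) -> float:
        return float(gemmi.Element(self.element).weight)


@dataclass
class Topology:
    """Atom table with a residue index.

    atom_ids are contiguous from 0; every atom belongs to exactly one
    residue; residue ids must be strictly increasing within a chain.
    """

    atoms: list[Atom]
    residue_atoms: dict[int, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.atom_id != i:
                raise ValueError(f"atom_ids must be contiguous from 0, got {a.atom_id} at {i}")
        per_chain: dict[str, int] = {}
        seen_res: dict[str, set[int]] = {}
        groups: dict[int, list[int]] = {}
        for a in self.atoms:
            last = per_chain.get(a.chain_id)
            if last is not None and a.residue_id < last:
                raise ValueError(
                    f"residue ids not increasing in chain {a.chain_id!r}: "
                    f"{a.residue_id} after {last}"
                )
            per_chain[a.chain_id] = a.residue_id
            seen_res.setdefault(a.chain_id, set()).add(a.residue_id)
            groups.setdefault(a.residue_id, []).append(a.atom_id)
        object.__setattr__(
            self, "residue_atoms", {r: np.asarray(ids, dtype=int) for r, ids in groups.items()}
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self.residue_atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_atoms)

    def residue_name(self, residue_id: int) -> str:
        return self.atoms[int(self.residue_atoms[residue_id][0])].residue_name

    def masses(self, atom_ids: Sequence[int] | None = None) -> np.ndarray:
        ids = range(self.n_atoms) if atom_ids is None else atom_ids
        return np.array([self.atoms[int(i)].mass for i in ids])


@dataclass
class Trajectory:
    """Coordinate time series (frames x atoms x 3, Angstrom) over a Topology."""

    topology: Topology
    coords: np.ndarray
    frame_interval_ns: float = 1.0
    segment_boundaries: list[int] = field(default_factory=lambda: [0])
    aligned_on: "AtomSelection | None" = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} != topology {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain non-finite values")
        if not self.segment_boundaries or self.segment_boundaries[0] != 0:
            raise ValueError("segment_boundaries must start with 0")
        if list(self.segment_boundaries) != sorted(set(self.segment_boundaries)):
            raise ValueError("segment_boundaries must be sorted and unique")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    def segment_slices(self) -> list[slice]:
        bounds = list(self.segment_boundaries) + [self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom selection: residue filter, atom-name filter, heavy-only.

    ``residue_ids=None`` selects all residues; ``atom_names=None`` all names.
    """

    residue_ids: tuple[int, ...] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False

    @staticmethod
    def make(
        residue_ids: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> "AtomSelection":
        return AtomSelection(
            residue_ids=None if residue_ids is None else tuple(residue_ids),
            atom_names=None if atom_names is None else frozenset(atom_names),
            heavy_only=heavy_only,
        )

    @staticmethod
    def alpha_carbons(residue_ids: Iterable[int] | None = None) -> "AtomSelection":
        return AtomSelection.make(residue_ids=residue_ids, atom_names=["CA"])

    def resolve(self, topology: Topology) -> np.ndarray:
        wanted = None if self.residue_ids is None else set(self.residue_ids)
        ids = [
            a.atom_id
            for a in topology.atoms
            if (wanted is None or a.residue_id in wanted)
            and (self.atom_names is None or a.name in self.atom_names)
            and (not self.heavy_only or a.is_heavy)
        ]
        if not ids:
            raise ValueError(f"selection resolved to zero atoms: {self}")
        return np.asarray(ids, dtype=int)


# ---------------------------------------------------------------------------
# reading / writing


def read_structure(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a Topology and a single-frame Trajectory.

    Only the first model is used.  When altloc duplicates are present, the
    first altloc of each atom is kept and a warning is issued.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"cannot parse PDB {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models / no ATOM records")

    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    dropped_altloc = 0
    model = st[0]
    for chain in model:
        for res in chain:
            seen_names: set[str] = set()
            for at in res:
                if at.name in seen_names:
                    dropped_altloc += 1
                    continue
                seen_names.add(at.name)
                atoms.append(
                    Atom(
                        atom_id=len(atoms),
                        name=at.name,
                        element=at.element.name,
                        residue_id=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                    )
                )
                coords.append((at.pos.x, at.pos.y, at.pos.z))
    if not atoms:
        raise PDBParseError(f"{path}: no atoms found")
    if dropped_altloc:
        warnings.warn(
            f"{path}: kept first altloc, dropped {dropped_altloc} duplicate atom(s)",
            stacklevel=2,
        )
    topology = Topology(atoms)
    traj = Trajectory(topology, np.asarray(coords)[None, :, :])
    return topology, traj


def _read_coordinate_file(path: Path, n_atoms: int) -> np.ndarray:
    """Return frames x atoms x 3 in Angstrom from DCD/XTC/NPZ."""
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as f:
            xyz, _, _ = f.read()
        return np.asarray(xyz, dtype=float)  # DCD stores Angstrom
    if suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as f:
            xyz, _, _, _ = f.read()
        return np.asarray(xyz, dtype=float) * 10.0  # nm -> Angstrom
    if suffix == ".npz":
        with np.load(path) as data:
            return np.asarray(data["coords"], dtype=float)
    raise ValueError(f"unsupported trajectory format: {path} (expected .dcd/.xtc/.npz)")


def read_trajectory(
    paths: Sequence[str | Path] | str | Path,
    topology: Topology,
    frame_interval_ns: float = 1.0,
) -> Trajectory:
    """Read and concatenate coordinate files; segment boundaries at file joins."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no trajectory files given")
    blocks: list[np.ndarray] = []
    boundaries: list[int] = []
    total = 0
    for p in paths:
        p = Path(p)
        xyz = _read_coordinate_file(p, topology.n_atoms)
        if xyz.ndim != 3 or xyz.shape[1] != topology.n_atoms:
            raise ValueError(
                f"{p}: atom count {xyz.shape[1] if xyz.ndim == 3 else '?'} does not match "
                f"topology ({topology.n_atoms})"
            )
        boundaries.append(total)
        total += xyz.shape[0]
        blocks.append(xyz)
    return Trajectory(
        topology,
        np.concatenate(blocks, axis=0),
        frame_interval_ns=frame_interval_ns,
        segment_boundaries=boundaries,
    )


def write_structure(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write a single frame as PDB."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError(f"expected ({topology.n_atoms}, 3) coordinates, got {coords.shape}")
    # group atoms per (chain, residue); gemmi's add_* methods copy their
    # argument, so children must be complete before being added
    order: list[tuple[str, int]] = []
    grouped: dict[tuple[str, int], list[Atom]] = {}
    for atom in topology.atoms:
        key = (atom.chain_id, atom.residue_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(atom)

    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain_keys: list[str] = []
    chain_members: dict[str, list[gemmi.Residue]] = {}
    for chain_id, residue_id in order:
        members = grouped[(chain_id, residue_id)]
        res = gemmi.Residue()
        res.name = members[0].residue_name
        res.seqid = gemmi.SeqId(residue_id, " ")
        res.het_flag = "A"
        for atom in members:
            g = gemmi.Atom()
            g.name = atom.name
            g.element = gemmi.Element(atom.element)
            g.occ = 1.0
            x, y, z = coords[atom.atom_id]
            g.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(g)
        if chain_id not in chain_members:
            chain_members[chain_id] = []
            chain_keys.append(chain_id)
        chain_members[chain_id].append(res)
    for chain_id in chain_keys:
        chain = gemmi.Chain(chain_id)
        for res in chain_members[chain_id]:
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write coordinates as DCD, XTC, or the plain NPZ fallback."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as f:
            f.write(np.asarray(traj.coords, dtype=np.float32))
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as f:
            f.write(np.asarray(traj.coords, dtype=np.float32) / 10.0)
    elif suffix == ".npz":
        np.savez_compressed(
            path,
            coords=np.asarray(traj.coords, dtype=np.float32),
            segment_boundaries=np.asarray(traj.segment_boundaries),
            frame_interval_ns=traj.frame_interval_ns,
        )
    else:
        raise ValueError(f"unsupported trajectory format: {path}")


# ---------------------------------------------------------------------------
# superposition


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _check_not_degenerate(xyz: np.ndarray) -> None:
    centered = xyz - xyz.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-8:
        raise ValueError("selection is degenerate (collinear or coincident atoms)")


def superpose(traj: Trajectory, ref: Trajectory, sel: AtomSelection) -> Trajectory:
    """Least-squares superpose every frame onto the reference.

    The optimal rotation is the closed-form (SVD-based) solution restricted
    to proper rotations; the transform fitted on the selected atoms is
    applied to all atoms.  Returns a new Trajectory carrying a record of the
    alignment selection.
    """
    idx_t = sel.resolve(traj.topology)
    idx_r = sel.resolve(ref.topology)
    if len(idx_t) != len(idx_r):
        raise ValueError(
            f"selection resolves to {len(idx_t)} atoms on trajectory but "
            f"{len(idx_r)} on reference"
        )
    if len(idx_t) < 3:
        raise ValueError(f"need >= 3 atoms to superpose, selection has {len(idx_t)}")
    ref_xyz = ref.coords[0, idx_r]
    _check_not_degenerate(ref_xyz)
    ref_center = ref_xyz.mean(axis=0)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mobile = traj.coords[f, idx_t]
        _check_not_degenerate(mobile)
        mob_center = mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_xyz - ref_center, mobile - mob_center)
        out[f] = rot.apply(traj.coords[f] - mob_center) + ref_center
    return replace(traj, coords=out, aligned_on=sel)
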