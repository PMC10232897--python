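"""Ground-truth fixture generators for every stage of the pipeline.

Real production trajectories for this kind of analysis are hundreds of
microseconds of all-atom MD; the generators here emulate the statistical
features each analysis stage consumes, with the ground truth attached:

- a bead-model trajectory with planted, time-localized contact-pattern
  changes and a ligand bead that switches binding site at the same event
  (contacts / RED / collective variables / end-to-end tests),
- a raw contact-matrix fixture with planted switching, constitutive and
  flickering pairs (RED at realistic pair counts),
- Gaussian displacement ensembles with a known latent-factor covariance
  (closed-form targets for every information-theoretic measure),
- collective-variable time series emitted from a known Markov chain
  (tICA / MSM / TPT recovery tests).

All generators are deterministic given a spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import ContactTimeSeries
from .traj_io import Atom, Topology, Trajectory

__all__ = [
    "PlantedEventSpec",
    "PlantedEventTruth",
    "gen_planted_trajectory",
    "ContactFixtureTruth",
    "gen_contact_fixture",
    "LatentSpec",
    "BlockSpec",
    "GaussianNetworkSpec",
    "gen_gaussian_network",
    "MarkovEmissionSpec",
    "gen_markov_cv",
    "sample_markov_chain",
]

CONTACT_CUTOFF = 3.5  # A, matching the contacts module default
IN_CONTACT_DIST = CONTACT_CUTOFF - 0.5
OUT_CONTACT_DIST = CONTACT_CUTOFF + 1.5


# ---------------------------------------------------------------------------
# planted-event bead trajectory


@dataclass
class PlantedEventSpec:
    """Multi-state bead model with contact-pattern switches and a mobile ligand.

    ``states`` lists, per conformational state, the set of residue pairs in
    contact; ``event_frames`` are the frames at which the trajectory moves to
    the next state.  ``ligand_sites`` optionally gives, per state, the
    residue next to which the ligand bead is parked.
    """

    n_residues: int = 20
    states: Sequence[frozenset] = field(
        default_factory=lambda: [frozenset({(3, 12), (5, 15)}), frozenset({(3, 12), (7, 17)})]
    )
    event_frames: Sequence[int] = (500,)
    n_frames: int = 1000
    ligand_sites: Sequence[int] | None = None
    sigma: float = 0.2
    spacing: float = 20.0
    frame_interval_ns: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.states = [frozenset((min(i, j), max(i, j)) for i, j in s) for s in self.states]
        if len(self.states) < 1:
            raise ValueError("need at least one state")
        if list(self.event_frames) != sorted(set(self.event_frames)):
            raise ValueError("event frames must be strictly increasing")
        if self.event_frames and (
            self.event_frames[0] <= 0 or self.event_frames[-1] >= self.n_frames
        ):
            raise ValueError("event frames must lie strictly inside the frame range")
        if len(self.event_frames) != len(self.states) - 1:
            raise ValueError("need exactly one event per state change")
        if len(self.states) > 1 and all(
            self.states[k] == self.states[k + 1] for k in range(len(self.states) - 1)
        ):
            raise ValueError("states must differ in at least one pair target")
        for s in self.states:
            for i, j in s:
                if i == j:
                    raise ValueError(f"contradictory pair target ({i},{j})")
                if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                    raise ValueError(f"pair ({i},{j}) outside residue range")
        if self.ligand_sites is not None and len(self.ligand_sites) != len(self.states):
            raise ValueError("need one ligand site per state")


@dataclass
class PlantedEventTruth:
    state_per_frame: np.ndarray
    switching_pairs: list[tuple[int, int]]  # pairs whose status differs between states
    event_frames: list[int]
    ligand_sites: list[int] | None
    ligand_residue_id: int | None


def gen_planted_trajectory(spec: PlantedEventSpec) -> tuple[Trajectory, PlantedEventTruth]:
    """Build the bead trajectory and its ground-truth record.

    Residue core beads sit on a circle with ~``spacing`` A between
    neighbours (never in contact); each planted pair gets a dedicated bead
    on both residues, placed symmetrically about the pair midpoint at
    separation cutoff-0.5 A (in contact) or cutoff+1.5 A (out of contact)
    depending on the state, so positional noise up to ~0.3 A cannot flip a
    planted contact.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    radius = spec.spacing / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    base = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )  # residue r (1-based) -> base[r-1]

    all_pairs = sorted(set().union(*spec.states)) if spec.states else []
    switching = [
        p
        for p in all_pairs
        if any(
            (p in a) != (p in b)
            for a, b in zip(spec.states[:-1], spec.states[1:])
        )
    ]
    if spec.ligand_sites is not None and len(set(spec.ligand_sites)) > 1:
        lig = spec.n_residues + 1
        switching.extend(sorted({(site, lig) for site in set(spec.ligand_sites)}))

    # topology: per residue one CA core bead plus one CB-style bead per planted pair
    atoms: list[Atom] = []
    pair_atoms: dict[tuple[int, int], tuple[int, int]] = {}
    ligand_res = None
    per_res_atoms: dict[int, list[tuple[str, tuple[int, int] | None]]] = {
        r: [("CA", None)] for r in range(1, n + 1)
    }
    for p in all_pairs:
        i, j = p
        per_res_atoms[i].append((f"C{len(per_res_atoms[i])}", p))
        per_res_atoms[j].append((f"C{len(per_res_atoms[j])}", p))
    for r in range(1, n + 1):
        for name, pair in per_res_atoms[r]:
            aid = len(atoms)
            atoms.append(Atom(aid, name, "C", r, "BEA", "A"))
            if pair is not None:
                a, b = pair_atoms.get(pair, (-1, -1))
                pair_atoms[pair] = (aid, b) if r == pair[0] else (a, aid)
    if spec.ligand_sites is not None:
        ligand_res = n + 1
        atoms.append(Atom(len(atoms), "L1", "C", ligand_res, "LIG", "L"))
    topology = Topology(atoms)

    state_per_frame = np.zeros(spec.n_frames, dtype=int)
    for k, ev in enumerate(spec.event_frames):
        state_per_frame[ev:] = k + 1

    coords = np.zeros((spec.n_frames, topology.n_atoms, 3))
    for r in range(1, n + 1):
        coords[:, topology.residue_atoms[r], :] = base[r - 1]
    for state_idx, state in enumerate(spec.states):
        frames = np.where(state_per_frame == state_idx)[0]
        if frames.size == 0:
            continue
        for pair, (aid_i, aid_j) in pair_atoms.items():
            i, j = pair
            # contact site in a per-pair z-plane so distinct pairs never
            # approach each other even when their chords cross in xy
            z_off = 3.0 * spec.spacing * (1 + all_pairs.index(pair))
            mid = 0.5 * (base[i - 1] + base[j - 1]) + np.array([0.0, 0.0, z_off])
            axis = base[j - 1] - base[i - 1]
            axis = axis / np.linalg.norm(axis)
            d = IN_CONTACT_DIST if pair in state else OUT_CONTACT_DIST
            coords[np.ix_(frames, [aid_i])] = mid - 0.5 * d * axis
            coords[np.ix_(frames, [aid_j])] = mid + 0.5 * d * axis
        if ligand_res is not None:
            site = spec.ligand_sites[state_idx]
            outward = base[site - 1] / np.linalg.norm(base[site - 1])
            pos = base[site - 1] + IN_CONTACT_DIST * outward
            coords[np.ix_(frames, topology.residue_atoms[ligand_res])] = pos
    coords += rng.normal(0.0, spec.sigma, size=coords.shape)

    traj = Trajectory(
        topology,
        coords,
        frame_interval_ns=spec.frame_interval_ns,
        segment_boundaries=[0],
    )
    truth = PlantedEventTruth(
        state_per_frame=state_per_frame,
        switching_pairs=switching,
        event_frames=list(spec.event_frames),
        ligand_sites=None if spec.ligand_sites is None else list(spec.ligand_sites),
        ligand_residue_id=ligand_res,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# contact-matrix fixture (RED at realistic pair counts)


@dataclass
class ContactFixtureTruth:
    switching_pairs: list[tuple[int, int]]
    switching_directions: list[str]  # formed / broken across the event
    constitutive_pairs: list[tuple[int, int]]
    event_frames: list[int]  # global frame indices, one per replica
    state_per_frame: np.ndarray


def gen_contact_fixture(
    n_frames: int = 1000,
    n_pairs: int = 200,
    n_switching: int = 8,
    n_constitutive: int = 32,
    event_frame: int = 500,
    n_replicas: int = 1,
    p_on: float = 0.95,
    noise_mean_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> tuple[ContactTimeSeries, ContactFixtureTruth]:
    """Raw binary contact matrix with planted switching pairs.

    Each replica of ``n_frames`` frames switches state at ``event_frame``.
    Switching pairs occupy state-dependent Bernoulli occupancies
    (p_on / 1 - p_on), alternating between forming and breaking across the
    event; constitutive pairs stay at p_on throughout; the remaining pairs
    flicker independently around a per-pair mean drawn from U(0.2, 0.8), so
    their smoothed profiles are flat and state-independent.
    """
    if n_switching + n_constitutive > n_pairs:
        raise ValueError("more special pairs than total pairs")
    if not 0 < event_frame < n_frames:
        raise ValueError("event frame outside range")
    rng = np.random.default_rng(seed)

    # synthesize a pair index from a fictitious residue numbering
    pairs: list[tuple[int, int]] = []
    i = 1
    while len(pairs) < n_pairs:
        for j in range(i + 2, i + 2 + max(1, n_pairs // 50)):
            pairs.append((i, j))
            if len(pairs) == n_pairs:
                break
        i += 1

    cols = rng.permutation(n_pairs)
    switching_cols = cols[:n_switching]
    constitutive_cols = cols[n_switching : n_switching + n_constitutive]
    noise_cols = cols[n_switching + n_constitutive :]

    total = n_frames * n_replicas
    state = np.zeros(total, dtype=int)
    event_frames = []
    for r in range(n_replicas):
        start = r * n_frames
        state[start + event_frame : start + n_frames] = 1
        event_frames.append(start + event_frame)

    values = np.zeros((total, n_pairs))
    directions = []
    for k, c in enumerate(switching_cols):
        forming = k % 2 == 0
        p_active = np.where(state == (1 if forming else 0), p_on, 1.0 - p_on)
        values[:, c] = rng.random(total) < p_active
        directions.append("formed" if forming else "broken")
    for c in constitutive_cols:
        values[:, c] = rng.random(total) < p_on
    means = rng.uniform(*noise_mean_range, size=noise_cols.size)
    for m, c in zip(means, noise_cols):
        values[:, c] = rng.random(total) < m

    cts = ContactTimeSeries(
        values,
        pairs,
        segment_boundaries=[r * n_frames for r in range(n_replicas)],
    )
    truth = ContactFixtureTruth(
        switching_pairs=[pairs[c] for c in switching_cols],
        switching_directions=directions,
        constitutive_pairs=[pairs[c] for c in constitutive_cols],
        event_frames=event_frames,
        state_per_frame=state,
    )
    return cts, truth


# ---------------------------------------------------------------------------
# Gaussian latent-factor network (NbIT ground truth)


@dataclass
class LatentSpec:
    """One latent signal: optionally driven by an earlier latent."""

    parent: int | None = None
    coeff: float = 1.0
    noise_var: float = 1.0


@dataclass
class BlockSpec:
    """One motif block: n_atoms scalar variables loading one latent."""

    name: str
    n_atoms: int
    latent: int
    loading: float = 1.0
    noise_var: float = 0.25
    atoms_per_residue: int = 1


@dataclass
class GaussianNetworkSpec:
    latents: list[LatentSpec]
    blocks: list[BlockSpec]
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for k, lat in enumerate(self.latents):
            if lat.parent is not None and not 0 <= lat.parent < k:
                raise ValueError("latent parents must precede their children (acyclic)")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        for b in self.blocks:
            if not 0 <= b.latent < len(self.latents):
                raise ValueError(f"block {b.name} references unknown latent {b.latent}")
            if b.noise_var <= 0:
                raise ValueError("block noise variance must be positive for a PD covariance")
            if b.n_atoms % b.atoms_per_residue:
                raise ValueError("n_atoms must divide into residues")


def _latent_covariance(latents: list[LatentSpec]) -> np.ndarray:
    m = len(latents)
    cov = np.zeros((m, m))
    for k, lat in enumerate(latents):
        if lat.parent is None:
            cov[k, k] = lat.noise_var
        else:
            p = lat.parent
            cov[k, :k] = lat.coeff * cov[p, :k]
            cov[:k, k] = cov[k, :k]
            cov[k, k] = lat.coeff**2 * cov[p, p] + lat.noise_var
    return cov


def gen_gaussian_network(
    spec: GaussianNetworkSpec,
) -> tuple[dict, np.ndarray, dict[str, np.ndarray]]:
    """Sample the network and return (ensembles, exact covariance, column map).

    Returns a dict of block name -> DisplacementEnsemble, the exact implied
    covariance of all variables (so every information measure has a
    closed-form target), and the mapping from block name to its column
    indices in that covariance.
    """
    from .nbit import DisplacementEnsemble

    cov_z = _latent_covariance(spec.latents)
    n_total = sum(b.n_atoms for b in spec.blocks)
    cov = np.zeros((n_total, n_total))
    slices: dict[str, np.ndarray] = {}
    offset = 0
    for b in spec.blocks:
        slices[b.name] = np.arange(offset, offset + b.n_atoms)
        offset += b.n_atoms
    for a in spec.blocks:
        for b in spec.blocks:
            block = (
                a.loading * b.loading * cov_z[a.latent, b.latent]
                * np.ones((a.n_atoms, b.n_atoms))
            )
            if a.name == b.name:
                block = block + a.noise_var * np.eye(a.n_atoms)
            cov[np.ix_(slices[a.name], slices[b.name])] = block
    # sanity: implied covariance must be positive definite
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig <= 0:
        raise ValueError(f"implied covariance not positive definite (min eig {min_eig:.3e})")

    rng = np.random.default_rng(spec.seed)
    z = rng.multivariate_normal(np.zeros(len(spec.latents)), cov_z, size=spec.n_frames)
    ensembles = {}
    atom_offset = 0
    res_offset = 0
    for b in spec.blocks:
        x = b.loading * z[:, [b.latent]] + rng.normal(
            0.0, np.sqrt(b.noise_var), size=(spec.n_frames, b.n_atoms)
        )
        n_res = b.n_atoms // b.atoms_per_residue
        blocks = {
            res_offset + r: np.arange(r * b.atoms_per_residue, (r + 1) * b.atoms_per_residue)
            for r in range(n_res)
        }
        ensembles[b.name] = DisplacementEnsemble(
            samples=x,
            name=b.name,
            atom_ids=np.arange(atom_offset, atom_offset + b.n_atoms),
            residue_blocks=blocks,
            mode="scalar",
        )
        atom_offset += b.n_atoms
        res_offset += n_res
    return ensembles, cov, slices


# ---------------------------------------------------------------------------
# Markov-chain CV emissions (tICA / MSM / TPT ground truth)


def sample_markov_chain(
    tpm: np.ndarray, n_steps: int, rng: np.random.Generator, start: int | None = None
) -> np.ndarray:
    """Sample a state sequence from a row-stochastic transition matrix."""
    tpm = np.asarray(tpm, dtype=float)
    cum = np.cumsum(tpm, axis=1)
    if start is None:
        # stationary start for equilibrium statistics
        vals, vecs = np.linalg.eig(tpm.T)
        pi = np.abs(vecs[:, np.argmax(vals.real)].real)
        pi /= pi.sum()
        start = int(rng.choice(len(pi), p=pi))
    states = np.empty(n_steps, dtype=np.int64)
    u = rng.random(n_steps)
    s = start
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t]))
        states[t] = s
    return states


@dataclass
class MarkovEmissionSpec:
    tpm: np.ndarray
    means: np.ndarray  # n_states x n_cv
    noise_std: float | Sequence[float] = 0.25  # scalar or per-CV
    n_frames: int = 100_000
    n_segments: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("TPM rows must sum to 1")
        if self.means.shape[0] != self.tpm.shape[0]:
            raise ValueError("one emission mean per state required")
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(
            csr_matrix(self.tpm > 0), directed=True, connection="strong"
        )
        if n_comp != 1:
            raise ValueError("TPM must be irreducible")


def gen_markov_cv(
    spec: MarkovEmissionSpec,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Emit CV segments from the latent chain.

    Returns (cv_segments, label_segments, true_tpm); each segment has
    ``n_frames`` frames, with Gaussian emissions around the state means.
    """
    rng = np.random.default_rng(spec.seed)
    segments = []
    labels = []
    noise = np.broadcast_to(
        np.asarray(spec.noise_std, dtype=float), (spec.means.shape[1],)
    )
    for _ in range(spec.n_segments):
        states = sample_markov_chain(spec.tpm, spec.n_frames, rng)
        x = spec.means[states] + noise * rng.standard_normal(
            (spec.n_frames, spec.means.shape[1])
        )
        segments.append(x)
        labels.append(states)
    return segments, labels, spec.tpm
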