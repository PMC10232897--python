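"""Gaussian information-theoretic coordination measures on aligned ensembles.

After rigid-body alignment of a trajectory to a reference, the motion of a
structural motif is summarized by a displacement ensemble X: per frame,
either one scalar per atom (distance to the reference position) or three
Cartesian deviations per atom.  Treating the ensemble as multivariate
Gaussian, its configurational entropy has the closed form

    H(X) = 1/2 ln((2 pi e)^N |C_X|)        [nats]

with C_X the covariance of the N variables.  On top of this entropy the
module implements the coordination measures used for quantifying allosteric
communication between motifs:

- total correlation          TC(X_1..X_N)   = sum_i H(X_i) - H(X_1..X_N)
- conditional TC             TC(.|X_m)      = sum_i [H(X_i, X_m) - H(X_m)]
                                              - [H(X_1..X_N, X_m) - H(X_m)]
- coordination information   CI(R, X_m)     = TC(R) - TC(R | X_m)
- normalized CI              NCI            = 100 * CI / TC(R)
- mutual coordination info   MCI(R,X_m,X_n) = CI(R,X_m) + CI(R,X_n)
                                              - CI(R, X_m u X_n)
- normalized MCI             NMCI           = 100 * MCI / CI(R, X_m)

where the receiver R is a set of >= 2 motifs; a single receiver motif is
split into per-residue blocks.  The transmitter is the motif whose knowledge
reduces the receiver's internal coordination, and the channel X_n is the
structural element through which transmitter and receiver share information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traj_io import AtomSelection, Trajectory

__all__ = [
    "DisplacementEnsemble",
    "MotifSet",
    "STARD4_MOTIFS",
    "displacement_ensemble",
    "entropy",
    "total_correlation",
    "conditional_tc",
    "coordination_information",
    "mutual_coordination",
    "coordination_matrix",
    "channel_profile",
    "transmitter_contribution",
]

# Structural motif presets for the StarD4-cholesterol system: name -> 1-based
# residue ids.  The cholesterol-binding site plus the peripheral gate/corridor
# elements whose coordination with it defines the allosteric network.
STARD4_MOTIFS: dict[str, list[int]] = {
    "CHLsite": [136, 147, 171, 92, 117],
    "beta1": [46, 47, 48, 49, 50, 51, 52],
    "beta2beta3": [58, 59, 60, 67, 68, 69],
    "beta2beta3loop": [62, 63, 64, 65],
    "H4head": [199, 200, 201, 203, 204, 207],
    "Omega1loop": [124, 125, 126],
    "beta9": [192, 194, 195],
    "beta7beta8loop-nearbeta9": [162, 163, 164],
    "beta7beta8loop-mid": [157, 158, 159, 160],
    "beta7beta8loop-nearbeta6": [153, 154, 155, 156],
    "H4tail": [218, 219, 220, 221],
    "beta3tail": [73, 74, 75, 76],
    "beta8beta9loop": [179, 180, 181, 182],
}


@dataclass
class MotifSet:
    """Named residue groups plus the atom policy used to realize them."""

    motifs: dict[str, list[int]]
    atom_policy: str = "heavy"  # heavy | calpha | all

    def __post_init__(self) -> None:
        for name, residues in self.motifs.items():
            if not residues:
                raise ValueError(f"motif {name!r} has no residues")
            if len(set(residues)) != len(residues):
                raise ValueError(f"motif {name!r} lists a residue twice")
        if self.atom_policy not in ("heavy", "calpha", "all"):
            raise ValueError(f"unknown atom policy {self.atom_policy!r}")

    def selection(self, name: str) -> AtomSelection:
        residues = self.motifs[name]
        if self.atom_policy == "calpha":
            return AtomSelection.alpha_carbons(residues)
        return AtomSelection.make(
            residue_ids=residues, heavy_only=(self.atom_policy == "heavy")
        )


@dataclass
class DisplacementEnsemble:
    """frames x n_vars displacement samples for one motif.

    ``atom_ids`` maps every column to the source atom (3 columns per atom in
    vector mode), and ``residue_blocks`` maps residue ids to column indices,
    enabling per-residue splitting and overlap checks between motifs.
    """

    samples: np.ndarray
    name: str
    atom_ids: np.ndarray  # per column
    residue_blocks: dict[int, np.ndarray]
    mode: str  # scalar | vector

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (frames, variables)")
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite displacement values")
        if len(self.atom_ids) != self.samples.shape[1]:
            raise ValueError("atom_ids length must match variable count")

    @property
    def n_vars(self) -> int:
        return self.samples.shape[1]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    def residue_split(self) -> list["DisplacementEnsemble"]:
        """One sub-ensemble per residue (used to give a lone receiver >= 2 blocks)."""
        out = []
        for rid in sorted(self.residue_blocks):
            cols = self.residue_blocks[rid]
            out.append(
                DisplacementEnsemble(
                    samples=self.samples[:, cols],
                    name=f"{self.name}:res{rid}",
                    atom_ids=np.asarray(self.atom_ids)[cols],
                    residue_blocks={rid: np.arange(len(cols))},
                    mode=self.mode,
                )
            )
        return out

    def without_residue(self, residue_id: int) -> "DisplacementEnsemble":
        keep = [r for r in sorted(self.residue_blocks) if r != residue_id]
        if not keep:
            raise ValueError("cannot drop the only residue")
        cols = np.concatenate([self.residue_blocks[r] for r in keep])
        blocks = {}
        offset = 0
        for r in keep:
            n = len(self.residue_blocks[r])
            blocks[r] = np.arange(offset, offset + n)
            offset += n
        return DisplacementEnsemble(
            samples=self.samples[:, cols],
            name=f"{self.name}-res{residue_id}",
            atom_ids=np.asarray(self.atom_ids)[cols],
            residue_blocks=blocks,
            mode=self.mode,
        )


def merge_ensembles(
    ensembles: list[DisplacementEnsemble], name: str
) -> DisplacementEnsemble:
    """Concatenate disjoint ensembles into one (e.g., transmitter u channel)."""
    _check_disjoint(ensembles)
    samples = np.concatenate([e.samples for e in ensembles], axis=1)
    atom_ids = np.concatenate([np.asarray(e.atom_ids) for e in ensembles])
    blocks: dict[int, np.ndarray] = {}
    offset = 0
    for e in ensembles:
        for rid, cols in e.residue_blocks.items():
            if rid in blocks:
                raise ValueError(f"residue {rid} appears in two merged ensembles")
            blocks[rid] = np.asarray(cols) + offset
        offset += e.n_vars
    return DisplacementEnsemble(
        samples=samples,
        name=name,
        atom_ids=atom_ids,
        residue_blocks=blocks,
        mode=ensembles[0].mode,
    )


def displacement_ensemble(
    traj: Trajectory,
    motif_residues: list[int],
    reference: Trajectory,
    name: str = "motif",
    atom_policy: str = "heavy",
    mode: str = "scalar",
) -> DisplacementEnsemble:
    """Per-atom displacement of a motif relative to the reference frame.

    Scalar mode records the Euclidean distance of each atom to its reference
    position (one variable per atom); vector mode records the (dx, dy, dz)
    deviation (three variables per atom).  The trajectory must have been
    superposed onto the reference first.
    """
    if traj.aligned_on is None:
        raise ValueError(
            "trajectory carries no superposition record; run traj_io.superpose first"
        )
    if mode not in ("scalar", "vector"):
        raise ValueError(f"unknown displacement mode {mode!r}")
    sel = MotifSet({name: list(motif_residues)}, atom_policy=atom_policy).selection(name)
    ids = sel.resolve(traj.topology)
    ref_ids = sel.resolve(reference.topology)
    if len(ids) != len(ref_ids):
        raise ValueError("motif resolves differently on trajectory and reference")
    delta = traj.coords[:, ids, :] - reference.coords[0, ref_ids, :]
    res_of = np.array([traj.topology.atoms[int(i)].residue_id for i in ids])
    if mode == "scalar":
        samples = np.linalg.norm(delta, axis=2)
        atom_ids = ids
        col_res = res_of
    else:
        samples = delta.reshape(traj.n_frames, -1)
        atom_ids = np.repeat(ids, 3)
        col_res = np.repeat(res_of, 3)
    blocks = {int(r): np.where(col_res == r)[0] for r in np.unique(col_res)}
    return DisplacementEnsemble(
        samples=samples, name=name, atom_ids=atom_ids, residue_blocks=blocks, mode=mode
    )


# ---------------------------------------------------------------------------
# entropy and coordination measures

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))
_EIG_FLOOR_REL = 1e-8


def _entropy_from_cov(cov: np.ndarray) -> float:
    cov = np.atleast_2d(cov)
    vals = np.linalg.eigvalsh(cov)
    floor = _EIG_FLOOR_REL * max(float(np.mean(np.abs(vals))), np.finfo(float).tiny)
    vals = np.clip(vals, floor, None)
    return 0.5 * (cov.shape[0] * _LN_2PIE + float(np.sum(np.log(vals))))


def _samples(ensembles) -> np.ndarray:
    if isinstance(ensembles, DisplacementEnsemble):
        return ensembles.samples
    return np.concatenate([e.samples for e in ensembles], axis=1)


def _check_disjoint(ensembles: list[DisplacementEnsemble]) -> None:
    seen: set[int] = set()
    for e in ensembles:
        ids = set(int(a) for a in np.asarray(e.atom_ids))
        if seen & ids:
            raise ValueError(
                f"motifs overlap in atoms {sorted(seen & ids)}; "
                "joint covariance would double-count"
            )
        seen |= ids


def entropy(x: DisplacementEnsemble | np.ndarray) -> float:
    """Gaussian differential entropy of the ensemble, in nats."""
    samples = x.samples if isinstance(x, DisplacementEnsemble) else np.asarray(x, float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if not np.isfinite(samples).all():
        raise ValueError("non-finite samples")
    if samples.shape[0] <= samples.shape[1]:
        warnings.warn(
            f"{samples.shape[0]} frames for {samples.shape[1]} variables: "
            "covariance is rank-deficient, entropy relies on the eigenvalue floor",
            stacklevel=2,
        )
    cov = np.cov(samples, rowvar=False)
    return _entropy_from_cov(cov)


def total_correlation(motifs: list[DisplacementEnsemble]) -> float:
    """TC = sum of marginal entropies minus the joint entropy (nats)."""
    if len(motifs) < 2:
        raise ValueError("total correlation needs >= 2 motifs")
    _check_disjoint(motifs)
    joint = _samples(motifs)
    return float(sum(entropy(m) for m in motifs) - entropy(joint))


def conditional_tc(
    motifs: list[DisplacementEnsemble], conditioner: DisplacementEnsemble
) -> float:
    """Total correlation of the motifs given the conditioner (nats)."""
    if len(motifs) < 2:
        raise ValueError("conditional TC needs >= 2 motifs")
    _check_disjoint(list(motifs) + [conditioner])
    h_m = entropy(conditioner)
    total = 0.0
    for x in motifs:
        total += entropy(np.concatenate([x.samples, conditioner.samples], axis=1)) - h_m
    joint = np.concatenate([_samples(motifs), conditioner.samples], axis=1)
    total -= entropy(joint) - h_m
    return float(total)


def _receiver_blocks(
    receiver: DisplacementEnsemble | list[DisplacementEnsemble],
) -> list[DisplacementEnsemble]:
    if isinstance(receiver, DisplacementEnsemble):
        blocks = receiver.residue_split()
        if len(blocks) < 2:
            raise ValueError(
                "a lone receiver motif must span >= 2 residues to define its TC"
            )
        return blocks
    if len(receiver) < 2:
        raise ValueError("receiver must be a set of >= 2 motifs")
    return list(receiver)


def _is_static(ensemble: DisplacementEnsemble, scale: float, rel: float = 1e-12) -> bool:
    """True when the motif has no motion at the receiver's variance scale.

    A (near-)frozen motif carries no information but would make the joint
    covariance numerically degenerate, so it is short-circuited instead.
    """
    return float(ensemble.samples.var(axis=0).max()) < rel * scale


def _variance_scale(blocks: list[DisplacementEnsemble]) -> float:
    return max(float(b.samples.var(axis=0).max()) for b in blocks)


def coordination_information(
    receiver: DisplacementEnsemble | list[DisplacementEnsemble],
    transmitter: DisplacementEnsemble,
    tc_tolerance: float = 1e-12,
) -> tuple[float, float]:
    """(CI in nats, NCI in percent) of the receiver coordinated by the transmitter.

    CI = TC(receiver) - TC(receiver | transmitter); NCI = 100 * CI / TC(receiver).
    NCI is NaN (with a warning) when the receiver's TC is at tolerance level.
    A transmitter with no motion yields CI = NCI = 0 exactly.
    """
    blocks = _receiver_blocks(receiver)
    _check_disjoint(blocks + [transmitter])
    if _is_static(transmitter, _variance_scale(blocks)):
        return 0.0, 0.0
    tc = total_correlation(blocks)
    ci = tc - conditional_tc(blocks, transmitter)
    if tc <= tc_tolerance:
        warnings.warn("receiver total correlation ~ 0; NCI undefined", stacklevel=2)
        return float(ci), float("nan")
    return float(ci), float(100.0 * ci / tc)


def mutual_coordination(
    receiver: DisplacementEnsemble | list[DisplacementEnsemble],
    transmitter: DisplacementEnsemble,
    channel: DisplacementEnsemble,
    ci_tolerance: float = 1e-12,
) -> tuple[float, float]:
    """(MCI in nats, NMCI in percent): transmitter-receiver coordination
    that is also shared with the channel.

    MCI = CI(R, X_m) + CI(R, X_n) - CI(R, X_m u X_n); NMCI = 100 * MCI / CI(R, X_m).
    """
    blocks = _receiver_blocks(receiver)
    _check_disjoint(blocks + [transmitter, channel])
    scale = _variance_scale(blocks)
    if _is_static(channel, scale):
        ci_t, _ = coordination_information(blocks, transmitter)
        if abs(ci_t) <= ci_tolerance:
            warnings.warn("CI(receiver, transmitter) ~ 0; NMCI undefined", stacklevel=2)
            return 0.0, float("nan")
        return 0.0, 0.0
    ci_t, _ = coordination_information(blocks, transmitter)
    ci_c, _ = coordination_information(blocks, channel)
    union = merge_ensembles([transmitter, channel], f"{transmitter.name}+{channel.name}")
    ci_u, _ = coordination_information(blocks, union)
    mci = ci_t + ci_c - ci_u
    if abs(ci_t) <= ci_tolerance:
        warnings.warn("CI(receiver, transmitter) ~ 0; NMCI undefined", stacklevel=2)
        return float(mci), float("nan")
    return float(mci), float(100.0 * mci / ci_t)


def coordination_matrix(motifs: dict[str, DisplacementEnsemble]) -> pd.DataFrame:
    """Motif x motif table: TC (nats) on the diagonal, NCI (%) off-diagonal.

    Rows are receivers, columns transmitters; the table is generally
    asymmetric because NCI is normalized by the receiver's TC.
    """
    names = list(motifs)
    if len(names) < 2:
        raise ValueError("need >= 2 motifs")
    out = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for r in names:
        out.loc[r, r] = total_correlation(_receiver_blocks(motifs[r]))
        for t in names:
            if t == r:
                continue
            _, nci = coordination_information(motifs[r], motifs[t])
            out.loc[r, t] = nci
    return out


def channel_profile(
    receiver: DisplacementEnsemble | list[DisplacementEnsemble],
    transmitter: DisplacementEnsemble,
    candidates: dict[str, DisplacementEnsemble],
) -> pd.Series:
    """NMCI (%) with each candidate residue/motif acting as the channel."""
    values = {}
    for name, cand in candidates.items():
        try:
            _, nmci = mutual_coordination(receiver, transmitter, cand)
        except ValueError:
            nmci = float("nan")
        values[name] = nmci
    return pd.Series(values, name="NMCI_percent")


def transmitter_contribution(
    receiver: DisplacementEnsemble | list[DisplacementEnsemble],
    transmitter: DisplacementEnsemble,
) -> pd.Series:
    """Leave-one-residue-out CI drop for every transmitter residue (nats).

    contribution(r) = CI(receiver, transmitter) - CI(receiver, transmitter \\ r).
    Redundantly encoded residues can legitimately score ~ 0.
    """
    residues = sorted(transmitter.residue_blocks)
    if len(residues) < 2:
        raise ValueError("transmitter must have >= 2 residues for leave-one-out")
    ci_full, _ = coordination_information(receiver, transmitter)
    drops = {}
    for rid in residues:
        ci_wo, _ = coordination_information(receiver, transmitter.without_residue(rid))
        drops[rid] = ci_full - ci_wo
    return pd.Series(drops, name="CI_drop_nats")
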