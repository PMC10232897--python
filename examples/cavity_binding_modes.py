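"""Track a ligand's binding mode and pocket position along a trajectory.

Generates a bead-model trajectory in which a ligand hops from one binding
site to another at frame 500 (together with a planted contact-pattern
change), then classifies each frame into the two binding modes from
probe-to-site distances and reports contact probabilities for the pairs
involved in the event.
"""

import numpy as np

from allokit import cvspace, synthetic
from allokit.traj_io import AtomSelection

spec = synthetic.PlantedEventSpec(
    n_residues=20,
    states=[frozenset({(3, 12), (5, 15)}), frozenset({(3, 12), (7, 17)})],
    event_frames=(500,),
    n_frames=1000,
    ligand_sites=[3, 15],
    sigma=0.2,
    seed=0,
)
traj, truth = synthetic.gen_planted_trajectory(spec)
lig = truth.ligand_residue_id


def core(rid):
    return AtomSelection.make(residue_ids=[rid], atom_names=["CA"])


channels = {
    "ser_dist": cvspace.com_distance(traj, AtomSelection.make([lig]), core(3)),
    "trp_dist": cvspace.com_distance(traj, AtomSelection.make([lig]), core(15)),
}
modes = cvspace.classify_binding_mode(channels, d_site=6.0)
unique, counts = np.unique(modes.labels, return_counts=True)
print("binding-mode occupancy over 1000 frames:")
for mode, count in zip(unique, counts):
    print(f"  {mode}: {count} frames")

print("\ncontact probabilities (percent of frames) for the event pairs:")
for i, j in truth.switching_pairs:
    print(f"  {i:>3}-{j:<3} {cvspace.contact_probability(traj, i, j):6.1f} %")
print(
    "\nThe ligand sits at site residue 3 before frame 500 and at residue 15\n"
    "after, so the mode series splits ~50/50 and the switching pairs show\n"
    "~50 % contact probability each."
)
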