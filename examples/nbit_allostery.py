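"""Quantify allosteric coordination in a transmitter -> channel -> receiver chain.

Samples Gaussian displacement ensembles from a latent-factor network where
block A drives block B which drives block C (no direct A -> C link), then
computes the information-theoretic coordination measures: total correlation
(TC), normalized coordination information (NCI), and normalized mutual
coordination information (NMCI), which identifies B as the channel.

For a real protein system the ensembles would come from
``nbit.displacement_ensemble`` on a superposed trajectory; the motif presets
for the StarD4-cholesterol complex ship as ``nbit.STARD4_MOTIFS``.
"""

import numpy as np

from allokit import nbit, synthetic

spec = synthetic.GaussianNetworkSpec(
    latents=[
        synthetic.LatentSpec(noise_var=1.0),                        # z0
        synthetic.LatentSpec(parent=0, coeff=0.9, noise_var=0.05),  # z1 = 0.9 z0 + e
        synthetic.LatentSpec(parent=1, coeff=0.9, noise_var=0.05),  # z2 = 0.9 z1 + e
    ],
    blocks=[
        synthetic.BlockSpec("transmitter", 4, 0, noise_var=0.2),
        synthetic.BlockSpec("channel", 4, 1, noise_var=0.2),
        synthetic.BlockSpec("receiver", 6, 2, noise_var=0.2, atoms_per_residue=2),
    ],
    n_frames=100_000,
    seed=0,
)
ensembles, cov, _ = synthetic.gen_gaussian_network(spec)
t, c, r = ensembles["transmitter"], ensembles["channel"], ensembles["receiver"]

tc = nbit.total_correlation(r.residue_split())
ci, nci = nbit.coordination_information(r, t)
mci, nmci = nbit.mutual_coordination(r, t, c)

print(f"receiver internal TC:            {tc:.3f} nats")
print(f"CI(receiver <- transmitter):     {ci:.3f} nats  (NCI = {nci:.1f} %)")
print(f"MCI through the channel:         {mci:.3f} nats  (NMCI = {nmci:.1f} %)")

print("\ncoordination matrix (TC on the diagonal, NCI % off-diagonal):")
print(nbit.coordination_matrix(ensembles).round(2).to_string())
print(
    "\nNCI ~ tells how much of the receiver's internal coordination is shared\n"
    "with the transmitter; NMCI near 100 % identifies the channel block as the\n"
    "element mediating that shared information (the planted topology)."
)
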