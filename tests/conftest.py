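import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from allokit import synthetic


@pytest.fixture(scope="session")
def planted_spec():
    return synthetic.PlantedEventSpec(
        n_residues=20,
        states=[frozenset({(3, 12), (5, 15)}), frozenset({(3, 12), (7, 17)})],
        event_frames=(500,),
        n_frames=1000,
        ligand_sites=[3, 15],
        sigma=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted(planted_spec):
    """Two-state bead trajectory with a contact switch and ligand hop at frame 500."""
    return synthetic.gen_planted_trajectory(planted_spec)


@pytest.fixture(scope="session")
def contact_fixture():
    """200-pair contact matrix with 8 planted switching pairs at frame 500."""
    return synthetic.gen_contact_fixture(
        n_frames=1000, n_pairs=200, n_switching=8, n_constitutive=32,
        event_frame=500, seed=5,
    )


@pytest.fixture(scope="session")
def chain_network():
    """Gaussian chain: transmitter -> channel -> receiver (A -> B -> C)."""
    spec = synthetic.GaussianNetworkSpec(
        latents=[
            synthetic.LatentSpec(noise_var=1.0),                      # z0 drives A
            synthetic.LatentSpec(parent=0, coeff=0.9, noise_var=0.05),  # z1 drives B
            synthetic.LatentSpec(parent=1, coeff=0.9, noise_var=0.05),  # z2 drives C
        ],
        blocks=[
            synthetic.BlockSpec("A", 4, 0, loading=1.0, noise_var=0.2),
            synthetic.BlockSpec("B", 4, 1, loading=1.0, noise_var=0.2),
            synthetic.BlockSpec("C", 6, 2, loading=1.0, noise_var=0.2, atoms_per_residue=2),
        ],
        n_frames=100_000,
        seed=7,
    )
    return synthetic.gen_gaussian_network(spec)


@pytest.fixture(scope="session")
def three_state_chain():
    """Reversible (birth-death) 3-state chain with well-separated emissions."""
    tpm = np.array(
        [[0.95, 0.05, 0.00],
         [0.03, 0.92, 0.05],
         [0.00, 0.04, 0.96]]
    )
    spec = synthetic.MarkovEmissionSpec(
        tpm=tpm, means=np.eye(3) * 5.0, noise_std=0.3, n_frames=200_000, seed=13
    )
    segments, labels, _ = synthetic.gen_markov_cv(spec)
    return segments, labels, tpm
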