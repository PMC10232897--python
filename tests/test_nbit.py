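import numpy as np
import pytest

from allokit import nbit, synthetic, traj_io
from allokit.nbit import DisplacementEnsemble

import oracles
from helpers import make_traj, random_rotation


def simple_ensemble(samples, name="x", atom_base=0, residues=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < samples.shape[1]:
        samples = samples.T
    n = samples.shape[1]
    if residues is None:
        residues = list(range(atom_base, atom_base + n))
    blocks = {}
    for i, r in enumerate(residues):
        blocks.setdefault(r, []).append(i)
    blocks = {r: np.asarray(c) for r, c in blocks.items()}
    return DisplacementEnsemble(
        samples=samples,
        name=name,
        atom_ids=np.arange(atom_base, atom_base + n),
        residue_blocks=blocks,
        mode="scalar",
    )


class TestDisplacementEnsemble:
    @pytest.fixture()
    def aligned_pair(self):
        rng = np.random.default_rng(0)
        ref = make_traj(rng.uniform(-5, 5, size=(1, 6, 3)), atoms_per_residue=[2, 2, 2])
        coords = np.repeat(ref.coords, 4, axis=0)
        coords[1, 0] += np.array([3.0, 4.0, 0.0])
        traj = traj_io.Trajectory(ref.topology, coords)
        traj = traj_io.superpose(traj, ref, traj_io.AtomSelection.make(residue_ids=[2, 3]))
        return traj, ref

    def test_identical_frame_gives_zeros(self):
        rng = np.random.default_rng(1)
        ref = make_traj(rng.uniform(-5, 5, size=(1, 5, 3)))
        traj = traj_io.Trajectory(ref.topology, ref.coords.copy())
        traj = traj_io.superpose(traj, ref, traj_io.AtomSelection())
        ens = nbit.displacement_ensemble(traj, [1, 2], ref, mode="scalar")
        np.testing.assert_allclose(ens.samples, 0.0, atol=1e-10)

    def test_three_four_five_displacement(self, aligned_pair):
        traj, ref = aligned_pair
        ens = nbit.displacement_ensemble(traj, [1], ref, mode="scalar")
        assert ens.samples[1, 0] == pytest.approx(5.0, abs=0.2)

    def test_scalar_equals_vector_row_norms(self, aligned_pair):
        traj, ref = aligned_pair
        scal = nbit.displacement_ensemble(traj, [1, 2], ref, mode="scalar")
        vec = nbit.displacement_ensemble(traj, [1, 2], ref, mode="vector")
        norms = np.linalg.norm(vec.samples.reshape(vec.n_frames, -1, 3), axis=2)
        np.testing.assert_allclose(scal.samples, norms, atol=1e-12)

    def test_unaligned_trajectory_rejected(self):
        traj = make_traj(np.zeros((3, 4, 3)))
        with pytest.raises(ValueError, match="superpos"):
            nbit.displacement_ensemble(traj, [1], traj, mode="scalar")


class TestEntropy:
    def test_unit_gaussian_closed_form(self):
        rng = np.random.default_rng(2)
        h = nbit.entropy(rng.standard_normal(100_000))
        assert h == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.01)

    def test_variance_scaling_law(self):
        rng = np.random.default_rng(3)
        h = nbit.entropy(2.0 * rng.standard_normal(100_000))
        assert h == pytest.approx(0.5 * np.log(2 * np.pi * np.e) + 0.5 * np.log(4), abs=0.01)

    def test_trivariate_known_covariance(self):
        rng = np.random.default_rng(4)
        cov = np.array([[2.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.5]])
        x = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        expected = 0.5 * (3 * np.log(2 * np.pi * np.e) + np.log(np.linalg.det(cov)))
        assert nbit.entropy(x) == pytest.approx(expected, abs=0.01)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((5000, 3))
        assert abs(nbit.entropy(x) - nbit.entropy(x + 123.4)) < 1e-10

    def test_rank_deficient_warns(self):
        x = np.random.default_rng(6).standard_normal((4, 10))
        with pytest.warns(UserWarning, match="rank-deficient"):
            nbit.entropy(x)


class TestTotalCorrelation:
    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(7)
        a = simple_ensemble(rng.standard_normal((50_000, 2)), "a", 0)
        b = simple_ensemble(rng.standard_normal((50_000, 2)), "b", 2)
        assert abs(nbit.total_correlation([a, b])) < 0.005

    def test_bivariate_closed_form(self):
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        x = rng.multivariate_normal(np.zeros(2), cov, size=200_000)
        a = simple_ensemble(x[:, :1], "a", 0)
        b = simple_ensemble(x[:, 1:], "b", 1)
        assert nbit.total_correlation([a, b]) == pytest.approx(-0.5 * np.log(0.19), rel=0.02)

    def test_shared_latent_matches_generator_covariance(self, chain_network):
        ensembles, cov, slices = chain_network
        got = nbit.total_correlation([ensembles["A"], ensembles["B"], ensembles["C"]])
        target = oracles.tc_cov(cov, [slices["A"], slices["B"], slices["C"]])
        assert got == pytest.approx(target, rel=0.05)

    def test_overlapping_motifs_rejected(self):
        rng = np.random.default_rng(9)
        a = simple_ensemble(rng.standard_normal((100, 2)), "a", 0)
        with pytest.raises(ValueError, match="overlap"):
            nbit.total_correlation([a, a])

    def test_non_negative(self, chain_network):
        ensembles, _, _ = chain_network
        for pair in (["A", "B"], ["B", "C"], ["A", "C"]):
            tc = nbit.total_correlation([ensembles[p] for p in pair])
            assert tc > -1e-9


class TestConditionalTC:
    def test_independent_conditioner_leaves_tc(self):
        rng = np.random.default_rng(10)
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        x = rng.multivariate_normal(np.zeros(2), cov, size=100_000)
        a = simple_ensemble(x[:, :1], "a", 0)
        b = simple_ensemble(x[:, 1:], "b", 1)
        c = simple_ensemble(rng.standard_normal((100_000, 2)), "c", 2)
        tc = nbit.total_correlation([a, b])
        ctc = nbit.conditional_tc([a, b], c)
        assert ctc == pytest.approx(tc, abs=0.01)

    def test_shielding_conditioner_kills_tc(self):
        """Blocks correlated only through a shared factor: conditioning on a
        near-noiseless copy of that factor removes the correlation."""
        rng = np.random.default_rng(11)
        z = rng.standard_normal((100_000, 1))
        a = simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "a", 0)
        b = simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "b", 1)
        c = simple_ensemble(z + 0.001 * rng.standard_normal((100_000, 1)), "c", 2)
        ctc = nbit.conditional_tc([a, b], c)
        assert abs(ctc) < 0.01 * nbit.total_correlation([a, b])

    def test_matches_schur_complement_oracle(self, chain_network):
        ensembles, cov, slices = chain_network
        got = nbit.conditional_tc([ensembles["A"], ensembles["C"]], ensembles["B"])
        target = oracles.ctc_cov(cov, [slices["A"], slices["C"]], slices["B"])
        assert got == pytest.approx(target, abs=0.02)


class TestCoordinationInformation:
    def test_independent_transmitter_zero(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((100_000, 1))
        recv = [
            simple_ensemble(z + 0.5 * rng.standard_normal((100_000, 1)), "r1", 0),
            simple_ensemble(z + 0.5 * rng.standard_normal((100_000, 1)), "r2", 1),
        ]
        trans = simple_ensemble(rng.standard_normal((100_000, 2)), "t", 2)
        ci, nci = nbit.coordination_information(recv, trans)
        assert abs(ci) < 0.01
        assert abs(nci) < 3.0

    def test_transmitter_carrying_shared_factor_saturates(self):
        rng = np.random.default_rng(13)
        z = rng.standard_normal((100_000, 1))
        recv = [
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r1", 0),
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r2", 1),
        ]
        trans = simple_ensemble(z + 0.001 * rng.standard_normal((100_000, 1)), "t", 2)
        _, nci = nbit.coordination_information(recv, trans)
        assert nci > 97.0

    def test_chain_matches_covariance_oracle(self, chain_network):
        ensembles, cov, slices = chain_network
        # receiver C split into residue blocks, transmitter A
        ci, nci = nbit.coordination_information(ensembles["C"], ensembles["A"])
        r_blocks = [slices["C"][:2], slices["C"][2:4], slices["C"][4:]]
        target_nci = oracles.nci_cov(cov, r_blocks, slices["A"])
        assert nci == pytest.approx(target_nci, abs=0.05 * target_nci)

    def test_lone_single_residue_receiver_rejected(self):
        rng = np.random.default_rng(14)
        recv = simple_ensemble(rng.standard_normal((100, 2)), "r", 0, residues=[0, 0])
        trans = simple_ensemble(rng.standard_normal((100, 1)), "t", 5)
        with pytest.raises(ValueError, match=">= 2"):
            nbit.coordination_information(recv, trans)


class TestMutualCoordination:
    def test_chain_channel_near_full_bypass_near_zero(self, chain_network):
        ensembles, _, _ = chain_network
        # information from A reaches C only through B -> B as channel ~ 100%
        _, nmci_chain = nbit.mutual_coordination(ensembles["C"], ensembles["A"], ensembles["B"])
        assert nmci_chain > 80.0
        # an independent block is no channel at all
        rng = np.random.default_rng(15)
        bypass = simple_ensemble(rng.standard_normal((ensembles["A"].n_frames, 3)), "ind", 900)
        _, nmci_bypass = nbit.mutual_coordination(ensembles["C"], ensembles["A"], bypass)
        assert abs(nmci_bypass) < 10.0

    def test_channel_copying_transmitter_saturates(self):
        rng = np.random.default_rng(16)
        z = rng.standard_normal((100_000, 1))
        recv = [
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r1", 0),
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r2", 1),
        ]
        trans = simple_ensemble(z + 0.2 * rng.standard_normal((100_000, 1)), "t", 2)
        chan = simple_ensemble(
            trans.samples + 0.001 * rng.standard_normal((100_000, 1)), "c", 3
        )
        _, nmci = nbit.mutual_coordination(recv, trans, chan)
        assert nmci > 95.0

    def test_independent_channel_mci_near_zero(self, chain_network):
        ensembles, _, _ = chain_network
        rng = np.random.default_rng(17)
        indep = simple_ensemble(rng.standard_normal((ensembles["A"].n_frames, 2)), "i", 950)
        mci, _ = nbit.mutual_coordination(ensembles["C"], ensembles["A"], indep)
        assert abs(mci) < 0.02


class TestBruteForceAgreement:
    def test_all_measures_match_subdeterminant_oracle(self, chain_network):
        """Sample-covariance evaluation agrees with the one-shot joint-covariance
        oracle to 1e-9 (well-conditioned, <= 50 variables)."""
        ensembles, _, _ = chain_network
        a, b, c = ensembles["A"], ensembles["B"], ensembles["C"]
        joint = np.concatenate([a.samples, b.samples, c.samples], axis=1)
        cov = np.cov(joint, rowvar=False)
        ia = np.arange(a.n_vars)
        ib = np.arange(a.n_vars, a.n_vars + b.n_vars)
        ic = np.arange(a.n_vars + b.n_vars, joint.shape[1])

        assert nbit.entropy(a) == pytest.approx(oracles.entropy_cov(cov, ia), abs=1e-9)
        assert nbit.total_correlation([a, b, c]) == pytest.approx(
            oracles.tc_cov(cov, [ia, ib, ic]), abs=1e-9
        )
        assert nbit.conditional_tc([a, c], b) == pytest.approx(
            oracles.ctc_cov(cov, [ia, ic], ib), abs=1e-9
        )
        ci, nci = nbit.coordination_information([a, c], b)
        assert ci == pytest.approx(oracles.ci_cov(cov, [ia, ic], ib), abs=1e-9)
        assert nci == pytest.approx(oracles.nci_cov(cov, [ia, ic], ib), abs=1e-7)
        c_blocks = [ic[:2], ic[2:4], ic[4:]]
        mci, nmci = nbit.mutual_coordination(c, a, b)
        assert mci == pytest.approx(oracles.mci_cov(cov, c_blocks, ia, ib), abs=1e-9)
        assert nmci == pytest.approx(oracles.nmci_cov(cov, c_blocks, ia, ib), abs=1e-6)


class TestCoordinationMatrix:
    def test_layout_and_independence(self):
        rng = np.random.default_rng(18)
        motifs = {
            "a": simple_ensemble(rng.standard_normal((50_000, 2)), "a", 0),
            "b": simple_ensemble(rng.standard_normal((50_000, 2)), "b", 2),
        }
        table = nbit.coordination_matrix(motifs)
        assert table.shape == (2, 2)
        assert abs(table.loc["a", "b"]) < 5.0
        assert abs(table.loc["b", "a"]) < 5.0

    def test_diagonal_is_receiver_tc(self, chain_network):
        ensembles, _, _ = chain_network
        motifs = {"A": ensembles["A"], "C": ensembles["C"]}
        table = nbit.coordination_matrix(motifs)
        assert table.loc["C", "C"] == pytest.approx(
            nbit.total_correlation(ensembles["C"].residue_split())
        )

    def test_asymmetric_for_unequal_receiver_tc(self, chain_network):
        ensembles, _, _ = chain_network
        motifs = {"A": ensembles["A"], "B": ensembles["B"], "C": ensembles["C"]}
        table = nbit.coordination_matrix(motifs)
        assert table.loc["A", "C"] != pytest.approx(table.loc["C", "A"], abs=1e-6)


class TestChannelProfileAndContribution:
    def test_on_path_residues_outrank_off_path(self, chain_network):
        ensembles, _, _ = chain_network
        rng = np.random.default_rng(19)
        candidates = {"on_path": ensembles["B"]}
        candidates["off_path"] = simple_ensemble(
            rng.standard_normal((ensembles["B"].n_frames, 4)), "off", 970
        )
        profile = nbit.channel_profile(ensembles["C"], ensembles["A"], candidates)
        assert profile["on_path"] > profile["off_path"] + 30.0

    def test_zero_variance_candidate_scores_nothing(self, chain_network):
        ensembles, _, _ = chain_network
        frozen = simple_ensemble(
            np.full((ensembles["A"].n_frames, 2), 3.7)
            + 1e-9 * np.random.default_rng(20).standard_normal((ensembles["A"].n_frames, 2)),
            "frozen",
            980,
        )
        profile = nbit.channel_profile(ensembles["C"], ensembles["A"], {"frozen": frozen})
        assert abs(profile["frozen"]) < 5.0

    def test_deterministic_given_ensemble(self, chain_network):
        ensembles, _, _ = chain_network
        args = (ensembles["C"], ensembles["A"], {"b": ensembles["B"]})
        p1 = nbit.channel_profile(*args)
        p2 = nbit.channel_profile(*args)
        assert p1.equals(p2)

    def test_single_signal_residue_dominates_contribution(self):
        rng = np.random.default_rng(21)
        z = rng.standard_normal((100_000, 1))
        recv = [
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r1", 0),
            simple_ensemble(z + 0.3 * rng.standard_normal((100_000, 1)), "r2", 1),
        ]
        # transmitter: residue 10 carries the factor, residue 11 pure noise
        t_samples = np.column_stack(
            [z[:, 0] + 0.1 * rng.standard_normal(100_000), rng.standard_normal(100_000)]
        )
        trans = simple_ensemble(t_samples, "t", 5, residues=[10, 11])
        contrib = nbit.transmitter_contribution(recv, trans)
        ci_full, _ = nbit.coordination_information(recv, trans)
        assert contrib[10] == pytest.approx(ci_full, rel=0.1)
        assert abs(contrib[11]) < 0.05 * ci_full

    def test_redundant_residues_contribute_nothing(self):
        rng = np.random.default_rng(22)
        z = rng.standard_normal((50_000, 1))
        recv = [
            simple_ensemble(z + 0.3 * rng.standard_normal((50_000, 1)), "r1", 0),
            simple_ensemble(z + 0.3 * rng.standard_normal((50_000, 1)), "r2", 1),
        ]
        t_samples = np.column_stack(
            [z[:, 0] + 0.1 * rng.standard_normal(50_000), z[:, 0] + 0.1 * rng.standard_normal(50_000)]
        )
        trans = simple_ensemble(t_samples, "t", 5, residues=[10, 11])
        contrib = nbit.transmitter_contribution(recv, trans)
        ci_full, _ = nbit.coordination_information(recv, trans)
        assert contrib.abs().max() < 0.2 * ci_full

    def test_single_residue_transmitter_rejected(self, chain_network):
        ensembles, _, _ = chain_network
        single = simple_ensemble(
            ensembles["A"].samples[:, :1], "s", 990, residues=[500]
        )
        with pytest.raises(ValueError, match=">= 2 residues"):
            nbit.transmitter_contribution(ensembles["C"], single)


class TestGeometryInvariance:
    def test_measures_invariant_under_rigid_motion_of_input(self, planted):
        """Superposition absorbs any global rotation+translation, so NbIT
        measures computed downstream are unchanged to numerical precision."""
        traj, truth = planted
        ref = traj_io.Trajectory(traj.topology, traj.coords[:1].copy())
        sel = traj_io.AtomSelection.make(atom_names=["CA"])
        sub = traj_io.Trajectory(traj.topology, traj.coords[:200])

        rng = np.random.default_rng(23)
        rot = random_rotation(rng)
        moved = traj_io.Trajectory(
            traj.topology, np.einsum("fad,ed->fae", sub.coords, rot) + 40.0
        )

        def measures(t):
            aligned = traj_io.superpose(t, ref, sel)
            m1 = nbit.displacement_ensemble(aligned, [5, 15], ref, name="m1")
            m2 = nbit.displacement_ensemble(aligned, [7, 17], ref, name="m2")
            return nbit.total_correlation([m1, m2])

        assert abs(measures(sub) - measures(moved)) < 1e-8


def test_sampling_consistency_between_n_and_4n(chain_network):
    """TC at n frames and 4n frames agree within the 95% bootstrap band at n."""
    ensembles, _, _ = chain_network
    a, b = ensembles["A"], ensembles["B"]
    n = 20_000
    sub_a, sub_b = a.samples[:n], b.samples[:n]

    def tc_of(xa, xb):
        return nbit.total_correlation(
            [simple_ensemble(xa, "a", 0), simple_ensemble(xb, "b", 10)]
        )

    tc_n = tc_of(sub_a, sub_b)
    tc_4n = tc_of(a.samples[: 4 * n], b.samples[: 4 * n])
    rng = np.random.default_rng(24)
    boot = []
    for _ in range(40):
        idx = rng.integers(0, n, size=n)
        boot.append(tc_of(sub_a[idx], sub_b[idx]))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    half_width = max(hi - tc_n, tc_n - lo)
    assert abs(tc_4n - tc_n) <= half_width
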