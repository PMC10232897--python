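import numpy as np
import pytest

from allokit import contacts, red, synthetic
from allokit.contacts import ContactTimeSeries


def series_from(values, smoothed=True, **kw):
    values = np.asarray(values, dtype=float)
    pairs = [(1, j + 2) for j in range(values.shape[1])]
    return ContactTimeSeries(values, pairs, smoothed=smoothed, window_frames=1, **kw)


@pytest.fixture(scope="module")
def fitted_fixture(contact_fixture):
    cts, truth = contact_fixture
    smoothed = contacts.smooth(cts, 25)
    model = red.fit_red(smoothed, c=2, seed=0)
    constitutive = red.identify_constitutive_pairs(model)
    return red.normalize_components(model, constitutive), truth, constitutive


class TestFit:
    def test_exact_low_rank_input_reconstructed(self):
        rng = np.random.default_rng(0)
        x = rng.random((300, 2)) @ rng.random((2, 40))
        x /= x.max()  # exactly rank-2, values in [0, 1]
        model = red.fit_red(series_from(x), c=2, seed=0, max_iter=20000, tol=1e-14)
        rel = np.linalg.norm(x - model.reconstruction()) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_error_non_increasing_in_components(self):
        rng = np.random.default_rng(1)
        x = np.clip(rng.random((200, 2)) @ rng.random((2, 30)), 0, 1)
        errs = [
            red.fit_red(series_from(x), c=c, seed=0).reconstruction_error for c in (2, 3, 4)
        ]
        assert errs[0] >= errs[1] >= errs[2] - 1e-12

    def test_negative_input_rejected(self):
        x = np.zeros((50, 4))
        cts = series_from(x)
        cts.values[0, 0] = -0.1  # bypass container validation deliberately
        with pytest.raises(ValueError, match="negative"):
            red.fit_red(cts, c=2)

    def test_deterministic_given_seed(self, contact_fixture):
        cts, _ = contact_fixture
        smoothed = contacts.smooth(cts, 25)
        a = red.fit_red(smoothed, c=3, seed=42, init="random")
        b = red.fit_red(smoothed, c=3, seed=42, init="random")
        np.testing.assert_array_equal(a.spatial, b.spatial)


class TestConstitutivePairs:
    def test_exact_recovery_of_designed_pairs(self):
        cts, truth = synthetic.gen_contact_fixture(
            n_frames=600, n_pairs=60, n_switching=4, n_constitutive=10,
            event_frame=300, noise_mean_range=(0.1, 0.4), seed=3,
        )
        model = red.fit_red(contacts.smooth(cts, 25), c=3, seed=0)
        found = red.identify_constitutive_pairs(model)
        assert set(found) == set(truth.constitutive_pairs)

    def test_uniform_pair_selected_single_component_excluded(self):
        spatial = np.array([[1.0, 1.0, 0.0], [1.0, 0.1, 0.9]])
        model = red.REDModel(
            spatial=spatial,
            temporal=np.ones((10, 2)),
            pair_index=[(1, 2), (1, 3), (1, 4)],
            reconstruction_error=0.0,
            seed=None,
            iterations=1,
        )
        found = red.identify_constitutive_pairs(model, cv_max=0.15, mean_min=0.5)
        assert found == [(1, 2)]

    def test_empty_result_advises(self):
        model = red.REDModel(
            spatial=np.array([[1.0, 0.0], [0.0, 1.0]]),
            temporal=np.ones((5, 2)),
            pair_index=[(1, 2), (1, 3)],
            reconstruction_error=0.0,
            seed=None,
            iterations=1,
        )
        with pytest.raises(ValueError, match="relax"):
            red.identify_constitutive_pairs(model)


class TestNormalization:
    def test_constitutive_mean_is_one_everywhere(self, fitted_fixture):
        model, _, constitutive = fitted_fixture
        cols = [model.pair_index.index(p) for p in constitutive]
        np.testing.assert_allclose(model.spatial[:, cols].mean(axis=1), 1.0, atol=1e-12)

    def test_reconstruction_unchanged(self, contact_fixture):
        cts, _ = contact_fixture
        model = red.fit_red(contacts.smooth(cts, 25), c=2, seed=0)
        normalized = red.normalize_components(model, red.identify_constitutive_pairs(model))
        delta = np.abs(model.reconstruction() - normalized.reconstruction()).max()
        assert delta < 1e-10

    def test_sdcp_values_may_exceed_one(self, fitted_fixture):
        model, _, _ = fitted_fixture
        assert model.spatial.max() > 1.0

    def test_empty_constitutive_set_rejected(self, contact_fixture):
        cts, _ = contact_fixture
        model = red.fit_red(contacts.smooth(cts, 25), c=2, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            red.normalize_components(model, [])


class TestSDCP:
    def test_planted_pairs_recovered_with_directions(self, fitted_fixture):
        model, truth, _ = fitted_fixture
        _, labels, _ = red.dominance_timeline(model)
        table = red.extract_sdcps(model, int(labels[0]), int(labels[-1]), k_sigma=4.0)
        found = {(r.res_i, r.res_j): r.direction for r in table.itertuples()}
        expected = dict(zip(truth.switching_pairs, truth.switching_directions))
        assert found == expected

    def test_identical_components_give_empty_table(self):
        spatial = np.vstack([np.ones(5), np.ones(5)])
        model = red.REDModel(
            spatial=spatial,
            temporal=np.ones((10, 2)),
            pair_index=[(1, k + 2) for k in range(5)],
            reconstruction_error=0.0,
            seed=None,
            iterations=1,
            normalization_factors=np.ones(2),
        )
        assert red.extract_sdcps(model, 0, 1).empty

    def test_zero_sigma_returns_all_nonzero_deltas(self, fitted_fixture):
        model, _, _ = fitted_fixture
        table = red.extract_sdcps(model, 0, 1, k_sigma=0.0)
        delta = model.spatial[1] - model.spatial[0]
        assert len(table) == int(np.sum(delta != 0))

    def test_requires_normalized_model(self, contact_fixture):
        cts, _ = contact_fixture
        model = red.fit_red(contacts.smooth(cts, 25), c=2, seed=0)
        with pytest.raises(ValueError, match="normalized"):
            red.extract_sdcps(model, 0, 1)


class TestDominanceTimeline:
    def test_single_transition_at_planted_event(self, fitted_fixture):
        model, truth, _ = fitted_fixture
        _, labels, transitions = red.dominance_timeline(model)
        assert len(set(labels)) == 2
        assert len(transitions) >= 1
        # every dominance change lies within a smoothing window of the event
        for t in transitions:
            assert abs(t - truth.event_frames[0]) <= 25

    def test_weights_non_negative(self, fitted_fixture):
        model, _, _ = fitted_fixture
        weights, _, _ = red.dominance_timeline(model)
        assert (weights >= 0).all()


class TestComponentMatching:
    def test_permutation_recovered(self, fitted_fixture):
        model, _, _ = fitted_fixture
        perm = [1, 0]
        permuted = red.REDModel(
            spatial=model.spatial[perm],
            temporal=model.temporal[:, perm],
            pair_index=model.pair_index,
            reconstruction_error=model.reconstruction_error,
            seed=model.seed,
            iterations=model.iterations,
        )
        assert red.match_components(model, permuted) == perm

    def test_sdcps_transform_consistently_under_relabeling(self, fitted_fixture):
        model, _, _ = fitted_fixture
        perm = [1, 0]
        permuted = red.REDModel(
            spatial=model.spatial[perm],
            temporal=model.temporal[:, perm],
            pair_index=model.pair_index,
            reconstruction_error=model.reconstruction_error,
            seed=model.seed,
            iterations=model.iterations,
            normalization_factors=model.normalization_factors[perm],
        )
        a = red.extract_sdcps(model, 0, 1)
        b = red.extract_sdcps(permuted, 1, 0)
        assert set(zip(a.res_i, a.res_j, a.direction)) == set(
            zip(b.res_i, b.res_j, b.direction)
        )


def test_joint_fit_generalizes_across_replicas():
    """SDCPs from a joint two-replica fit overlap each per-replica fit (Jaccard >= 0.8)."""
    cts, truth = synthetic.gen_contact_fixture(
        n_frames=800, n_pairs=120, n_switching=6, n_constitutive=24,
        event_frame=400, n_replicas=2, seed=9,
    )
    smoothed = contacts.smooth(cts, 25)

    def sdcp_set(series):
        model = red.fit_red(series, c=2, seed=0)
        model = red.normalize_components(model, red.identify_constitutive_pairs(model))
        _, labels, _ = red.dominance_timeline(model)
        table = red.extract_sdcps(model, int(labels[0]), int(labels[-1]), k_sigma=4.0)
        return set(zip(table.res_i, table.res_j))

    joint = sdcp_set(smoothed)
    for seg in smoothed.segment_slices():
        single = sdcp_set(
            ContactTimeSeries(
                smoothed.values[seg], smoothed.pair_index, smoothed=True, window_frames=25
            )
        )
        jaccard = len(joint & single) / len(joint | single)
        assert jaccard >= 0.8
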