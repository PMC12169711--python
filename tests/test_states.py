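"""State clustering, label matching, and dwell-time computation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import airdfc as a


@pytest.fixture(scope="module")
def planted_windows(templates):
    """Window vectors around 5 well-separated templates, noise sd 0.1."""
    rng = np.random.default_rng(21)
    labels = rng.integers(0, 5, 3000)
    vectors = a.simulate_window_vectors(templates, labels, noise_sd=0.1, seed=22)
    return labels, vectors


class TestFitStates:
    def test_planted_partition_recovery(self, planted_windows):
        labels, vectors = planted_windows
        model = a.fit_states(vectors, k=5, seed=0, n_restarts=5)
        found = a.assign_states(vectors, model)
        assert adjusted_rand_score(labels, found) > 0.9

    def test_k1_centroid_is_grand_mean(self, rng):
        x = rng.standard_normal((50, 6))
        model = a.fit_states(x, k=1, seed=0, n_restarts=1)
        np.testing.assert_allclose(model.centroids[0], x.mean(axis=0), atol=1e-8)

    def test_deterministic_given_seed(self, planted_windows):
        _, vectors = planted_windows
        m1 = a.fit_states(vectors, k=5, seed=3, n_restarts=2)
        m2 = a.fit_states(vectors, k=5, seed=3, n_restarts=2)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_restarts_only_improve_inertia(self, planted_windows):
        _, vectors = planted_windows
        few = a.fit_states(vectors, k=5, seed=0, n_restarts=1)
        many = a.fit_states(vectors, k=5, seed=0, n_restarts=5)
        assert many.inertia <= few.inertia + 1e-9

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            a.fit_states(rng.standard_normal((30, 4)), k=5)

    def test_fewer_distinct_vectors_than_k_rejected(self):
        x = np.tile(np.array([[1.0, 0.0], [0.0, 1.0]]), (30, 1))
        with pytest.raises(ValueError, match="distinct"):
            a.fit_states(x, k=3)


class TestMatchStates:
    def test_identity_match(self, templates):
        ref = a.StateModel(templates.zvectors())
        match = a.match_states(ref, ref)
        np.testing.assert_array_equal(match.permutation, np.arange(5))
        np.testing.assert_allclose(match.correlations, 1.0)

    def test_cyclic_shift_recovered(self, templates):
        z = templates.zvectors()
        shifted = a.StateModel(np.roll(z, 2, axis=0))  # shifted label i holds z[(i-2) % 5]
        match = a.match_states(shifted, a.StateModel(z))
        np.testing.assert_array_equal(match.permutation, (np.arange(5) - 2) % 5)

    def test_matches_brute_force_over_permutations(self, rng):
        """Hungarian result ties the exhaustive best over all 3! = 6
        permutations of 3 random centroids."""
        z = rng.standard_normal((3, 10))
        perm = np.array([2, 0, 1])
        model = a.StateModel(z[perm])
        match = a.match_states(model, a.StateModel(z))
        corr = np.corrcoef(z[perm], z)[:3, 3:]
        best = max(itertools.permutations(range(3)), key=lambda p: sum(corr[i, p[i]] for i in range(3)))
        np.testing.assert_array_equal(match.permutation, best)
        np.testing.assert_array_equal(match.permutation, perm)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            a.match_states(a.StateModel(rng.standard_normal((3, 5))), a.StateModel(rng.standard_normal((3, 6))))


class TestAssignStates:
    def test_centroids_assign_to_themselves(self, templates):
        model = a.StateModel(templates.zvectors())
        np.testing.assert_array_equal(a.assign_states(model.centroids, model), np.arange(5))

    def test_tie_breaks_to_lowest_label(self):
        model = a.StateModel(np.array([[0.0], [1.0], [2.0], [3.0]]))
        assert a.assign_states(np.array([[2.0]]), model)[0] == 2
        assert a.assign_states(np.array([[2.5]]), model)[0] == 2  # tie between 2 and 3

    def test_planted_assignment_accuracy(self, planted_windows, templates):
        labels, vectors = planted_windows
        model = a.fit_states(vectors, k=5, seed=0, n_restarts=5)
        match = a.match_states(model, a.StateModel(templates.zvectors()))
        relabeled = match.relabel(a.assign_states(vectors, model))
        assert (relabeled == labels).mean() > 0.9


class TestMeanDwellTime:
    def test_hand_counted_runs(self):
        res = a.mean_dwell_time(np.array([0, 0, 1, 1, 1, 0]), k=2)
        np.testing.assert_allclose(res.dwell, [1.5, 3.0])
        np.testing.assert_allclose(res.fraction, [0.5, 0.5])

    def test_constant_sequence(self):
        res = a.mean_dwell_time(np.zeros(40, dtype=int), k=3)
        assert res.dwell[0] == 40.0 and res.fraction[0] == 1.0
        assert np.isnan(res.dwell[1]) and res.fraction[1] == 0.0

    def test_alternating_sequence(self):
        res = a.mean_dwell_time(np.array([0, 1] * 10), k=2)
        np.testing.assert_allclose(res.dwell, [1.0, 1.0])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            a.mean_dwell_time(np.array([], dtype=int), k=2)

    def _brute_force(self, seq, k):
        dwell = np.full(k, np.nan)
        runs = {s: [] for s in range(k)}
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            runs[seq[i]].append(j - i)
            i = j
        frac = np.zeros(k)
        for s in range(k):
            if runs[s]:
                dwell[s] = float(np.mean(runs[s]))
                frac[s] = sum(runs[s]) / len(seq)
        return dwell, frac

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_run_length_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = rng.integers(0, 4, rng.integers(1, 200))
        res = a.mean_dwell_time(seq, k=4)
        dwell, frac = self._brute_force(list(seq), 4)
        np.testing.assert_allclose(res.dwell, dwell)
        np.testing.assert_allclose(res.fraction, frac)
        assert res.fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dwell_table_shape(self):
        table = a.dwell_table({("p1", 1): np.array([0, 0, 1]), ("p1", 2): np.array([1, 1, 1])}, k=2)
        assert len(table) == 4
        assert set(table.columns) == {"participant", "visit", "state", "dwell", "fraction"}
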