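"""Affinity propagation: message algebra, convergence, clustering quality."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from topichotspots import (
    APConfig,
    AffinityPropagation,
    affinity_propagation,
    build_similarity,
    cosine_similarity,
    make_planted_vectors,
)
from topichotspots.ap import (
    SimilarityMatrix,
    extract_exemplars,
    update_availability,
    update_responsibility,
)

# Fixed 3x3 similarity (preference -2 on the diagonal) used for the
# hand-traced message fixtures below.
S33 = np.array(
    [
        [-2.0, -1.5, -4.0],
        [-1.5, -2.0, -3.0],
        [-4.0, -3.0, -2.0],
    ]
)
# Cell-by-cell trace of r(i,k) = s(i,k) - max_{k'!=k}[a(i,k') + s(i,k')]
# with A = 0, then damped by 0.5 from R_prev = 0.
R33_EXPECTED = 0.5 * np.array(
    [
        [-0.5, 0.5, -2.5],
        [0.5, -0.5, -1.5],
        [-2.0, -1.0, 1.0],
    ]
)
# Trace of the availability rules applied to R33_EXPECTED, damped by 0.5
# from A_prev = 0.
A33_EXPECTED = 0.5 * np.array(
    [
        [0.25, -0.25, 0.0],
        [-0.25, 0.25, 0.0],
        [0.0, 0.0, 0.0],
    ]
)


def _responsibility_oracle(S, A):
    n = S.shape[0]
    R = np.empty_like(S)
    for i in range(n):
        for k in range(n):
            R[i, k] = S[i, k] - max(
                A[i, kp] + S[i, kp] for kp in range(n) if kp != k
            )
    return R


def _availability_oracle(R):
    n = R.shape[0]
    A = np.empty_like(R)
    for i in range(n):
        for k in range(n):
            if i == k:
                A[k, k] = sum(max(0.0, R[ip, k]) for ip in range(n) if ip != k)
            else:
                A[i, k] = min(
                    0.0,
                    R[k, k]
                    + sum(
                        max(0.0, R[ip, k])
                        for ip in range(n)
                        if ip not in (i, k)
                    ),
                )
    return A


def _net_similarity(S, exemplars):
    """Objective: sum of each item's similarity to its exemplar plus the
    exemplar preferences (S diagonal)."""
    exemplars = list(exemplars)
    total = sum(S[k, k] for k in exemplars)
    for i in range(S.shape[0]):
        if i not in exemplars:
            total += max(S[i, k] for k in exemplars)
    return total


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 0], [1, 0], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 1], [1, 0], 1 / np.sqrt(2)),
        ],
    )
    def test_closed_forms(self, x, y, expected):
        assert cosine_similarity(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


class TestBuildSimilarity:
    def test_identical_items_give_minus_one(self):
        sim = build_similarity(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert sim.S[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_items_clamped(self):
        sim = build_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert sim.S[0, 1] == pytest.approx(-1e12)

    def test_within_group_beats_between_group(self):
        vectors, labels = make_planted_vectors(3, 3, V=60, separation=50, seed=0)
        sim = build_similarity(vectors)
        n = len(labels)
        within = [
            sim.S[i, j]
            for i in range(n)
            for j in range(n)
            if i != j and labels[i] == labels[j]
        ]
        between = [
            sim.S[i, j]
            for i in range(n)
            for j in range(n)
            if labels[i] != labels[j]
        ]
        assert min(within) > max(between)

    def test_cosine_convention(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        sim = build_similarity(X, similarity="cosine")
        assert sim.S[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_preference_strategies(self):
        X = np.array([[1.0, 0.1], [0.1, 1.0], [1.0, 1.0]])
        med = build_similarity(X, "median")
        low = build_similarity(X, "min")
        fixed = build_similarity(X, -7.5)
        off = med.S[~np.eye(3, dtype=bool)]
        assert med.preference[0] == pytest.approx(np.median(off))
        assert low.preference[0] == pytest.approx(off.min())
        assert fixed.preference[0] == -7.5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_similarity(np.array([[1.0, 2.0]]))  # n < 2
        with pytest.raises(ValueError):
            build_similarity(np.array([[1.0, np.nan], [1.0, 1.0]]))


class TestMessageUpdates:
    def test_hand_traced_responsibility(self):
        R = update_responsibility(S33, np.zeros((3, 3)), np.zeros((3, 3)), 0.5)
        assert np.max(np.abs(R - R33_EXPECTED)) < 1e-12

    def test_hand_traced_availability(self):
        A = update_availability(R33_EXPECTED, np.zeros((3, 3)), 0.5)
        assert np.max(np.abs(A - A33_EXPECTED)) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_scalar_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        lam = 0.5
        S = rng.normal(size=(n, n))
        A = -rng.random((n, n))
        np.fill_diagonal(A, rng.random(n))
        R = update_responsibility(S, A, np.zeros((n, n)), lam)
        expected = (1 - lam) * _responsibility_oracle(S, A)
        assert np.max(np.abs(R - expected)) < 1e-12
        R2 = rng.normal(size=(n, n))
        A2 = update_availability(R2, np.zeros((n, n)), lam)
        expected = (1 - lam) * _availability_oracle(R2)
        assert np.max(np.abs(A2 - expected)) < 1e-12

    def test_damping_endpoint_freezes_messages(self):
        lam = 1 - 1e-12
        R = update_responsibility(S33, np.zeros((3, 3)), np.zeros((3, 3)), lam)
        assert np.max(np.abs(R)) < 1e-9

    def test_responsibility_with_zero_availability_reduces_to_s_margin(self):
        raw = update_responsibility(
            S33, np.zeros((3, 3)), np.zeros((3, 3)), 1e-15
        )
        expected = _responsibility_oracle(S33, np.zeros((3, 3)))
        assert np.max(np.abs(raw - expected)) < 1e-12

    def test_availability_with_all_negative_r(self):
        R = -np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 2.0], [3.0, 2.0, 1.0]])
        raw = update_availability(R, np.zeros((3, 3)), 1e-15)
        for i in range(3):
            for k in range(3):
                if i == k:
                    assert raw[k, k] == pytest.approx(0.0, abs=1e-12)
                else:
                    assert raw[i, k] == pytest.approx(R[k, k], abs=1e-12)

    def test_off_diagonal_availability_never_positive(self):
        rng = np.random.default_rng(7)
        R = rng.normal(size=(5, 5))
        A = update_availability(R, np.zeros((5, 5)), 0.3)
        off = A[~np.eye(5, dtype=bool)]
        assert np.all(off <= 1e-15)

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            update_responsibility(
                np.ones((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)), 0.5
            )


class TestExtractExemplars:
    def test_single_positive_diagonal(self):
        R = np.diag([1.0, -1.0, -1.0])
        A = np.zeros((3, 3))
        S = S33
        exemplars, labels = extract_exemplars(R, A, S)
        assert exemplars == [0]
        assert list(labels) == [0, 0, 0]

    def test_equidistant_item_joins_lowest_index(self):
        R = np.diag([1.0, 1.0, -5.0])
        A = np.zeros((3, 3))
        S = np.array(
            [[0.0, -9.0, -9.0], [-9.0, 0.0, -9.0], [-2.0, -2.0, 0.0]]
        )
        exemplars, labels = extract_exemplars(R, A, S)
        assert exemplars == [0, 1]
        assert labels[2] == 0  # tie between exemplars 0 and 1

    def test_no_positive_diagonal_falls_back_to_best(self):
        R = np.diag([-3.0, -1.0, -2.0])
        A = np.zeros((3, 3))
        exemplars, labels = extract_exemplars(R, A, S33)
        assert exemplars == [1]
        assert set(labels) == {1}


class TestAffinityPropagation:
    def test_single_item_short_circuit(self):
        result = affinity_propagation(np.zeros((1, 1)), APConfig())
        assert result.exemplars == [0]
        assert list(result.labels) == [0]
        assert result.converged

    def test_default_damping(self):
        assert APConfig().damping == 0.95
        assert AffinityPropagation().damping == 0.95

    def test_config_validation(self):
        with pytest.raises(ValueError):
            APConfig(damping=1.0)
        with pytest.raises(ValueError):
            APConfig(damping=0.0)
        with pytest.raises(ValueError):
            APConfig(max_iter=0)

    def test_planted_clusters_recovered_exactly(self):
        vectors, labels = make_planted_vectors(3, 10, V=60, separation=50,
                                               seed=3)
        model = AffinityPropagation().fit(vectors)
        assert model.converged_ and model.n_iter_ <= 1000
        assert len(model.exemplars_) == 3
        assert adjusted_rand_score(labels, model.labels_) == 1.0

    def test_deterministic(self):
        vectors, _ = make_planted_vectors(3, 5, seed=1)
        sim = build_similarity(vectors)
        r1 = affinity_propagation(sim, APConfig())
        r2 = affinity_propagation(sim, APConfig())
        assert r1.exemplars == r2.exemplars
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.iterations_run == r2.iterations_run

    def test_labels_are_valid_partition(self):
        vectors, _ = make_planted_vectors(4, 6, V=80, separation=20, seed=2)
        result = AffinityPropagation().fit(vectors).result_
        assert sorted(set(int(x) for x in result.labels)) == result.exemplars
        for k in result.exemplars:
            assert result.labels[k] == k

    def test_nonconvergence_warns(self):
        vectors, _ = make_planted_vectors(3, 5, seed=1)
        sim = build_similarity(vectors)
        with pytest.warns(UserWarning, match="did not converge"):
            result = affinity_propagation(sim, APConfig(max_iter=3))
        assert not result.converged

    @pytest.mark.parametrize("seed", range(20))
    def test_near_optimal_against_brute_force(self, seed):
        """On random 8-item instances (noisy two-group probability vectors,
        the structure the module is built to cluster) the AP net similarity
        is within 5% of the exhaustive optimum over exemplar subsets of
        equal cardinality."""
        vectors, _ = make_planted_vectors(
            2, 4, V=24, separation=5.0, seed=seed
        )
        sim = build_similarity(vectors, "median")
        result = affinity_propagation(sim, APConfig())
        ap_net = _net_similarity(sim.S, result.exemplars)
        m = len(result.exemplars)
        best = max(
            _net_similarity(sim.S, combo)
            for combo in combinations(range(8), m)
        )
        assert ap_net >= best - 0.05 * abs(best), (seed, ap_net, best)

    def test_preference_monotonicity(self):
        """Raising the preference never decreases the number of exemplars."""
        vectors, _ = make_planted_vectors(3, 5, V=60, separation=20, seed=4)
        sim = build_similarity(vectors)
        off = sim.S[~np.eye(sim.n, dtype=bool)]
        counts = []
        for pref in [off.min(), np.median(off), -1.0]:
            s = build_similarity(vectors, float(pref))
            counts.append(len(affinity_propagation(s, APConfig()).exemplars))
        assert counts == sorted(counts)

    def test_estimator_protocol(self):
        vectors, _ = make_planted_vectors(2, 4, seed=0)
        model = AffinityPropagation(damping=0.9).set_params(max_iter=500)
        labels = model.fit_predict(vectors)
        assert labels.shape == (8,)
        assert model.get_params()["max_iter"] == 500

    def test_precomputed_similarity(self):
        sim = build_similarity(make_planted_vectors(2, 3, seed=5)[0])
        model = AffinityPropagation(similarity="precomputed").fit(sim.S)
        direct = affinity_propagation(SimilarityMatrix(sim.S), APConfig())
        assert model.exemplars_ == direct.exemplars
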