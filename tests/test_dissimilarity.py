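import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import jensenshannon

from scsc import (
    SQRT_LN2,
    AdjacencyMatrix,
    DiscreteDistribution,
    DuplicateStateWarning,
    InputError,
    TrajectoryEnsemble,
    build_adjacency,
    js_dissimilarity,
    trajectory_dissimilarity,
)


def ensemble_from_positions(positions, periodic=None):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(positions.shape[1], dtype=float)
    return TrajectoryEnsemble(
        positions=positions, times=times, periodic_lengths=periodic
    )


class TestTrajectoryMetric:
    def test_worked_example_two_samples(self, small_ensemble):
        # distances 1 and 3 -> mean 2, sqrt(1+1)/2
        value = trajectory_dissimilarity(small_ensemble, 0, 1)
        assert value == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert trajectory_dissimilarity(small_ensemble, 1, 0) == pytest.approx(value)

    def test_identical_trajectories_are_duplicates(self):
        ens = ensemble_from_positions([[[0, 0], [1, 1]], [[0, 0], [1, 1]]])
        with pytest.warns(DuplicateStateWarning):
            assert trajectory_dissimilarity(ens, 0, 1) == 0.0

    def test_rigid_co_translation_scores_zero(self):
        base = np.cumsum(np.ones((7, 2)), axis=0)
        ens = ensemble_from_positions([base, base + [1.0, 0.0]])
        assert trajectory_dissimilarity(ens, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_image_distance_in_periodic_dimension(self):
        # states near opposite ends of a periodic x: true separation 0.2
        pos = [[[0.1, 0.0], [0.1, 0.0]], [[9.9, 0.0], [9.8, 0.0]]]
        ens = ensemble_from_positions(pos, periodic=[10.0, np.nan])
        # distances: 0.2 then 0.3 -> mean 0.25, sqrt(2*0.05^2)/0.25
        expected = np.sqrt(2 * 0.05**2) / 0.25
        assert trajectory_dissimilarity(ens, 0, 1) == pytest.approx(expected)

    @given(
        positions=arrays(
            float,
            (3, 4, 2),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        ),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, positions, scale):
        ens = ensemble_from_positions(positions)
        scaled = ensemble_from_positions(positions * scale)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            with np.errstate(all="ignore"):
                a = trajectory_dissimilarity(ens, i, j)
                b = trajectory_dissimilarity(scaled, i, j)
            assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_index_out_of_range(self, small_ensemble):
        with pytest.raises(InputError):
            trajectory_dissimilarity(small_ensemble, 0, 5)


class TestJensenShannon:
    def test_identity_and_disjoint_bounds(self):
        assert js_dissimilarity([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert js_dissimilarity([1, 0], [0, 1]) == pytest.approx(SQRT_LN2)

    def test_worked_example(self):
        expected = np.sqrt(
            0.5 * np.log(4 / 3) + 0.25 * np.log(2 / 3) + 0.25 * np.log(2)
        )
        assert js_dissimilarity([1, 0], [0.5, 0.5]) == pytest.approx(expected)
        assert expected == pytest.approx(0.4645, abs=5e-5)

    @given(
        raw_p=arrays(float, 5, elements=st.floats(0.0, 1.0, width=32)),
        raw_q=arrays(float, 5, elements=st.floats(0.0, 1.0, width=32)),
    )
    def test_bounds_and_scipy_agreement(self, raw_p, raw_q):
        if raw_p.sum() == 0 or raw_q.sum() == 0:
            return
        p = raw_p / raw_p.sum()
        q = raw_q / raw_q.sum()
        value = js_dissimilarity(p, q)
        assert 0.0 <= value <= SQRT_LN2 + 1e-12
        # independent implementation of the same quantity
        assert value == pytest.approx(jensenshannon(p, q, base=np.e), abs=1e-9)

    def test_accepts_distribution_objects(self):
        d = DiscreteDistribution([0.25, 0.75])
        assert js_dissimilarity(d, d) == 0.0

    @pytest.mark.parametrize(
        "p, q",
        [([1, 0], [1, 0, 0]), ([1.0, -0.1], [0.55, 0.55]), ([0.2, 0.2], [1, 0])],
    )
    def test_invalid_inputs(self, p, q):
        with pytest.raises(InputError):
            js_dissimilarity(p, q)


class TestBuildAdjacency:
    def test_metric_evaluated_once_per_unordered_pair(self):
        calls = []

        def metric(a, b):
            calls.append((a, b))
            return abs(a - b)

        n = 7
        A = build_adjacency(list(range(n)), metric=metric)
        assert len(calls) == n * (n - 1) // 2
        assert A.values.shape == (n, n)
        np.testing.assert_allclose(A.values, A.values.T)
        assert np.all(np.diag(A.values) == 0)

    def test_evaluation_order_does_not_matter(self):
        rng = np.random.default_rng(0)
        items = list(rng.random(6))
        metric = lambda a, b: abs(a - b)  # noqa: E731
        A = build_adjacency(items, metric=metric)
        perm = [3, 1, 5, 0, 4, 2]
        B = build_adjacency([items[i] for i in perm], metric=metric)
        np.testing.assert_allclose(
            A.values[np.ix_(perm, perm)], B.values, atol=1e-15
        )

    def test_non_finite_metric_names_the_pair(self):
        def metric(a, b):
            return np.inf if (a, b) == (1, 2) else 1.0

        with pytest.raises(InputError, match=r"\(1, 2\)"):
            build_adjacency([0, 1, 2], metric=metric)

    def test_duplicate_states_warn_and_zero(self):
        pos = np.zeros((2, 3, 2))
        ens = ensemble_from_positions(pos)
        with pytest.warns(DuplicateStateWarning):
            A = build_adjacency(ens)
        np.testing.assert_array_equal(A.values, 0.0)

    def test_stationary_collinear_points_score_zero(self):
        pos = np.stack([np.tile([i, 0.0], (5, 1)) for i in range(3)])
        ens = ensemble_from_positions(pos)
        A = build_adjacency(ens)
        np.testing.assert_allclose(A.values, 0.0, atol=1e-12)

    def test_trajectory_fast_path_matches_pair_op(self):
        rng = np.random.default_rng(3)
        ens = ensemble_from_positions(rng.random((5, 11, 2)))
        A = build_adjacency(ens)
        for i in range(5):
            for j in range(i + 1, 5):
                assert A.values[i, j] == pytest.approx(
                    trajectory_dissimilarity(ens, i, j), rel=1e-10
                )

    def test_js_metric_on_rows(self):
        rows = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        A = build_adjacency(rows, metric="js")
        assert A.values[0, 2] == pytest.approx(SQRT_LN2)
        assert A.values[0, 1] == pytest.approx(0.4645, abs=5e-5)


class TestContainers:
    @pytest.mark.parametrize(
        "values",
        [
            [[0, 1], [2, 0]],  # asymmetric
            [[1, 1], [1, 0]],  # nonzero diagonal
            [[0, -1], [-1, 0]],  # negative
            [[0, np.nan], [np.nan, 0]],  # non-finite
        ],
    )
    def test_adjacency_invariants_enforced(self, values):
        with pytest.raises(InputError):
            AdjacencyMatrix(values)

    def test_ensemble_validation(self):
        with pytest.raises(InputError):
            TrajectoryEnsemble(np.zeros((2, 1, 2)), np.array([0.0]))  # T < 2
        with pytest.raises(InputError):
            TrajectoryEnsemble(np.zeros((2, 2, 2)), np.array([1.0, 0.0]))
        with pytest.raises(InputError):
            TrajectoryEnsemble(
                np.zeros((2, 2, 2)), np.array([0.0, 1.0]), periodic_lengths=[-1, 1]
            )
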