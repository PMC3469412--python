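import numpy as np
import pytest
from scipy.integrate import solve_ivp

from modflux.dynamics import (
    InfluenceModel,
    TimeCourse,
    Trajectory,
    rmsd_performance,
    simulate_trajectory,
    weighted_correlation_performance,
    weighted_profile_correlation,
)

TIMES = np.array([3.0, 24.0, 72.0, 75.0, 96.0])


def _model(a, counts=None):
    a = np.asarray(a, dtype=float)
    counts = np.ones(a.shape[0], dtype=int) if counts is None else counts
    return InfluenceModel(a, counts)


class TestSimulate:
    def test_zero_matrix_keeps_state(self):
        model = _model(np.zeros((3, 3)))
        c0 = np.array([1.0, -2.0, 0.5])
        traj = simulate_trajectory(model, c0, TIMES)
        assert np.allclose(traj.values, c0[:, None])

    def test_uncoupled_exponential_decay(self):
        model = _model(-np.eye(2))
        traj = simulate_trajectory(model, np.array([1.0, 2.0]), TIMES)
        expected = np.array([1.0, 2.0])[:, None] * np.exp(-(TIMES - 3.0))
        assert np.allclose(traj.values, expected, rtol=1e-12)

    def test_nilpotent_closed_form(self):
        # A = [[0,1],[0,0]] gives c(t) = (c2*(t-t0) + c1, c2)
        model = _model([[0.0, 1.0], [0.0, 0.0]])
        traj = simulate_trajectory(model, np.array([0.0, 1.0]), TIMES)
        assert np.allclose(traj.values[0], TIMES - 3.0, rtol=1e-12)
        assert np.allclose(traj.values[1], 1.0)
        # independent check against a fine-step integration
        sol = solve_ivp(
            lambda t, c: model.a @ c, (3.0, 96.0), [0.0, 1.0],
            t_eval=TIMES, rtol=1e-10, atol=1e-12,
        )
        assert np.allclose(traj.values, sol.y, rtol=1e-7)

    def test_initial_state_exact(self):
        rng = np.random.default_rng(0)
        model = _model(rng.normal(size=(4, 4)) - 2 * np.eye(4))
        c0 = rng.normal(size=4)
        traj = simulate_trajectory(model, c0, TIMES)
        assert np.array_equal(traj.values[:, 0], c0)

    def test_superposition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 5))
        a -= np.eye(5) * (np.abs(np.linalg.eigvals(a).real).max() + 0.1)
        model = _model(a)
        c0a, c0b = rng.normal(size=5), rng.normal(size=5)
        ta = simulate_trajectory(model, c0a, TIMES).values
        tb = simulate_trajectory(model, c0b, TIMES).values
        tab = simulate_trajectory(model, c0a + c0b, TIMES).values
        assert np.allclose(ta + tb, tab, atol=1e-10)

    def test_shape_validation(self):
        model = _model(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            simulate_trajectory(model, np.zeros(3), TIMES)

    def test_non_finite_model_rejected(self):
        with pytest.raises(ValueError):
            InfluenceModel(np.array([[np.inf]]), np.array([1]))


class TestWeightedCorrelation:
    def _course(self, values):
        return TimeCourse("t", TIMES, np.asarray(values, dtype=float))

    def test_identity_scores_one(self, toy_model, toy_course):
        sim = Trajectory(TIMES, toy_course.observed.copy())
        score = weighted_correlation_performance(
            sim, toy_course, toy_model.gene_counts
        )
        assert score == pytest.approx(1.0)

    def test_sign_flip_scores_minus_one(self, toy_course, toy_model):
        sim = Trajectory(TIMES, -toy_course.observed)
        score = weighted_correlation_performance(
            sim, toy_course, toy_model.gene_counts
        )
        assert score == pytest.approx(-1.0)

    def test_weighted_mean_three_one(self):
        # clusters correlate (1.0, 0.0) with gene counts (3, 1) -> 0.75
        obs = np.array([[0.0, 1.0, 2.0, 3.0, 4.0],
                        [1.0, -1.0, 1.0, -1.0, 1.0]])
        sim = np.array([[0.0, 2.0, 4.0, 6.0, 8.0],
                        [0.0, 0.0, 0.0, 0.0, 0.0]])  # constant -> r = 0
        score = weighted_profile_correlation(sim, obs, np.array([3, 1]))
        assert score == pytest.approx(0.75)

    def test_affine_invariance_per_cluster(self, toy_course, toy_model):
        scaled = toy_course.observed * np.array([[2.0], [5.0], [0.3]]) + np.array(
            [[1.0], [-4.0], [0.0]]
        )
        sim = Trajectory(TIMES, scaled)
        score = weighted_correlation_performance(
            sim, toy_course, toy_model.gene_counts
        )
        assert score == pytest.approx(1.0)

    def test_constant_vectors_score_zero(self):
        obs = np.zeros((2, 5))
        sim = np.ones((2, 5))
        assert weighted_profile_correlation(sim, obs, np.array([1, 1])) == 0.0

    def test_shape_mismatch(self, toy_course, toy_model):
        sim = Trajectory(TIMES, np.zeros((2, 5)))
        with pytest.raises(ValueError):
            weighted_correlation_performance(sim, toy_course, toy_model.gene_counts)

    def test_divergent_simulation_scores_zero(self):
        obs = np.array([[0.0, 1.0, 2.0, 3.0, 4.0]])
        sim = np.array([[0.0, np.inf, np.nan, 1.0, 2.0]])
        assert weighted_profile_correlation(sim, obs, np.array([2])) == 0.0


class TestRmsd:
    def test_zero_for_identical(self, toy_course):
        sim = Trajectory(TIMES, toy_course.observed.copy())
        assert rmsd_performance(sim, toy_course) == 0.0

    def test_full_range_offset_is_one(self):
        obs = np.array([[0.0, 1.0, 0.5, 0.2, 0.9]])
        course = TimeCourse("t", TIMES, obs)
        sim = Trajectory(TIMES, obs + 1.0)  # offset by the full range
        assert rmsd_performance(sim, course) == pytest.approx(1.0)

    def test_mean_over_clusters(self):
        obs = np.array([[0.0, 1.0, 0.0, 1.0, 0.0], [0.0, 2.0, 0.0, 2.0, 0.0]])
        course = TimeCourse("t", TIMES, obs)
        sim = Trajectory(TIMES, obs + np.array([[0.2], [0.8]]))
        assert rmsd_performance(sim, course) == pytest.approx(0.3)

    def test_zero_range_cluster_excluded_with_warning(self):
        obs = np.array([[1.0, 1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0, 0.0]])
        course = TimeCourse("t", TIMES, obs)
        sim = Trajectory(TIMES, obs.copy())
        with pytest.warns(UserWarning):
            assert rmsd_performance(sim, course) == 0.0


class TestAgainstAdaptiveIntegrator:
    def test_random_stable_systems(self):
        """Closed-form exponentials track an adaptive integrator to <1e-8."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            a = rng.normal(scale=0.05, size=(10, 10))
            a -= np.eye(10) * (np.max(np.linalg.eigvals(a).real) + 0.02)
            model = _model(a)
            c0 = rng.normal(size=10)
            traj = simulate_trajectory(model, c0, TIMES)
            sol = solve_ivp(
                lambda t, c: a @ c, (TIMES[0], TIMES[-1]), c0,
                t_eval=TIMES, rtol=1e-11, atol=1e-13,
            )
            err = np.max(
                np.abs(traj.values - sol.y) / np.maximum(np.abs(sol.y), 1e-12)
            )
            worst = max(worst, err)
        assert worst < 1e-8


class TestModelContainer:
    def test_from_weights_diagonal(self):
        weights = np.array([[0.0, 1.0], [2.0, 0.5]])
        model = InfluenceModel.from_weights(
            weights, np.array([10.0, 4.0]), [1, 1]
        )
        assert model.a[0, 0] == pytest.approx(-0.1)
        assert model.a[1, 1] == pytest.approx(0.5 - 0.25)
        assert model.a[0, 1] == 1.0
        assert np.allclose(model.tau[0], 10.0)

    def test_tau_requires_positive(self):
        with pytest.raises(ValueError):
            InfluenceModel.from_weights(np.zeros((2, 2)), np.array([1.0, -3.0]), [1, 1])

    def test_tsv_round_trip(self, tmp_path, toy_model):
        toy_model.to_tsv(tmp_path / "m.tsv")
        back = InfluenceModel.from_tsv(tmp_path / "m.tsv")
        assert np.allclose(back.a, toy_model.a)
        assert np.array_equal(back.gene_counts, toy_model.gene_counts)

    def test_edge_count(self, toy_model):
        assert toy_model.n_edges == 2
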