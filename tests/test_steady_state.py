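import numpy as np
import pytest

from modflux.expression import ClusterProfileMatrix, SampleMeta
from modflux.steady_state import (
    SteadyStateFold,
    SteadyStateInfluence,
    consensus_initial_model,
    fit_target_lasso,
    infer_cv_models,
)


def _coordinate_descent_oracle(y, x, lam, n_iter=5000):
    """Plain cyclic coordinate descent for 0.5/n * ||y - Xw||^2 + lam * |w|_1."""
    n, p = x.shape
    w = np.zeros(p)
    col_sq = (x**2).sum(axis=0) / n
    for _ in range(n_iter):
        for j in range(p):
            r = y - x @ w + x[:, j] * w[j]
            rho = (x[:, j] @ r) / n
            w[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / max(col_sq[j], 1e-30)
    return w


class TestFitTargetLasso:
    def test_recovers_single_regulator(self):
        rng = np.random.default_rng(0)
        regs = rng.normal(size=(4, 30))
        target = regs[0]
        coef = fit_target_lasso(target, regs, penalty=0.01)
        assert abs(coef[0] - 1.0) < 0.05
        assert np.all(coef[1:] == 0.0)

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(25, 4))
        w_true = np.array([1.5, 0.0, -0.8, 0.0])
        y = x @ w_true + rng.normal(scale=0.1, size=25)
        for lam in (0.01, 0.1, 0.5):
            ours = fit_target_lasso(y, x.T, lam)
            oracle = _coordinate_descent_oracle(
                y - y.mean(), x - x.mean(axis=0), lam
            )
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_huge_penalty_shrinks_all(self):
        rng = np.random.default_rng(2)
        regs = rng.normal(size=(3, 20))
        coef = fit_target_lasso(regs[0], regs, penalty=1e6)
        assert np.all(coef == 0.0)

    def test_orthogonal_target_gives_zero(self):
        x = np.array([[1.0, -1.0, 1.0, -1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        coef = fit_target_lasso(y, x, penalty=0.01)
        assert np.all(coef == 0.0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_target_lasso(np.zeros(3), np.zeros((2, 3)), penalty=-1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_target_lasso(np.zeros(1), np.zeros((2, 1)), penalty=0.1)

    def test_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 6))
        y = x @ np.array([2.0, -1.0, 0.5, 0.0, 0.0, 0.0]) + rng.normal(size=30) * 0.2
        sizes = [
            int(np.count_nonzero(fit_target_lasso(y, x.T, lam)))
            for lam in (0.001, 0.01, 0.1, 0.5, 2.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


def _profiles(values, treatments, times):
    samples = [
        SampleMeta(t, float(h), f"{t}_{h:g}") for t in treatments for h in times
    ]
    return ClusterProfileMatrix(
        list(range(1, values.shape[0] + 1)),
        values,
        np.ones(values.shape[0], dtype=int),
        samples,
    )


class TestCrossValidatedInference:
    TIMES = (3.0, 24.0, 72.0, 75.0, 96.0)
    TREATS = ("a", "b", "c", "d", "e")

    def test_one_fold_per_treatment(self):
        rng = np.random.default_rng(0)
        prof = _profiles(rng.normal(size=(4, 25)), self.TREATS, self.TIMES)
        folds = infer_cv_models(prof, penalty_grid=(0.1, 1.0))
        assert sorted(f.held_out_treatment for f in folds) == list(self.TREATS)
        for f in folds:
            assert np.all(np.diag(f.coefficients) == 0.0)

    def test_identical_treatments_give_identical_folds(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(4, 5))
        values = np.tile(block, (1, 5))
        prof = _profiles(values, self.TREATS, self.TIMES)
        folds = infer_cv_models(prof, penalty_grid=(0.1, 1.0))
        for f in folds[1:]:
            assert np.allclose(f.coefficients, folds[0].coefficients)

    def test_single_treatment_rejected(self):
        rng = np.random.default_rng(2)
        prof = _profiles(rng.normal(size=(3, 5)), ("only",), self.TIMES)
        with pytest.raises(ValueError):
            infer_cv_models(prof)

    def test_exact_linear_targets_recovered_per_fold(self):
        """Targets that are exact sparse combinations of exogenous profiles
        are recovered with the correct support in every fold."""
        rng = np.random.default_rng(3)
        sources = rng.normal(size=(3, 25))  # clusters 1-3 exogenous
        t4 = 0.9 * sources[0] - 0.7 * sources[2]
        t5 = 0.8 * sources[1] + 0.6 * sources[2]
        values = np.vstack([sources, t4, t5])
        prof = _profiles(values, self.TREATS, self.TIMES)
        folds = infer_cv_models(prof, penalty_grid=(0.001, 0.01, 0.1, 1.0))
        for f in folds:
            assert set(np.nonzero(f.coefficients[3])[0]) == {0, 2}
            assert set(np.nonzero(f.coefficients[4])[0]) == {1, 2}
            assert np.allclose(f.coefficients[3, [0, 2]], [0.9, -0.7], atol=0.05)


class TestConsensus:
    def _fold(self, coefs, treatment="t"):
        coefs = np.asarray(coefs, dtype=float)
        return SteadyStateFold(treatment, coefs, np.zeros(coefs.shape[0]), 0.5)

    def test_low_support_edge_zeroed(self):
        base = np.zeros((2, 2))
        withedge = base.copy()
        withedge[0, 1] = 0.8
        folds = [self._fold(withedge), self._fold(withedge)] + [
            self._fold(base) for _ in range(3)
        ]
        report = consensus_initial_model(folds, min_support=3, weight_floor=0.1)
        assert report.consensus[0, 1] == 0.0
        assert report.support_counts[0, 1] == 2

    def test_small_mean_edge_zeroed(self):
        m = np.zeros((2, 2))
        m[0, 1] = 0.05
        folds = [self._fold(m) for _ in range(5)]
        report = consensus_initial_model(folds)
        assert report.consensus[0, 1] == 0.0

    def test_consistent_edge_retained(self):
        m = np.zeros((2, 2))
        m[0, 1] = 0.5
        folds = [self._fold(m) for _ in range(5)]
        report = consensus_initial_model(folds)
        assert report.consensus[0, 1] == pytest.approx(0.5)

    def test_consensus_support_subset_of_fold_union(self):
        rng = np.random.default_rng(4)
        folds = []
        for _ in range(5):
            m = np.where(rng.random((4, 4)) < 0.4, rng.normal(size=(4, 4)), 0.0)
            np.fill_diagonal(m, 0.0)
            folds.append(self._fold(m))
        report = consensus_initial_model(folds)
        union = np.any(np.stack([f.coefficients != 0 for f in folds]), axis=0)
        assert np.all(union[report.consensus != 0])

    def test_empty_folds_rejected(self):
        with pytest.raises(ValueError):
            consensus_initial_model([])

    def test_min_support_bounds(self):
        folds = [self._fold(np.zeros((2, 2)))]
        with pytest.raises(ValueError):
            consensus_initial_model(folds, min_support=2)


class TestModelWrapper:
    def test_fit_returns_summary_and_model(self):
        rng = np.random.default_rng(5)
        sources = rng.normal(size=(2, 25))
        t3 = 0.9 * sources[0] - 0.7 * sources[1]
        prof = _profiles(
            np.vstack([sources, t3]),
            ("a", "b", "c", "d", "e"),
            (3.0, 24.0, 72.0, 75.0, 96.0),
        )
        res = SteadyStateInfluence(prof).fit(penalty_grid=(0.001, 0.1))
        assert "Steady-state" in res.summary()
        model = res.influence_model()
        assert model.n_clusters == 3
        assert np.all(np.diag(model.a) < 0)
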