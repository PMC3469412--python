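"""Initial influence-model inference by steady-state lasso regression.

Each sampled time point is treated as an independent steady-state
observation; every cluster's mean profile is regressed on all other
clusters' profiles with an L1 penalty, so the starting model is a sparse
set of cluster-to-cluster influences.  Robustness comes from a
leave-one-treatment-out scheme: one fold per treatment, each trained on
the remaining treatments, with the penalty chosen per target by an inner
leave-one-treatment-out grid search.  Fold coefficients are averaged and
filtered (support in >= 3 of 5 folds, |mean| >= 0.1 by default) into the
consensus matrix that seeds the dynamic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .dynamics import weighted_profile_correlation
from .expression import ClusterProfileMatrix

__all__ = [
    "DEFAULT_PENALTY_GRID",
    "SteadyStateFold",
    "InitialModelReport",
    "fit_target_lasso",
    "infer_cv_models",
    "consensus_initial_model",
    "SteadyStateInfluence",
    "SteadyStateResults",
]

#: Penalty grid spanning near-OLS to full shrinkage on log2FC-scale data.
DEFAULT_PENALTY_GRID: tuple[float, ...] = (
    0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0,
)


@dataclass
class SteadyStateFold:
    """One leave-one-treatment-out fold of the steady-state regression."""

    held_out_treatment: str
    coefficients: np.ndarray  # K x K, row = target, diagonal zero
    penalties: np.ndarray  # chosen lambda per target
    heldout_performance: float

    def __post_init__(self) -> None:
        if np.any(np.diag(self.coefficients) != 0):
            raise ValueError("self-influence (diagonal) entries must be zero")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite fold coefficients")


@dataclass
class InitialModelReport:
    """Consensus starting matrix with fold support and performance summary."""

    consensus: np.ndarray
    support_counts: np.ndarray
    mean_performance: float
    per_treatment_performance: dict[str, float]
    min_support: int
    weight_floor: float


def fit_target_lasso(
    target_profile: np.ndarray,
    regulator_profiles: np.ndarray,
    penalty: float,
) -> np.ndarray:
    """Minimise 0.5 * mean squared residual + penalty * l1-norm of weights.

    Rows of ``regulator_profiles`` are regulators, columns are samples.  The
    data are centred and no intercept is fitted (values are fold changes
    relative to baseline).  ``penalty = 0`` falls back to ordinary least
    squares.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    y = np.asarray(target_profile, dtype=float)
    x = np.asarray(regulator_profiles, dtype=float).T  # samples x regulators
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if x.shape[0] != y.size:
        raise ValueError("regulator profiles and target cover different samples")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    if penalty == 0:
        coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        return coef
    model = Lasso(alpha=penalty, fit_intercept=False, max_iter=100_000, tol=1e-8)
    with warnings.catch_warnings():
        # near-collinear profiles at tiny penalties stop on max_iter; the
        # partially converged fit is still the best the grid point offers
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(xc, yc)
    return model.coef_.copy()


def _treatment_blocks(samples) -> dict[str, np.ndarray]:
    blocks: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        blocks.setdefault(s.treatment, []).append(i)
    return {t: np.asarray(ix) for t, ix in blocks.items()}


def _fit_target_cv(
    values: np.ndarray,
    target: int,
    train_treatments: list[str],
    blocks: dict[str, np.ndarray],
    penalty_grid,
) -> tuple[np.ndarray, float]:
    """Pick lambda by inner leave-one-treatment-out MSE, refit on all folds."""
    k = values.shape[0]
    regs = [l for l in range(k) if l != target]
    train_idx = np.concatenate([blocks[t] for t in train_treatments])
    best_lam, best_err = None, np.inf
    for lam in penalty_grid:
        errs = []
        for held in train_treatments:
            inner_train = np.concatenate(
                [blocks[t] for t in train_treatments if t != held]
            )
            x_tr = values[np.ix_(regs, inner_train)]
            y_tr = values[target, inner_train]
            coef = fit_target_lasso(y_tr, x_tr, lam)
            x_means = x_tr.mean(axis=1)
            y_mean = y_tr.mean()
            x_te = values[np.ix_(regs, blocks[held])]
            pred = y_mean + coef @ (x_te - x_means[:, None])
            errs.append(np.mean((pred - values[target, blocks[held]]) ** 2))
        err = float(np.mean(errs))
        if err < best_err:
            best_err, best_lam = err, lam
    coef = fit_target_lasso(
        values[target, train_idx], values[np.ix_(regs, train_idx)], best_lam
    )
    full = np.zeros(k)
    full[regs] = coef
    return full, float(best_lam)


def infer_cv_models(
    profiles: ClusterProfileMatrix,
    penalty_grid=DEFAULT_PENALTY_GRID,
) -> list[SteadyStateFold]:
    """One steady-state fold per treatment, each leaving that treatment out.

    Held-out performance is the gene-count-weighted mean of per-cluster
    Pearson correlations between predicted and observed values on the
    held-out treatment's samples.
    """
    blocks = _treatment_blocks(profiles.samples)
    treatments = list(blocks)
    if len(treatments) < 2:
        raise ValueError("need at least 2 distinct treatments for cross-validation")
    penalty_grid = [float(l) for l in penalty_grid]
    if any(l < 0 for l in penalty_grid):
        raise ValueError("penalties must be >= 0")
    k = profiles.n_clusters
    folds = []
    for held in treatments:
        train_treatments = [t for t in treatments if t != held]
        coefs = np.zeros((k, k))
        lams = np.zeros(k)
        train_idx = np.concatenate([blocks[t] for t in train_treatments])
        preds = np.zeros((k, blocks[held].size))
        for tgt in range(k):
            coefs[tgt], lams[tgt] = _fit_target_cv(
                profiles.values, tgt, train_treatments, blocks, penalty_grid
            )
            regs = [l for l in range(k) if l != tgt]
            x_tr = profiles.values[np.ix_(regs, train_idx)]
            y_mean = profiles.values[tgt, train_idx].mean()
            x_means = x_tr.mean(axis=1)
            x_te = profiles.values[np.ix_(regs, blocks[held])]
            preds[tgt] = y_mean + coefs[tgt, regs] @ (x_te - x_means[:, None])
        perf = weighted_profile_correlation(
            preds, profiles.values[:, blocks[held]], profiles.gene_counts
        )
        folds.append(SteadyStateFold(held, coefs, lams, perf))
    return folds


def consensus_initial_model(
    folds: list[SteadyStateFold],
    min_support: int = 3,
    weight_floor: float = 0.1,
) -> InitialModelReport:
    """Average fold coefficients and drop weakly supported influences.

    An influence survives only if nonzero in at least ``min_support`` folds
    and its across-fold mean magnitude reaches ``weight_floor``.
    """
    if not folds:
        raise ValueError("no folds supplied")
    if not 1 <= min_support <= len(folds):
        raise ValueError(f"min_support must lie in [1, {len(folds)}]")
    if weight_floor < 0:
        raise ValueError("weight_floor must be >= 0")
    stack = np.stack([f.coefficients for f in folds])
    support = (stack != 0).sum(axis=0)
    mean = stack.mean(axis=0)
    consensus = np.where(
        (support >= min_support) & (np.abs(mean) >= weight_floor), mean, 0.0
    )
    np.fill_diagonal(consensus, 0.0)
    per_treatment = {f.held_out_treatment: f.heldout_performance for f in folds}
    return InitialModelReport(
        consensus=consensus,
        support_counts=support,
        mean_performance=float(np.mean(list(per_treatment.values()))),
        per_treatment_performance=per_treatment,
        min_support=min_support,
        weight_floor=weight_floor,
    )


class SteadyStateInfluence:
    """Steady-state influence model of cluster-mean expression profiles.

    Parameters
    ----------
    profiles : ClusterProfileMatrix
        Cluster-mean log2 fold changes with per-sample treatment/time
        metadata; every time point is treated as an independent
        steady-state observation.
    """

    def __init__(self, profiles: ClusterProfileMatrix):
        self.profiles = profiles

    @classmethod
    def from_table(cls, table, assign) -> "SteadyStateInfluence":
        from .expression import cluster_mean_profiles

        return cls(cluster_mean_profiles(table, assign))

    def fit(
        self,
        penalty_grid=DEFAULT_PENALTY_GRID,
        min_support: int = 3,
        weight_floor: float = 0.1,
    ) -> "SteadyStateResults":
        folds = infer_cv_models(self.profiles, penalty_grid)
        report = consensus_initial_model(folds, min_support, weight_floor)
        return SteadyStateResults(self, folds, report)


@dataclass
class SteadyStateResults:
    """Fitted steady-state model: folds, consensus matrix and diagnostics."""

    model: SteadyStateInfluence
    folds: list[SteadyStateFold]
    report: InitialModelReport
    _: dict = field(default_factory=dict, repr=False)

    @property
    def consensus(self) -> np.ndarray:
        return self.report.consensus

    def influence_model(self, tau: np.ndarray | None = None):
        """Package the consensus matrix as a dynamic InfluenceModel.

        If no decay constants are supplied, a neutral 24 h decay is used for
        every cluster; downstream annealing re-optimises the diagonal.
        """
        from .dynamics import InfluenceModel

        k = self.consensus.shape[0]
        if tau is None:
            tau = np.full(k, 24.0)
        return InfluenceModel.from_weights(
            self.consensus, tau, self.model.profiles.gene_counts
        )

    def summary(self) -> str:
        rep = self.report
        lines = [
            "Steady-state influence model (L1-penalised, leave-one-treatment-out)",
            f"  clusters: {self.consensus.shape[0]}",
            f"  folds: {len(self.folds)}",
            f"  consensus edges: {int(np.count_nonzero(rep.consensus))} "
            f"(support >= {rep.min_support}, |mean| >= {rep.weight_floor})",
            f"  mean held-out weighted correlation: {rep.mean_performance:.3f}",
        ]
        for t, p in rep.per_treatment_performance.items():
            lines.append(f"    {t}: {p:.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        k = self.consensus.shape[0]
        frame = pd.DataFrame(
            self.consensus, index=range(1, k + 1), columns=range(1, k + 1)
        )
        frame.index.name = "target"
        return frame
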