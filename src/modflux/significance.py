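"""Randomisation nulls for influence-matrix performance.

Three null families probe what a model's dynamic performance owes to its
numbers versus its wiring:

* ``resample`` -- permute the nonzero values among the existing nonzero
  positions (structure kept, values shuffled),
* ``uniform`` -- redraw each nonzero value from U(-2, 2) (structure kept,
  values replaced),
* ``scramble`` -- permute all entries over all positions (structure
  destroyed, value multiset kept).

The observed weighted-correlation score is compared with the scores of
``n_reps`` randomised matrices simulated under identical initial state and
times; both a rank-based empirical p-value and a one-sided normal tail are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dynamics import (
    InfluenceModel,
    TimeCourse,
    simulate_trajectory,
    weighted_correlation_performance,
)

__all__ = ["NullResult", "randomize_matrix", "significance_test", "normal_tail_p"]

MODES = ("resample", "uniform", "scramble")


@dataclass
class NullResult:
    """Null distribution of performance scores and the observed score."""

    mode: str
    n_reps: int
    null_scores: np.ndarray
    observed: float
    empirical_p: float
    parametric_p: float | None  # None when the null sd is degenerate
    null_mean: float
    null_sd: float

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_reps": self.n_reps,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "parametric_p": self.parametric_p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_scores": self.null_scores.tolist(),
        }


def randomize_matrix(
    model: InfluenceModel, mode: str, rng: np.random.Generator
) -> InfluenceModel:
    """Return a randomised variant of the effective matrix A.

    The diagonal participates like any other entry; null matrices may imply
    non-positive decay constants, which the container permits.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    a = model.a.copy()
    if mode == "scramble":
        flat = a.ravel()
        a = rng.permutation(flat).reshape(a.shape)
    else:
        pos = np.argwhere(a != 0)
        vals = a[a != 0]
        if mode == "resample":
            new_vals = rng.permutation(vals)
        else:  # uniform
            new_vals = rng.uniform(-2.0, 2.0, size=vals.size)
        for (i, j), v in zip(pos, new_vals):
            a[i, j] = v
    return InfluenceModel(a, model.gene_counts)


def normal_tail_p(observed: float, null_mean: float, null_sd: float) -> float:
    """One-sided upper tail of a normal fitted to the null sample."""
    return float(norm.sf(observed, loc=null_mean, scale=null_sd))


def significance_test(
    model: InfluenceModel,
    course: TimeCourse,
    mode: str,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> NullResult:
    """Compare a model's dynamic performance against a randomisation null.

    The empirical p-value uses the add-one rank rule
    (1 + #{null >= observed}) / (n_reps + 1), so it is never exactly zero.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    init = course.initial_state
    sim = simulate_trajectory(model, init, course.times)
    observed = weighted_correlation_performance(sim, course, model.gene_counts)
    nulls = np.empty(n_reps)
    for r in range(n_reps):
        null_model = randomize_matrix(model, mode, rng)
        null_sim = simulate_trajectory(null_model, init, course.times)
        nulls[r] = weighted_correlation_performance(
            null_sim, course, model.gene_counts
        )
    empirical_p = (1 + int(np.sum(nulls >= observed))) / (n_reps + 1)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n_reps > 1 else 0.0
    parametric = normal_tail_p(observed, mean, sd) if sd > 0 else None
    return NullResult(
        mode=mode,
        n_reps=n_reps,
        null_scores=nulls,
        observed=float(observed),
        empirical_p=float(empirical_p),
        parametric_p=parametric,
        null_mean=mean,
        null_sd=sd,
    )
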