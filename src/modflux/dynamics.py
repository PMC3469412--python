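"""Linear ODE influence models, trajectory simulation and fit metrics.

The expression of cluster i evolves as

    dc_i/dt = -c_i / tau_i + sum_{l != i} w_il c_l

where tau_i is a per-cluster expression decay constant (hours) and w_il the
signed influence of regulator cluster l on target i (per hour, per unit
log2 fold change).  Folding the decay into the diagonal, dc/dt = A c with
A_ii = w_ii - 1/tau_i, so trajectories are matrix exponentials of the
effective matrix A acting on the initial state.

Simulations are scored against observed time courses by the mean of the
per-cluster Pearson correlations weighted by cluster gene counts; an
alternative normalised-RMSD metric is provided for comparison only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "InfluenceModel",
    "TimeCourse",
    "Trajectory",
    "simulate_trajectory",
    "weighted_profile_correlation",
    "weighted_correlation_performance",
    "rmsd_performance",
]


@dataclass
class InfluenceModel:
    """Effective influence matrix A plus per-cluster gene counts.

    ``a`` is stored directly: off-diagonal entries are regulator weights
    (row = target, column = regulator), the diagonal holds w_ii - 1/tau_i.
    Randomisation nulls may produce diagonals implying non-positive decay
    constants; storing A itself keeps those representable.
    """

    a: np.ndarray
    gene_counts: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.gene_counts = np.asarray(self.gene_counts, dtype=int)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ValueError(f"influence matrix must be square, got {self.a.shape}")
        if not np.isfinite(self.a).all():
            raise ValueError("non-finite influence matrix entries")
        if self.gene_counts.shape != (self.a.shape[0],):
            raise ValueError("gene_counts length must equal the cluster count")

    @classmethod
    def from_weights(
        cls,
        weights: np.ndarray,
        tau: np.ndarray,
        gene_counts: np.ndarray | Sequence[int],
    ) -> "InfluenceModel":
        """Build A from off-diagonal weights and decay constants tau (> 0)."""
        weights = np.asarray(weights, dtype=float)
        tau = np.asarray(tau, dtype=float)
        if (tau <= 0).any():
            raise ValueError("decay constants tau must be positive")
        a = weights.copy()
        idx = np.diag_indices_from(a)
        a[idx] = weights[idx] - 1.0 / tau
        return cls(a, np.asarray(gene_counts))

    @property
    def n_clusters(self) -> int:
        return self.a.shape[0]

    @property
    def tau(self) -> np.ndarray:
        """Implied decay constants -1/A_ii (inf where A_ii >= 0)."""
        diag = np.diag(self.a)
        with np.errstate(divide="ignore"):
            return np.where(diag < 0, -1.0 / diag, np.inf)

    def off_diagonal_support(self) -> np.ndarray:
        """Boolean mask of nonzero off-diagonal entries (the model edges)."""
        mask = self.a != 0
        np.fill_diagonal(mask, False)
        return mask

    @property
    def n_edges(self) -> int:
        return int(self.off_diagonal_support().sum())

    def spectral_abscissa(self) -> float:
        return float(np.max(np.linalg.eigvals(self.a).real))

    def copy(self) -> "InfluenceModel":
        return InfluenceModel(self.a.copy(), self.gene_counts.copy())

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV plus a JSON sidecar with gene counts."""
        k = self.n_clusters
        frame = pd.DataFrame(
            self.a, index=range(1, k + 1), columns=range(1, k + 1)
        )
        frame.index.name = "target"
        frame.to_csv(path, sep="\t", float_format="%.10g")
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(
            json.dumps({"gene_counts": self.gene_counts.tolist()}, indent=1)
        )

    @classmethod
    def from_tsv(cls, path) -> "InfluenceModel":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        a = frame.to_numpy(dtype=float)
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            counts = np.asarray(json.loads(sidecar.read_text())["gene_counts"])
        else:
            counts = np.ones(a.shape[0], dtype=int)
        return cls(a, counts)


@dataclass
class TimeCourse:
    """Observed cluster-mean profiles for one treatment condition.

    The first time point doubles as the ODE initialisation state.
    """

    treatment: str
    times: np.ndarray
    observed: np.ndarray  # clusters x times

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.times.ndim != 1 or (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.observed.shape[1] != self.times.size:
            raise ValueError("observed matrix must have one column per time")

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def initial_state(self) -> np.ndarray:
        return self.observed[:, 0].copy()

    @classmethod
    def from_profiles(cls, profiles, treatment: str) -> "TimeCourse":
        """Extract one treatment's time course from a ClusterProfileMatrix."""
        cols = [
            (i, s.time_h)
            for i, s in enumerate(profiles.samples)
            if s.treatment == treatment
        ]
        if not cols:
            raise KeyError(f"treatment {treatment!r} not present")
        cols.sort(key=lambda it: it[1])
        idx = [i for i, _ in cols]
        times = np.array([t for _, t in cols])
        return cls(treatment, times, profiles.values[:, idx])


@dataclass
class Trajectory:
    """Simulated cluster trajectories evaluated at the requested times."""

    times: np.ndarray
    values: np.ndarray  # clusters x times
    treatment: str = ""

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values,
            index=range(1, self.values.shape[0] + 1),
            columns=self.times,
        )
        frame.index.name = "cluster"
        return frame

    def plot(self, course: "TimeCourse | None" = None, ax=None):
        """Plot simulated (and optionally observed) cluster trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for i, row in enumerate(self.values):
            (line,) = ax.plot(self.times, row, label=f"cluster {i + 1}")
            if course is not None:
                ax.plot(
                    course.times,
                    course.observed[i],
                    "o--",
                    color=line.get_color(),
                    alpha=0.5,
                )
        ax.set_xlabel("time (h)")
        ax.set_ylabel("log2 fold change")
        ax.legend(fontsize=7, ncol=2)
        return ax


def simulate_trajectory(
    model: InfluenceModel, initial: np.ndarray, times: Sequence[float]
) -> Trajectory:
    """Solve c(t) = expm(A (t - t0)) c(t0) at each requested time.

    The closed-form matrix exponential is exact for a linear system; the
    value at times[0] equals ``initial`` exactly.
    """
    initial = np.asarray(initial, dtype=float)
    times = np.asarray(times, dtype=float)
    if initial.shape != (model.n_clusters,):
        raise ValueError(
            f"initial state has {initial.shape} entries for {model.n_clusters} clusters"
        )
    if not np.isfinite(model.a).all() or not np.isfinite(initial).all():
        raise ValueError("non-finite model or initial state")
    values = np.empty((model.n_clusters, times.size))
    values[:, 0] = initial
    t0 = times[0]
    # strongly unstable matrices (randomisation nulls) can overflow the
    # exponential; the resulting non-finite columns are scored as pattern-free
    with np.errstate(over="ignore", invalid="ignore"):
        for j, t in enumerate(times[1:], start=1):
            values[:, j] = expm(model.a * (t - t0)) @ initial
    return Trajectory(times.copy(), values)


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either vector is constant.

    Non-finite values (e.g. an unstable null matrix whose trajectory
    overflows the exponential) also score 0: a divergent simulation carries
    no usable pattern.
    """
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        return 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        sx = x - x.mean()
        sy = y - y.mean()
        nx = np.sqrt((sx**2).sum())
        ny = np.sqrt((sy**2).sum())
        if nx == 0 or ny == 0 or not (np.isfinite(nx) and np.isfinite(ny)):
            return 0.0
        r = float((sx @ sy) / (nx * ny))
    return r if np.isfinite(r) else 0.0


def weighted_profile_correlation(
    sim_values: np.ndarray, obs_values: np.ndarray, weights: np.ndarray
) -> float:
    """Gene-count-weighted mean of per-cluster Pearson correlations."""
    sim_values = np.asarray(sim_values, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if sim_values.shape != obs_values.shape:
        raise ValueError("simulated and observed shapes differ")
    if weights.shape != (sim_values.shape[0],):
        raise ValueError("one weight per cluster required")
    r = np.array(
        [_pearson_or_zero(sim_values[i], obs_values[i]) for i in range(len(weights))]
    )
    return float(np.sum(weights * r) / np.sum(weights))


def weighted_correlation_performance(
    sim: Trajectory, obs: TimeCourse, gene_counts: np.ndarray
) -> float:
    """Score a simulation against a time course on [-1, 1].

    Per-cluster Pearson correlation across all observation times (the
    anchored initial point included), weighted by cluster gene count.
    """
    if sim.values.shape != obs.observed.shape or not np.array_equal(
        sim.times, obs.times
    ):
        raise ValueError("simulation and observation cover different clusters/times")
    if obs.times.size < 3:
        raise ValueError("need at least 3 time points for a correlation score")
    return weighted_profile_correlation(sim.values, obs.observed, gene_counts)


def rmsd_performance(sim: Trajectory, obs: TimeCourse) -> float:
    """Mean per-cluster RMSD normalised by the observed expression range.

    Clusters with zero observed range are excluded with a warning.  Provided
    as an alternative error metric; correlation is the primary score.
    """
    if sim.values.shape != obs.observed.shape or not np.array_equal(
        sim.times, obs.times
    ):
        raise ValueError("simulation and observation cover different clusters/times")
    out = []
    for i in range(obs.observed.shape[0]):
        rng = obs.observed[i].max() - obs.observed[i].min()
        if rng == 0:
            warnings.warn(
                f"cluster {i + 1} has zero observed range; excluded from RMSD",
                stacklevel=2,
            )
            continue
        rmsd = np.sqrt(np.mean((sim.values[i] - obs.observed[i]) ** 2))
        out.append(rmsd / rng)
    if not out:
        raise ValueError("no cluster with nonzero observed range")
    return float(np.mean(out))
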