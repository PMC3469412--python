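"""Ground-truth models and fully synthetic datasets for the pipeline.

The generator plants a sparse stable influence matrix, simulates
cluster-mean time courses under several treatment conditions, expands
clusters into noisy gene-level profiles, and derives annotation and
interaction data aligned (to a controllable degree) with the planted
structure.  Everything is reproducible from a single seed.

Two expression modes are provided:

* trajectory mode (default): each treatment is a relaxation time course of
  the planted ODE system from a random initial state -- the data the
  dynamic-calibration stages consume;
* equilibrium mode: each sample is the steady state reached under a
  sample-specific constant stimulus, c* = -A^{-1} u -- data that satisfy
  the steady-state regression relation the inference stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discovery import ClusterAssignment
from .dynamics import InfluenceModel, simulate_trajectory
from .expression import ExpressionTable, SampleMeta, cluster_mean_profiles
from .validation import InteractionSet

__all__ = [
    "SyntheticTruth",
    "generate_truth_model",
    "make_truth",
    "generate_expression_dataset",
    "generate_steady_state_dataset",
    "generate_validation_data",
    "generate_probe_stats",
    "DEFAULT_TREATMENTS",
    "DEFAULT_TIMES",
]

DEFAULT_TREATMENTS = ("cpg", "ipc", "lps", "saline", "sham")
DEFAULT_TIMES = (3.0, 24.0, 72.0, 75.0, 96.0)


def generate_truth_model(
    n_clusters: int = 10,
    edge_density: float = 0.1,
    rng: np.random.Generator | int | None = None,
    tau_range: tuple[float, float] = (5.0, 50.0),
    weight_range: tuple[float, float] = (0.1, 1.0),
    stability_margin: float = -0.005,
    cluster_size_range: tuple[int, int] = (20, 100),
    max_shrink_iter: int = 200,
) -> InfluenceModel:
    """Plant a sparse stable influence matrix.

    Off-diagonal edges appear independently with probability
    ``edge_density``; weights have random sign and magnitude uniform in
    ``weight_range``; decay constants are uniform in ``tau_range`` hours.
    Off-diagonal weights are shrunk geometrically until the spectral
    abscissa of A is at most ``stability_margin`` per hour, keeping the
    96-hour trajectories bounded without forcing monotone decay.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = n_clusters
    mask = rng.random((k, k)) < edge_density
    np.fill_diagonal(mask, False)
    weights = np.zeros((k, k))
    weights[mask] = rng.uniform(*weight_range, mask.sum()) * rng.choice(
        [-1.0, 1.0], mask.sum()
    )
    tau = rng.uniform(*tau_range, k)
    sizes = rng.integers(cluster_size_range[0], cluster_size_range[1] + 1, k)
    model = InfluenceModel.from_weights(weights, tau, sizes)
    off = ~np.eye(k, dtype=bool)
    for _ in range(max_shrink_iter):
        if model.spectral_abscissa() <= stability_margin:
            return model
        model.a[off] *= 0.9
    raise RuntimeError(
        f"could not stabilise the planted matrix within {max_shrink_iter} shrinks"
    )


@dataclass
class SyntheticTruth:
    """Planted model plus the stochastic parameters of the emulated study."""

    model: InfluenceModel
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    times: tuple[float, ...] = DEFAULT_TIMES
    sigma_obs: float = 0.1  # cluster-level observation noise (log2FC units)
    sigma_gene: float = 0.3  # gene-level scatter around the cluster value
    purity: float = 0.9  # probability a gene carries its own cluster's term
    concordance: float = 0.9  # fraction of interactions aligned with true edges
    seed: int = 0
    initial_states: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model.spectral_abscissa() >= 0:
            raise ValueError("planted model must be stable")
        if not self.initial_states:
            rng = np.random.default_rng(np.random.SeedSequence((self.seed, 1)))
            self.initial_states = {
                t: rng.normal(0.0, 1.0, self.model.n_clusters)
                for t in self.treatments
            }

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.model.gene_counts

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(int(self.cluster_sizes.sum()))]

    def assignment(self) -> ClusterAssignment:
        mapping = {}
        i = 0
        for c, size in enumerate(self.cluster_sizes, start=1):
            for _ in range(int(size)):
                mapping[f"g{i + 1:04d}"] = c
                i += 1
        return ClusterAssignment(mapping)


def make_truth(
    n_clusters: int = 10,
    edge_density: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> SyntheticTruth:
    """Convenience constructor drawing the planted model from ``seed``."""
    model_kwargs = {
        key: kwargs.pop(key)
        for key in (
            "tau_range", "weight_range", "stability_margin",
            "cluster_size_range", "max_shrink_iter",
        )
        if key in kwargs
    }
    model = generate_truth_model(
        n_clusters,
        edge_density,
        rng=np.random.default_rng(np.random.SeedSequence((seed, 0))),
        **model_kwargs,
    )
    return SyntheticTruth(model=model, seed=seed, **kwargs)


def _expand_to_genes(
    truth: SyntheticTruth, cluster_values: np.ndarray, samples, rng
) -> tuple[ExpressionTable, list[SampleMeta], ClusterAssignment, object]:
    assign = truth.assignment()
    sizes = truth.cluster_sizes
    gene_values = np.repeat(cluster_values, sizes, axis=0)
    if truth.sigma_gene > 0:
        gene_values = gene_values + rng.normal(
            0.0, truth.sigma_gene, gene_values.shape
        )
    table = ExpressionTable(truth.gene_ids(), gene_values, list(samples))
    profiles = cluster_mean_profiles(table, assign)
    return table, table.samples, assign, profiles


def generate_expression_dataset(truth: SyntheticTruth):
    """Trajectory-mode dataset: one planted-ODE time course per treatment.

    Returns ``(table, samples, assignment, profiles)`` where the profile
    matrix is the exact cluster mean of the generated gene table.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 2)))
    samples, columns = [], []
    for treatment in truth.treatments:
        traj = simulate_trajectory(
            truth.model, truth.initial_states[treatment], truth.times
        )
        observed = traj.values
        if truth.sigma_obs > 0:
            observed = observed + rng.normal(0.0, truth.sigma_obs, observed.shape)
        for j, t in enumerate(truth.times):
            samples.append(SampleMeta(treatment, float(t), f"{treatment}_{t:g}"))
            columns.append(observed[:, j])
    cluster_values = np.column_stack(columns)
    return _expand_to_genes(truth, cluster_values, samples, rng)


def generate_steady_state_dataset(truth: SyntheticTruth):
    """Equilibrium-mode dataset: steady states under per-sample constant inputs.

    Each (treatment, time) sample receives an independent stimulus vector
    u ~ N(0, 1) and the cluster values are the equilibria c* = -A^{-1} u of
    the planted system, so each cluster satisfies the steady-state relation
    c_i = tau_i (sum_l w_il c_l + u_i) exactly before observation noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 3)))
    k = truth.model.n_clusters
    n = len(truth.treatments) * len(truth.times)
    inputs = rng.normal(0.0, 1.0, (k, n))
    cluster_values = np.linalg.solve(-truth.model.a, inputs)
    if truth.sigma_obs > 0:
        cluster_values = cluster_values + rng.normal(
            0.0, truth.sigma_obs, cluster_values.shape
        )
    samples = [
        SampleMeta(treatment, float(t), f"{treatment}_{t:g}")
        for treatment in truth.treatments
        for t in truth.times
    ]
    return _expand_to_genes(truth, cluster_values, samples, rng)


def generate_validation_data(
    truth: SyntheticTruth,
    n_sets: int = 2,
    per_edge_count: float = 10.0,
) -> tuple[dict[str, set[str]], list[InteractionSet]]:
    """Annotations of controllable purity plus interaction sets.

    Annotations: one private term per planted cluster; each gene carries its
    own cluster's term with probability ``purity``, otherwise a uniformly
    random other cluster's term.

    Interactions: for every true edge (regulator cluster l -> target i),
    regulator-gene/target-gene pairs are included so the expected count per
    true edge is ``per_edge_count * concordance``; uniformly random
    background pairs add an expected ``per_edge_count * (1 - concordance)``
    per true edge in total.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 4)))
    assign = truth.assignment()
    genes = np.array(sorted(assign.mapping))
    labels = np.array([assign.mapping[g] for g in genes])
    k = truth.model.n_clusters

    annot: dict[str, set[str]] = {}
    for g, c in zip(genes, labels):
        if truth.purity >= 1 or rng.uniform() < truth.purity:
            term = c
        else:
            term = int(rng.choice([x for x in range(1, k + 1) if x != c]))
        annot[str(g)] = {f"term_c{term}"}

    support = truth.model.off_diagonal_support()
    true_edges = np.argwhere(support)  # rows: (target i, regulator l)
    members = {c: genes[labels == c] for c in range(1, k + 1)}
    sets = []
    for s_idx in range(n_sets):
        edges: list[tuple[str, str]] = []
        kappa = truth.concordance
        for i, l in true_edges:
            reg, tgt = members[l + 1], members[i + 1]
            p_pair = min(1.0, per_edge_count * kappa / (len(reg) * len(tgt)))
            hits = rng.random((len(reg), len(tgt))) < p_pair
            for a, b in np.argwhere(hits):
                edges.append((str(reg[a]), str(tgt[b])))
        n_background = rng.poisson(per_edge_count * (1 - kappa) * max(len(true_edges), 1))
        for _ in range(n_background):
            a, b = rng.choice(genes, 2)
            edges.append((str(a), str(b)))
        sets.append(InteractionSet(f"synthetic_{s_idx + 1}", edges, directed=True))
    return annot, sets


def generate_probe_stats(truth: SyntheticTruth, table: ExpressionTable):
    """Synthetic differential-expression statistics for the probe filter.

    Fold changes are computed from the generated table (so weakly changing
    genes genuinely fail the 2-fold cut); p-values are drawn small for
    genes with substantial fold change and large otherwise.
    """
    from .expression import ProbeStats

    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 5)))
    max_abs_log2 = np.abs(table.values).max(axis=1)
    stats = []
    for g, m in zip(table.gene_ids, max_abs_log2):
        changed = m > 0.5
        p = rng.uniform(0.0001, 0.04) if changed else rng.uniform(0.06, 0.9)
        stats.append(ProbeStats(g, float(p), float(2.0**m)))
    return stats
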