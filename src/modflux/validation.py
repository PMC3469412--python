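"""External validation of model edges against gene-gene interaction sets.

Interactions (ChIP regulator-target pairs, protein-protein contacts,
curated regulatory neighbourhoods, inferred functional links, ...) are
counted between every ordered cluster pair; significance of each count is
assessed by permuting clustered-gene identities across the edge list
(topology and degree sequence preserved) and re-counting.  Cluster pairs
are then labelled against the model's edges:

* model edge present, count significant   -> TP
* model edge present, count not significant -> FN
* no model edge, count not significant    -> TN
* no model edge, count significant        -> FP

and per-dataset accuracy is (TP+TN)/(TP+TN+FP+FN).  The labelling follows
the validation protocol literally even though a conventional confusion
matrix would name the second case differently.  A combined "any" accuracy
counts a pair correct if at least one dataset yields TP or TN for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import ClusterAssignment
from .dynamics import InfluenceModel

__all__ = [
    "InteractionSet",
    "read_interaction_set",
    "pair_interaction_counts",
    "rewire_pvalues",
    "validation_accuracy",
    "ValidationTable",
]

logger = logging.getLogger(__name__)


@dataclass
class InteractionSet:
    """A named list of gene-gene edges, directed or undirected.

    Duplicate edges collapse (for undirected sets, (a,b) and (b,a) are the
    same edge); self-edges are permitted.
    """

    name: str
    edges: list[tuple[str, str]]
    directed: bool = True

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        for a, b in self.edges:
            key = (a, b) if self.directed else (min(a, b), max(a, b))
            seen.setdefault(key, None)
        self.edges = list(seen)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def read_interaction_set(path, name: str | None = None) -> InteractionSet:
    """Read a ``gene_a\tgene_b`` TSV; a ``#directed=false`` first line marks
    the set undirected (default directed)."""
    directed = True
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#directed="):
            directed = first.split("=", 1)[1].strip().lower() in ("true", "1", "yes")
            df = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("interaction file needs columns gene_a, gene_b")
    edges = list(zip(df["gene_a"], df["gene_b"]))
    return InteractionSet(name or str(path), edges, directed)


def _usable_edge_indices(
    assign: ClusterAssignment, iset: InteractionSet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Map edges with both endpoints clustered to gene-index arrays."""
    genes = sorted(assign.mapping)
    gene_idx = {g: i for i, g in enumerate(genes)}
    src, dst = [], []
    dropped = 0
    for a, b in iset.edges:
        if a in gene_idx and b in gene_idx:
            src.append(gene_idx[a])
            dst.append(gene_idx[b])
        else:
            dropped += 1
    if dropped:
        logger.info(
            "%s: dropped %d edges with unclustered endpoints (%d kept)",
            iset.name, dropped, len(src),
        )
    return np.asarray(src, dtype=int), np.asarray(dst, dtype=int), genes


def _count_from_labels(
    src_cl: np.ndarray, dst_cl: np.ndarray, k: int, directed: bool
) -> np.ndarray:
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (src_cl, dst_cl), 1)
    if not directed:
        np.add.at(counts, (dst_cl, src_cl), 1)
    return counts


def pair_interaction_counts(
    assign: ClusterAssignment, iset: InteractionSet
) -> np.ndarray:
    """Clusters x clusters edge counts (row = source cluster).

    Undirected edges contribute to both ordered pairs (and twice to the
    diagonal when both endpoints share a cluster); edges touching
    unclustered genes are dropped.
    """
    src, dst, genes = _usable_edge_indices(assign, iset)
    k = assign.n_clusters
    if src.size == 0:
        return np.zeros((k, k), dtype=int)
    labels = np.array([assign.mapping[g] - 1 for g in genes])
    return _count_from_labels(labels[src], labels[dst], k, iset.directed)


def rewire_pvalues(
    assign: ClusterAssignment,
    iset: InteractionSet,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation p-values for every ordered cluster-pair count.

    Each null replicate applies one uniformly random permutation of the
    clustered-gene identities to all edge endpoints, preserving the edge
    topology and degree sequence, then re-counts.  p = (1 + #{null >=
    observed}) / (n_reps + 1), add-one smoothed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(assign.mapping) < 2:
        raise ValueError("need at least 2 clustered genes to permute")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    src, dst, genes = _usable_edge_indices(assign, iset)
    k = assign.n_clusters
    labels = np.array([assign.mapping[g] - 1 for g in genes])
    observed = (
        _count_from_labels(labels[src], labels[dst], k, iset.directed)
        if src.size
        else np.zeros((k, k), dtype=int)
    )
    exceed = np.zeros((k, k), dtype=int)
    for _ in range(n_reps):
        perm = rng.permutation(labels.size)
        null_labels = labels[perm]
        null = (
            _count_from_labels(null_labels[src], null_labels[dst], k, iset.directed)
            if src.size
            else np.zeros((k, k), dtype=int)
        )
        exceed += null >= observed
    return (1 + exceed) / (n_reps + 1)


@dataclass
class ValidationTable:
    """Per-pair labels and accuracies for one or more interaction datasets."""

    table: pd.DataFrame  # dataset, source, target, p_value, model_edge, label
    per_dataset_accuracy: dict[str, float]
    combined_accuracy: float  # "any"-dataset accuracy
    within_cluster: pd.DataFrame  # dataset, cluster, p_value (diagnostic)
    alpha: float = 0.05
    counts: dict[str, np.ndarray] = field(default_factory=dict)


def validation_accuracy(
    model: InfluenceModel,
    pvals: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> ValidationTable:
    """Label every ordered off-diagonal cluster pair per dataset.

    ``pvals`` maps dataset name to a K x K p-value matrix from
    :func:`rewire_pvalues`.  Within-cluster (diagonal) p-values are reported
    as a separate diagnostic and do not enter accuracy.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = model.n_clusters
    for name, mat in pvals.items():
        if np.asarray(mat).shape != (k, k):
            raise ValueError(f"p-value matrix {name!r} does not match model size")
    # counts/p-values are (source -> target); A rows are targets, so transpose
    support = model.off_diagonal_support().T
    rows = []
    within = []
    per_acc = {}
    pair_correct: dict[tuple[int, int], bool] = {}
    for name, mat in pvals.items():
        mat = np.asarray(mat)
        tp = tn = fp = fn = 0
        for s in range(k):
            within.append({"dataset": name, "cluster": s + 1, "p_value": mat[s, s]})
            for t in range(k):
                if s == t:
                    continue
                edge = bool(support[s, t])
                sig = bool(mat[s, t] < alpha)
                if edge and sig:
                    label = "TP"
                    tp += 1
                elif edge:
                    label = "FN"
                    fn += 1
                elif not sig:
                    label = "TN"
                    tn += 1
                else:
                    label = "FP"
                    fp += 1
                rows.append(
                    {
                        "dataset": name,
                        "source": s + 1,
                        "target": t + 1,
                        "p_value": mat[s, t],
                        "model_edge": edge,
                        "label": label,
                    }
                )
                if label in ("TP", "TN"):
                    pair_correct[(s, t)] = True
                else:
                    pair_correct.setdefault((s, t), False)
        per_acc[name] = (tp + tn) / (tp + tn + fp + fn)
    n_pairs = k * (k - 1)
    combined = sum(pair_correct.values()) / n_pairs if pvals else float("nan")
    return ValidationTable(
        table=pd.DataFrame(rows),
        per_dataset_accuracy=per_acc,
        combined_accuracy=float(combined),
        within_cluster=pd.DataFrame(within),
        alpha=alpha,
    )
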