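"""Functional-module discovery.

Genes are clustered by hierarchical agglomeration (Ward's minimum-variance
linkage on Euclidean distances between log2 fold-change profiles) and the
tree is cut at a sweep of candidate division counts.  Each division is
scored by *functional coherence*: the number of genes that carry at least
one annotation term significantly enriched (one-sided hypergeometric test
against all other clustered genes) in the gene's own cluster.  The division
maximising coherence is selected as the working set of functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .expression import ExpressionTable

__all__ = [
    "ClusterAssignment",
    "AnnotationMap",
    "CoherenceCurve",
    "build_tree_and_cut",
    "enrich_cluster",
    "coherence_curve",
    "read_annotations",
    "cluster_correlation_diagnostic",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Gene -> cluster index mapping with contiguous indices 1..K."""

    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty cluster assignment")
        labels = sorted(set(self.mapping.values()))
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError(
                f"cluster indices must be contiguous 1..K, got {labels[:10]}..."
            )

    @property
    def n_clusters(self) -> int:
        return max(self.mapping.values())

    @property
    def genes(self) -> list[str]:
        return list(self.mapping)

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.mapping.items() if c == cluster]

    def gene_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_clusters, dtype=int)
        for c in self.mapping.values():
            counts[c - 1] += 1
        return counts

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.mapping), "cluster": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cluster": int})
        return cls(dict(zip(df["gene_id"], df["cluster"])))


#: gene -> set of functional term ids (term ids are opaque strings)
AnnotationMap = dict


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column ``gene_id\tterm_id`` TSV into an annotation map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation file needs columns gene_id, term_id")
    annot: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        annot.setdefault(g, set()).add(t)
    return annot


@dataclass
class CoherenceCurve:
    """Coherence scores over (division, enrichment threshold) combinations."""

    divisions: list[int]
    thresholds: list[float]
    scores: np.ndarray  # divisions x thresholds, gene counts
    n_annotated: int
    best_division: dict[float, int] = field(default_factory=dict)

    @property
    def normalized(self) -> np.ndarray:
        """Scores divided by the number of annotated genes (0 if none)."""
        if self.n_annotated == 0:
            return np.zeros_like(self.scores, dtype=float)
        return self.scores / self.n_annotated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.divisions, columns=self.thresholds
        ).rename_axis(index="division", columns="threshold")


def build_tree_and_cut(
    table: "ExpressionTable", divisions: Iterable[int]
) -> dict[int, ClusterAssignment]:
    """Cut one Ward tree of gene profiles at each requested cluster count.

    All requested divisions are cuts of the same tree, so the partitions are
    nested: every cluster at K' > K is a subset of some cluster at K.
    """
    divisions = list(divisions)
    n = len(table.gene_ids)
    if n < 2:
        raise ValueError("need at least 2 genes to build a tree")
    for k in divisions:
        if not 1 <= k <= n:
            raise ValueError(f"division K={k} outside [1, {n}]")
    tree = linkage(table.values, method="ward")
    out: dict[int, ClusterAssignment] = {}
    for k in divisions:
        raw = fcluster(tree, t=k, criterion="maxclust")
        # relabel to contiguous 1..K in order of first appearance (determinism)
        relabel: dict[int, int] = {}
        for lab in raw:
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
        out[k] = ClusterAssignment(
            {g: relabel[lab] for g, lab in zip(table.gene_ids, raw)}
        )
    return out


def enrich_cluster(
    cluster_genes: set[str],
    universe: set[str],
    annot: Mapping[str, set[str]],
    term: str,
) -> float:
    """One-sided hypergeometric tail P(X >= observed) for one term in one cluster.

    The urn is the clustered-gene universe, successes are genes annotated with
    ``term``, and the draw is the cluster.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not cluster_genes <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    n_universe = len(universe)
    term_genes = {g for g in universe if term in annot.get(g, ())}
    n_term = len(term_genes)
    n_cluster = len(cluster_genes)
    observed = len(cluster_genes & term_genes)
    if observed == 0:
        return 1.0
    return float(hypergeom.sf(observed - 1, n_universe, n_term, n_cluster))


def coherence_curve(
    assignments: Mapping[int, ClusterAssignment],
    annot: Mapping[str, set[str]],
    thresholds: Iterable[float],
) -> CoherenceCurve:
    """Score every division at every enrichment threshold.

    For each cluster, every term annotating at least one member gene is
    tested; a gene counts toward coherence if at least one of its own terms
    is enriched (p < threshold) in its own cluster.  Ties in the best
    division resolve to the smallest K.
    """
    thresholds = list(thresholds)
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"threshold {t} outside (0, 1)")
    divisions = sorted(assignments)
    scores = np.zeros((len(divisions), len(thresholds)), dtype=int)
    universe_genes: set[str] = set()
    for d_idx, k in enumerate(divisions):
        assign = assignments[k]
        universe = set(assign.mapping)
        universe_genes = universe
        for c in range(1, assign.n_clusters + 1):
            members = set(assign.members(c))
            terms_here = set().union(*(annot.get(g, set()) for g in members))
            if not terms_here:
                continue
            pvals = {
                term: enrich_cluster(members, universe, annot, term)
                for term in terms_here
            }
            for t_idx, thr in enumerate(thresholds):
                enriched = {term for term, p in pvals.items() if p < thr}
                if not enriched:
                    continue
                scores[d_idx, t_idx] += sum(
                    1 for g in members if annot.get(g, set()) & enriched
                )
    n_annotated = sum(1 for g in universe_genes if annot.get(g))
    best = {
        thr: divisions[int(np.argmax(scores[:, t_idx]))]
        for t_idx, thr in enumerate(thresholds)
    }
    return CoherenceCurve(divisions, thresholds, scores, n_annotated, best)


def cluster_correlation_diagnostic(
    table: "ExpressionTable", assign: ClusterAssignment
) -> tuple[float, float]:
    """Mean within-cluster vs between-cluster Pearson correlation of gene rows.

    A descriptive check of cluster tightness; it plays no role in selecting
    the division.
    """
    idx = {g: i for i, g in enumerate(table.gene_ids)}
    rows = table.values
    corr = np.corrcoef(rows)
    labels = np.array([assign.mapping[g] for g in table.gene_ids if g in assign.mapping])
    sel = np.array([idx[g] for g in table.gene_ids if g in assign.mapping])
    corr = corr[np.ix_(sel, sel)]
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    within = corr[same & off_diag]
    between = corr[~same]
    return (
        float(np.mean(within)) if within.size else float("nan"),
        float(np.mean(between)) if between.size else float("nan"),
    )
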