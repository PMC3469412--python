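"""Ensemble summaries and condition-group consensus models.

An annealing stage yields an ensemble of optimised matrices; the summary
counts how often each edge appears and combines weights by mean / median
(absent treated as zero).  Condition-level champion models can be merged
into group consensus models -- an edge survives if present in at least a
configured fraction (default half) of the member models, with the weight
averaged over the members that contain it -- and two groups are compared
edge-by-edge into conserved / differential / opposite-sign classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .dynamics import InfluenceModel

__all__ = [
    "EdgeSummary",
    "GroupConsensusModel",
    "ensemble_summary",
    "group_consensus",
    "compare_groups",
]


@dataclass
class EdgeSummary:
    """Per-cell presence counts and weight statistics across an ensemble."""

    n_models: int
    counts: np.ndarray
    mean: np.ndarray  # absent edges enter as 0
    median: np.ndarray
    weight_min: np.ndarray
    weight_max: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.counts.shape[0]
        rows = []
        for s in range(k):
            for t in range(k):
                if s == t or self.counts[s, t] == 0:
                    continue
                rows.append(
                    {
                        "target": s + 1,
                        "regulator": t + 1,
                        "count": int(self.counts[s, t]),
                        "mean": self.mean[s, t],
                        "median": self.median[s, t],
                        "min": self.weight_min[s, t],
                        "max": self.weight_max[s, t],
                    }
                )
        return pd.DataFrame(rows)


def _check_same_shape(models: list[InfluenceModel]) -> int:
    if not models:
        raise ValueError("empty model list")
    k = models[0].n_clusters
    for m in models:
        if m.n_clusters != k:
            raise ValueError("models have mismatched cluster counts")
    return k


def ensemble_summary(models: list[InfluenceModel]) -> EdgeSummary:
    """Edge presence counts and weight statistics over an ensemble.

    Mean and median are taken over *all* ensemble values with absent edges
    contributing 0, matching the combined-model construction.
    """
    _check_same_shape(models)
    stack = np.stack([m.a for m in models])
    counts = (stack != 0).sum(axis=0)
    return EdgeSummary(
        n_models=len(models),
        counts=counts,
        mean=stack.mean(axis=0),
        median=np.median(stack, axis=0),
        weight_min=stack.min(axis=0),
        weight_max=stack.max(axis=0),
    )


@dataclass
class GroupConsensusModel:
    """Consensus matrix for one condition group (e.g. injurious)."""

    label: str
    members: list[InfluenceModel]
    matrix: np.ndarray
    presence_fraction: np.ndarray  # fraction of members containing each edge
    threshold: float

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[0]

    def support(self) -> np.ndarray:
        mask = self.matrix != 0
        np.fill_diagonal(mask, False)
        return mask


def group_consensus(
    best_models: list[InfluenceModel],
    label: str = "",
    presence_fraction: float = 0.5,
) -> GroupConsensusModel:
    """Merge one champion model per member condition into a group model.

    An off-diagonal edge is kept when nonzero in at least
    ceil(presence_fraction * n_members) members; its weight is the mean over
    the members in which it is present.  Edges that average to exactly zero
    are treated as absent.  The diagonal is averaged over all members.
    """
    k = _check_same_shape(best_models)
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    n = len(best_models)
    need = ceil(presence_fraction * n)
    stack = np.stack([m.a for m in best_models])
    present = stack != 0
    n_present = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_present = np.where(
            n_present > 0, stack.sum(axis=0) / np.maximum(n_present, 1), 0.0
        )
    matrix = np.where(n_present >= need, mean_present, 0.0)
    np.fill_diagonal(matrix, stack.mean(axis=0).diagonal())
    return GroupConsensusModel(
        label=label,
        members=list(best_models),
        matrix=matrix,
        presence_fraction=n_present / n,
        threshold=presence_fraction,
    )


def compare_groups(a: GroupConsensusModel, b: GroupConsensusModel) -> pd.DataFrame:
    """Classify every edge present in at least one group.

    conserved -- present in both with the same sign; differential -- present
    in exactly one group; opposite -- present in both with opposite signs.
    """
    if a.n_clusters != b.n_clusters:
        raise ValueError("group models have mismatched cluster counts")
    sup_a, sup_b = a.support(), b.support()
    rows = []
    for s, t in np.argwhere(sup_a | sup_b):
        wa, wb = a.matrix[s, t], b.matrix[s, t]
        if sup_a[s, t] and sup_b[s, t]:
            status = "conserved" if np.sign(wa) == np.sign(wb) else "opposite"
        else:
            status = "differential"
        rows.append(
            {
                "target": s + 1,
                "regulator": t + 1,
                "weight_a": wa,
                "weight_b": wb,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows, columns=["target", "regulator", "weight_a", "weight_b", "status"]
    )
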