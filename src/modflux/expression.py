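"""Expression tables, sample metadata, probe filtering and cluster means.

The pipeline starts from a genes x samples matrix of log2 fold changes
relative to an untreated baseline, with each sample labelled by a treatment
and a time in hours.  Upstream array processing (normalisation, probe
summarisation) is out of scope; the significance filter operates on
per-gene differential-expression statistics supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discovery import ClusterAssignment

__all__ = [
    "SampleMeta",
    "ExpressionTable",
    "ProbeStats",
    "ClusterProfileMatrix",
    "read_expression_table",
    "write_expression_table",
    "read_probe_stats",
    "filter_probes",
    "cluster_mean_profiles",
]


class ExpressionFormatError(ValueError):
    """Malformed expression table (duplicates, non-numeric, non-finite)."""


class MetadataError(ValueError):
    """Sample metadata inconsistent with the expression table."""


@dataclass(frozen=True, order=True)
class SampleMeta:
    """One sample: a treatment label and hours post-pretreatment."""

    treatment: str
    time_h: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise MetadataError(f"negative time for sample {self.sample!r}")


@dataclass
class ExpressionTable:
    """Genes x samples log2 fold-change matrix with per-sample metadata.

    Columns are kept sorted by (treatment, time_h) so downstream behaviour
    does not depend on file column order.
    """

    gene_ids: list[str]
    values: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ExpressionFormatError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ExpressionFormatError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ExpressionFormatError("non-finite expression values")
        keys = [(s.treatment, s.time_h) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise MetadataError("duplicate (treatment, time_h) sample pairs")
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        if order != list(range(len(keys))):
            self.samples = [self.samples[i] for i in order]
            self.values = self.values[:, order]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.treatment, None)
        return list(seen)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes absent from table: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionTable(list(gene_ids), self.values[rows], list(self.samples))

    def to_frame(self) -> pd.DataFrame:
        cols = [s.sample or f"{s.treatment}_{s.time_h:g}" for s in self.samples]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


def read_expression_table(path, meta_path) -> ExpressionTable:
    """Read an expression TSV and its sample-metadata TSV.

    The expression file has a ``gene_id`` first column and one column per
    sample; the metadata file has columns ``sample``, ``treatment``,
    ``time_h``.  Every expression column must be described by exactly one
    metadata row.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ExpressionFormatError("first column must be 'gene_id'")
    meta = pd.read_csv(meta_path, sep="\t")
    if not {"sample", "treatment", "time_h"} <= set(meta.columns):
        raise MetadataError("metadata needs columns sample, treatment, time_h")
    sample_cols = list(df.columns[1:])
    meta_samples = list(meta["sample"].astype(str))
    unknown = set(meta_samples) - set(sample_cols)
    if unknown:
        raise MetadataError(f"metadata samples absent from header: {sorted(unknown)}")
    missing = set(sample_cols) - set(meta_samples)
    if missing:
        raise MetadataError(f"samples missing metadata: {sorted(missing)}")
    try:
        values = df[sample_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise ExpressionFormatError(f"non-numeric expression cell: {exc}") from exc
    by_name = {
        str(r["sample"]): SampleMeta(str(r["treatment"]), float(r["time_h"]), str(r["sample"]))
        for _, r in meta.iterrows()
    }
    samples = [by_name[c] for c in sample_cols]
    return ExpressionTable(list(df["gene_id"]), values, samples)


def write_expression_table(table: ExpressionTable, path, meta_path, precision: int = 6) -> None:
    """Write a table and metadata so a read round-trips to equal values."""
    frame = table.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=f"%.{precision}g")
    pd.DataFrame(
        {
            "sample": [s.sample or f"{s.treatment}_{s.time_h:g}" for s in table.samples],
            "treatment": [s.treatment for s in table.samples],
            "time_h": [s.time_h for s in table.samples],
        }
    ).to_csv(meta_path, sep="\t", index=False)


@dataclass(frozen=True)
class ProbeStats:
    """Differential-expression summary for one gene/probe set."""

    gene_id: str
    p_value: float
    max_abs_fc: float  # maximum absolute *linear* fold change over conditions

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.max_abs_fc < 0:
            raise ValueError("max_abs_fc must be >= 0")


def read_probe_stats(path) -> list[ProbeStats]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        ProbeStats(r["gene_id"], float(r["p_value"]), float(r["max_abs_fc"]))
        for _, r in df.iterrows()
    ]


def filter_probes(
    stats: Iterable[ProbeStats], p_max: float = 0.05, fc_min: float = 2.0
) -> list[str]:
    """Keep genes with p < p_max and linear fold change > fc_min (both strict).

    The defaults are the conventional significance filter for two-colour
    fold-change designs: p below 0.05 and at least a two-fold change.
    """
    if not 0 < p_max < 1:
        raise ValueError(f"p_max {p_max} outside (0, 1)")
    if fc_min <= 1:
        raise ValueError(f"fc_min {fc_min} must exceed 1 on the linear scale")
    return [s.gene_id for s in stats if s.p_value < p_max and s.max_abs_fc > fc_min]


@dataclass
class ClusterProfileMatrix:
    """Clusters x samples matrix of mean member-gene log2 fold changes."""

    cluster_ids: list[int]
    values: np.ndarray
    gene_counts: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_counts = np.asarray(self.gene_counts, dtype=int)
        if (self.gene_counts <= 0).any():
            raise ValueError("gene_counts must be positive")
        if self.values.shape != (len(self.cluster_ids), len(self.samples)):
            raise ValueError("profile matrix shape mismatch")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [s.sample or f"{s.treatment}_{s.time_h:g}" for s in self.samples]
        frame = pd.DataFrame(self.values, index=self.cluster_ids, columns=cols)
        frame.index.name = "cluster"
        return frame


def cluster_mean_profiles(
    table: ExpressionTable, assign: ClusterAssignment
) -> ClusterProfileMatrix:
    """Unweighted mean of member-gene rows for each cluster."""
    idx = {g: i for i, g in enumerate(table.gene_ids)}
    missing = [g for g in assign.mapping if g not in idx]
    if missing:
        raise KeyError(f"clustered genes absent from table: {missing[:5]}")
    k = assign.n_clusters
    values = np.zeros((k, len(table.samples)))
    counts = np.zeros(k, dtype=int)
    for g, c in assign.mapping.items():
        values[c - 1] += table.values[idx[g]]
        counts[c - 1] += 1
    if (counts == 0).any():
        empty = [c + 1 for c in np.where(counts == 0)[0]]
        raise ValueError(f"clusters with zero members: {empty}")
    values /= counts[:, None]
    return ClusterProfileMatrix(list(range(1, k + 1)), values, counts, list(table.samples))
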