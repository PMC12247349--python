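"""Count-matrix normalization and clustered expression summaries.

Counts are scaled to counts per million (CPM) per sample, log2-transformed
after adding a pseudocount of 1, and hierarchically clustered (Euclidean
distance, complete linkage by default) to order genes and samples for
heatmap-style reporting. A gene is flagged expressed when it reaches
CPM >= 1 in at least one sample; both thresholds are configurable and
echoed into output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CountMatrix",
    "ExpressionSummary",
    "cpm_log2",
    "flag_expressed",
    "cluster_heatmap_order",
    "summarize_expression",
    "read_count_matrix",
]


@dataclass
class CountMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # genes x samples, non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionSummary:
    log2cpm: pd.DataFrame
    expressed: pd.Series  # bool per gene
    gene_order: list[int]
    sample_order: list[int]
    min_cpm: float
    pseudocount: float


def read_count_matrix(path) -> CountMatrix:
    """Read a genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
    )


def cpm_log2(m: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); errors on a sample with zero total counts."""
    colsum = m.counts.sum(axis=0, dtype=float)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"sample {m.sample_ids[zero[0]]!r} has zero total counts")
    cpm = m.counts * 1e6 / colsum[None, :]
    return pd.DataFrame(
        np.log2(cpm + pseudocount), index=m.gene_ids, columns=m.sample_ids
    )


def flag_expressed(
    log2cpm: pd.DataFrame, min_cpm: float = 1.0, pseudocount: float = 1.0
) -> pd.Series:
    """Expressed iff CPM >= min_cpm in at least one sample."""
    threshold = np.log2(min_cpm + pseudocount)
    return (log2cpm >= threshold).any(axis=1)


def cluster_heatmap_order(
    log2cpm: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "complete",
) -> tuple[list[int], list[int], np.ndarray, np.ndarray]:
    """Agglomerative leaf orders for genes (rows) and samples (columns).

    Returns (gene_order, sample_order, gene_linkage, sample_linkage). Leaf
    order is deterministic; scipy breaks merge ties by input index.
    """
    if log2cpm.shape[0] < 2 or log2cpm.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")
    x = log2cpm.to_numpy()
    zg = linkage(pdist(x, metric=distance), method=linkage_method)
    zs = linkage(pdist(x.T, metric=distance), method=linkage_method)
    return list(leaves_list(zg)), list(leaves_list(zs)), zg, zs


def summarize_expression(
    m: CountMatrix,
    pseudocount: float = 1.0,
    min_cpm: float = 1.0,
    distance: str = "euclidean",
    linkage_method: str = "complete",
) -> ExpressionSummary:
    log2cpm = cpm_log2(m, pseudocount)
    expressed = flag_expressed(log2cpm, min_cpm, pseudocount)
    if m.counts.shape[0] >= 2 and m.counts.shape[1] >= 2:
        gene_order, sample_order, _, _ = cluster_heatmap_order(
            log2cpm, distance, linkage_method
        )
    else:
        gene_order = list(range(m.counts.shape[0]))
        sample_order = list(range(m.counts.shape[1]))
    return ExpressionSummary(
        log2cpm=log2cpm,
        expressed=expressed,
        gene_order=gene_order,
        sample_order=sample_order,
        min_cpm=min_cpm,
        pseudocount=pseudocount,
    )
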