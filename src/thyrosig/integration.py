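"""Cross-dataset integration: common genes, per-dataset z-scores, Ward
clustering and PCA.

Cell-line profiles and tissue-cohort profiles come from different platforms
and batches, so they are made comparable by (i) restricting to the genes
common to both datasets and (ii) standardizing every gene within each
dataset to zero mean and unit (sample, n-1) standard deviation. The merged
z-scored matrix is then analyzed unsupervised: agglomerative clustering of
samples on Euclidean distances with Ward's minimum-variance criterion
(the Ward.D2 update), and principal component analysis, optionally
restricted to a gene signature (the BRAF-RAS signature reproduces the
subtype co-clustering analysis). An adjusted Rand index quantifies the
agreement between a clustering and known sample classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .containers import ExpressionMatrix, GeneSignature, MergedDataset, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_by_dataset",
    "merge_common",
    "merge_and_standardize",
    "ClusterResult",
    "ward_cluster",
    "PCAResult",
    "pca_project",
    "cluster_agreement",
]


def zscore_by_dataset(expr: ExpressionMatrix, batch: pd.Series) -> ExpressionMatrix:
    """Standardize each gene within each dataset (batch) to mean 0, SD 1.

    The SD uses the n-1 divisor. Genes with zero variance in any batch are
    dropped from the output entirely (a per-batch zero SD would produce
    non-finite values and spurious distances); the dropped list is logged.
    Every batch needs >= 2 samples.
    """
    batch = batch.reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    out = expr.data.copy()
    degenerate: set[str] = set()
    for label, samples in batch.groupby(batch).groups.items():
        cols = list(samples)
        if len(cols) < 2:
            raise ValueError(f"batch {label!r} has a single sample; cannot z-score")
        block = out[cols]
        sd = block.std(axis=1, ddof=1)
        zero = sd[sd == 0].index
        degenerate.update(zero)
        out[cols] = block.sub(block.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)
    if degenerate:
        logger.info(
            "zscore_by_dataset: dropped %d zero-variance genes: %s",
            len(degenerate),
            sorted(degenerate)[:10],
        )
        out = out.drop(index=sorted(degenerate))
    if out.shape[0] == 0:
        raise ValueError("all genes had zero variance in some batch")
    return ExpressionMatrix(out)


def merge_common(
    expr_a: ExpressionMatrix, expr_b: ExpressionMatrix
) -> tuple[ExpressionMatrix, pd.Series]:
    """Join two datasets on their common genes (sorted for determinism).

    Returns the concatenated matrix plus a per-sample batch label series
    (``"a"`` / ``"b"``). Sample-id collisions across datasets and empty
    gene intersections are errors.
    """
    common = sorted(set(expr_a.gene_ids) & set(expr_b.gene_ids))
    if not common:
        raise ValueError("the two datasets share no genes")
    collision = set(expr_a.sample_ids) & set(expr_b.sample_ids)
    if collision:
        raise ValueError(f"sample ids present in both datasets: {sorted(collision)[:10]}")
    merged = pd.concat([expr_a.data.loc[common], expr_b.data.loc[common]], axis=1)
    batch = pd.Series(
        ["a"] * len(expr_a.sample_ids) + ["b"] * len(expr_b.sample_ids),
        index=merged.columns,
        name="dataset",
    )
    return ExpressionMatrix(merged), batch


def merge_and_standardize(
    expr_a: ExpressionMatrix,
    ann_a: SampleAnnotation,
    expr_b: ExpressionMatrix,
    ann_b: SampleAnnotation,
) -> MergedDataset:
    """Full integration step: common genes, per-dataset z-scores, labels.

    Batch labels come from the annotations' ``dataset`` column and group
    labels from ``group``; each gene of the result has mean ~0 / SD 1
    within each batch.
    """
    merged, _ = merge_common(expr_a, expr_b)
    ann = pd.concat([ann_a.table, ann_b.table], ignore_index=True)
    ann = ann.set_index("sample_id").loc[merged.sample_ids]
    batch = ann["dataset"]
    z = zscore_by_dataset(merged, batch)
    return MergedDataset(values=z.data, batch=batch, group=ann["group"])


def _restricted_values(data: MergedDataset, restrict: GeneSignature | None) -> np.ndarray:
    if restrict is None:
        return data.values.to_numpy().T
    present = [g for g in restrict.genes if g in data.values.index]
    if len(present) < 2:
        raise ValueError(
            f"signature {restrict.name!r} has {len(present)} gene(s) in the merged data; need >= 2"
        )
    return data.values.loc[present].to_numpy().T


@dataclass
class ClusterResult:
    """Ward merge tree over samples plus helpers to cut it.

    ``linkage_matrix`` is in scipy format (child1, child2, height, size);
    heights are non-decreasing for Ward linkage.
    """

    linkage_matrix: np.ndarray
    sample_ids: list[str]

    def labels(self, k: int) -> pd.Series:
        """Flat cluster assignment with exactly k clusters."""
        if k > len(self.sample_ids):
            raise ValueError(f"cannot cut {len(self.sample_ids)} samples into {k} clusters")
        lab = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name="cluster")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ward_cluster(
    data: MergedDataset, restrict: GeneSignature | None = None
) -> ClusterResult:
    """Hierarchical clustering of samples: Euclidean distance, Ward linkage.

    Uses the Ward.D2 variance-minimizing update on Euclidean input (the
    modern default; dendrogram heights differ from the legacy Ward.D).
    ``restrict`` limits the distance computation to a signature's genes.
    """
    x = _restricted_values(data, restrict)
    if x.shape[0] < 2:
        raise ValueError("clustering needs >= 2 samples")
    z = linkage(x, method="ward", metric="euclidean")
    return ClusterResult(linkage_matrix=z, sample_ids=data.sample_ids)


@dataclass
class PCAResult:
    """Sample coordinates on principal components and variance fractions."""

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_project(
    data: MergedDataset,
    restrict: GeneSignature | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Project samples onto the principal components of gene space.

    Genes are mean-centered (no rescaling — the merged matrix is already
    z-scored per dataset); explained-variance fractions are non-increasing.
    """
    x = _restricted_values(data, restrict)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 genes")
    if not np.any(x.var(axis=0) > 0):
        raise ValueError("degenerate input: zero total variance")
    max_comp = min(x.shape)
    pca = PCA(n_components=n_components or max_comp)
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=data.sample_ids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def cluster_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same samples.

    1.0 iff the partitions are identical up to relabeling; ~0 for chance
    agreement; negative for worse-than-chance.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))
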