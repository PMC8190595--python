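"""Pseudo-bulk aggregation of single-cell counts and per-cluster projection.

Single cells are too sparse to rank directly against a bulk reference, so
within each cluster cells are pooled into small fixed-size groups (eight by
default) whose summed counts behave like miniature bulk samples. Summing raw
counts is deliberate: the subsequent rank transform absorbs depth
differences, so no per-cell normalization is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ProjectionResult, project
from .core_io import AtlasModel, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CELLS_PER_SAMPLE = 8


@dataclass
class CellClustering:
    """Cluster label per barcode; every barcode labeled exactly once."""

    labels: pd.Series  # index: barcode, values: cluster label

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate barcodes in clustering: {dups[:5]}")
        if self.labels.isna().any():
            bad = self.labels.index[self.labels.isna()].tolist()
            raise ValidationError(f"unlabeled barcodes: {bad[:5]}")

    @classmethod
    def from_tsv(cls, path) -> "CellClustering":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"barcode", "cluster"}.issubset(df.columns):
            raise ValidationError(
                f"{path}: clustering TSV needs 'barcode' and 'cluster' columns"
            )
        return cls(df.set_index("barcode")["cluster"])


@dataclass
class PseudoBulk:
    """Aggregated pseudo-samples plus the cell-to-pseudo-sample assignment."""

    matrix: ExpressionMatrix  # genes x pseudo-samples, counts
    membership: pd.Series  # index: barcode -> pseudo-sample id
    clusters: pd.Series  # index: pseudo-sample id -> cluster label


def aggregate(
    counts: ExpressionMatrix,
    clustering: CellClustering,
    cells_per_sample: int = DEFAULT_CELLS_PER_SAMPLE,
    seed: int = 0,
) -> PseudoBulk:
    """Pool cells into fixed-size pseudo-bulk samples within each cluster.

    Barcodes of each cluster are shuffled with the given seed and split into
    consecutive chunks of ``cells_per_sample``; the final remainder chunk is
    kept so rare clusters stay represented. Every cell is used exactly once,
    so per-gene sums over pseudo-samples equal per-gene sums over cells.
    Pseudo-sample ids encode cluster, chunk index, chunk size and seed.
    """
    if cells_per_sample < 1:
        raise ValidationError(f"cells_per_sample must be >= 1, got {cells_per_sample}")
    if counts.value_kind != "counts":
        raise ValidationError("aggregate expects raw counts input")
    barcodes = counts.sample_ids
    missing = barcodes.difference(clustering.labels.index)
    if len(missing):
        raise ValidationError(f"barcodes without cluster label: {missing.tolist()[:5]}")
    labels = clustering.labels.reindex(barcodes)
    declared = pd.unique(clustering.labels)
    empty = [c for c in declared if c not in set(labels)]
    for c in empty:
        warnings.warn(f"cluster {c!r} has no cells in the matrix; skipped", UserWarning)

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    member_rows: list[tuple[str, str]] = []
    cluster_of: dict[str, str] = {}
    V = counts.values
    for cluster in sorted(pd.unique(labels).tolist(), key=str):
        members = sorted(barcodes[labels == cluster].tolist())
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        for chunk_idx in range(0, len(shuffled), cells_per_sample):
            chunk = shuffled[chunk_idx : chunk_idx + cells_per_sample]
            pid = (
                f"{cluster}.c{chunk_idx // cells_per_sample:03d}"
                f".k{cells_per_sample}.s{seed}"
            )
            cols[pid] = V[chunk].sum(axis=1).to_numpy()
            cluster_of[pid] = cluster
            member_rows.extend((b, pid) for b in chunk)
    if not cols:
        raise ValidationError("no cells to aggregate")
    mat = pd.DataFrame(cols, index=counts.gene_ids)
    membership = pd.Series(dict(member_rows), name="pseudo_sample")
    membership.index.name = "barcode"
    logger.info(
        "aggregated %d cells from %d clusters into %d pseudo-samples (k=%d, seed=%d)",
        len(membership), labels.nunique(), mat.shape[1], cells_per_sample, seed,
    )
    return PseudoBulk(
        matrix=ExpressionMatrix(mat, "counts"),
        membership=membership,
        clusters=pd.Series(cluster_of, name="cluster"),
    )


@dataclass
class ClusterProjection:
    """Pseudo-sample projection plus per-cluster centroid coordinates."""

    projection: ProjectionResult
    cluster_coords: pd.DataFrame  # clusters x PC1..PCK
    pseudobulk: PseudoBulk


def project_clusters(
    model: AtlasModel,
    counts: ExpressionMatrix,
    clustering: CellClustering,
    cells_per_sample: int = DEFAULT_CELLS_PER_SAMPLE,
    seed: int = 0,
) -> ClusterProjection:
    """Aggregate, project every pseudo-sample, and average per cluster.

    The per-cluster mean coordinate is the cluster's position on the atlas.
    """
    pb = aggregate(counts, clustering, cells_per_sample=cells_per_sample, seed=seed)
    proj = project(model, pb.matrix)
    cluster_coords = proj.coords.groupby(pb.clusters).mean()
    cluster_coords.index.name = "cluster"
    return ClusterProjection(projection=proj, cluster_coords=cluster_coords, pseudobulk=pb)
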