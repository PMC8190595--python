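"""Atlas construction and projection.

The atlas is a frozen PCA frame over platform-filtered percentile ranks.
Samples are observations, filtered genes are features; per-gene mean ranks
are subtracted and the top-K right singular vectors form the loadings.
External queries are mapped into that frame without re-fitting or
re-centering — benchmarking semantics, not co-embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AtlasModel,
    ExpressionMatrix,
    RANK_CONVENTION,
    DUPLICATE_GENE_POLICY,
    SampleTable,
    ValidationError,
)
from .transform import rank_transform

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 3
LOW_COVERAGE_WARNING = 0.5


@dataclass
class ProjectionResult:
    """Coordinates of query samples in the atlas frame.

    ``coverage`` is the fraction of atlas genes measured in each query
    sample; atlas genes absent from a query are imputed at the atlas mean
    rank (contributing zero after centering) and counted against coverage.
    """

    coords: pd.DataFrame  # queries x PC1..PCK
    coverage: pd.Series
    warnings: list = field(default_factory=list)


def build_atlas(
    ranks: ExpressionMatrix,
    samples: SampleTable,
    gene_stats: pd.DataFrame,
    n_components: int = DEFAULT_N_COMPONENTS,
    extra_config: dict | None = None,
) -> AtlasModel:
    """Fit the reference PCA on the kept-gene rank matrix.

    Ranks must have been computed on each sample's full measured gene set
    (see :func:`rankatlas.transform.rank_transform`); this function only
    subsets rows to the kept genes — it never re-ranks. The PCA sign is fixed
    so each loading column's largest-magnitude entry is positive, making
    rebuilds bit-comparable. Any residual missing entries are imputed at the
    per-gene mean rank.
    """
    if ranks.value_kind != "rank":
        raise ValidationError("build_atlas expects a rank-transformed matrix")
    samples.require_cover(ranks.sample_ids)
    kept = gene_stats.index[gene_stats["kept"].astype(bool)]
    kept = kept.intersection(ranks.gene_ids)
    if len(kept) < n_components:
        raise ValidationError(
            f"only {len(kept)} kept genes; need at least n_components={n_components}"
        )
    if ranks.n_samples < n_components + 1:
        raise ValidationError(
            f"{ranks.n_samples} samples cannot support {n_components} components; "
            f"need at least {n_components + 1}"
        )
    R = ranks.values.loc[kept]
    mu = R.mean(axis=1)
    Xc = R.sub(mu, axis=0).fillna(0.0)
    A = Xc.T.to_numpy(dtype=float)  # samples x genes
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    tol = max(A.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    achievable = int((S > tol).sum())
    if n_components > achievable:
        raise ValidationError(
            f"requested {n_components} components but the centered rank matrix "
            f"has rank {achievable}; achievable K = {achievable}"
        )
    L = Vt[:n_components].T  # genes x K
    # deterministic sign: largest-|loading| entry of each column positive
    flip = np.sign(L[np.abs(L).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    L = L * flip
    coords = A @ L
    ev = (S[:n_components] ** 2) / max(A.shape[0] - 1, 1)

    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    config = {
        "n_components": int(n_components),
        "rank_convention": RANK_CONVENTION,
        "duplicate_gene_policy": DUPLICATE_GENE_POLICY,
        "theta": gene_stats.attrs.get("theta"),
        "min_dataset_frac": gene_stats.attrs.get("min_dataset_frac"),
    }
    if extra_config:
        config.update(extra_config)
    model = AtlasModel(
        gene_ids=pd.Index(kept, name="gene_id"),
        gene_means=pd.Series(mu, index=kept, name="mean_rank"),
        loadings=pd.DataFrame(L, index=kept, columns=pc_names),
        explained_variance=ev,
        coords=pd.DataFrame(coords, index=ranks.sample_ids, columns=pc_names),
        sample_table=samples.select(ranks.sample_ids),
        gene_stats=gene_stats,
        config=config,
    )
    logger.info(
        "built atlas: %d genes, %d samples, K=%d, explained variance %s",
        len(kept), ranks.n_samples, n_components, np.round(ev, 4).tolist(),
    )
    return model


def project(model: AtlasModel, m: ExpressionMatrix) -> ProjectionResult:
    """Map external samples into the frozen atlas frame.

    Counts/intensity input is rank-transformed over the query's full
    measured gene set first; a query that is already ``rank`` kind is used
    as-is. Atlas genes the query does not measure are imputed at the atlas
    mean rank and reduce the reported coverage; coverage below 0.5 attaches
    a warning. Projection inherits the rank transform's invariance to
    strictly monotone per-sample transforms of the query.
    """
    ranks = m if m.value_kind == "rank" else rank_transform(m)
    shared = model.gene_ids.intersection(ranks.gene_ids)
    if len(shared) == 0:
        raise ValidationError("query shares no gene ids with the atlas")
    R = ranks.values.reindex(model.gene_ids)
    coverage = R.notna().mean(axis=0)
    centered = R.sub(model.gene_means, axis=0).fillna(0.0)
    coords = centered.T.to_numpy(dtype=float) @ model.loadings.to_numpy(dtype=float)
    coords = pd.DataFrame(coords, index=ranks.sample_ids, columns=model.loadings.columns)
    warnings_list = [
        f"sample {s!r}: only {coverage[s]:.1%} of atlas genes measured"
        for s in coverage.index[coverage < LOW_COVERAGE_WARNING]
    ]
    for w in warnings_list:
        logger.warning(w)
    return ProjectionResult(coords=coords, coverage=coverage, warnings=warnings_list)


def axis_summary(
    model: AtlasModel, axis: int, group_by: str = "sample_source"
) -> pd.DataFrame:
    """Per-group location/spread of one principal-component coordinate.

    ``axis`` is one-based (axis 3 = PC3). Useful for statements of the form
    "group X separates from group Y along PCk".
    """
    if not (1 <= axis <= model.n_components):
        raise ValidationError(
            f"axis must be in 1..{model.n_components}, got {axis}"
        )
    if group_by not in model.sample_table.data.columns:
        raise ValidationError(
            f"unknown annotation field {group_by!r}; available: "
            f"{model.sample_table.data.columns.tolist()}"
        )
    pc = model.coords.iloc[:, axis - 1]
    groups = model.sample_table.data[group_by]
    out = pc.groupby(groups).agg(
        n="count", median="median", mean="mean", q25=lambda v: v.quantile(0.25),
        q75=lambda v: v.quantile(0.75), min="min", max="max"
    )
    out.index.name = group_by
    return out


def coords_table(
    model: AtlasModel, projections: dict[str, ProjectionResult] | None = None
) -> pd.DataFrame:
    """Reference (and optionally projected) coordinates with annotations.

    One row per sample with PC columns, joined annotation columns for
    reference samples, and a ``source`` column distinguishing reference from
    each named projection.
    """
    ref = model.coords.join(model.sample_table.data)
    ref.insert(model.n_components, "source", "reference")
    frames = [ref]
    for name, proj in (projections or {}).items():
        df = proj.coords.copy()
        df.insert(model.n_components, "source", name)
        df["coverage"] = proj.coverage
        frames.append(df)
    out = pd.concat(frames, axis=0)
    out.index.name = "sample_id"
    return out
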