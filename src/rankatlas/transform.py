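"""Percentile-rank transformation and platform-variance gene filtering.

The integration core. Each sample is reduced to the percentile ranks of its
genes, ``r = (average_rank - 0.5) / n_measured``, which is invariant to any
strictly monotone per-sample transform — CPM/TPM/log scaling and global
platform response curves all cancel, making microarray and RNA-seq samples
directly comparable. Genes whose rank still carries a platform signature are
then detected by a two-stage variance decomposition and removed before the
atlas is fitted.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THETA = 0.25
DEFAULT_MIN_DATASET_FRAC = 0.9
#: A gene counts as "measured" in a dataset when non-missing in at least this
#: fraction of the dataset's samples.
MEASURED_SAMPLE_FRAC = 0.5


def rank_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample percentile ranks across genes, average ties.

    Missing entries stay missing and are excluded from the per-sample gene
    count ``n``; a tie-free sample's ranks are a permutation of
    ``(i - 0.5)/n`` and a constant sample maps to all 0.5.
    """
    if m.value_kind not in ("counts", "intensity"):
        raise ValidationError(
            f"rank_transform expects counts or intensity input, got {m.value_kind!r}"
        )
    n_measured = m.values.notna().sum(axis=0)
    empty = n_measured.index[n_measured == 0]
    if len(empty):
        raise ValidationError(f"all values missing for sample(s): {empty.tolist()[:5]}")
    thin = n_measured.index[n_measured < 2]
    if len(thin):
        raise ValidationError(
            f"fewer than 2 measured genes for sample(s): {thin.tolist()[:5]}"
        )
    ranks = m.values.rank(axis=0, method="average", na_option="keep")
    r = (ranks - 0.5).div(n_measured, axis=1)
    return ExpressionMatrix(r, "rank")


class PlatformVariance(NamedTuple):
    """Result of the per-gene platform-variance decomposition."""

    fraction: float
    degenerate: bool  # zero residual variance: fraction reported as 0
    confounded: bool  # every cell type observed on a single platform only


def platform_variance_fraction(
    gene_ranks, platforms, cell_types
) -> PlatformVariance:
    """Fraction of a gene's cell-type-adjusted rank variance attributable to platform.

    Two stages: (1) residuals are formed by subtracting each sample's
    cell-type mean, so biology shared within a cell type is not charged to
    platform; (2) the between-platform sum of squares of those residuals is
    divided by their total sum of squares. This is the per-gene "gray stripe"
    statistic used by :func:`filter_genes`.
    """
    r = pd.Series(np.asarray(gene_ranks, dtype=float))
    plat = pd.Series(np.asarray(platforms, dtype=object), index=r.index)
    ct = pd.Series(np.asarray(cell_types, dtype=object), index=r.index)
    if len(r) != len(plat) or len(r) != len(ct):
        raise ValidationError("gene_ranks, platforms and cell_types must align")
    ok = r.notna()
    r, plat, ct = r[ok], plat[ok], ct[ok]
    if plat.nunique() < 2:
        raise ValidationError(
            "platform variance fraction undefined with a single platform"
        )
    confounded = bool((plat.groupby(ct, observed=True).nunique() == 1).all())
    if confounded:
        warnings.warn(
            "platform fully confounded with cell type; platform variance "
            "fraction cannot be separated from biology",
            UserWarning,
            stacklevel=2,
        )
    resid = r - ct.map(r.groupby(ct).mean())
    sst = float((resid**2).sum())
    if sst == 0.0:
        return PlatformVariance(0.0, degenerate=True, confounded=confounded)
    by_plat = resid.groupby(plat)
    ssb = float((by_plat.count() * by_plat.mean() ** 2).sum())
    frac = min(max(ssb / sst, 0.0), 1.0)
    return PlatformVariance(frac, degenerate=False, confounded=confounded)


def filter_genes(
    ranks: ExpressionMatrix,
    samples: SampleTable,
    theta: float = DEFAULT_THETA,
    min_dataset_frac: float = DEFAULT_MIN_DATASET_FRAC,
) -> pd.DataFrame:
    """Per-gene platform-variance fractions and the keep/drop decision.

    A gene is kept iff its platform-variance fraction is at most ``theta``
    and it is measured (non-missing in >=50% of a dataset's samples) in at
    least ``min_dataset_frac`` of the datasets. Fully vectorized; result is
    deterministic given inputs.

    Returns a DataFrame indexed by gene id with columns
    ``platform_fraction``, ``n_datasets_measured``, ``kept``; the filter
    parameters are attached as ``.attrs``.
    """
    if not (0 < theta <= 1):
        raise ValidationError(f"theta must be in (0, 1], got {theta}")
    if not (0 < min_dataset_frac <= 1):
        raise ValidationError(
            f"min_dataset_frac must be in (0, 1], got {min_dataset_frac}"
        )
    if ranks.value_kind != "rank":
        raise ValidationError("filter_genes expects a rank-transformed matrix")
    samples.require_cover(ranks.sample_ids)
    ann = samples.data.loc[ranks.sample_ids]
    plat = ann["platform"]
    ct = ann["cell_type"]
    ds = ann["dataset_id"]
    if plat.nunique() < 2:
        raise ValidationError("gene filtering requires samples from >=2 platforms")

    R = ranks.values  # genes x samples
    # stage 1: remove cell-type means so shared biology is not charged to platform
    ct_means = R.T.groupby(ct.values).transform("mean").T
    resid = R - ct_means
    # stage 2: one-way between-platform decomposition of the residuals
    by_plat_mean = resid.T.groupby(plat.values).mean().T  # genes x platforms
    by_plat_n = resid.notna().T.groupby(plat.values).sum().T
    ssb = (by_plat_n * by_plat_mean.pow(2)).sum(axis=1)
    sst = resid.pow(2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (ssb / sst).clip(0.0, 1.0)
    frac = frac.where(sst > 0, 0.0).fillna(0.0)

    measured = R.notna().T.groupby(ds.values).mean().T >= MEASURED_SAMPLE_FRAC
    n_measured = measured.sum(axis=1)
    n_datasets = ds.nunique()
    coverage_ok = n_measured >= min_dataset_frac * n_datasets

    kept = (frac <= theta) & coverage_ok
    if not kept.any():
        raise ValidationError(
            f"no genes pass the filter (theta={theta}, "
            f"min_dataset_frac={min_dataset_frac}); relax the thresholds"
        )
    stats = pd.DataFrame(
        {
            "platform_fraction": frac.astype(float),
            "n_datasets_measured": n_measured.astype(int),
            "kept": kept.astype(bool),
        },
        index=ranks.gene_ids,
    )
    stats.attrs["theta"] = float(theta)
    stats.attrs["min_dataset_frac"] = float(min_dataset_frac)
    stats.attrs["n_datasets"] = int(n_datasets)
    logger.info(
        "gene filter: kept %d / %d genes (theta=%.3g, min_dataset_frac=%.3g)",
        int(kept.sum()), len(kept), theta, min_dataset_frac,
    )
    return stats
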