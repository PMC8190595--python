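"""Cell-identity scoring against atlas centroids and rank-based DE.

Two complementary scores are offered for a query rank vector:

* correlation mode — Pearson correlation with each reference cell-type
  centroid (a similarity heat-map score);
* weight mode — non-negative least squares of the query onto the centroid
  matrix, normalized to the probability simplex. Near-uniform top weights
  flag hybrid/intermediate identities (e.g. a cluster sitting between
  classical monocyte and DC2).

Group comparisons use the two-sided Mann-Whitney-Wilcoxon rank-sum test on
percentile ranks with Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .core_io import AtlasModel, ExpressionMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HYBRID_THRESHOLD = 0.5
LOW_CONFIDENCE_MIN_SAMPLES = 3
#: Exact MWW enumeration only for small tie-free groups; tie-corrected
#: normal approximation otherwise.
EXACT_MWW_MAX_N = 8


@dataclass
class CentroidSet:
    """Per-cell-type mean rank vectors over the atlas genes."""

    centroids: pd.DataFrame  # genes x cell types, values in [0, 1]
    n_samples: pd.Series  # samples per type
    low_confidence: list = field(default_factory=list)  # types with <3 samples

    @property
    def types(self) -> pd.Index:
        return self.centroids.columns


def build_centroids(
    model: AtlasModel,
    by: str = "cell_type",
    ranks: ExpressionMatrix | None = None,
) -> CentroidSet:
    """Mean rank vector per annotation group over the atlas genes.

    When the training rank matrix is available, pass it via ``ranks`` for
    exact centroids. Otherwise centroids are reconstructed from the stored
    low-rank representation, ``mu + L @ coords``, which is the part of each
    sample's rank vector the atlas retains (values clipped to [0, 1]).
    """
    if by not in model.sample_table.data.columns:
        raise ValidationError(f"unknown annotation field {by!r}")
    groups = model.sample_table.data[by]
    if groups.isna().all():
        raise ValidationError(f"annotation field {by!r} is empty")
    if ranks is not None:
        if ranks.value_kind != "rank":
            raise ValidationError("build_centroids expects a rank matrix")
        R = ranks.values.reindex(index=model.gene_ids, columns=model.coords.index)
    else:
        recon = model.loadings.to_numpy() @ model.coords.to_numpy().T
        R = pd.DataFrame(
            recon, index=model.gene_ids, columns=model.coords.index
        ).add(model.gene_means, axis=0).clip(0.0, 1.0)
    cent = R.T.groupby(groups).mean().T
    n = groups.value_counts()
    low = sorted(n.index[n < LOW_CONFIDENCE_MIN_SAMPLES].tolist())
    if low:
        logger.warning("low-confidence centroids (<%d samples): %s",
                       LOW_CONFIDENCE_MIN_SAMPLES, low)
    return CentroidSet(
        centroids=cent, n_samples=n.reindex(cent.columns), low_confidence=low
    )


def _query_frame(query) -> pd.DataFrame:
    """Coerce a query (Series, DataFrame or rank ExpressionMatrix) to genes x queries."""
    if isinstance(query, ExpressionMatrix):
        if query.value_kind != "rank":
            raise ValidationError("queries must be rank-transformed")
        return query.values
    if isinstance(query, pd.Series):
        return query.to_frame(query.name or "query")
    if isinstance(query, pd.DataFrame):
        return query
    raise ValidationError(f"unsupported query type: {type(query)!r}")


def similarity_scores(centroid_set: CentroidSet, query) -> pd.DataFrame:
    """Pearson correlation of each query with each cell-type centroid.

    Computed over the atlas genes the query measures (>=3 required). Returns
    one row per query with a per-type score column and a ``call`` column
    holding the best-correlated type.
    """
    Q = _query_frame(query)
    C = centroid_set.centroids
    rows = {}
    for qid in Q.columns:
        q = Q[qid].reindex(C.index)
        ok = q.notna()
        if int(ok.sum()) < 3:
            raise ValidationError(
                f"query {qid!r} shares only {int(ok.sum())} genes with centroids; need >=3"
            )
        qv = q[ok].to_numpy(dtype=float)
        if np.ptp(qv) == 0 or np.std(qv) == 0:
            raise ValidationError(f"query {qid!r} has zero variance over shared genes")
        qc = qv - qv.mean()
        scores = {}
        for t in C.columns:
            cv = C.loc[ok, t].to_numpy(dtype=float)
            cc = cv - cv.mean()
            denom = np.sqrt((qc**2).sum() * (cc**2).sum())
            scores[t] = float((qc * cc).sum() / denom) if denom > 0 else np.nan
        rows[qid] = scores
    out = pd.DataFrame.from_dict(rows, orient="index")[C.columns]
    out["call"] = out[C.columns].idxmax(axis=1)
    out.index.name = "query_id"
    out.attrs["mode"] = "correlation"
    return out


def capybara_weights(
    centroid_set: CentroidSet,
    query,
    hybrid_threshold: float = DEFAULT_HYBRID_THRESHOLD,
) -> pd.DataFrame:
    """Simplex identity weights: NNLS of the query onto the centroid matrix.

    Solves ``min ||C w - q||^2, w >= 0`` per query over the shared atlas
    genes, then normalizes ``w`` to sum to one. The call is the argmax type
    when its weight reaches ``hybrid_threshold``, otherwise ``hybrid:`` with
    the top two types. An all-zero unnormalized solution yields uniform
    weights and a degenerate flag.
    """
    C = centroid_set.centroids
    if C.shape[1] >= 2:
        spread = C.to_numpy().max(axis=1) - C.to_numpy().min(axis=1)
        if np.nanmax(spread) == 0:
            raise ValidationError("all centroids identical; weights undefined")
    Q = _query_frame(query)
    rows, calls, degenerate = {}, {}, []
    for qid in Q.columns:
        q = Q[qid].reindex(C.index)
        ok = q.notna()
        if int(ok.sum()) < C.shape[1]:
            raise ValidationError(
                f"query {qid!r} measures only {int(ok.sum())} atlas genes; "
                f"need >= {C.shape[1]}"
            )
        w, _ = nnls(C.loc[ok].to_numpy(dtype=float), q[ok].to_numpy(dtype=float))
        total = w.sum()
        if total == 0:
            w = np.full(C.shape[1], 1.0 / C.shape[1])
            degenerate.append(qid)
        else:
            w = w / total
        rows[qid] = dict(zip(C.columns, w))
        order = np.argsort(w)[::-1]
        if w[order[0]] >= hybrid_threshold:
            calls[qid] = str(C.columns[order[0]])
        else:
            calls[qid] = f"hybrid:{C.columns[order[0]]}+{C.columns[order[1]]}"
    out = pd.DataFrame.from_dict(rows, orient="index")[C.columns]
    out["call"] = pd.Series(calls)
    out.index.name = "query_id"
    out.attrs["mode"] = "capybara"
    out.attrs["hybrid_threshold"] = float(hybrid_threshold)
    out.attrs["degenerate"] = degenerate
    return out


# ---------------------------------------------------------------------------
# Differential rank expression
# ---------------------------------------------------------------------------


def parse_group_filter(spec: str) -> dict[str, str]:
    """Parse a ``key=value,key=value`` group filter over annotation columns."""
    out: dict[str, str] = {}
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValidationError(f"bad group filter fragment {part!r}; expected key=value")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    if not out:
        raise ValidationError(f"empty group filter: {spec!r}")
    return out


def select_samples(samples: SampleTable, spec) -> pd.Index:
    """Resolve a group specification to sample ids.

    ``spec`` may be a list of sample ids, a dict of annotation equality
    constraints, or a ``key=value,key=value`` string.
    """
    if isinstance(spec, str):
        spec = parse_group_filter(spec)
    if isinstance(spec, dict):
        mask = pd.Series(True, index=samples.sample_ids)
        for k, v in spec.items():
            if k not in samples.data.columns:
                raise ValidationError(f"unknown annotation field in group filter: {k!r}")
            mask &= samples.data[k].astype(str) == str(v)
        return samples.sample_ids[mask]
    return pd.Index([s for s in spec])


def _mww(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided MWW: exact for small tie-free groups, else tie-corrected normal."""
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(len(a), len(b)) <= EXACT_MWW_MAX_N:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rank_sum_de(
    ranks: ExpressionMatrix,
    samples: SampleTable,
    group_a,
    group_b,
    gene_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney-Wilcoxon between two sample groups.

    Operates on percentile ranks. P-values are exact (full enumeration of
    the U distribution) when the smaller group has <=8 samples and the
    pooled values are tie-free, and use the tie-corrected normal
    approximation otherwise. Benjamini-Hochberg adjustment is applied across
    genes. ``delta_median_rank`` is median(A) - median(B), so swapping the
    groups negates it and leaves p unchanged.
    """
    if ranks.value_kind != "rank":
        raise ValidationError("rank_sum_de expects a rank-transformed matrix")
    ids_a = select_samples(samples, group_a)
    ids_b = select_samples(samples, group_b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValidationError(
            f"empty group (|A|={len(ids_a)}, |B|={len(ids_b)})"
        )
    overlap = ids_a.intersection(ids_b)
    if len(overlap):
        raise ValidationError(f"groups overlap: {overlap.tolist()[:5]}")
    missing = [s for s in list(ids_a) + list(ids_b) if s not in ranks.sample_ids]
    if missing:
        raise ValidationError(f"group samples absent from matrix: {missing[:5]}")

    A = ranks.values[list(ids_a)]
    B = ranks.values[list(ids_b)]
    records = []
    for gene in ranks.gene_ids:
        a = A.loc[gene].dropna().to_numpy(dtype=float)
        b = B.loc[gene].dropna().to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            records.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        u, p = _mww(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        records.append((gene, med_a, med_b, med_a - med_b, u, p))
    out = pd.DataFrame(
        records,
        columns=["gene_id", "median_a", "median_b", "delta_median_rank",
                 "u_statistic", "p_value"],
    ).set_index("gene_id")
    tested = out["p_value"].notna()
    q = pd.Series(np.nan, index=out.index)
    if tested.any():
        q[tested] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    if gene_stats is not None and "platform_fraction" in gene_stats.columns:
        out["platform_fraction"] = gene_stats["platform_fraction"].reindex(out.index)
    out.attrs["n_a"] = int(len(ids_a))
    out.attrs["n_b"] = int(len(ids_b))
    return out
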