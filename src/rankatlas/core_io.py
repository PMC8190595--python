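"""Data model and I/O: expression matrices, sample annotations, atlas bundles.

Conventions
-----------
* Expression matrices are gene-by-sample. On disk the first column holds gene
  identifiers and the header row holds sample identifiers (TSV or CSV).
* Missing values are represented as NaN inside the matrix; all validity
  constraints (non-negativity, rank range) apply to non-missing entries only.
* Single-cell counts are read from a MatrixMarket triplet file plus companion
  gene and barcode lists, as written by cell-ranger-style pipelines.
* A fitted atlas is persisted as a directory bundle: ``manifest.json`` plus
  plain TSV matrices, so bundles are diffable and self-describing.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("counts", "intensity", "rank")

#: Canonical sample-source tiers: profiled directly from tissue or blood,
#: isolated then cultured, or differentiated entirely in a dish.
TIERS = ("in vivo", "ex vivo", "in vitro")

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "dataset_id",
    "platform",
    "cell_type",
    "sample_source",
    "tissue",
)

#: Recorded in every bundle manifest so serialized atlases are self-describing.
RANK_CONVENTION = "(average_rank - 0.5) / n_measured_genes; ties averaged; per sample"
DUPLICATE_GENE_POLICY = "per-sample maximum over duplicate gene rows"

BUNDLE_FILES = (
    "manifest.json",
    "genes.tsv",
    "loadings.tsv",
    "gene_means.tsv",
    "coords.tsv",
    "samples.tsv",
    "gene_stats.tsv",
)


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class SchemaError(ValidationError):
    """Required column missing from an annotation table."""


class IntegrityError(ValueError):
    """Atlas bundle is incomplete or internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix with a value-kind flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. NaN marks
        a missing measurement.
    value_kind
        ``counts`` (sequencing), ``intensity`` (array) or ``rank``
        (percentile-rank transformed, values in [0, 1]).
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="gene_id", columns="sample_id")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and finite.min() < 0:
            raise ValidationError(
                f"negative values not allowed for value_kind={self.value_kind!r}"
            )
        if self.value_kind == "rank" and finite.size and finite.max() > 1 + 1e-12:
            raise ValidationError("rank values must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing entries."""
        return self.values.isna()

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.value_kind)


@dataclass
class SampleTable:
    """Per-sample annotations, indexed by sample id.

    Required columns: dataset_id, platform, cell_type, sample_source
    (one of the three tiers), tissue. Extra columns (activation_status,
    disease, progenitor_type, ...) are carried through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [
            c for c in REQUIRED_SAMPLE_COLUMNS if c != "sample_id" and c not in self.data.columns
        ]
        if missing:
            raise SchemaError(f"annotation table missing required columns: {missing}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in annotations: {dups[:5]}")
        bad = self.data.index[~self.data["sample_source"].isin(TIERS)]
        if len(bad):
            raise ValidationError(
                "sample_source must be one of "
                f"{TIERS}; offending samples: {bad.tolist()[:10]}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def select(self, sample_ids: Sequence[str]) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from annotation table: {missing[:5]}")
        return SampleTable(self.data.loc[list(sample_ids)])

    def require_cover(self, sample_ids: Sequence[str]) -> None:
        """Assert every given sample id is annotated exactly once."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(
                f"samples missing from annotation table: {missing[:10]}"
            )


@dataclass
class AtlasModel:
    """A frozen reference atlas: filtered genes, PCA frame, coordinates.

    ``coords`` row *s* equals ``loadings.T @ (r_s - gene_means)`` for the rank
    vector ``r_s`` used at build time, so any sample with full gene coverage
    re-projects onto its stored coordinates.
    """

    gene_ids: pd.Index
    gene_means: pd.Series  # per-gene mean rank over atlas samples
    loadings: pd.DataFrame  # genes x PC1..PCK, columns orthonormal
    explained_variance: np.ndarray  # length K, non-increasing
    coords: pd.DataFrame  # samples x PC1..PCK
    sample_table: SampleTable
    gene_stats: pd.DataFrame  # per-gene platform_fraction / coverage / kept
    config: dict

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def validate(self) -> None:
        L = self.loadings.to_numpy(dtype=float)
        gram = L.T @ L
        if not np.allclose(gram, np.eye(L.shape[1]), atol=1e-8):
            raise IntegrityError("loadings columns are not orthonormal (tol 1e-8)")
        ev = np.asarray(self.explained_variance, dtype=float)
        if ev.ndim != 1 or ev.shape[0] != L.shape[1]:
            raise IntegrityError("explained_variance length must equal n_components")
        if np.any(np.diff(ev) > 1e-12) or np.any(ev < -1e-12):
            raise IntegrityError("explained_variance must be non-negative, non-increasing")
        if not self.loadings.index.equals(self.gene_ids):
            raise IntegrityError("loadings index does not match gene_ids")
        if not self.gene_means.index.equals(self.gene_ids):
            raise IntegrityError("gene_means index does not match gene_ids")
        if self.coords.shape[1] != L.shape[1]:
            raise IntegrityError("coords width does not match n_components")
        if not self.coords.index.equals(self.sample_table.sample_ids):
            raise IntegrityError("coords samples do not match sample table")


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------


def _check_header(path: Path, sep: str) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ParseError(f"{path}: line 1: empty header")
    fields = header.split(sep)
    if len(fields) < 2:
        raise ParseError(
            f"{path}: line 1: header has {len(fields)} field(s); expected a gene-id "
            "column followed by sample ids"
        )
    sample_ids = fields[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValidationError(f"{path}: duplicate sample id in header: {s!r}")
        seen.add(s)


def _read_id_list(path: Path) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_matrix(
    path: str | Path,
    format: str = "tsv",
    value_kind: str = "counts",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix.

    ``value_kind`` must be supplied by the caller (typically from run
    configuration); it is never guessed from the data. Duplicate gene rows
    are collapsed by the per-sample maximum (probe-to-gene convention; the
    policy is recorded in atlas manifests).

    For ``format="mtx_triplet"``, ``path`` is the MatrixMarket file and the
    companion gene/barcode lists default to ``genes.tsv`` / ``barcodes.tsv``
    next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        _check_header(path, sep)
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"{path}: {exc}") from exc
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(np.where(bad.to_numpy())[0][0]) + 2  # +1 header, +1 one-based
                raise ParseError(
                    f"{path}: line {line}: non-numeric value {df[col][bad].iloc[0]!r} "
                    f"in column {col!r}"
                )
            df[col] = coerced
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx_triplet":
        from scipy.io import mmread

        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        for companion in (genes_path, barcodes_path):
            if not companion.exists():
                raise FileNotFoundError(f"companion file not found: {companion}")
        mat = mmread(str(path))
        genes = _read_id_list(genes_path)
        barcodes = _read_id_list(barcodes_path)
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if dense.shape != (len(genes), len(barcodes)):
            raise IntegrityError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        df = pd.DataFrame(dense, index=genes, columns=barcodes)
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"{path}: duplicate barcode ids: {dups[:5]}")
    else:
        raise ValueError(f"unknown matrix format: {format!r}")

    if df.index.has_duplicates:
        n_before = df.shape[0]
        df = df.groupby(level=0, sort=False).max()
        logger.info(
            "collapsed %d duplicate gene rows by per-sample max (%d -> %d genes)",
            n_before - df.shape[0], n_before, df.shape[0],
        )
    return ExpressionMatrix(df, value_kind)


def write_matrix(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV/CSV (gene-id first column, sample-id header)."""
    sep = "\t" if format == "tsv" else ","
    m.values.to_csv(path, sep=sep, index_label="gene_id")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_TIER_CANON = {re.sub(r"[\s_-]+", " ", t): t for t in TIERS}


def normalize_tier(value: str) -> str | None:
    """Map a free-text sample-source string onto a canonical tier, or None."""
    if not isinstance(value, str):
        return None
    key = re.sub(r"[\s_-]+", " ", value.strip().lower())
    return _TIER_CANON.get(key)


def read_annotations(path: str | Path) -> SampleTable:
    """Read a sample annotation TSV.

    ``sample_source`` strings are normalized case-insensitively onto the three
    canonical tiers; anything outside that closed vocabulary is an error that
    names the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    tiers = df["sample_source"].map(normalize_tier)
    bad = df.index[tiers.isna()]
    if len(bad):
        detail = ", ".join(
            f"row {i + 2} (sample_id={df.loc[i, 'sample_id']!r}, "
            f"sample_source={df.loc[i, 'sample_source']!r})"
            for i in bad[:10]
        )
        raise ValidationError(
            f"{path}: sample_source must be one of {TIERS}; offending: {detail}"
        )
    df = df.assign(sample_source=tiers).set_index("sample_id")
    return SampleTable(df)


def write_annotations(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Atlas bundle serialization
# ---------------------------------------------------------------------------


def save_atlas(model: AtlasModel, outdir: str | Path) -> Path:
    """Serialize an atlas to a directory bundle of JSON + TSV files.

    ``load_atlas(save_atlas(m))`` reproduces loadings and coordinates
    bit-for-bit (floats are written with shortest-round-trip repr).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "package": "rankatlas",
        "n_genes": int(len(model.gene_ids)),
        "n_samples": int(model.coords.shape[0]),
        "n_components": int(model.n_components),
        "explained_variance": [float(v) for v in model.explained_variance],
        "rank_convention": RANK_CONVENTION,
        "duplicate_gene_policy": DUPLICATE_GENE_POLICY,
        "config": model.config,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    pd.Series(model.gene_ids, name="gene_id").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    model.loadings.to_csv(outdir / "loadings.tsv", sep="\t", index_label="gene_id")
    model.gene_means.rename("mean_rank").to_csv(
        outdir / "gene_means.tsv", sep="\t", index_label="gene_id"
    )
    model.coords.to_csv(outdir / "coords.tsv", sep="\t", index_label="sample_id")
    write_annotations(model.sample_table, outdir / "samples.tsv")
    model.gene_stats.to_csv(outdir / "gene_stats.tsv", sep="\t", index_label="gene_id")
    return outdir


def load_atlas(bundle_dir: str | Path) -> AtlasModel:
    """Load a bundle written by :func:`save_atlas`, verifying its integrity."""
    bundle_dir = Path(bundle_dir)
    for name in BUNDLE_FILES:
        if not (bundle_dir / name).exists():
            raise IntegrityError(f"atlas bundle incomplete: missing {name}")
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    genes = pd.read_csv(bundle_dir / "genes.tsv", sep="\t")["gene_id"].astype(str)
    gene_index = pd.Index(genes, name="gene_id")
    loadings = pd.read_csv(bundle_dir / "loadings.tsv", sep="\t", index_col=0)
    loadings.index = loadings.index.astype(str)
    gene_means = pd.read_csv(bundle_dir / "gene_means.tsv", sep="\t", index_col=0)["mean_rank"]
    gene_means.index = gene_means.index.astype(str)
    coords = pd.read_csv(bundle_dir / "coords.tsv", sep="\t", index_col=0)
    coords.index = coords.index.astype(str)
    samples = read_annotations(bundle_dir / "samples.tsv")
    gene_stats = pd.read_csv(bundle_dir / "gene_stats.tsv", sep="\t", index_col=0)
    gene_stats.index = gene_stats.index.astype(str)

    K = int(manifest["n_components"])
    if loadings.shape[1] != K:
        raise IntegrityError(
            f"manifest declares n_components={K} but loadings has "
            f"{loadings.shape[1]} columns"
        )
    if coords.shape[1] != K:
        raise IntegrityError(
            f"manifest declares n_components={K} but coords has {coords.shape[1]} columns"
        )
    if manifest["n_genes"] != len(gene_index) or loadings.shape[0] != len(gene_index):
        raise IntegrityError("gene list length disagrees with manifest/loadings")
    if manifest["n_samples"] != coords.shape[0]:
        raise IntegrityError("sample count disagrees with manifest")
    ev = np.asarray(manifest["explained_variance"], dtype=float)
    return AtlasModel(
        gene_ids=gene_index,
        gene_means=gene_means.reindex(gene_index),
        loadings=loadings.reindex(gene_index),
        explained_variance=ev,
        coords=coords,
        sample_table=samples.select(coords.index),
        gene_stats=gene_stats,
        config=manifest.get("config", {}),
    )
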