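"""Synthetic multi-platform, multi-cell-type expression cohorts with ground truth.

The generator emulates the statistical structure a cross-platform atlas must
cope with, without imitating any real biology:

* per-gene log-normal expression with cell-type-specific effects on a
  marker subset — the biology the atlas should retain;
* a global, strictly monotone platform response ``y = a_p * x ** g_p`` —
  removed entirely by per-sample ranking, by construction;
* an additive platform artifact on a small "platform-sensitive" gene set,
  in units of the gene's within-type SD — this survives ranking and is what
  the variance filter must find;
* an optional additive culture shift on a disjoint gene set for ex vivo /
  in vitro samples (doubled for in vitro), giving the sample-source tiers a
  real transcriptional axis;
* a negative-binomial single-cell block sharing the same cell-type profiles.

All randomness flows from the mandatory seed; runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleTable, TIERS, write_annotations, write_matrix
from .single_cell import CellClustering


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Magnitudes of the platform and culture shifts are expressed in units of
    the gene's within-cell-type standard deviation on the expression scale,
    so they are comparable across genes of different abundance.
    """

    seed: int
    n_genes: int = 2000
    n_cell_types: int = 4
    n_datasets: int = 4
    n_platforms: int = 2
    samples_per_dataset: int = 12
    platform_sensitive_fraction: float = 0.1  # f: fraction of genes with artifact
    platform_shift: float = 2.0  # delta, within-type SD units
    culture_fraction: float = 0.05  # genes carrying the tier effect
    culture_shift: float = 0.0  # tier effect magnitude, SD units (off by default)
    noise_sd: float = 0.3  # sigma, natural-log scale
    marker_fraction: float = 0.25  # genes with cell-type effects
    marker_effect_sd: float = 1.0  # natural-log scale
    base_log_mean: float = 2.0
    base_log_sd: float = 1.0
    platform_scale: list | None = None  # a_p; default 1 + p
    platform_exponent: list | None = None  # g_p; default 1 + 0.15 p
    sc_mean_scale: float = 0.2  # single-cell depth relative to bulk means
    sc_dispersion: float = 2.0  # NB size parameter; larger -> closer to Poisson
    sc_size_factor_sd: float = 0.3  # log-normal per-cell library scaling

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types", "n_datasets", "n_platforms",
                     "samples_per_dataset"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.platform_sensitive_fraction < 1):
            raise ConfigError("platform_sensitive_fraction must be in [0, 1)")
        if self.platform_sensitive_fraction + self.culture_fraction > 1:
            raise ConfigError("platform-sensitive and culture fractions exceed 1")
        for name in ("platform_shift", "culture_shift", "noise_sd",
                     "marker_effect_sd", "sc_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def scales(self) -> np.ndarray:
        if self.platform_scale is not None:
            return np.asarray(self.platform_scale, dtype=float)
        return 1.0 + np.arange(self.n_platforms, dtype=float)

    def exponents(self) -> np.ndarray:
        if self.platform_exponent is not None:
            return np.asarray(self.platform_exponent, dtype=float)
        return 1.0 + 0.15 * np.arange(self.n_platforms, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated cohort."""

    true_type: pd.Series  # per sample / barcode
    tier: pd.Series | None
    platform_sensitive_genes: list
    culture_genes: list


def _gene_params(cfg: SimConfig):
    """Gene-level parameters; drawn first so bulk and single-cell share profiles."""
    rng = np.random.default_rng(cfg.seed)
    G, T = cfg.n_genes, cfg.n_cell_types
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, G)
    n_markers = int(np.floor(cfg.marker_fraction * G))
    marker_idx = rng.choice(G, n_markers, replace=False)
    effects = np.zeros((G, T))
    effects[marker_idx, :] = rng.normal(0.0, cfg.marker_effect_sd, (n_markers, T))
    log_mu = base[:, None] + effects  # G x T
    perm = rng.permutation(G)
    n_sens = int(np.floor(cfg.platform_sensitive_fraction * G))
    n_cult = int(np.floor(cfg.culture_fraction * G))
    sensitive = np.sort(perm[:n_sens])
    culture = np.sort(perm[n_sens : n_sens + n_cult])
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    return rng, gene_ids, log_mu, sensitive, culture


# multiplier applied to the culture shift per tier
_TIER_MULT = {"in vivo": 0.0, "ex vivo": 1.0, "in vitro": 2.0}


def simulate_bulk(cfg: SimConfig) -> tuple[ExpressionMatrix, SampleTable, SimTruth]:
    """Simulate a multi-dataset bulk cohort.

    A sample of cell type *t* in dataset *d* on platform *p* is
    ``x_g = exp(log_mu[g, t] + eps)`` with ``eps ~ N(0, sigma^2)``; the
    platform-sensitive set then receives ``p * delta * SD_gt`` additively
    (platform 0 is the unshifted anchor), culture genes receive the tier
    shift for non-in-vivo samples, and finally the whole sample passes
    through the monotone platform response ``y = a_p * x ** g_p``.
    Datasets are assigned platforms and tiers round-robin; cell types cycle
    within each dataset.
    """
    rng, gene_ids, log_mu, sensitive, culture = _gene_params(cfg)
    G = cfg.n_genes
    scales, exps = cfg.scales(), cfg.exponents()
    if len(scales) != cfg.n_platforms or len(exps) != cfg.n_platforms:
        raise ConfigError("platform_scale/platform_exponent length must equal n_platforms")

    sample_ids, ds_col, plat_col, type_col, tier_col = [], [], [], [], []
    type_idx, plat_idx = [], []
    for d in range(cfg.n_datasets):
        p = d % cfg.n_platforms
        tier = TIERS[d % len(TIERS)]
        for i in range(cfg.samples_per_dataset):
            t = i % cfg.n_cell_types
            sample_ids.append(f"ds{d:02d}.s{i:02d}")
            ds_col.append(f"ds{d:02d}")
            plat_col.append(f"platform{p}")
            type_col.append(f"type{t}")
            tier_col.append(tier)
            type_idx.append(t)
            plat_idx.append(p)
    n = len(sample_ids)
    type_idx = np.asarray(type_idx)
    plat_idx = np.asarray(plat_idx)

    eps = rng.normal(0.0, cfg.noise_sd, (G, n))
    x = np.exp(log_mu[:, type_idx] + eps)

    # within-type SD on the expression scale (log-normal moments)
    s2 = cfg.noise_sd**2
    sd_gt = np.exp(log_mu + s2 / 2.0) * np.sqrt(np.expm1(s2))  # G x T
    sd_cols = sd_gt[:, type_idx]
    if len(sensitive):
        shift = plat_idx[None, :] * cfg.platform_shift * sd_cols[sensitive, :]
        x[sensitive, :] += shift
    if len(culture) and cfg.culture_shift > 0:
        mult = np.asarray([_TIER_MULT[t] for t in tier_col])
        x[culture, :] += mult[None, :] * cfg.culture_shift * sd_cols[culture, :]

    y = scales[plat_idx][None, :] * np.power(x, exps[plat_idx][None, :])

    values = pd.DataFrame(y, index=gene_ids, columns=sample_ids)
    table = SampleTable(
        pd.DataFrame(
            {
                "dataset_id": ds_col,
                "platform": plat_col,
                "cell_type": type_col,
                "sample_source": tier_col,
                "tissue": "simulated",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SimTruth(
        true_type=pd.Series(type_col, index=sample_ids, name="true_type"),
        tier=pd.Series(tier_col, index=sample_ids, name="tier"),
        platform_sensitive_genes=[gene_ids[i] for i in sensitive],
        culture_genes=[gene_ids[i] for i in culture],
    )
    return ExpressionMatrix(values, "intensity"), table, truth


def simulate_single_cell(
    cfg: SimConfig, n_cells_per_type: int = 100
) -> tuple[ExpressionMatrix, CellClustering, SimTruth]:
    """Simulate single-cell counts sharing the bulk cohort's cell-type profiles.

    Counts are negative-binomial (gamma-Poisson) with per-cell log-normal
    size factors; the cluster labels are the true cell types. No platform
    artifact is applied: a single-cell run is one platform.
    """
    if n_cells_per_type <= 0:
        raise ConfigError("n_cells_per_type must be positive")
    _, gene_ids, log_mu, sensitive, culture = _gene_params(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    G, T = cfg.n_genes, cfg.n_cell_types
    mu = np.exp(log_mu) * cfg.sc_mean_scale  # G x T

    barcodes, labels, cols = [], [], []
    for t in range(T):
        size_factors = rng.lognormal(0.0, cfg.sc_size_factor_sd, n_cells_per_type)
        for i in range(n_cells_per_type):
            m = mu[:, t] * size_factors[i]
            lam = rng.gamma(shape=cfg.sc_dispersion, scale=m / cfg.sc_dispersion)
            cols.append(rng.poisson(lam))
            barcodes.append(f"type{t}.cell{i:04d}")
            labels.append(f"type{t}")
    values = pd.DataFrame(
        np.column_stack(cols).astype(float), index=gene_ids, columns=barcodes
    )
    clustering = CellClustering(
        pd.Series(labels, index=pd.Index(barcodes, name="barcode"), name="cluster")
    )
    truth = SimTruth(
        true_type=pd.Series(labels, index=barcodes, name="true_type"),
        tier=None,
        platform_sensitive_genes=[gene_ids[i] for i in sensitive],
        culture_genes=[gene_ids[i] for i in culture],
    )
    return ExpressionMatrix(values, "counts"), clustering, truth


def write_simulation(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    samples: SampleTable,
    truth: SimTruth,
) -> Path:
    """Write a simulated bulk cohort in the standard on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(matrix, outdir / "matrix.tsv")
    write_annotations(samples, outdir / "samples.tsv")
    truth.true_type.to_csv(outdir / "truth_types.tsv", sep="\t", index_label="sample_id")
    pd.Series(truth.platform_sensitive_genes, name="gene_id").to_csv(
        outdir / "truth_platform_sensitive_genes.tsv", sep="\t", index=False
    )
    pd.Series(truth.culture_genes, name="gene_id").to_csv(
        outdir / "truth_culture_genes.tsv", sep="\t", index=False
    )
    return outdir
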