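"""Normalization, platform-specific cell QC and two-stage feature selection.

Normalization follows the TP0.1M / TPM convention: per-cell counts are
scaled so that the total over *non-excluded* genes equals ``scale_factor``
(1e5 for droplet UMI data, 1e6 for plate-based read counts), then
log2(x + 1)-transformed.  A configurable list of extremely abundant genes
(islet hormones and friends) can be excluded from the denominator so they do
not distort the library-size estimate; the excluded genes themselves are
still scaled by the same denominator and kept in the matrix.

Feature selection is two-stage: (1) rank genes by a trend-corrected
dispersion statistic and keep the top ``n_hvg``; (2) keep only genes that
are coexpressed with at least ``n`` other HVGs at correlation > ``c`` and
that are expressed in a fraction of cells within ``[min, max]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

#: Abundant transcripts excluded from the per-cell denominator in
#: plate-based (Smart-seq3-style) normalization of mouse islet data.
SMARTSEQ3_EXCLUDED_GENES = (
    "Ins1", "Ins2", "Gcg", "Sst", "Ttr", "Ppy", "Iapp", "Pyy", "Yam1",
)


@dataclass
class QCParams:
    """Platform-specific cell quality-control thresholds.

    ``smartseq3``: keep cells with strictly more than ``min_genes_detected``
    genes at TPM > 0 (default 4000).  ``tenx``: keep cells with at least
    ``min_genes_detected`` detected genes (default 3000) and a mitochondrial
    UMI fraction of at most ``max_mito_fraction`` (default 0.20).
    """

    platform: Literal["smartseq3", "tenx"] = "tenx"
    min_genes_detected: int | None = None
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes_detected is None:
            self.min_genes_detected = 4000 if self.platform == "smartseq3" else 3000
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class FeatureSelectionParams:
    """Parameters of the HVG + coexpression-degree gene filter."""

    n_hvg: int = 2000
    n: int = 10          # minimum number of coexpressed partners
    c: float = 0.25      # correlation threshold rho
    min: float = 0.01    # minimum expressed fraction
    max: float = 0.95    # maximum expressed fraction
    exclusion_genes: tuple = field(default_factory=tuple)
    method: Literal["spearman", "pearson"] = "spearman"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min < self.max <= 1.0):
            raise ValueError("need 0 <= min < max <= 1")
        if not (-1.0 < self.c < 1.0):
            raise ValueError("c must be in (-1, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.exclusion_genes = tuple(self.exclusion_genes)


def normalize(
    counts: CountMatrix,
    scale_factor: float = 1e5,
    excluded_genes: Sequence[str] = (),
) -> NormalizedMatrix:
    """log2(scaled + 1) normalization with hormone-style gene exclusion.

    The per-cell denominator is the total count over genes *not* in
    ``excluded_genes``; every gene (including excluded ones) is scaled by it.
    Cells whose denominator is zero cannot be normalized and are dropped
    with a logged warning.
    """
    excluded = [g for g in excluded_genes if g in counts.gene_ids]
    mask = np.asarray(~counts.gene_ids.isin(excluded))
    denom = counts.values[mask, :].sum(axis=0).astype(np.float64)
    keep = denom > 0
    if not keep.all():
        dropped = counts.cell_ids[~keep].tolist()
        logger.warning(
            "dropping %d cell(s) with zero non-excluded counts: %s",
            len(dropped), dropped[:5],
        )
    vals = counts.values[:, keep].astype(np.float64)
    scaled = vals / denom[keep] * scale_factor
    return NormalizedMatrix(
        counts.gene_ids,
        counts.cell_ids[keep],
        np.log2(scaled + 1.0),
        scale_factor=scale_factor,
        excluded_genes=tuple(excluded),
    )


def qc_filter(counts: CountMatrix, params: QCParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter cells by detected-gene count and (10x) mitochondrial fraction.

    Returns the retained matrix and a per-removed-cell report with a
    ``reason`` column.
    """
    detected = (counts.values > 0).sum(axis=0)
    reasons: dict[str, str] = {}
    if params.platform == "smartseq3":
        bad = detected <= params.min_genes_detected
        for cid in counts.cell_ids[bad]:
            reasons[cid] = "low_genes_detected"
    else:
        prefix = params.mito_gene_prefix.lower()
        mito = np.array([g.lower().startswith(prefix) for g in counts.gene_ids])
        total = counts.values.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, counts.values[mito, :].sum(axis=0) / np.maximum(total, 1), 0.0)
        low = detected < params.min_genes_detected
        high_mito = mito_frac > params.max_mito_fraction
        for cid in counts.cell_ids[low]:
            reasons[cid] = "low_genes_detected"
        for cid in counts.cell_ids[high_mito & ~low]:
            reasons[cid] = "high_mito_fraction"
    keep = [c for c in counts.cell_ids if c not in reasons]
    report = pd.DataFrame(
        {"cell_id": list(reasons), "reason": list(reasons.values())}
    )
    return counts.subset_cells(keep), report


def expressed_fraction(norm: NormalizedMatrix) -> np.ndarray:
    """Per-gene fraction of cells with normalized value > 0."""
    return (norm.values > 0).mean(axis=1)


def pairwise_correlation(
    values: np.ndarray, method: str = "spearman"
) -> np.ndarray:
    """Pairwise gene-gene correlation matrix over cells.

    Rows of ``values`` are genes.  Constant genes have undefined
    correlation; their rows/columns are set to 0 and a warning is logged.
    """
    if method == "spearman":
        data = rankdata(values, axis=1)
    elif method == "pearson":
        data = np.asarray(values, dtype=np.float64)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) in correlation; rho set to 0", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(data)
    rho = np.atleast_2d(rho)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def hvg_dispersion(norm: NormalizedMatrix) -> pd.Series:
    """Trend-corrected dispersion statistic for HVG ranking.

    Per-gene log-variance is regressed on log-mean with a lowess smoother;
    the statistic is the residual (observed minus trend), so genes that are
    more variable than expected at their expression level rank highest.
    """
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1)
    eps = 1e-12
    lm, lv = np.log10(mean + eps), np.log10(var + eps)
    order = np.argsort(lm, kind="stable")
    # lowess needs a few distinct points; degenerate inputs fall back to raw var
    if len(np.unique(lm)) >= 5:
        trend = lowess(lv[order], lm[order], frac=0.3, return_sorted=False)
        resid = np.empty_like(lv)
        resid[order] = lv[order] - trend
    else:
        resid = lv
    resid[var == 0] = -np.inf
    return pd.Series(resid, index=norm.gene_ids, name="dispersion")


def select_features(
    norm: NormalizedMatrix, params: FeatureSelectionParams | None = None
) -> list[str]:
    """Two-stage feature selection; returns surviving genes sorted by id.

    Stage 1 keeps the top ``n_hvg`` genes by trend-corrected dispersion
    (ties broken by gene id for determinism) and drops configured exclusion
    genes.  Stage 2 keeps genes with at least ``n`` coexpression partners at
    rho > ``c`` among the remaining HVGs and with expressed fraction in
    ``[min, max]``.
    """
    if params is None:
        params = FeatureSelectionParams()
    if norm.n_cells < 2:
        raise ValueError("feature selection requires at least 2 cells")
    disp = hvg_dispersion(norm)
    if norm.n_genes <= params.n_hvg:
        if norm.n_genes < params.n_hvg:
            logger.warning(
                "only %d genes available for %d requested HVGs; using all",
                norm.n_genes, params.n_hvg,
            )
        hvgs = list(norm.gene_ids)
    else:
        # ties broken by gene id: sort index first, then stable-sort by value
        ranked = disp.loc[sorted(disp.index)].sort_values(
            ascending=False, kind="stable"
        )
        hvgs = list(ranked.index[: params.n_hvg])
    hvgs = [g for g in hvgs if g not in set(params.exclusion_genes)]
    if len(hvgs) < 2:
        return sorted(hvgs)
    hvgs = sorted(hvgs)
    sub = norm.subset_genes(hvgs)
    rho = pairwise_correlation(sub.values, params.method)
    partners = ((rho > params.c).sum(axis=1) - 1)  # exclude self-correlation
    frac = expressed_fraction(sub)
    keep = (partners >= params.n) & (frac >= params.min) & (frac <= params.max)
    return [g for g, k in zip(hvgs, keep) if k]
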