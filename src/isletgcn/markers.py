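"""Marker statistics, pseudobulk similarity scoring and cross-species overlap.

Marker genes are found per group (one-vs-rest) with the Wilcoxon rank-sum
test; fold change is computed on the linear (un-logged) scale with a +1
pseudocount, and pct.1 / pct.2 are the fractions of expressing cells inside
and outside the group.  The pseudobulk-Spearman similarity statistic
classifies individual (typically bihormonal) cells as more alpha-like or
more PP-like: each query cell is Spearman-correlated with the mean DEG
profile of two reference populations and labelled by the larger score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEGThresholds:
    """Row filters for the marker table (defaults follow the strict panel)."""

    max_p_adj: float = 0.05
    min_log2fc: float = 0.5
    min_pct1: float = 0.5
    max_pct2: float = 0.9

    def __post_init__(self) -> None:
        for f in (self.min_pct1, self.max_pct2):
            if not 0.0 <= f <= 1.0:
                raise ValueError("pct thresholds must be in [0, 1]")


#: Threshold panel used for cross-species marker comparison.
CROSS_SPECIES_THRESHOLDS = DEGThresholds(
    max_p_adj=1e-5, min_log2fc=0.5, min_pct1=0.35, max_pct2=1.0
)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration when there are no ties and the pooled sample has
    at most 12 observations; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and pooled.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment preserving input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def _group_stats(norm: NormalizedMatrix, in_group: np.ndarray,
                 pseudocount: float = 1.0):
    linear = norm.linear()
    mean_in = linear[:, in_group].mean(axis=1)
    mean_out = linear[:, ~in_group].mean(axis=1)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    pct1 = (norm.values[:, in_group] > 0).mean(axis=1)
    pct2 = (norm.values[:, ~in_group] > 0).mean(axis=1)
    return log2fc, pct1, pct2


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    thresholds: DEGThresholds | None = None,
    adjust: str = "bonferroni",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table, thresholded.

    ``labels`` maps cell id -> group.  P-values are adjusted over all genes
    tested within a group.  Rows failing any threshold are dropped; the
    result is sorted by (group, descending log2fc).
    """
    thresholds = thresholds or DEGThresholds()
    labels = labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    for group in groups:
        in_group = (labels == group).to_numpy()
        if in_group.sum() < 3:
            logger.warning("group %r has < 3 cells; skipped", group)
            continue
        x = norm.values[:, in_group]
        y = norm.values[:, ~in_group]
        if norm.n_cells <= 12:
            pv = np.array(
                [wilcoxon_rank_sum(x[i], y[i])[1] for i in range(norm.n_genes)]
            )
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", axis=1)
            pv = np.asarray(res.pvalue)
        log2fc, pct1, pct2 = _group_stats(norm, in_group, pseudocount)
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.gene_ids,
                    "group": group,
                    "log2fc": log2fc,
                    "p_value": pv,
                    "p_adj": adjust_pvalues(pv, adjust),
                    "pct1": pct1,
                    "pct2": pct2,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    keep = (
        (table["p_adj"] <= thresholds.max_p_adj)
        & (table["log2fc"] >= thresholds.min_log2fc)
        & (table["pct1"] >= thresholds.min_pct1)
        & (table["pct2"] <= thresholds.max_pct2)
    )
    table = table.loc[keep]
    return table.sort_values(
        ["group", "log2fc"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def pseudobulk_profile(
    norm: NormalizedMatrix, cell_ids, genes
) -> pd.Series:
    """Per-gene mean normalized expression over a cell set."""
    cells = list(cell_ids)
    if not cells:
        raise ValueError("empty cell set")
    sub = norm.subset_genes(list(genes)).subset_cells(cells)
    return pd.Series(sub.values.mean(axis=1), index=sub.gene_ids, name="pseudobulk")


def similarity_classify(
    norm: NormalizedMatrix,
    query_cells,
    deg_genes,
    ref1_profile: pd.Series,
    ref2_profile: pd.Series,
    ref1_name: str = "ref1",
    ref2_name: str = "ref2",
) -> pd.DataFrame:
    """Label query cells by Spearman similarity to two pseudobulk references.

    Per cell, Spearman rho over ``deg_genes`` against each reference; the
    larger score wins, exact ties are labelled "tie".
    """
    genes = list(deg_genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 DEG genes for a meaningful correlation")
    sub = norm.subset_genes(genes).subset_cells(list(query_cells))
    r1 = ref1_profile.reindex(genes).to_numpy()
    r2 = ref2_profile.reindex(genes).to_numpy()
    if np.isnan(r1).any() or np.isnan(r2).any():
        raise ValueError("reference profiles do not cover all DEG genes")
    rows = []
    for j, cell in enumerate(sub.cell_ids):
        v = sub.values[:, j]
        s1 = stats.spearmanr(v, r1).statistic
        s2 = stats.spearmanr(v, r2).statistic
        label = "tie" if s1 == s2 else (ref1_name if s1 > s2 else ref2_name)
        rows.append((cell, float(s1), float(s2), label))
    return pd.DataFrame(
        rows, columns=["cell_id", f"score_{ref1_name}", f"score_{ref2_name}", "label"]
    ).set_index("cell_id")


def downsample_balanced(labels: pd.Series, seed: int) -> list[str]:
    """Sample each group down to the smallest group size, without replacement."""
    if labels.empty:
        raise ValueError("no cells to downsample")
    rng = np.random.default_rng(seed)
    n_min = int(labels.value_counts().min())
    chosen: list[str] = []
    for group in sorted(labels.unique()):
        cells = np.asarray(sorted(labels.index[labels == group]))
        chosen.extend(rng.choice(cells, size=n_min, replace=False).tolist())
    return chosen


def expressed_gene_overlap(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    ortholog_map: pd.DataFrame,
    min_fraction: float = 0.15,
) -> dict[str, int]:
    """Cross-species overlap of expressed genes over a 1:1 ortholog table.

    ``ortholog_map`` has two columns (species-A gene, species-B gene);
    many-to-many rows are dropped with a warning.  A gene counts as
    expressed when detected (> 0) in at least ``min_fraction`` of cells.
    Returns counts {"a_only", "shared", "b_only"} over mapped gene pairs.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    om = ortholog_map.iloc[:, :2].astype(str)
    om.columns = ["a", "b"]
    dup = om["a"].duplicated(keep=False) | om["b"].duplicated(keep=False)
    if dup.any():
        logger.warning("dropping %d non-1:1 ortholog rows", int(dup.sum()))
        om = om.loc[~dup]
    frac_a = pd.Series((norm_a.values > 0).mean(axis=1), index=norm_a.gene_ids)
    frac_b = pd.Series((norm_b.values > 0).mean(axis=1), index=norm_b.gene_ids)
    om = om[om["a"].isin(frac_a.index) & om["b"].isin(frac_b.index)]
    expr_a = frac_a.loc[om["a"]].to_numpy() >= min_fraction if min_fraction > 0 else frac_a.loc[om["a"]].to_numpy() > 0
    expr_b = frac_b.loc[om["b"]].to_numpy() >= min_fraction if min_fraction > 0 else frac_b.loc[om["b"]].to_numpy() > 0
    return {
        "a_only": int((expr_a & ~expr_b).sum()),
        "shared": int((expr_a & expr_b).sum()),
        "b_only": int((~expr_a & expr_b).sum()),
    }
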