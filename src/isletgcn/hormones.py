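"""Quantile-threshold hormone calling and bihormonal/polyhormonal triage.

Endocrine identity is called from the four islet hormones.  For each
hormone gene a dataset-specific cutoff is placed at an empirical quantile
of its log-normalized expression across *all* cells (zeros included,
linear-interpolation quantile); a cell is positive for a hormone when any
of the hormone's genes exceeds its cutoff strictly.  Cells are then
classified by the number of positive hormones: negative (0), monohormonal
(1), bihormonal (2) or polyhormonal (>= 3).  Droplet datasets cannot
distinguish bihormonal cells from doublets by thresholding alone, so the
pipeline conservatively excludes all multi-hormone cells before
coexpression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix
from .synthdata import HORMONE_LINEAGE, HUMAN_HORMONES, MOUSE_HORMONES


class HormoneClass(str, Enum):
    NEGATIVE = "negative"
    MONOHORMONAL = "monohormonal"
    BIHORMONAL = "bihormonal"
    POLYHORMONAL = "polyhormonal"


@dataclass
class HormoneCallConfig:
    """Hormone gene sets and per-gene quantile thresholds."""

    hormone_genes: dict[str, tuple[str, ...]]
    quantiles: dict[str, float]
    preset: str = "custom"
    ins_rule: str = "or"  # positivity over Ins1/Ins2: "or" (default) or "and"

    def __post_init__(self) -> None:
        for g, q in self.quantiles.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"quantile for {g} outside [0, 1]: {q}")
        for h, genes in self.hormone_genes.items():
            missing = [g for g in genes if g not in self.quantiles]
            if missing:
                raise ValueError(f"no quantile configured for {h} gene(s) {missing}")


#: Dataset-specific quantile thresholds of the five studied datasets.
_PRESETS: dict[str, tuple[dict[str, tuple[str, ...]], dict[str, float]]] = {
    "mouse_embryo_10x": (
        MOUSE_HORMONES,
        {"Ins1": 0.1, "Ins2": 0.1, "Sst": 0.1, "Gcg": 0.1, "Ppy": 0.25},
    ),
    "mouse_adult_10x": (
        MOUSE_HORMONES,
        {"Ins1": 0.55, "Ins2": 0.03, "Sst": 0.05, "Gcg": 0.3, "Ppy": 0.07},
    ),
    "human_embryo": (
        {h: g for h, g in HUMAN_HORMONES.items() if h != "Ppy"},
        {"INS": 0.03, "GCG": 0.03, "SST": 0.001},
    ),
    "human_adult": (
        HUMAN_HORMONES,
        {"INS": 0.1, "SST": 0.1, "GCG": 0.1, "PPY": 0.35},
    ),
    "hesc": (
        {h: g for h, g in HUMAN_HORMONES.items() if h != "Ppy"},
        {"INS": 0.1, "GCG": 0.1, "SST": 0.35},
    ),
}

#: Hormone positivity to cell-type mapping (Ins+ -> beta, etc.).
HORMONE_TO_TYPE = {h: t for h, t in HORMONE_LINEAGE.items()}


def preset_call_config(preset: str) -> HormoneCallConfig:
    try:
        genes, quantiles = _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown hormone preset {preset!r}; known: {sorted(_PRESETS)}"
        ) from None
    return HormoneCallConfig(dict(genes), dict(quantiles), preset=preset)


def compute_quantile_cutoffs(
    norm: NormalizedMatrix, config: HormoneCallConfig
) -> dict[str, float]:
    """Per-gene cutoff at the configured empirical quantile over all cells.

    Linear-interpolation quantile (index h = q * (n - 1)).
    """
    cutoffs: dict[str, float] = {}
    for hormone, genes in config.hormone_genes.items():
        for g in genes:
            if g not in norm.gene_ids:
                raise KeyError(f"hormone gene {g!r} not present in the matrix")
            row = norm.values[norm.gene_ids.get_loc(g), :]
            cutoffs[g] = float(np.quantile(row, config.quantiles[g]))
    return cutoffs


def call_hormone_classes(
    norm: NormalizedMatrix,
    cutoffs: dict[str, float],
    config: HormoneCallConfig,
) -> pd.DataFrame:
    """Classify every cell by its set of positive hormones.

    A hormone is positive when its gene list is positive under the
    configured rule (default: any gene strictly above its cutoff).  Returns
    a frame indexed by cell with per-hormone boolean columns, the positive
    set, the class, and the ordered pair for bihormonal cells.
    """
    hormones = sorted(config.hormone_genes)
    pos = {}
    for hormone in hormones:
        genes = config.hormone_genes[hormone]
        flags = np.stack(
            [
                norm.values[norm.gene_ids.get_loc(g), :] > cutoffs[g]
                for g in genes
            ]
        )
        pos[hormone] = flags.all(axis=0) if config.ins_rule == "and" and len(genes) > 1 else flags.any(axis=0)
    pos_df = pd.DataFrame(pos, index=norm.cell_ids)
    n_pos = pos_df.sum(axis=1)
    cls = np.select(
        [n_pos == 0, n_pos == 1, n_pos == 2],
        [
            HormoneClass.NEGATIVE.value,
            HormoneClass.MONOHORMONAL.value,
            HormoneClass.BIHORMONAL.value,
        ],
        default=HormoneClass.POLYHORMONAL.value,
    )
    positives = pos_df.apply(lambda r: tuple(h for h in hormones if r[h]), axis=1)
    pairs = positives.where(n_pos == 2, other=None).map(
        lambda t: "+".join(t) if t else "", na_action="ignore"
    ).fillna("")
    out = pos_df.copy()
    out["positive_hormones"] = positives
    out["hormone_class"] = cls
    out["pair"] = pairs
    out["called_type"] = positives.map(
        lambda t: HORMONE_TO_TYPE[t[0]] if len(t) == 1 else ""
    )
    return out


def filter_monohormonal(
    norm: NormalizedMatrix, calls: pd.DataFrame
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Keep only monohormonal cells; return an audit of removals per class.

    All dual- and multi-hormone cells (and hormone-negative cells) are
    excluded before coexpression analysis, since droplet data cannot
    separate genuine bihormonal cells from doublets.
    """
    missing = [c for c in norm.cell_ids if c not in calls.index]
    if missing:
        raise ValueError(f"hormone calls missing for cells {missing[:5]}")
    cls = calls.loc[norm.cell_ids, "hormone_class"]
    keep = [c for c, k in cls.items() if k == HormoneClass.MONOHORMONAL.value]
    audit = (
        cls.value_counts()
        .reindex([c.value for c in HormoneClass], fill_value=0)
        .rename_axis("hormone_class")
        .rename("n_cells")
        .reset_index()
    )
    return norm.subset_cells(keep), audit
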