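"""Gene-coexpression-network construction, module detection and cell clustering.

The engine builds an undirected graph over selected genes with edges at
correlation rho > c, detects gene modules with the Walktrap random-walk
community algorithm (agglomerative merging of short-random-walk
neighbourhoods, cut at maximal modularity), scores every cell on each
major module, and clusters cells hierarchically (Ward linkage on the
z-scored module-score matrix, tree cut at k = number of major modules).
Applied recursively to each resulting cell cluster with subset-specific
feature re-selection, this yields a hierarchy of progressively finer
endocrine cell classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .matrix import NormalizedMatrix
from .preprocess import FeatureSelectionParams, pairwise_correlation, select_features

logger = logging.getLogger(__name__)


@dataclass
class GCNParams:
    c: float = 0.25              # edge threshold on rho
    walk_steps: int = 4          # Walktrap random-walk length
    min_module_size: int = 10    # smaller modules are reported as "minor"
    # Stop recursing below this subset size.  With the default edge rule
    # (rho > 0.25, >= 10 partners), null Spearman noise at n < ~150 cells
    # already yields >10 spurious partners per gene, so smaller subsets
    # cannot be analysed meaningfully at these thresholds.
    min_cells: int = 150
    method: str = "spearman"
    max_depth: int = 3


@dataclass
class GeneModule:
    module_id: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class HierarchyNode:
    """One node of the stratified classification tree."""

    name: str
    cell_ids: tuple[str, ...]
    major_modules: list[GeneModule] = field(default_factory=list)
    minor_modules: list[GeneModule] = field(default_factory=list)
    labels: pd.Series | None = None  # per-cell cluster label, None at leaves
    children: list["HierarchyNode"] = field(default_factory=list)

    def leaves(self) -> list["HierarchyNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def find(self, name: str) -> "HierarchyNode | None":
        if self.name == name:
            return self
        for ch in self.children:
            got = ch.find(name)
            if got is not None:
                return got
        return None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_cells": len(self.cell_ids),
            "major_modules": {
                m.module_id: list(m.genes) for m in self.major_modules
            },
            "minor_modules": {
                m.module_id: list(m.genes) for m in self.minor_modules
            },
            "cluster_sizes": (
                self.labels.value_counts().sort_index().to_dict()
                if self.labels is not None
                else {}
            ),
            "children": [ch.to_dict() for ch in self.children],
        }


def build_coexpression_graph(
    norm: NormalizedMatrix,
    features: list[str],
    c: float = 0.25,
    method: str = "spearman",
) -> ig.Graph:
    """Graph over ``features`` with edges where rho > c (weight = rho).

    Vertices are ordered by sorted gene id; isolated vertices are retained.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 features to build a graph")
    feats = sorted(features)
    sub = norm.subset_genes(feats)
    rho = pairwise_correlation(sub.values, method)
    iu = np.triu_indices(len(feats), k=1)
    above = rho[iu] > c
    edges = list(zip(iu[0][above].tolist(), iu[1][above].tolist()))
    g = ig.Graph(n=len(feats), edges=edges)
    g.vs["name"] = feats
    g.es["weight"] = rho[iu][above].tolist()
    return g


def detect_modules(
    graph: ig.Graph, min_module_size: int = 10, walk_steps: int = 4
) -> tuple[list[GeneModule], list[GeneModule]]:
    """Walktrap communities cut at maximal modularity.

    Returns ``(major, minor)`` modules; modules smaller than
    ``min_module_size`` are set aside as minor and take no part in cell
    assignment.  Together they partition the graph's vertices.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if graph.ecount() == 0:
        logger.warning("graph has no edges; every gene is its own minor module")
        membership = list(range(graph.vcount()))
    else:
        dendro = graph.community_walktrap(weights="weight", steps=walk_steps)
        membership = dendro.as_clustering().membership
    groups: dict[int, list[str]] = {}
    for v, m in zip(graph.vs["name"], membership):
        groups.setdefault(m, []).append(v)
    ordered = sorted(groups.values(), key=lambda gs: (-len(gs), gs[0]))
    major, minor = [], []
    for k, genes in enumerate(ordered, start=1):
        mod = GeneModule(f"M{k}", tuple(sorted(genes)))
        (major if mod.size >= min_module_size else minor).append(mod)
    return major, minor


def module_scores(
    norm: NormalizedMatrix, modules: list[GeneModule]
) -> pd.DataFrame:
    """Cells x modules score matrix: mean expression, z-scored per module."""
    rows = {}
    for mod in modules:
        idx = norm.gene_index(list(mod.genes))
        score = norm.values[idx, :].mean(axis=0)
        sd = score.std()
        if sd == 0:
            logger.warning("module %s has constant score; z set to 0", mod.module_id)
            rows[mod.module_id] = np.zeros_like(score)
        else:
            rows[mod.module_id] = (score - score.mean()) / sd
    return pd.DataFrame(rows, index=norm.cell_ids)


def assign_cells_to_modules(
    norm: NormalizedMatrix, major_modules: list[GeneModule]
) -> tuple[pd.Series, pd.DataFrame]:
    """Ward-cluster cells on module z-scores and name clusters by modules.

    The tree is cut into k = number of major modules clusters; each cell
    cluster is named after the module with the highest mean z-score inside
    it (duplicate winners are suffix-disambiguated).
    """
    if not major_modules:
        raise ValueError("need at least one major module")
    scores = module_scores(norm, major_modules)
    k = len(major_modules)
    if norm.n_cells <= k:
        raise ValueError(f"cannot cut {norm.n_cells} cells into {k} clusters")
    Z = linkage(scores.to_numpy(), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    n_found = len(np.unique(raw))
    if n_found < k:
        logger.warning("requested %d clusters but tree yields %d", k, n_found)
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    for cl in sorted(np.unique(raw)):
        mean_z = scores.loc[raw == cl].mean(axis=0)
        winner = str(mean_z.idxmax())
        used[winner] = used.get(winner, 0) + 1
        if used[winner] > 1:
            logger.warning("module %s won multiple clusters; suffixing", winner)
            winner = f"{winner}_{used[winner]}"
        names[cl] = winner
    labels = pd.Series([names[c] for c in raw], index=norm.cell_ids, name="cluster")
    return labels, scores


def analyze_subset(
    norm: NormalizedMatrix,
    fs_params: FeatureSelectionParams,
    params: GCNParams,
    name: str = "root",
) -> HierarchyNode:
    """Feature selection + graph + modules + cell assignment for one subset."""
    node = HierarchyNode(name=name, cell_ids=tuple(norm.cell_ids))
    features = select_features(norm, fs_params)
    if len(features) < 2:
        logger.info("node %s: %d usable features; leaf", name, len(features))
        return node
    graph = build_coexpression_graph(norm, features, c=params.c, method=params.method)
    major, minor = detect_modules(
        graph, min_module_size=params.min_module_size, walk_steps=params.walk_steps
    )
    node.major_modules, node.minor_modules = major, minor
    if len(major) < 2:
        logger.info("node %s: %d major module(s); not split", name, len(major))
        return node
    labels, _ = assign_cells_to_modules(norm, major)
    node.labels = labels
    return node


def stratified_gcn(
    norm: NormalizedMatrix,
    fs_params: FeatureSelectionParams | None = None,
    params: GCNParams | None = None,
    plan: str | dict = "auto",
) -> HierarchyNode:
    """Recursive GCN classification with per-subset feature re-selection.

    ``plan="auto"`` recurses into every cluster with at least
    ``params.min_cells`` cells; a dict plan maps node names to the list of
    child cluster names to recurse into.  Recursion also stops when a
    subset yields fewer than two major modules.
    """
    fs_params = fs_params or FeatureSelectionParams()
    params = params or GCNParams()

    def recurse(sub: NormalizedMatrix, name: str, depth: int) -> HierarchyNode:
        if sub.n_cells == 0:
            logger.warning("node %s: empty subset skipped", name)
            return HierarchyNode(name=name, cell_ids=())
        node = analyze_subset(sub, fs_params, params, name=name)
        if node.labels is None or depth >= params.max_depth:
            return node
        for cluster in sorted(node.labels.unique()):
            cells = node.labels.index[node.labels == cluster]
            child_name = f"{name}/{cluster}"
            if plan == "auto":
                if len(cells) < params.min_cells:
                    continue
            elif cluster not in dict(plan).get(name, []):
                continue
            node.children.append(
                recurse(sub.subset_cells(list(cells)), child_name, depth + 1)
            )
        return node

    return recurse(norm, "root", 0)
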