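"""Seeded generator of synthetic islet scRNA-seq datasets and ATAC fixtures.

The generator plants the population structure that the downstream
classification pipeline is designed to recover:

* four endocrine lineages (alpha, beta, delta, PP), each with a
  type-specific gene program (a block of genes whose mean is multiplied by
  ``2**log2_effect`` in cells of that type);
* in mouse presets, a strong transcriptional program shared by alpha and
  PP cells plus weaker alpha- and PP-private programs, so that a
  top-level coexpression analysis merges alpha/PP into one cluster while a
  subset analysis separates them;
* in mouse presets, a beta split into Glut2-High / Glut2-Low subtypes with
  subtype-private programs; in human presets, a delta split into
  delta1 / delta2 at roughly 9:1 with subtype-private programs;
* hormone genes (Ins1/Ins2 or INS, Gcg, Sst, Ppy) at extremely high counts
  in their own lineage and near zero elsewhere;
* rare bihormonal cells drawn from convex mixtures of two lineage mean
  profiles (intermediate hormone levels on both sides);
* doublets formed by summing the counts of two randomly chosen cells;
* negative-binomial count noise and lognormal library sizes.

Counts for cell j are NB(mean = L_j * p_g, size = 1/dispersion) where L_j
is the cell's lognormal library size and p_g its type's mean expression
proportion for gene g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

MOUSE_HORMONES: dict[str, tuple[str, ...]] = {
    "Ins": ("Ins1", "Ins2"),
    "Gcg": ("Gcg",),
    "Sst": ("Sst",),
    "Ppy": ("Ppy",),
}
HUMAN_HORMONES: dict[str, tuple[str, ...]] = {
    "Ins": ("INS",),
    "Gcg": ("GCG",),
    "Sst": ("SST",),
    "Ppy": ("PPY",),
}
HORMONE_LINEAGE = {"Ins": "beta", "Gcg": "alpha", "Sst": "delta", "Ppy": "pp"}

#: Baseline relative weight of a hormone gene outside its own lineage.
#: Kept tiny so spurious hormone positives (and hence spurious bihormonal
#: calls) are rare, as in well-behaved real data.
_HORMONE_BACKGROUND_WEIGHT = 0.002


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Program:
    """A coexpressed gene program active in a set of cell classes.

    ``active_in`` holds type names ("alpha") or type:subtype selectors
    ("beta:glut2_high").
    """

    name: str
    n_genes: int
    log2_effect: float
    active_in: tuple[str, ...]
    #: baseline relative weight (vs background median 1.0) of the program's
    #: genes in cells where the program is inactive.  Kept low enough that
    #: a program gene stays below ~95% detection overall, or the
    #: expressed-fraction cap of feature selection would discard it.
    #: Programs of rare cell classes use a low baseline (near-binary marker
    #: behaviour): rank correlation between two genes of a rare program is
    #: bounded by ~3*f*(1-f) unless the inactive majority ties at zero.
    baseline: float = 1.5
    #: sd (log2 units) of a per-cell program-activity factor shared by all
    #: of the program's genes in cells where it is active.  Models graded
    #: program usage and creates within-type coexpression, which is the
    #: only usable correlation signal for a program active in most of an
    #: analysis subset.
    activity_sd: float = 0.0

    def is_active(self, cell_type: str, subtype: str) -> bool:
        return cell_type in self.active_in or f"{cell_type}:{subtype}" in self.active_in


@dataclass
class GeneratorConfig:
    preset: str = "mouse_adult"
    n_genes: int = 3000
    n_cells: int = 2000
    type_proportions: dict[str, float] = field(default_factory=dict)
    programs: tuple[Program, ...] = ()
    shared_alpha_pp_effect: float = 2.5
    delta2_prevalence: float = 0.10
    beta_low_prevalence: float = 0.50
    bihormonal_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    doublet_rate: float = 0.02
    nb_dispersion: float = 0.3
    libsize_lognormal: tuple[float, float] = (9.2, 0.3)
    hormone_boost: float = 1.5e5
    program_baseline: float = 1.0  # global multiplier on per-program baselines
    seed: int = 0

    @property
    def species(self) -> str:
        return "human" if self.preset.startswith("human") else "mouse"

    @property
    def hormone_genes(self) -> dict[str, tuple[str, ...]]:
        return HUMAN_HORMONES if self.species == "human" else MOUSE_HORMONES

    def validate(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type_proportions sum to {total}, expected 1")
        fracs = list(self.type_proportions.values()) + list(
            self.bihormonal_rates.values()
        ) + [self.doublet_rate, self.delta2_prevalence, self.beta_low_prevalence]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        n_hormone = sum(len(g) for g in self.hormone_genes.values())
        n_program = sum(p.n_genes for p in self.programs)
        if self.n_genes < n_hormone + n_program:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_program} program genes "
                f"plus {n_hormone} hormone genes"
            )


def _mouse_programs(shared_effect: float, private_effect: float,
                    identity_effect: float) -> tuple[Program, ...]:
    return (
        Program("shared_alpha_pp", 150, shared_effect, ("alpha", "pp")),
        Program("beta_identity", 100, identity_effect, ("beta",)),
        Program("delta_identity", 100, identity_effect, ("delta",)),
        # alpha/PP private marker sets are broad in real islets; 200 genes
        # per side gives the pseudobulk-similarity statistic a realistic
        # DEG panel width
        Program("alpha_private", 200, private_effect, ("alpha",)),
        Program("pp_private", 200, private_effect, ("pp",)),
        Program("glut2_high_private", 60, private_effect, ("beta:glut2_high",)),
        Program("glut2_low_private", 60, private_effect, ("beta:glut2_low",)),
    )


def _human_programs(identity_effect: float, subtype_effect: float) -> tuple[Program, ...]:
    # delta and PP are rare (<10% of cells), so their identity programs use
    # the near-binary marker design (low baseline, strong activation);
    # delta1 covers ~90% of delta cells, so its program additionally
    # carries graded per-cell activity -- the only correlation signal that
    # survives rank transformation for a near-ubiquitous program.
    return (
        Program("alpha_identity", 100, identity_effect, ("alpha",)),
        Program("beta_identity", 100, identity_effect, ("beta",)),
        Program("delta_identity", 100, identity_effect + 1.2, ("delta",), baseline=0.2),
        Program("pp_identity", 100, identity_effect + 1.6, ("pp",), baseline=0.1),
        Program("delta1_private", 60, subtype_effect, ("delta:delta1",),
                baseline=0.3, activity_sd=0.8),
        Program("delta2_private", 60, subtype_effect + 1.6, ("delta:delta2",),
                baseline=0.1),
    )


# Effect sizes (log2 units) chosen so that, under the default NB noise,
# lineage-program gene pairs correlate above the default coexpression
# threshold (rho > 0.25) in a whole-dataset analysis while subtype-private
# program pairs only cross it within their parent cluster -- the stratified
# behaviour the classifier is designed to expose.  See docs/methods.md.
_MOUSE_PRIVATE_EFFECT = 1.4
_HUMAN_IDENTITY_EFFECT = 3.2
_HUMAN_SUBTYPE_EFFECT = 2.5


def preset_config(preset: str, **overrides) -> GeneratorConfig:
    """Named generator presets mirroring the studied populations."""
    if preset == "mouse_adult":
        cfg = GeneratorConfig(
            preset=preset,
            type_proportions={"beta": 0.40, "delta": 0.20, "alpha": 0.20, "pp": 0.20},
            programs=_mouse_programs(2.5, _MOUSE_PRIVATE_EFFECT, 2.5),
            bihormonal_rates={("Gcg", "Ppy"): 0.005, ("Gcg", "Ins"): 0.005},
        )
    elif preset == "mouse_embryo":
        cfg = GeneratorConfig(
            preset=preset,
            type_proportions={"beta": 0.30, "delta": 0.20, "alpha": 0.25, "pp": 0.25},
            programs=_mouse_programs(2.5, _MOUSE_PRIVATE_EFFECT, 2.5)[:5],
            bihormonal_rates={("Gcg", "Ins"): 0.03, ("Gcg", "Ppy"): 0.02},
        )
    elif preset == "human_adult":
        # proportions follow the reported adult composition:
        # 10858 beta, 2370 delta, 9635 alpha, 1122 PP of 23985 cells
        cfg = GeneratorConfig(
            preset=preset,
            type_proportions={
                "beta": 10858 / 23985,
                "delta": 2370 / 23985,
                "alpha": 9635 / 23985,
                "pp": 1122 / 23985,
            },
            programs=_human_programs(_HUMAN_IDENTITY_EFFECT, _HUMAN_SUBTYPE_EFFECT),
            bihormonal_rates={("Gcg", "Ppy"): 0.005, ("Ins", "Gcg"): 0.005},
        )
    elif preset == "human_embryo":
        cfg = GeneratorConfig(
            preset=preset,
            type_proportions={"beta": 0.35, "delta": 0.15, "alpha": 0.35, "pp": 0.15},
            programs=_human_programs(_HUMAN_IDENTITY_EFFECT, _HUMAN_SUBTYPE_EFFECT)[:4],
            bihormonal_rates={("Ins", "Gcg"): 0.03},
        )
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    truth: pd.DataFrame  # indexed by cell_id
    gene_meta: pd.DataFrame  # indexed by gene id: program membership
    config: GeneratorConfig
    #: expected per-class mean expression proportions (genes x "type:subtype"),
    #: before per-cell program-activity factors; column sums are 1
    class_profiles: pd.DataFrame | None = None

    @property
    def singlet_mask(self) -> pd.Series:
        return ~self.truth["is_doublet"]


def _cell_classes(cfg: GeneratorConfig) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Enumerate (type, subtype) classes and their probabilities."""
    classes: list[tuple[str, str]] = []
    probs: list[float] = []
    for t, p in sorted(cfg.type_proportions.items()):
        if t == "beta" and any("beta:" in sel for pr in cfg.programs for sel in pr.active_in):
            classes += [("beta", "glut2_high"), ("beta", "glut2_low")]
            probs += [p * (1 - cfg.beta_low_prevalence), p * cfg.beta_low_prevalence]
        elif t == "delta" and any("delta:" in sel for pr in cfg.programs for sel in pr.active_in):
            classes += [("delta", "delta1"), ("delta", "delta2")]
            probs += [p * (1 - cfg.delta2_prevalence), p * cfg.delta2_prevalence]
        else:
            classes.append((t, ""))
            probs.append(p)
    return classes, np.asarray(probs)


def _base_weights(cfg: GeneratorConfig, rng: np.random.Generator,
                  gene_ids: list[str], program_of: np.ndarray) -> np.ndarray:
    """Baseline relative expression weights (before program activation)."""
    n = cfg.n_genes
    w = rng.lognormal(0.0, 0.8, size=n)
    # program genes sit at their program's configured baseline exactly:
    # keeping the two sides of a lineage contrast at identical aggregate
    # weight makes planted mixture weights (bihormonal truth) line up with
    # transcriptome-level similarity
    baselines = {p.name: p.baseline * cfg.program_baseline for p in cfg.programs}
    is_program = program_of != ""
    w[is_program] = np.array([baselines[p] for p in program_of[is_program]])
    hormone_set = {g for genes in cfg.hormone_genes.values() for g in genes}
    for i, g in enumerate(gene_ids):
        if g in hormone_set:
            w[i] = _HORMONE_BACKGROUND_WEIGHT
    return w


def _class_profile(cfg: GeneratorConfig, weights: np.ndarray,
                   gene_slices: dict[str, slice], hormone_idx: dict[str, np.ndarray],
                   cell_type: str, subtype: str) -> np.ndarray:
    w = weights.copy()
    for prog in cfg.programs:
        if prog.is_active(cell_type, subtype):
            w[gene_slices[prog.name]] *= 2.0 ** prog.log2_effect
    for hormone, lineage in HORMONE_LINEAGE.items():
        if lineage == cell_type and hormone in hormone_idx:
            w[hormone_idx[hormone]] *= cfg.hormone_boost
    return w  # unnormalized; columns are normalized per cell at the end


def generate_islet_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a seeded synthetic dataset with full per-cell ground truth.

    The truth table has one row per cell with columns ``type``, ``subtype``,
    ``bihormonal_pair`` ("" for monohormonal cells), ``mix_weight`` (weight
    of the first hormone's lineage in a bihormonal mixture), ``is_doublet``
    and ``parent1``/``parent2``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- gene universe: hormone genes first, then program blocks, then background
    hormone_gene_list = [g for h in sorted(cfg.hormone_genes) for g in cfg.hormone_genes[h]]
    gene_ids = list(hormone_gene_list)
    program_of = [""] * len(gene_ids)
    gene_slices: dict[str, slice] = {}
    pos = len(gene_ids)
    for prog in cfg.programs:
        gene_slices[prog.name] = slice(pos, pos + prog.n_genes)
        gene_ids += [f"{prog.name}_g{i:03d}" for i in range(prog.n_genes)]
        program_of += [prog.name] * prog.n_genes
        pos += prog.n_genes
    gene_ids += [f"bg_g{i:04d}" for i in range(cfg.n_genes - pos)]
    program_of += [""] * (cfg.n_genes - pos)
    program_of = np.asarray(program_of, dtype=object)
    hormone_idx = {
        h: np.array([gene_ids.index(g) for g in genes])
        for h, genes in cfg.hormone_genes.items()
    }

    weights = _base_weights(cfg, rng, gene_ids, program_of)

    # --- cell classes (singlets)
    classes, class_probs = _cell_classes(cfg)
    pair_list = sorted(cfg.bihormonal_rates)
    pair_rate = sum(cfg.bihormonal_rates.values())
    # bihormonal categories claim their configured share of cells; the
    # remaining mass follows type_proportions
    cat_probs = np.concatenate(
        [class_probs * (1.0 - pair_rate),
         [cfg.bihormonal_rates[p] for p in pair_list]]
    )
    cat = rng.choice(len(cat_probs), size=cfg.n_cells, p=cat_probs / cat_probs.sum())

    profiles = np.stack(
        [
            _class_profile(cfg, weights, gene_slices, hormone_idx, t, s)
            for t, s in classes
        ],
        axis=1,
    )  # genes x n_classes
    type_profile = {}
    for (t, s), k in zip(classes, range(len(classes))):
        type_profile.setdefault(t, profiles[:, k])  # first (majority) subtype profile

    n = cfg.n_cells
    mean_prop = np.empty((cfg.n_genes, n))
    types = np.empty(n, dtype=object)
    subtypes = np.empty(n, dtype=object)
    pairs = np.array([""] * n, dtype=object)
    mix_w = np.full(n, np.nan)
    for j in range(n):
        k = cat[j]
        if k < len(classes):
            t, s = classes[k]
            types[j], subtypes[j] = t, s
            mean_prop[:, j] = profiles[:, k]
        else:
            h1, h2 = pair_list[k - len(classes)]
            lam = rng.uniform(0.3, 0.7)
            p1 = type_profile[HORMONE_LINEAGE[h1]]
            p2 = type_profile[HORMONE_LINEAGE[h2]]
            mean_prop[:, j] = lam * p1 / p1.sum() + (1.0 - lam) * p2 / p2.sum()
            types[j], subtypes[j] = "bihormonal", ""
            pairs[j] = f"{h1}+{h2}"
            mix_w[j] = lam

    # graded per-cell program activity (shared lognormal factor across a
    # program's genes) for programs that model within-type heterogeneity
    for prog in cfg.programs:
        if prog.activity_sd <= 0:
            continue
        z = rng.standard_normal(n)
        active = np.array(
            [
                types[j] != "bihormonal" and prog.is_active(types[j], subtypes[j])
                for j in range(n)
            ]
        )
        factor = np.where(active, 2.0 ** (prog.activity_sd * z), 1.0)
        mean_prop[gene_slices[prog.name], :] *= factor[None, :]

    mean_prop /= mean_prop.sum(axis=0, keepdims=True)
    libsize = rng.lognormal(*cfg.libsize_lognormal, size=n)
    mean = mean_prop * libsize
    size = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mean)).astype(np.int64)

    cell_ids = [f"cell{j:05d}" for j in range(n)]
    truth = pd.DataFrame(
        {
            "type": types,
            "subtype": subtypes,
            "bihormonal_pair": pairs,
            "mix_weight": mix_w,
            "is_doublet": False,
            "parent1": "",
            "parent2": "",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(pd.Index(gene_ids), pd.Index(cell_ids), counts)

    # --- doublets: sums of two distinct singlet columns
    n_doub = int(round(cfg.doublet_rate * n))
    if n_doub > 0:
        pair_idx = [rng.choice(n, size=2, replace=False) for _ in range(n_doub)]
        doublet_pairs = [(cell_ids[i], cell_ids[j]) for i, j in pair_idx]
        cm = make_artificial_doublets(cm, doublet_pairs)
        rows = []
        for d, (p1, p2) in enumerate(doublet_pairs):
            rows.append(
                {
                    "type": "doublet",
                    "subtype": "",
                    "bihormonal_pair": "",
                    "mix_weight": np.nan,
                    "is_doublet": True,
                    "parent1": p1,
                    "parent2": p2,
                }
            )
        extra = pd.DataFrame(rows, index=pd.Index(cm.cell_ids[n:], name="cell_id"))
        truth = pd.concat([truth, extra])

    gene_meta = pd.DataFrame(
        {"program": program_of}, index=pd.Index(gene_ids, name="gene")
    )
    class_profiles = pd.DataFrame(
        {
            f"{t}:{s}" if s else t: profiles[:, k] / profiles[:, k].sum()
            for k, (t, s) in enumerate(classes)
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return SyntheticDataset(
        counts=cm, truth=truth, gene_meta=gene_meta, config=cfg,
        class_profiles=class_profiles,
    )


def make_artificial_doublets(
    counts: CountMatrix, pairs: Sequence[tuple[str, str]]
) -> CountMatrix:
    """Append doublet columns that are elementwise sums of two parent cells.

    Mirrors the experimental construction of artificial doublets (two cells
    deliberately processed as one).  Parent columns are left untouched;
    doublets get synthesized ids ``doubletNNN:<p1>+<p2>``.
    """
    if not pairs:
        return counts
    i1 = counts.cell_index([p[0] for p in pairs])
    i2 = counts.cell_index([p[1] for p in pairs])
    doub = counts.values[:, i1] + counts.values[:, i2]
    ids = [f"doublet{k:03d}:{a}+{b}" for k, (a, b) in enumerate(pairs)]
    return CountMatrix(
        counts.gene_ids,
        counts.cell_ids.append(pd.Index(ids)),
        np.concatenate([counts.values, doub], axis=1),
    )


def generate_atac_fixture(
    n_alpha: int,
    n_beta: int,
    high_fraction: float,
    seed: int,
    region: str = "Ins1",
):
    """Synthetic region x cell accessibility fixture with planted high-SI alpha cells.

    Beta cells draw positive signal intensities from a lognormal; a
    Bernoulli(``high_fraction``) subset of alpha cells is planted above
    0.45 x the beta maximum, the rest sit at zero or low background (capped
    well below the threshold).  Returns ``(signal_matrix, truth_high)``
    where ``truth_high`` is a boolean Series over alpha cells.
    """
    from .atac import SignalMatrix  # local import to avoid cycle

    if n_alpha <= 0 or n_beta <= 0:
        raise ValueError("cell counts must be positive")
    if not 0.0 <= high_fraction <= 1.0:
        raise ValueError("high_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    beta_si = rng.lognormal(3.5, 0.4, size=n_beta)
    bmax = beta_si.max()
    high = rng.random(n_alpha) < high_fraction
    alpha_si = np.zeros(n_alpha)
    n_low = int((~high).sum())
    background = np.minimum(rng.exponential(0.05 * bmax, size=n_low), 0.2 * bmax)
    background[rng.random(n_low) < 0.6] = 0.0
    alpha_si[~high] = background
    alpha_si[high] = rng.uniform(0.5, 0.95, size=int(high.sum())) * bmax
    cells = [f"alpha{j:05d}" for j in range(n_alpha)] + [
        f"beta{j:05d}" for j in range(n_beta)
    ]
    si = np.concatenate([alpha_si, beta_si])[None, :]
    groups = pd.Series(
        ["alpha"] * n_alpha + ["beta"] * n_beta, index=cells, name="group"
    )
    sm = SignalMatrix(
        region_ids=pd.Index([region]),
        cell_ids=pd.Index(cells),
        values=si,
        cell_groups=groups,
    )
    truth_high = pd.Series(high, index=cells[:n_alpha], name="planted_high")
    return sm, truth_high
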