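"""Wilcoxon statistics, adjustment, marker tables and similarity scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletgcn import (
    DEGThresholds,
    adjust_pvalues,
    downsample_balanced,
    expressed_gene_overlap,
    find_markers,
    pseudobulk_profile,
    similarity_classify,
    wilcoxon_rank_sum,
)

from conftest import norm_from_values


def exact_two_sided_p(x, y):
    """Enumeration oracle: P(|U - mu| >= |u_obs - mu|) over all rank splits."""
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: r for r, v in enumerate(pooled)}
    mu = nx * ny / 2

    def u_of(idx):
        rank_sum = sum(idx)
        return rank_sum - nx * (nx - 1) / 2

    u_obs = u_of([ranks[v] for v in x])
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(nx + ny), nx):
        total += 1
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestWilcoxon:
    def test_separated_triples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2/20 rank splits as extreme

    def test_separated_pairs(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every no-tie input with |x|+|y| <= 10 (up to rank pattern)."""
        for n in range(2, 11):
            for nx in range(1, n):
                for comb in itertools.combinations(range(n), nx):
                    x = [float(i) for i in comb]
                    y = [float(i) for i in range(n) if i not in comb]
                    _, p = wilcoxon_rank_sum(x, y)
                    assert p == pytest.approx(exact_two_sided_p(x, y)), (x, y)


class TestAdjust:
    def test_bonferroni_capped(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.2, 0.5], "bonferroni"), [0.03, 0.6, 1.0]
        )

    def test_bh_step_up(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            np.testing.assert_allclose(adjust_pvalues([0.123], method), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "bh")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_ordering_bonferroni_ge_bh_ge_raw(self, ps):
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        assert np.all(bonf >= bh - 1e-12)
        assert np.all(bh >= np.asarray(ps) - 1e-12)


def _marker_norm():
    """Two groups of 6 cells, one clean marker plus filler genes."""
    rng = np.random.default_rng(0)
    n = 12
    lin = np.vstack(
        [
            np.r_[np.full(6, 3.0), np.full(6, 1.0)],   # marker: log2fc = 1
            rng.uniform(0.5, 1.5, n),                    # null filler
            np.r_[np.full(6, 2.0), np.zeros(6)],         # group-only gene
        ]
    )
    vals = np.log2(lin + 1)
    labels = pd.Series(["A"] * 6 + ["B"] * 6,
                       index=[f"c{i}" for i in range(n)])
    return norm_from_values(vals, genes=["marker", "filler", "only_a"],
                            cells=list(labels.index)), labels


class TestFindMarkers:
    def test_log2fc_and_pct_definitions(self):
        norm, labels = _marker_norm()
        table = find_markers(
            norm, labels,
            DEGThresholds(max_p_adj=1.0, min_log2fc=-10, min_pct1=0.0, max_pct2=1.0),
        )
        row = table[(table["gene"] == "marker") & (table["group"] == "A")].iloc[0]
        assert row["log2fc"] == pytest.approx(1.0)  # log2((3+1)/(1+1))
        only_a = table[(table["gene"] == "only_a") & (table["group"] == "A")].iloc[0]
        assert only_a["pct1"] == 1.0 and only_a["pct2"] == 0.0

    def test_pct_counts_expressing_cells(self):
        vals = np.array([[1.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        labels = pd.Series(["A"] * 4 + ["B"] * 4,
                           index=[f"c{i}" for i in range(8)])
        norm = norm_from_values(vals, genes=["g"], cells=list(labels.index))
        table = find_markers(
            norm, labels,
            DEGThresholds(max_p_adj=1.0, min_log2fc=-10, min_pct1=0.0, max_pct2=1.0),
        )
        row = table[(table["gene"] == "g") & (table["group"] == "A")].iloc[0]
        assert row["pct1"] == 0.5  # 2 of 4 group cells express it

    def test_thresholds_hold_row_wise(self, mouse_norm, mouse_dataset):
        truth = mouse_dataset.truth
        cells = [c for c in mouse_norm.cell_ids
                 if truth.loc[c, "type"] in ("alpha", "beta")][:300]
        labels = truth.loc[cells, "type"]
        thr = DEGThresholds(max_p_adj=0.05, min_log2fc=0.5, min_pct1=0.5, max_pct2=0.9)
        table = find_markers(mouse_norm.subset_cells(cells), labels, thr)
        assert len(table) > 0
        assert (table["p_adj"] <= thr.max_p_adj).all()
        assert (table["log2fc"] >= thr.min_log2fc).all()
        assert (table["pct1"] >= thr.min_pct1).all()
        assert (table["pct2"] <= thr.max_pct2).all()
        assert (table["p_adj"] >= table["p_value"] - 1e-12).all()

    def test_tiny_group_skipped(self, caplog):
        norm, labels = _marker_norm()
        labels = labels.copy()
        labels.iloc[:2] = "C"  # a 2-cell group
        labels.iloc[2:6] = "A"
        with caplog.at_level("WARNING"):
            table = find_markers(
                norm, labels,
                DEGThresholds(max_p_adj=1.0, min_log2fc=-10, min_pct1=0.0, max_pct2=1.0),
            )
        assert "C" not in set(table["group"])
        assert "skipped" in caplog.text


class TestPseudobulkAndSimilarity:
    def test_pseudobulk_means(self):
        norm = norm_from_values([[1.0, 3.0], [2.0, 2.0]], genes=["a", "b"])
        prof = pseudobulk_profile(norm, ["c0", "c1"], ["a", "b"])
        assert prof["a"] == 2.0 and prof["b"] == 2.0
        single = pseudobulk_profile(norm, ["c0"], ["a"])
        assert single["a"] == 1.0
        with pytest.raises(ValueError):
            pseudobulk_profile(norm, [], ["a"])

    def test_self_profile_queries(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        p1 = pd.Series(rng.uniform(0, 5, 10), index=genes)
        p2 = pd.Series(rng.uniform(0, 5, 10), index=genes)
        vals = np.column_stack([p1.to_numpy(), p2.to_numpy()])
        norm = norm_from_values(vals, genes=genes, cells=["q1", "q2"])
        res = similarity_classify(norm, ["q1", "q2"], genes, p1, p2,
                                  "ref1", "ref2")
        assert res.loc["q1", "score_ref1"] == pytest.approx(1.0)
        assert res.loc["q1", "label"] == "ref1"
        assert res.loc["q2", "label"] == "ref2"

    def test_invariant_under_monotone_transform_of_query(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(15)]
        p1 = pd.Series(rng.uniform(0, 5, 15), index=genes)
        p2 = pd.Series(rng.uniform(0, 5, 15), index=genes)
        q = rng.uniform(0, 5, 15)
        norm_a = norm_from_values(q[:, None], genes=genes, cells=["q"])
        norm_b = norm_from_values(np.expm1(q)[:, None], genes=genes, cells=["q"])
        ra = similarity_classify(norm_a, ["q"], genes, p1, p2)
        rb = similarity_classify(norm_b, ["q"], genes, p1, p2)
        assert ra.loc["q", "score_ref1"] == pytest.approx(rb.loc["q", "score_ref1"])
        assert ra.loc["q", "label"] == rb.loc["q", "label"]

    def test_too_few_genes_rejected(self):
        norm = norm_from_values([[1.0], [2.0]], genes=["a", "b"])
        p = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            similarity_classify(norm, ["c0"], ["a", "b"], p, p)


class TestDownsample:
    def test_printed_group_sizes_reduce_to_1122(self):
        sizes = {"beta": 10858, "delta": 2370, "alpha": 9635, "pp": 1122}
        labels = pd.Series(
            np.repeat(list(sizes), list(sizes.values())),
            index=[f"c{i}" for i in range(sum(sizes.values()))],
        )
        chosen = downsample_balanced(labels, seed=0)
        counts = labels.loc[chosen].value_counts()
        assert (counts == 1122).all()
        assert len(chosen) == len(set(chosen))

    def test_equal_groups_identity_and_determinism(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5,
                           index=[f"c{i}" for i in range(10)])
        chosen = downsample_balanced(labels, seed=3)
        assert sorted(chosen) == sorted(labels.index)
        assert downsample_balanced(labels, seed=7) == downsample_balanced(labels, seed=7)


class TestOverlap:
    @staticmethod
    def _norm(expr, genes):
        return norm_from_values(np.asarray(expr, dtype=float), genes=genes)

    def test_set_algebra(self):
        a = self._norm([[1, 1], [1, 1], [0, 0]], ["a1", "a2", "a3"])
        b = self._norm([[1, 1], [0, 0], [0, 0]], ["b1", "b2", "b3"])
        omap = pd.DataFrame({"a": ["a1", "a2", "a3"], "b": ["b1", "b2", "b3"]})
        out = expressed_gene_overlap(a, b, omap, min_fraction=0.15)
        assert out == {"a_only": 1, "shared": 1, "b_only": 0}

    def test_identity_map_symmetry(self):
        rng = np.random.default_rng(0)
        vals = (rng.uniform(0, 1, size=(6, 30)) > 0.4) * 1.0
        genes = [f"g{i}" for i in range(6)]
        n = self._norm(vals, genes)
        omap = pd.DataFrame({"a": genes, "b": genes})
        out = expressed_gene_overlap(n, n, omap, min_fraction=0.15)
        assert out["a_only"] == 0 and out["b_only"] == 0

    def test_min_fraction_zero_means_any_expression(self):
        a = self._norm([[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]], ["a1"])
        b = self._norm([[0] * 10], ["b1"])
        omap = pd.DataFrame({"a": ["a1"], "b": ["b1"]})
        out = expressed_gene_overlap(a, b, omap, min_fraction=0.0)
        assert out == {"a_only": 1, "shared": 0, "b_only": 0}

    def test_non_one_to_one_rows_dropped(self, caplog):
        a = self._norm([[1, 1], [1, 1]], ["a1", "a2"])
        b = self._norm([[1, 1]], ["b1"])
        omap = pd.DataFrame({"a": ["a1", "a2"], "b": ["b1", "b1"]})
        with caplog.at_level("WARNING"):
            out = expressed_gene_overlap(a, b, omap)
        assert "non-1:1" in caplog.text
        assert out == {"a_only": 0, "shared": 0, "b_only": 0}

    def test_empty_map_rejected(self):
        a = self._norm([[1.0]], ["a1"])
        with pytest.raises(ValueError):
            expressed_gene_overlap(a, a, pd.DataFrame(columns=["a", "b"]))
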