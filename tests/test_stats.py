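"""Community statistics: aggregation, diversity, ordination and tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mcrapipe.config import TREATMENTS
from mcrapipe.stats import (
    aggregate_taxa,
    alpha_diversity,
    anova_tukey,
    braycurtis_matrix,
    compact_letters,
    cophenetic,
    diversity_table,
    group_means,
    heatmap_export,
    kruskal_bh,
    nmds,
    pairwise_wilcoxon_bh,
    pcoa,
    upgma_dendrogram,
)
from mcrapipe.tables import CLUSTER_TAXONOMY, TABLE1, table2_frame


class TestAggregateTaxa:
    def test_single_cluster_identity(self):
        frame = pd.DataFrame({"c1": [100.0, 100.0]}, index=["s1", "s2"])
        out = aggregate_taxa(frame, {"c1": ("F", "G", "c")}, "family")
        assert list(out.columns) == ["F"]
        assert (out["F"] == 100.0).all()

    def test_row_sums_preserved(self):
        rng = np.random.default_rng(0)
        raw = rng.random((6, 10))
        frame = pd.DataFrame(100 * raw / raw.sum(1, keepdims=True),
                             columns=[f"c{i}" for i in range(10)])
        taxonomy = {f"c{i}": ("F1" if i < 4 else "F2", None, None)
                    for i in range(10)}
        out = aggregate_taxa(frame, taxonomy, "family")
        assert np.allclose(out.sum(1), 100.0)

    def test_unlabelled_pool_into_unassigned(self):
        frame = pd.DataFrame({"c1": [60.0], "c2": [40.0]})
        out = aggregate_taxa(frame, {"c1": ("F", "G", None)}, "genus")
        assert out.loc[0, "G"] == 60.0
        assert out.loc[0, "unassigned"] == 40.0

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            aggregate_taxa(pd.DataFrame(), {}, "species")

    def test_published_cells_approximately(self):
        # column sums of the printed cluster table against the printed
        # family/genus table; printed rounding leaves up to ~0.2 slack
        agg = {}
        frame = table2_frame()
        for rank in ("family", "genus", "clade"):
            agg[rank] = aggregate_taxa(frame, CLUSTER_TAXONOMY, rank)
        for (rank, taxon), values in TABLE1.items():
            for t_index, treatment in enumerate(TREATMENTS):
                got = agg[rank].loc[treatment, taxon]
                assert got == pytest.approx(values[t_index], abs=0.25), \
                    (rank, taxon, treatment)


class TestAlphaDiversity:
    def test_degenerate_single_cluster(self):
        row = alpha_diversity([50, 0, 0])
        assert row.observed == 1
        assert row.shannon == pytest.approx(0.0)
        assert row.simpson == pytest.approx(0.0)

    def test_uniform_four_clusters(self):
        row = alpha_diversity([25, 25, 25, 25])
        assert row.shannon == pytest.approx(np.log(4))
        assert row.simpson == pytest.approx(0.75)

    def test_margalef_closed_form(self):
        row = alpha_diversity([96, 1, 1, 1, 1])  # S=5, N=100
        assert row.margalef == pytest.approx(4 / np.log(100))

    def test_margalef_undefined_for_tiny_n(self):
        assert np.isnan(alpha_diversity([1]).margalef)

    def test_matches_independent_formulas_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            counts = rng.integers(0, 50, size=12)
            if counts.sum() < 2:
                continue
            row = alpha_diversity(counts)
            p = counts[counts > 0] / counts.sum()
            assert row.shannon == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
            assert row.simpson == pytest.approx(1 - (p ** 2).sum(), abs=1e-12)
            assert row.margalef == pytest.approx(
                ((counts > 0).sum() - 1) / np.log(counts.sum()), abs=1e-12)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        frame = pd.DataFrame([[10.0, 5.0], [10.0, 5.0]], index=["a", "b"])
        assert braycurtis_matrix(frame).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        frame = pd.DataFrame([[10.0, 0.0], [0.0, 7.0]], index=["a", "b"])
        assert braycurtis_matrix(frame).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_sqrt_case(self):
        frame = pd.DataFrame([[4.0, 1.0], [1.0, 4.0]], index=["x", "y"])
        assert braycurtis_matrix(frame).loc["x", "y"] == pytest.approx(1 / 3)

    def test_two_zero_rows_rejected(self):
        frame = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]],
                             index=["z1", "z2", "ok"])
        with pytest.raises(ValueError, match="z1"):
            braycurtis_matrix(frame)


class TestPcoa:
    def test_collinear_points(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        coords, eigvals = pcoa(d)
        spacing = np.abs(np.diff(coords.iloc[:, 0]))
        assert spacing == pytest.approx([1.0, 1.0])
        assert eigvals[1] == pytest.approx(0.0, abs=1e-9)

    def test_identical_points_zero_eigenvalues(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        _, eigvals = pcoa(d)
        assert np.allclose(eigvals, 0.0)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(X)))
        coords, eigvals = pcoa(d)
        k = (eigvals > 1e-9).sum()
        rec = squareform(pdist(coords.to_numpy()[:, :k]))
        assert np.allclose(rec, d.to_numpy(), atol=1e-9)


class TestNmds:
    def test_embeddable_configuration_low_stress(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(X)))
        _, stress, _ = nmds(d, n_restarts=8, seed=4)
        assert stress < 0.01

    def test_two_points_zero_stress(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]])
        coords, stress, _ = nmds(d, seed=0)
        assert stress == 0.0
        assert coords.shape == (2, 2)

    def test_stress_monotone_within_run(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(X)))
        _, _, history = nmds(d, n_restarts=3, seed=6)
        assert all(history[i + 1] <= history[i] + 1e-12
                   for i in range(len(history) - 1))

    def test_excessive_dimension_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            nmds(d, k=2, seed=0)


class TestDendrogram:
    def test_tight_pairs_merge_first(self):
        d = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        Z, order = upgma_dendrogram(pd.DataFrame(d, index=list("abcd"),
                                                 columns=list("abcd")))
        first_two = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
        assert (np.diff(Z[:, 2]) >= 0).all()

    def test_ultrametric_recovered_exactly(self):
        # cophenetic distances of a UPGMA tree on ultrametric input equal it
        d = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ])
        frame = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        assert np.allclose(cophenetic(frame).to_numpy(), d)

    def test_two_samples_single_merge(self):
        frame = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["a", "b"],
                             columns=["a", "b"])
        Z, order = upgma_dendrogram(frame)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.3)


class TestHeatmap:
    def test_values_are_sqrt_and_zero_column_stays_zero(self):
        frame = pd.DataFrame(
            [[81.0, 19.0, 0.0], [64.0, 36.0, 0.0], [49.0, 51.0, 0.0],
             [25.0, 75.0, 0.0]],
            index=["s1", "s2", "s3", "s4"], columns=["c1", "c2", "c3"])
        grid = heatmap_export(frame)
        assert set(grid.columns) == {"c1", "c2", "c3"}
        assert (grid["c3"] == 0.0).all()
        for s in frame.index:
            for c in frame.columns:
                assert grid.loc[s, c] == pytest.approx(np.sqrt(frame.loc[s, c]))

    def test_row_order_matches_dendrogram(self):
        frame = pd.DataFrame(
            [[90.0, 10.0], [89.0, 11.0], [10.0, 90.0], [11.0, 89.0]],
            index=["r1", "r2", "x1", "x2"], columns=["c1", "c2"])
        grid = heatmap_export(frame)
        _, order = upgma_dendrogram(braycurtis_matrix(frame))
        assert list(grid.index) == order


class TestKruskalBH:
    def test_identical_groups_null(self):
        frame = pd.DataFrame({"c1": [5.0] * 8})
        treatments = {i: t for i, t in zip(frame.index, "RRAARRAA")}
        results = kruskal_bh(frame, treatments)
        assert results[0].statistic == 0.0
        assert results[0].p_raw == 1.0

    def test_bh_step_up_hand_oracle(self):
        # raw (0.01, 0.02, 0.03, 0.04), m=4 -> all adjusted to 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_fdr_controlled_under_global_null(self):
        rng = np.random.default_rng(7)
        n_reps, n_clusters = 300, 10
        false_hits = 0
        for rep in range(n_reps):
            frame = pd.DataFrame(rng.normal(size=(16, n_clusters)),
                                 columns=[f"c{i}" for i in range(n_clusters)])
            treatments = {i: t for i, t in
                          zip(frame.index, "RRRRAAAARARARARA")}
            results = kruskal_bh(frame, treatments)
            false_hits += sum(r.p_adjusted < 0.05 for r in results)
        rate = false_hits / (n_reps * n_clusters)
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (n_reps * n_clusters))

    def test_small_group_rejected(self):
        frame = pd.DataFrame({"c1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            kruskal_bh(frame, {0: "R", 1: "R", 2: "A"})


class TestWilcoxonLetters:
    def test_identical_groups_share_a_letter(self):
        frame = pd.DataFrame({"c1": [5.0, 5.1, 4.9, 5.0] * 4})
        treatments = {i: t for i, t in zip(frame.index,
                                           ["R"] * 4 + ["A"] * 4 + ["RA"] * 4
                                           + ["AA"] * 4)}
        _, letters = pairwise_wilcoxon_bh(frame, treatments)
        assert set(letters["c1"].values()) == {"a"}

    def test_separated_group_gets_distinct_letter(self):
        rng = np.random.default_rng(8)
        n = 13
        base = rng.normal(0, 1, size=3 * n)
        shifted = rng.normal(10, 1, size=n)  # 10 SDs away
        frame = pd.DataFrame({"c1": np.concatenate([base, shifted])})
        treatments = {i: t for i, t in zip(
            frame.index, ["R"] * n + ["A"] * n + ["RA"] * n + ["AA"] * n)}
        _, letters = pairwise_wilcoxon_bh(frame, treatments)
        others = {letters["c1"][g] for g in ("R", "A", "RA")}
        assert letters["c1"]["AA"] not in others

    def test_adjusted_monotone_in_raw(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(24, 5)),
                             columns=[f"c{i}" for i in range(5)])
        treatments = {i: ["R", "A", "RA", "AA"][i % 4] for i in frame.index}
        results, _ = pairwise_wilcoxon_bh(frame, treatments)
        ordered = sorted(results, key=lambda r: r.p_raw)
        for a, b in itertools.pairwise(ordered):
            assert a.p_adjusted <= b.p_adjusted + 1e-12
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert r.p_adjusted <= 1.0


class TestAnovaTukey:
    def test_two_groups_equal_t_test(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        table = pd.DataFrame({"shannon": np.concatenate([a, b])})
        treatments = {i: ("R" if i < 8 else "A") for i in table.index}
        results, _ = anova_tukey(table, treatments)
        omnibus = results[0]
        _, t_p = scipy.stats.ttest_ind(a, b)
        assert omnibus.p_raw == pytest.approx(t_p)

    def test_separated_group_distinct_letter(self):
        table = pd.DataFrame({"idx": [1, 2, 3, 1, 2, 3, 11, 12, 13]})
        treatments = {i: t for i, t in zip(table.index,
                                           ["R"] * 3 + ["A"] * 3 + ["RA"] * 3)}
        _, letters = anova_tukey(table, treatments)
        assert letters["idx"]["RA"] != letters["idx"]["R"]
        assert letters["idx"]["R"] == letters["idx"]["A"]

    def test_zero_variance_equal_means_reports_null(self):
        table = pd.DataFrame({"idx": [2.0] * 8})
        treatments = {i: ("R" if i < 4 else "A") for i in table.index}
        results, letters = anova_tukey(table, treatments)
        assert results[0].p_raw == 1.0
        assert set(letters["idx"].values()) == {"a"}

    def test_tukey_adjusted_not_below_pairwise_t(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"idx": rng.normal(size=16)})
        treatments = {i: ["R", "A", "RA", "AA"][i % 4] for i in table.index}
        results, _ = anova_tukey(table, treatments)
        groups = {}
        for i, t in treatments.items():
            groups.setdefault(t, []).append(table.loc[i, "idx"])
        for r in results[1:]:
            name = r.feature.split(":")[1]
            a, b = name.split("-")
            _, t_p = scipy.stats.ttest_ind(groups[a], groups[b])
            assert r.p_adjusted >= t_p - 1e-9


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        out = compact_letters(["R", "A"], set())
        assert out == {"R": "a", "A": "a"}

    def test_chain_structure(self):
        # a != c, but b overlaps both
        out = compact_letters(["a_grp", "b_grp", "c_grp"],
                              {("a_grp", "c_grp")})
        assert set(out["a_grp"]) & set(out["c_grp"]) == set()
        assert set(out["b_grp"]) & set(out["a_grp"])
        assert set(out["b_grp"]) & set(out["c_grp"])


def test_group_means_layout(study_panel, profiles):
    frame = pd.DataFrame(
        [[60.0, 40.0], [58.0, 42.0], [20.0, 80.0], [22.0, 78.0]],
        index=["r1", "r2", "a1", "a2"], columns=["c1", "c2"])
    out = group_means(frame, {"r1": "R", "r2": "R", "a1": "A", "a2": "A"})
    assert out.loc["R", "c1"] == pytest.approx(59.0)
    assert out.loc["A", "c2"] == pytest.approx(79.0)


def test_diversity_table_shape():
    counts = pd.DataFrame([[10, 5, 0], [3, 3, 3]], index=["s1", "s2"],
                          columns=["c1", "c2", "c3"])
    table = diversity_table(counts)
    assert list(table.columns) == ["observed", "margalef", "shannon", "simpson"]
    assert table.loc["s2", "shannon"] == pytest.approx(np.log(3))
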