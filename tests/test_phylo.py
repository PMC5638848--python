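"""Alignment, masking, Fitch parsimony, tree search, bootstrap and
taxonomy assignment."""

from __future__ import annotations

import numpy as np
import pytest

from mcrapipe.phylo import (
    MaskedAlignment,
    Tree,
    align_sequences,
    align_to_panel,
    assign_taxonomy,
    bootstrap_support,
    fitch_length,
    mask_columns,
    mp_search,
    parse_newick,
    strict_consensus,
)


def _aln(rows: dict[str, str]) -> MaskedAlignment:
    ncol = len(next(iter(rows.values())))
    return MaskedAlignment(list(rows), rows, list(range(ncol)))


def _tree(adj, n, names):
    return Tree({k: list(v) for k, v in adj.items()}, n, names)


class TestAlignment:
    def test_identical_sequences_gap_free(self):
        aln = align_sequences({f"s{i}": "MKTAYIAKQR" * 5 for i in range(4)})
        assert all("-" not in row for row in aln.rows.values())

    def test_insertion_makes_one_gap_block(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        longer = base[:15] + "WWW" + base[15:]
        aln = align_sequences({"a": base, "b": longer, "c": base})
        assert aln.n_columns == len(longer)
        for name in ("a", "c"):
            row = aln.rows[name]
            assert row.count("-") == 3
            gap_start = row.index("-")
            assert row[gap_start : gap_start + 3] == "---"

    def test_degapping_recovers_inputs(self, study_panel):
        panel, _, _ = study_panel
        seqs = {e.id: e.peptide for e in panel.entries[:8]}
        aln = align_sequences(seqs)
        for name, seq in seqs.items():
            assert aln.rows[name].replace("-", "") == seq

    def test_align_to_panel_guards(self, study_panel):
        panel, _, _ = study_panel
        with pytest.raises(ValueError, match="empty"):
            align_to_panel({"c": "MKT"}, [])
        with pytest.raises(ValueError, match="collides"):
            align_to_panel({panel.entries[0].id: "MKT"}, panel)


class TestMasking:
    def test_gap_free_keeps_all(self):
        aln = _aln({f"s{i}": "MKTAY" for i in range(4)})
        assert mask_columns(aln, 0.85).n_positions == 5

    def test_low_coverage_column_removed(self):
        rows = {f"s{i}": ("M-KT" if i < 2 else "MAKT") for i in range(10)}
        masked = mask_columns(_aln(rows), 0.85)  # column 1 coverage 0.8
        assert masked.kept_columns == [0, 2, 3]

    def test_157_position_construction(self, study_panel):
        panel, _, _ = study_panel
        aln = align_sequences({e.id: e.peptide for e in panel})
        masked = mask_columns(aln, 0.85)
        assert masked.n_positions == 157

    def test_all_masked_is_an_error(self):
        rows = {"a": "M---", "b": "-K--", "c": "--T-", "d": "---V"}
        with pytest.raises(ValueError, match="no informative"):
            mask_columns(_aln(rows), 0.85)


class TestFitch:
    def test_three_taxa_single_column(self):
        aln = _aln({"a": "A", "b": "A", "c": "C"})
        tree = _tree({3: [0, 1, 2], 0: [3], 1: [3], 2: [3]}, 3, aln.ids)
        assert fitch_length(tree, aln) == 1

    def test_four_taxa_topology_dependence(self):
        aln = _aln({"a": "A", "b": "A", "c": "C", "d": "C"})
        grouped = _tree({4: [0, 1, 5], 5: [2, 3, 4],
                         0: [4], 1: [4], 2: [5], 3: [5]}, 4, aln.ids)
        crossed = _tree({4: [0, 2, 5], 5: [1, 3, 4],
                         0: [4], 1: [5], 2: [4], 3: [5]}, 4, aln.ids)
        assert fitch_length(grouped, aln) == 1
        assert fitch_length(crossed, aln) == 2

    def test_invariant_column_zero_everywhere(self):
        aln = _aln({"a": "AA", "b": "AA", "c": "AA", "d": "AA"})
        grouped = _tree({4: [0, 1, 5], 5: [2, 3, 4],
                         0: [4], 1: [4], 2: [5], 3: [5]}, 4, aln.ids)
        assert fitch_length(grouped, aln) == 0

    def test_gaps_are_missing_data(self):
        aln = _aln({"a": "A", "b": "-", "c": "A", "d": "A"})
        grouped = _tree({4: [0, 1, 5], 5: [2, 3, 4],
                         0: [4], 1: [4], 2: [5], 3: [5]}, 4, aln.ids)
        assert fitch_length(grouped, aln) == 0

    def test_leaf_mismatch_rejected(self):
        aln = _aln({"a": "A", "b": "A", "c": "C"})
        bad = _tree({4: [0, 1, 5], 5: [2, 3, 4],
                     0: [4], 1: [4], 2: [5], 3: [5]}, 4,
                    ["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            fitch_length(bad, aln)


class TestSearch:
    def test_identical_sequences_length_zero(self):
        aln = _aln({f"s{i}": "MKTAY" for i in range(6)})
        trees, length = mp_search(aln, random_addition_reps=2, seed=0)
        assert length == 0

    def test_fewer_than_four_taxa_single_topology(self):
        aln = _aln({"a": "MKT", "b": "MKV", "c": "MRT"})
        trees, _ = mp_search(aln, seed=0)
        assert len(trees) == 1
        assert sorted(trees[0].leaves()) == [0, 1, 2]

    def test_recovers_generating_topology(self):
        # two blocks of diagnostic columns define ((a1,a2,a3),(b1,b2,b3),...)
        rows = {
            "a1": "AAAAAAAAAA" + "CCCCC",
            "a2": "AAAAAAAAAA" + "CCCCC",
            "a3": "AAAAAAAAAG" + "CCCCC",
            "b1": "TTTTTTTTTT" + "CCCCC",
            "b2": "TTTTTTTTTT" + "CCCCC",
            "b3": "TTTTTTTTTC" + "CCCCC",
            "c1": "GGGGGGGGGG" + "AAAAA",
        }
        trees, _ = mp_search(_aln(rows), random_addition_reps=4, seed=1)
        splits = trees[0].splits()
        names = trees[0].names
        group_a = frozenset(i for i, n in enumerate(names) if n.startswith("a"))
        group_b = frozenset(i for i, n in enumerate(names) if n.startswith("b"))
        as_canonical = lambda s: s if 0 not in s else frozenset(range(7)) - s
        assert as_canonical(group_a) in {as_canonical(s) for s in splits} or \
            as_canonical(group_b) in {as_canonical(s) for s in splits}

    def test_deterministic_given_seed(self, study_panel):
        panel, _, _ = study_panel
        aln = align_sequences({e.id: e.peptide for e in panel.entries[:10]})
        r1 = mp_search(aln, random_addition_reps=3, seed=5)
        r2 = mp_search(aln, random_addition_reps=3, seed=5)
        assert r1[1] == r2[1]
        assert r1[0][0].splits() == r2[0][0].splits()


class TestBootstrap:
    def test_strong_signal_central_split(self):
        rows = {
            "a1": "A" * 30, "a2": "A" * 30, "a3": "A" * 29 + "C", "a4": "A" * 30,
            "b1": "T" * 30, "b2": "T" * 30, "b3": "T" * 29 + "G", "b4": "T" * 30,
        }
        aln = _aln(rows)
        trees, _ = mp_search(aln, random_addition_reps=3, seed=2)
        st = bootstrap_support(aln, reps=50, seed=3, addition_reps=1,
                               best_trees=trees)
        names = st.tree.names
        group_a = frozenset(i for i, n in enumerate(names) if n.startswith("a"))
        canonical = group_a if 0 not in group_a else frozenset(range(8)) - group_a
        assert st.supports.get(canonical, 0.0) >= 99.0

    def test_supports_bounded_and_collapse_subset(self, study_panel):
        panel, _, _ = study_panel
        aln = align_sequences({e.id: e.peptide for e in panel.entries[:12]})
        trees, _ = mp_search(aln, random_addition_reps=2, seed=4)
        st = bootstrap_support(aln, reps=20, seed=5, addition_reps=1,
                               best_trees=trees)
        assert all(0.0 <= s <= 100.0 for s in st.supports.values())
        assert st.tree.splits() <= strict_consensus(trees).splits()
        assert set(st.tree.leaves()) == set(range(12))


class TestNewick:
    def test_round_trip_preserves_splits(self, study_panel):
        panel, _, _ = study_panel
        aln = align_sequences({e.id: e.peptide for e in panel.entries[:9]})
        trees, _ = mp_search(aln, random_addition_reps=2, seed=6)
        tree = trees[0]
        back = parse_newick(tree.newick(), tree.names)
        assert back.splits() == tree.splits()


class TestAssignTaxonomy:
    def _supported(self, adj, n, names):
        from mcrapipe.phylo import SupportedTree

        return SupportedTree(_tree(adj, n, names), {})

    def test_sister_to_single_reference(self):
        # query q sister to ref1; (q,ref1) | (ref2,ref3)
        names = ["ref2", "q", "ref1", "ref3"]
        st = self._supported({4: [0, 3, 5], 5: [1, 2, 4],
                              0: [4], 3: [4], 1: [5], 2: [5]}, 4, names)
        taxonomy = {"ref1": ("Methanobacteriaceae", "Methanobrevibacter",
                             "ruminantium"),
                    "ref2": ("Methanobacteriaceae", "Methanosphaera", "stadtmanae"),
                    "ref3": ("Methanobacteriaceae", "Methanosphaera", "stadtmanae")}
        out = assign_taxonomy(st, taxonomy)
        assert out["q"].family == "Methanobacteriaceae"
        assert out["q"].genus == "Methanobrevibacter"
        assert out["q"].clade == "ruminantium"

    def test_label_conflict_becomes_unassigned(self):
        # q in a collapsed polytomy mixing two clades of one genus
        names = ["out1", "q", "gott", "rum", "out2"]
        st = self._supported({5: [1, 2, 3, 6], 6: [0, 4, 5],
                              0: [6], 4: [6], 1: [5], 2: [5], 3: [5]}, 5, names)
        taxonomy = {"gott": ("Methanobacteriaceae", "Methanobrevibacter",
                             "gottschalkii"),
                    "rum": ("Methanobacteriaceae", "Methanobrevibacter",
                            "ruminantium"),
                    "out1": ("Methanomassiliicoccaceae", "Methanomassiliicoccus",
                             "mmc"),
                    "out2": ("Methanomassiliicoccaceae", "Methanomassiliicoccus",
                             "mmc")}
        out = assign_taxonomy(st, taxonomy)
        assert out["q"].genus == "Methanobrevibacter"
        assert out["q"].clade == "unassigned"

    def test_fully_collapsed_tree_falls_back_to_whole_panel(self):
        names = ["ref1", "q", "ref2"]
        st = self._supported({3: [0, 1, 2], 0: [3], 1: [3], 2: [3]}, 3, names)
        taxonomy = {"ref1": ("FamA", "GenA", "cl1"),
                    "ref2": ("FamA", "GenB", "cl2")}
        out = assign_taxonomy(st, taxonomy)
        assert out["q"].family == "FamA"
        assert out["q"].genus == "unassigned"
        assert out["q"].support == 0.0

    def test_no_panel_leaves_is_an_error(self):
        names = ["q1", "q2", "q3"]
        st = self._supported({3: [0, 1, 2], 0: [3], 1: [3], 2: [3]}, 3, names)
        with pytest.raises(ValueError, match="no panel"):
            assign_taxonomy(st, {})

    def test_full_recovery_on_study_panel(self, study_panel):
        panel, community, refs = study_panel
        aln = mask_columns(align_sequences({e.id: e.peptide for e in panel}))
        trees, _ = mp_search(aln, random_addition_reps=3, seed=9)
        st = bootstrap_support(aln, reps=30, seed=10, addition_reps=1,
                               best_trees=trees)
        taxonomy = {r: panel.get(r).taxonomy for r in refs}
        out = assign_taxonomy(st, taxonomy)
        correct = sum(
            (out[c].family, out[c].genus, out[c].clade) == panel.get(c).taxonomy
            for c in community)
        assert correct == len(community)
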