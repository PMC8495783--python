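"""Branch/clade matching across taxon-incomplete gene trees and metric
table assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchsel.codeml_io import BranchMetrics, ModelFit
from branchsel.extract import (
    BELOW_THRESHOLD,
    METRICS_MISSING,
    NOT_MONOPHYLETIC,
    SINGLE_SPECIES_CLADE,
    ExtractConfig,
    ExtractError,
    build_tables,
    enumerate_branch_species,
    match_definition,
    retrieve_metrics,
)
from branchsel.labeling import CladeDefinition
from branchsel.trees import parse_newick, prune_to_taxa, random_binary_tree


def brute_force_match(defn, gene_taxa, gene_tree, cfg):
    """Independent re-derivation: enumerate every edge by recursive subtree
    collection and test thresholds/set equality directly."""
    present = defn.species & gene_taxa
    need = (
        len(defn.species)
        if cfg.mode == "A"
        else (math.ceil(cfg.threshold * len(defn.species)) if cfg.threshold < 1 else int(cfg.threshold))
    )
    if len(present) < need:
        return False
    if len(present) == 1 and defn.token.startswith("$") and len(defn.species) > 1:
        return False

    def subtree_leaves(node):
        if node.is_leaf:
            return frozenset([node.name])
        out = frozenset()
        for c in node.children:
            out |= subtree_leaves(c)
        return out

    edges = []
    for node in gene_tree.preorder():
        for child in node.children:
            edges.append(subtree_leaves(child))
    return present in edges


class TestEnumerate:
    def test_quartet_edges(self, quartet_tree):
        keys = set(enumerate_branch_species(quartet_tree))
        assert keys == {
            frozenset({x}) for x in "ABCD"
        } | {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_star_tree_only_singletons(self):
        keys = set(enumerate_branch_species(parse_newick("(A,B,C);")))
        assert keys == {frozenset({x}) for x in "ABC"}

    def test_matches_bruteforce_traversal(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            tree = random_binary_tree([f"t{i}" for i in range(n)], rng)
            keys = set(enumerate_branch_species(tree))

            def collect(node):
                if node.is_leaf:
                    return frozenset([node.name])
                return frozenset().union(*(collect(c) for c in node.children))

            brute = {collect(c) for nd in tree.preorder() for c in nd.children}
            assert keys == brute


DEFN_CDE = CladeDefinition("x", "$1", frozenset({"C", "D", "E"}))


class TestMatchDefinition:
    def test_mode_a_complete_clade(self):
        tree = parse_newick("(A,((C,D),E));")
        res = match_definition(DEFN_CDE, frozenset("ACDE"), tree, ExtractConfig(mode="A"))
        assert res.matched and res.matched_leaf_set == {"C", "D", "E"}

    def test_mode_a_internal_missing_species_unmatched(self):
        tree = parse_newick("((A,B),(C,E));")
        res = match_definition(DEFN_CDE, frozenset("ABCE"), tree, ExtractConfig(mode="A"))
        assert not res.matched and res.reason == BELOW_THRESHOLD

    def test_mode_b_threshold_admits_partial_clade(self):
        tree = parse_newick("((A,B),(C,E));")
        cfg = ExtractConfig(mode="B", threshold=0.6)
        res = match_definition(DEFN_CDE, frozenset("ABCE"), tree, cfg)
        # |P| = 2 >= ceil(0.6 * 3) = 2 and {C,E} is an edge
        assert res.matched and res.matched_leaf_set == {"C", "E"}

    def test_proportion_0_8_of_ten_species_needs_eight(self):
        species = frozenset(f"s{i}" for i in range(10))
        defn = CladeDefinition("big", "$1", species)
        cfg = ExtractConfig(mode="B", threshold=0.8)
        assert cfg.min_present(10) == 8
        rng = np.random.default_rng(0)
        for n_present in (8, 7):
            present = sorted(species)[:n_present]
            tree = random_binary_tree(present, rng)
            glued = parse_newick(
                f"({_newick_of(tree)[:-1]}:0.1,(o1:0.1,o2:0.1):0.1);"
            )
            res = match_definition(defn, glued.leaf_names, glued, cfg)
            assert res.matched == (n_present >= 8)
            if not res.matched:
                assert res.reason == BELOW_THRESHOLD

    def test_non_monophyletic_present_species(self):
        tree = parse_newick("((C,A),(D,E));")
        res = match_definition(DEFN_CDE, frozenset("ACDE"), tree, ExtractConfig(mode="A"))
        assert not res.matched and res.reason == NOT_MONOPHYLETIC

    def test_clade_reduced_to_single_species(self):
        tree = parse_newick("((A,B),(C,F));")
        cfg = ExtractConfig(mode="B", threshold=1)
        res = match_definition(DEFN_CDE, frozenset("ABCF"), tree, cfg)
        assert not res.matched and res.reason == SINGLE_SPECIES_CLADE
        # a branch (#) definition still matches the terminal branch
        branch_defn = CladeDefinition("x", "#1", frozenset({"C", "D", "E"}))
        res2 = match_definition(branch_defn, frozenset("ABCF"), tree, cfg)
        assert res2.matched and res2.matched_leaf_set == {"C"}

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_agreement_on_random_subsets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        taxa = [f"t{i}" for i in range(n)]
        tree = random_binary_tree(taxa, rng)
        defn_size = int(rng.integers(2, n))
        defn = CladeDefinition(
            "d", rng.choice(["#1", "$1"]), frozenset(rng.choice(taxa, defn_size, replace=False))
        )
        for _ in range(10):
            k = int(rng.integers(2, n + 1))
            keep = frozenset(rng.choice(taxa, k, replace=False))
            gene_tree = prune_to_taxa(tree, keep)
            for cfg in (
                ExtractConfig(mode="A"),
                ExtractConfig(mode="B", threshold=float(rng.uniform(0.3, 0.99))),
                ExtractConfig(mode="B", threshold=int(rng.integers(1, defn_size + 1))),
            ):
                got = match_definition(defn, keep, gene_tree, cfg)
                assert got.matched == brute_force_match(defn, keep, gene_tree, cfg)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        """Lowering the mode-B threshold never unmatches a matched gene."""
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(7)]
        tree = random_binary_tree(taxa, rng)
        defn = CladeDefinition("d", "$1", frozenset(taxa[:4]))
        keep = frozenset(rng.choice(taxa, int(rng.integers(2, 8)), replace=False))
        gene_tree = prune_to_taxa(tree, keep)
        matched = [
            match_definition(defn, keep, gene_tree, ExtractConfig(mode="B", threshold=th)).matched
            for th in (0.95, 0.75, 0.5, 0.3)
        ]
        assert matched == sorted(matched)  # once matched, stays matched

    def test_mode_a_equals_full_absolute_threshold(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(taxa, rng)
        defn = CladeDefinition("d", "$1", frozenset(taxa[:4]))
        for _ in range(30):
            keep = frozenset(rng.choice(taxa, int(rng.integers(2, 9)), replace=False))
            gene_tree = prune_to_taxa(tree, keep)
            a = match_definition(defn, keep, gene_tree, ExtractConfig(mode="A"))
            b = match_definition(
                defn, keep, gene_tree, ExtractConfig(mode="B", threshold=len(defn.species))
            )
            assert a.matched == b.matched

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_prune_preserves_monophyly(self, seed):
        """A clade monophyletic on the species tree stays monophyletic in
        any pruned gene tree that retains >= 2 of its species."""
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(taxa, rng)
        sets = tree.descendant_leaf_sets()
        clades = [s for s in sets.values() if 2 <= len(s) <= 6]
        clade = clades[int(rng.integers(len(clades)))]
        keep = frozenset(rng.choice(taxa, int(rng.integers(3, 9)), replace=False))
        present = clade & keep
        if len(keep) < 2 or len(present) < 2:
            return
        gene_tree = prune_to_taxa(tree, keep)
        if present == keep:
            # the clade is the whole gene tree: trivially monophyletic but
            # no stem edge exists to attribute metrics to
            assert present == gene_tree.leaf_names
        else:
            assert present in set(enumerate_branch_species(gene_tree))


def _newick_of(tree):
    from branchsel.trees import write_newick

    return write_newick(tree, include_lengths=False)


def toy_fit(gene="g", keys=(("C",), ("D",), ("E",), ("C", "D"), ("C", "D", "E"))):
    metrics = [
        BranchMetrics(leaf_set=frozenset(k), t=0.1, dnds=0.2 + 0.1 * i, dn=0.01 * (i + 1), ds=0.05)
        for i, k in enumerate(keys)
    ]
    return ModelFit(gene_id=gene, model_tag="alternative", lnl=-10.0, np=2, branch_metrics=metrics)


class TestRetrieveMetrics:
    def test_branch_definition_single_stem_row(self):
        tree = parse_newick("(A,((C,D),E));")
        defn = CladeDefinition("x", "#1", frozenset({"C", "D"}))
        match = match_definition(defn, tree.leaf_names, tree, ExtractConfig(mode="A"))
        rows, reason = retrieve_metrics(match, defn, toy_fit())
        assert reason is None
        assert len(rows) == 1 and rows[0].branch == "C,D"

    def test_clade_definition_subset_rows_plus_mean(self):
        tree = parse_newick("(A,((C,D),E));")
        match = match_definition(DEFN_CDE, tree.leaf_names, tree, ExtractConfig(mode="A"))
        rows, reason = retrieve_metrics(match, DEFN_CDE, toy_fit())
        assert reason is None
        branches = [r.branch for r in rows]
        assert branches == ["C", "C,D", "C,D,E", "D", "E", "clade-mean"]
        mean_row = rows[-1]
        assert mean_row.derived
        assert mean_row.dnds == pytest.approx(np.mean([r.dnds for r in rows[:-1]]))

    def test_empty_branch_metrics_reported_missing(self):
        tree = parse_newick("(A,((C,D),E));")
        match = match_definition(DEFN_CDE, tree.leaf_names, tree, ExtractConfig(mode="A"))
        fit = ModelFit(gene_id="g", model_tag="alternative", lnl=-1.0, np=2, branch_metrics=[])
        rows, reason = retrieve_metrics(match, DEFN_CDE, fit)
        assert rows == [] and reason == METRICS_MISSING


class TestBuildTables:
    def test_coverage_counts_unmatched(self):
        full = parse_newick("(A,((C,D),E));")
        reduced = parse_newick("((A,C),E);")
        genes = {
            "g1": (full, toy_fit("g1")),
            "g2": (reduced, toy_fit("g2", keys=(("C",), ("E",)))),
            "g3": (reduced, toy_fit("g3", keys=(("C",), ("E",)))),
        }
        tables, coverage = build_tables(genes, [DEFN_CDE], ExtractConfig(mode="A"))
        assert set(tables["x"].to_dataframe()["gene_id"]) == {"g1"}
        unmatched = coverage[~coverage["matched"]]
        assert len(unmatched) == 2
        assert set(unmatched["reason"]) == {BELOW_THRESHOLD}

    def test_empty_definitions_fatal(self):
        full = parse_newick("(A,((C,D),E));")
        with pytest.raises(ExtractError):
            build_tables({"g": (full, toy_fit())}, [], ExtractConfig(mode="A"))
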