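"""Bipartition concordance scoring against a reference tree."""

import itertools

import numpy as np
import pytest

from mitoconcord.concordance import (CONCORDANT, CONFLICTING, UNINFORMATIVE,
                                     bipartitions, concordance_table,
                                     score_node)
from mitoconcord.tree import Tree

from conftest import random_resolved_tree, small_tree


def _set_supports(tree: Tree, value: float) -> Tree:
    t = tree.copy()
    for n in t.postorder():
        if n.parent is not None and not n.is_leaf:
            n.support = value
    return t


class TestBipartitions:
    def test_four_tip_tree_has_one_nontrivial_split(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        bips = bipartitions(t, min_support=0)
        assert bips == {frozenset({"a", "b"})} or bips == {frozenset({"c", "d"})}
        assert len(bips) == 1

    def test_threshold_filters_low_support(self):
        t = Tree.from_newick("((a:1,b:1)40:1,(c:1,d:1):1);")
        assert bipartitions(t, min_support=50) == set()
        assert len(bipartitions(t, min_support=0)) == 1

    def test_absent_support_passes_only_at_zero(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert len(bipartitions(t, min_support=0)) == 1
        assert bipartitions(t, min_support=50) == set()

    def test_fully_resolved_23_tip_tree_has_20_splits(self, default_cfg):
        assert len(bipartitions(default_cfg.tree.unroot())) == 20  # n - 3


class TestScoreNode:
    def test_identical_tree_concordant_everywhere(self):
        ref = Tree.from_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1);")
        gene = _set_supports(ref, 100.0)
        for bip in bipartitions(ref):
            assert score_node(bip, gene, min_support=50) == CONCORDANT

    def test_alternative_quartet_resolution_conflicts(self):
        ref = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        gene = _set_supports(Tree.from_newick("((a:1,c:1):1,(b:1,d:1):1);"), 90.0)
        (bip,) = bipartitions(ref)
        assert score_node(bip, gene, min_support=50) == CONFLICTING

    def test_subthreshold_resolution_is_uninformative(self):
        ref = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        gene = _set_supports(Tree.from_newick("((a:1,c:1):1,(b:1,d:1):1);"), 30.0)
        (bip,) = bipartitions(ref)
        assert score_node(bip, gene, min_support=50) == UNINFORMATIVE

    def test_exhaustive_five_taxon_partition_of_unity(self):
        """Over all 15 resolved 5-taxon topologies, every reference split
        gets exactly one of the three labels."""
        names = list("abcde")
        topologies, seen = [], set()
        for pair in itertools.combinations(names, 2):
            rest = [n for n in names if n not in pair]
            for pair2 in itertools.combinations(rest, 2):
                last = [n for n in rest if n not in pair2][0]
                key = frozenset({frozenset(pair), frozenset(pair2)})
                if key in seen:
                    continue
                seen.add(key)
                nwk = (f"(({pair[0]}:1,{pair[1]}:1):1,"
                       f"({pair2[0]}:1,{pair2[1]}:1):1,{last}:1);")
                topologies.append(Tree.from_newick(nwk))
        assert len(topologies) == 15
        ref = topologies[0]
        for bip in bipartitions(ref):
            labels = [score_node(bip, g, min_support=0) for g in topologies]
            assert all(l in (CONCORDANT, CONFLICTING, UNINFORMATIVE)
                       for l in labels)
            # a fully resolved 5-taxon gene tree is never uninformative at 0%
            assert UNINFORMATIVE not in labels
            assert labels.count(CONCORDANT) >= 1

    def test_agrees_with_bruteforce_compatibility(self):
        rng = np.random.default_rng(8)
        names = [f"t{i}" for i in range(8)]
        tip_set = frozenset(names)
        for _ in range(15):
            ref = random_resolved_tree(names, rng)
            gene = random_resolved_tree(names, rng)
            gene_bips = bipartitions(gene)
            for bip in bipartitions(ref):
                got = score_node(bip, gene, min_support=0)
                other = tip_set - bip
                if any(bip == g or bip == tip_set - g for g in gene_bips):
                    expect = CONCORDANT
                else:
                    conflict = False
                    for g in gene_bips:
                        g2 = tip_set - g
                        if (bip & g) and (bip & g2) and (other & g) and (other & g2):
                            conflict = True
                    expect = CONFLICTING if conflict else UNINFORMATIVE
                assert got == expect


class TestConcordanceTable:
    def _ref_and_genes(self, n_species=4):
        tree, species_map, og = small_tree(n_species)
        genes = [_set_supports(tree, 100.0) for _ in range(6)]
        return tree, genes, species_map, og

    def test_reference_copies_all_concordant(self):
        ref, genes, _, og = self._ref_and_genes()
        table = concordance_table(ref, genes, min_support=0, outgroup=og)
        for row in table.rows:
            assert row[CONCORDANT] == 6
            assert row[CONFLICTING] == row[UNINFORMATIVE] == 0

    def test_counts_sum_to_n_genes_everywhere(self):
        rng = np.random.default_rng(4)
        names = [f"t{i}" for i in range(8)]
        ref = random_resolved_tree(names, rng)
        genes = [_set_supports(random_resolved_tree(names, rng),
                               float(rng.integers(0, 101))) for _ in range(9)]
        for thr in (0, 50):
            table = concordance_table(ref, genes, min_support=thr,
                                      outgroup=names[0])
            for row in table.rows:
                assert (row[CONCORDANT] + row[CONFLICTING]
                        + row[UNINFORMATIVE]) == 9

    def test_raising_threshold_never_raises_concordance(self):
        rng = np.random.default_rng(5)
        names = [f"t{i}" for i in range(8)]
        ref = random_resolved_tree(names, rng)
        genes = []
        for _ in range(8):
            g = random_resolved_tree(names, rng)
            for n in g.postorder():
                if n.parent is not None and not n.is_leaf:
                    n.support = float(rng.integers(0, 101))
            genes.append(g)
        t0 = concordance_table(ref, genes, min_support=0, outgroup=names[0])
        t50 = concordance_table(ref, genes, min_support=50, outgroup=names[0])
        for r0, r50 in zip(t0.rows, t50.rows):
            assert r50[CONCORDANT] <= r0[CONCORDANT]
            assert r50[CONFLICTING] <= r0[CONFLICTING]

    def test_species_collapsing_gives_species_level_nodes(self, default_cfg):
        ref = default_cfg.tree
        genes = [_set_supports(ref, 100.0) for _ in range(3)]
        table = concordance_table(ref, genes, min_support=0,
                                  outgroup=default_cfg.outgroup,
                                  species_map=default_cfg.species_map)
        assert len(table.rows) == 10  # 11 ingroup species + outgroup, rooted
        for row in table.rows:
            assert row[CONCORDANT] == 3

    def test_tip_set_mismatch_rejected(self):
        ref = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        gene = Tree.from_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(ValueError):
            concordance_table(ref, [gene], min_support=0)

    def test_nonmonophyletic_species_cannot_support_species_splits(self):
        tree, species_map, og = small_tree(4)
        # break monophyly of sp01 and sp03 by exchanging one individual
        gene = tree.copy()
        tips = {t.name: t for t in gene.tips()}
        tips["sp01_i2"].name, tips["sp03_i1"].name = "sp03_i1", "sp01_i2"
        gene = _set_supports(gene, 100.0)
        table = concordance_table(tree, [gene], min_support=0, outgroup=og,
                                  species_map=species_map)
        rows = {frozenset(r["clade"]): r for r in table.rows}
        # gene-tree splits now straddle sp01/sp03, so the sp01+sp02 node
        # cannot be matched by any mappable bipartition
        assert rows[frozenset({"sp01", "sp02"})][CONCORDANT] == 0
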