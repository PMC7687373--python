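"""Tree inference: NJ, ML search, bootstrap, constrained-topology ΔML."""

import numpy as np
import pytest

from mitoconcord.genestats import DistanceMatrix, p_distance_matrix
from mitoconcord.likelihood import LikelihoodEngine
from mitoconcord.ml import (bootstrap_support, delta_ml, ml_search, nj_tree,
                            optimize_branch_lengths, optimize_on_topology,
                            _initial_params)
from mitoconcord.msa import GeneAlignment, align_gene_set
from mitoconcord.simulate import SimConfig, SimElement, simulate_gene
from mitoconcord.substmodel import GTRGammaParams
from mitoconcord.tree import Tree

from conftest import small_tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_recovers_additive_five_taxon_tree(self):
        # hand-built additive matrix from ((a:2,b:3):1,(c:4,d:5):2,e:6)
        truth = Tree.from_newick("((a:2,b:3):1,(c:4,d:5):2,e:6);")
        ids = ["a", "b", "c", "d", "e"]
        paths = {
            ("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 10, ("a", "e"): 9,
            ("b", "c"): 10, ("b", "d"): 11, ("b", "e"): 10,
            ("c", "d"): 9, ("c", "e"): 12, ("d", "e"): 13,
        }
        m = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(ids, m))
        assert tree.rf_distance(truth) == 0
        # additive matrices are recovered with exact branch lengths
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 2, "b": 3, "c": 4, "d": 5, "e": 6})

    def test_all_equal_distances_resolved_with_zero_internals(self):
        ids = list("abcd")
        m = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(ids, m))
        assert sorted(tree.tip_names()) == ids
        internals = [n.length for n in tree.postorder()
                     if n.parent is not None and not n.is_leaf]
        assert all(l == pytest.approx(0.0, abs=1e-12) for l in internals)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.05, 0.4, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = DistanceMatrix([f"s{i}" for i in range(6)], m)
        assert nj_tree(d).to_newick() == nj_tree(d).to_newick()


class TestMLSearch:
    def test_identical_sequences_degenerate_likelihood(self):
        rows = ["ACGTACGTAC"] * 4
        aln = GeneAlignment("x", list("abcd"), rows)
        res = ml_search(aln, seed=0)
        freqs = np.array([rows[0].count(b) for b in "ACGT"]) / 10
        expected = 10 * np.sum(freqs * np.log(freqs))
        assert res.log_likelihood == pytest.approx(expected, abs=1e-4)
        assert res.tree.total_length() == pytest.approx(0.0, abs=1e-5)

    def test_recovers_simulated_topology(self):
        tree, _, _ = small_tree(2)  # 5 tips
        cfg = SimConfig(
            tree=tree,
            gene_table=[SimElement("g", "spacer", 8000, 1.0)],
            params=GTRGammaParams(
                np.array([1.0, 6.0, 1.0, 1.0, 10.0, 1.0]),
                np.array([.3, .3, .15, .25]), alpha=0.5, n_categories=4),
            seed=5, indel_rate=0.0)
        aln = GeneAlignment("g", list(simulate_gene(cfg, "g")),
                            list(simulate_gene(cfg, "g").values()))
        res = ml_search(aln, seed=0)
        assert res.tree.rf_distance(tree) == 0

    def test_final_ll_beats_optimized_nj_start(self, small_cfg):
        seqs = simulate_gene(small_cfg, "ND2")
        aln = align_gene_set(seqs, element="ND2")
        nj = nj_tree(p_distance_matrix(aln)).unroot()
        engine = LikelihoodEngine(aln, _initial_params(aln))
        nj_ll = optimize_branch_lengths(engine, nj)
        res = ml_search(aln, seed=0)
        assert res.log_likelihood >= nj_ll - 1e-6

    def test_parameter_recovery_on_long_alignments(self):
        """α and base frequencies recovered within 20% on 10 kb simulated
        data, across seeds."""
        tree, _, _ = small_tree(3, cherry=0.02, stem=0.05, step=0.04)
        true = GTRGammaParams(np.array([1.0, 4.0, 1.0, 1.0, 8.0, 1.0]),
                              np.array([.3, .3, .15, .25]),
                              alpha=0.5, n_categories=4)
        alpha_err, freq_err = [], []
        for seed in range(10):
            cfg = SimConfig(tree=tree,
                            gene_table=[SimElement("g", "spacer", 10000, 1.0)],
                            params=true, seed=seed, indel_rate=0.0)
            seqs = simulate_gene(cfg, "g")
            aln = GeneAlignment("g", list(seqs), list(seqs.values()))
            fit = optimize_on_topology(aln, tree)
            alpha_err.append(fit.params.alpha / true.alpha - 1)
            freq_err.append(np.max(np.abs(
                fit.params.base_freqs / true.base_freqs - 1)))
        assert np.mean(np.abs(alpha_err)) < 0.2
        assert np.mean(freq_err) < 0.2


class TestDeltaML:
    def test_zero_when_constraint_is_free_optimum(self, small_cfg):
        seqs = simulate_gene(small_cfg, "CytB")
        aln = align_gene_set(seqs, element="CytB")
        free = ml_search(aln, seed=0)
        d = delta_ml(aln, free.tree, free=free)
        assert abs(d) < 1e-3

    def test_positive_for_wrong_constraint(self, small_cfg):
        seqs = simulate_gene(small_cfg, "CytB")
        aln = align_gene_set(seqs, element="CytB")
        free = ml_search(aln, seed=0)
        # constrain to a deliberately wrong resolution: swap two tips
        wrong = free.tree.copy()
        tips = wrong.tips()
        tips[0].name, tips[-1].name = tips[-1].name, tips[0].name
        d = delta_ml(aln, wrong, free=free)
        assert d > 1.0

    def test_tip_mismatch_rejected(self, small_cfg):
        seqs = simulate_gene(small_cfg, "CytB")
        aln = align_gene_set(seqs, element="CytB")
        with pytest.raises(ValueError):
            delta_ml(aln, Tree.from_newick("(a:1,b:1,c:1);"))


class TestBootstrap:
    def _strong_signal_alignment(self):
        tree, _, _ = small_tree(3, cherry=0.03, stem=0.08, step=0.06)
        cfg = SimConfig(tree=tree,
                        gene_table=[SimElement("g", "spacer", 4000, 1.0)],
                        params=GTRGammaParams(
                            np.array([1.0, 6.0, 1.0, 1.0, 10.0, 1.0]),
                            np.array([.3, .3, .15, .25]),
                            alpha=0.5, n_categories=4),
                        seed=2, indel_rate=0.0)
        seqs = simulate_gene(cfg, "g")
        return GeneAlignment("g", list(seqs), list(seqs.values())), tree

    def test_clean_signal_gives_full_support(self):
        aln, truth = self._strong_signal_alignment()
        res = bootstrap_support(aln, n_reps=30, seed=0)
        assert res.tree.rf_distance(truth) == 0
        supports = [n.support for n in res.tree.postorder()
                    if n.parent is not None and not n.is_leaf
                    and n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_bounded_and_reproducible(self):
        aln, _ = self._strong_signal_alignment()
        r1 = bootstrap_support(aln, n_reps=10, seed=42)
        r2 = bootstrap_support(aln, n_reps=10, seed=42)
        assert r1.tree.to_newick() == r2.tree.to_newick()
        for n in r1.tree.postorder():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0

    def test_identical_sequences_give_degenerate_replicates(self):
        # site resampling of an invariant alignment reproduces the same
        # data every replicate, so supports are trivially maximal and equal
        rows = ["ACGTACGTACGTACGTACGT"] * 5
        aln = GeneAlignment("x", [f"s{i}" for i in range(5)], rows)
        res = bootstrap_support(aln, n_reps=10, seed=1)
        supports = {n.support for n in res.tree.postorder()
                    if n.parent is not None and not n.is_leaf
                    and n.support is not None}
        assert len(supports) <= 1

    def test_no_signal_gives_weak_support(self):
        # iid random sites carry no tree signal; replicates wander, so no
        # edge of the point-estimate tree should look strongly supported
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(6)]
        aln = GeneAlignment("x", [f"s{i}" for i in range(6)], rows)
        res = bootstrap_support(aln, n_reps=25, seed=1)
        supports = [n.support for n in res.tree.postorder()
                    if n.parent is not None and not n.is_leaf
                    and n.support is not None]
        assert np.mean(supports) <= 85.0
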