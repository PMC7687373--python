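"""Per-gene statistics: identity, distances, translation, regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoconcord.genestats import (DistanceMatrix, GeneStats,
                                   conservation_regression,
                                   mean_pairwise_identity, p_distance_matrix,
                                   percent_identical_columns, relative_rate,
                                   subs_per_site, translate,
                                   variable_residue_count)
from mitoconcord.msa import GeneAlignment
from mitoconcord.simulate import SimConfig, SimElement, simulate_gene
from mitoconcord.substmodel import GTRGammaParams
from mitoconcord.tree import Node, Tree


def _aln(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return GeneAlignment("g", ids, rows)


class TestIdentityStats:
    def test_identical_rows_are_100(self):
        assert percent_identical_columns(_aln(["AAA", "AAA"])) == 100.0
        assert mean_pairwise_identity(_aln(["AAA", "AAA"])) == 100.0

    def test_one_variable_column(self):
        assert percent_identical_columns(_aln(["AAT", "AAA"])) == pytest.approx(200 / 3)

    def test_pairwise_identity_skips_gaps_and_n(self):
        assert mean_pairwise_identity(_aln(["ACGT", "ACGA"])) == 75.0
        assert mean_pairwise_identity(_aln(["ACG-", "ACGA"])) == 100.0
        assert mean_pairwise_identity(_aln(["ACGN", "ACGA"])) == 100.0

    def test_column_with_gap_never_identical(self):
        assert percent_identical_columns(_aln(["AC-T", "AC-T"])) == 75.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            percent_identical_columns(_aln(["AAA", "AAA"]), ids=[])

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.text(alphabet="ACGT-N", min_size=10, max_size=10),
                    min_size=2, max_size=5))
    def test_identical_never_exceeds_pairwise(self, rows):
        aln = _aln(rows)
        try:
            pid = mean_pairwise_identity(aln)
        except Exception:
            return
        assert percent_identical_columns(aln) <= pid + 1e-9


class TestPDistance:
    def test_zero_for_identical(self):
        d = p_distance_matrix(_aln(["AAAA", "AAAA"]))
        assert np.all(d.matrix == 0)

    def test_quarter_for_one_of_four(self):
        d = p_distance_matrix(_aln(["ACGT", "ACGA"]))
        assert d.matrix[0, 1] == 0.25

    def test_matches_jc_expectation_on_simulation(self):
        # two taxa at divergence t under the JC limit of the simulator
        t = 0.1
        root = Node()
        root.add(Node("a", t / 2))
        root.add(Node("b", t / 2))
        cfg = SimConfig(
            tree=Tree(root),
            gene_table=[SimElement("g", "spacer", 30000, 1.0)],
            params=GTRGammaParams.jc(n_categories=1), seed=3, indel_rate=0.0)
        seqs = simulate_gene(cfg, "g")
        d = p_distance_matrix(_aln([seqs["a"], seqs["b"]]))
        expected = 0.75 * (1 - np.exp(-4 * t / 3))
        assert d.matrix[0, 1] == pytest.approx(expected, abs=0.006)

    def test_metric_on_gap_free_alignments(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
            m = p_distance_matrix(_aln(rows)).matrix
            assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)
            assert m[0, 2] <= m[0, 1] + m[1, 2] + 1e-12

    def test_jc_correction_flag(self):
        d = p_distance_matrix(_aln(["ACGT" * 5, "ACGA" * 5]), correction="jc")
        p = 0.25
        assert d.matrix[0, 1] == pytest.approx(-0.75 * np.log(1 - 4 * p / 3))


class TestTranslate:
    def test_tga_is_tryptophan_in_vertebrate_mito(self):
        assert translate("ATGTGA") == "MW"

    def test_aga_is_stop_in_vertebrate_mito(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate("ATGAGAAAA")

    def test_terminal_stop_and_partial_codon_dropped(self):
        assert translate("ATGTAA") == "M"
        assert translate("ATGGC") == "M"

    def test_standard_code_differs(self):
        assert translate("ATGTGG", code_id=1) == "MW"
        with pytest.raises(ValueError):
            translate("ATGTGATTT", code_id=1)  # TGA is a stop in code 1


class TestVariableResidues:
    def test_identical_rows_have_none_variable(self):
        aln = _aln(["ATGGCCTAA", "ATGGCCTAA"])
        assert variable_residue_count(aln) == (0, 2)

    def test_single_nonsynonymous_change(self):
        aln = _aln(["ATGGCCTAA", "ATGACCTAA"])  # GCC(A) -> ACC(T)
        assert variable_residue_count(aln) == (1, 2)

    def test_synonymous_change_not_variable(self):
        aln = _aln(["ATGGCCTAA", "ATGGCATAA"])  # GCC/GCA both Ala
        assert variable_residue_count(aln) == (0, 2)

    def test_internal_stop_names_offending_row(self):
        aln = _aln(["ATGAGATAA", "ATGGCCTAA"], ids=["bad", "good"])
        with pytest.raises(ValueError, match="bad"):
            variable_residue_count(aln)


class TestRelativeRate:
    def _toy(self, scale=1.0, n=5, seed=0):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.01, 0.2, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        return DistanceMatrix(ids, m), DistanceMatrix(ids, m * scale)

    def test_self_regression_is_exactly_one(self):
        ref, _ = self._toy()
        slope, r2 = relative_rate(ref, ref)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_exact_doubling(self):
        ref, double = self._toy(scale=2.0)
        slope, r2 = relative_rate(double, ref)
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_zero_reference_variance_rejected(self):
        ids = ["a", "b", "c"]
        flat = DistanceMatrix(ids, np.array([[0, .1, .1], [.1, 0, .1], [.1, .1, 0]]))
        gene = self._toy(n=3)[0]
        with pytest.raises(ValueError):
            relative_rate(gene, flat)


class TestConservationRegression:
    def test_collinear_inputs_give_r2_one(self):
        stats = [GeneStats(f"g{i}", 100, 60.0 + i, 90.0,
                           var_residues=(10 - i, 100)) for i in range(5)]
        slope, r2, p = conservation_regression(stats)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_null_slope_pvalues_are_uniform(self):
        """Monte-Carlo null: with no true association the slope p-value is
        Uniform(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            stats = [GeneStats(f"g{i}", 100,
                               float(rng.uniform(60, 90)), 90.0,
                               var_residues=(int(rng.integers(5, 50)), 100))
                     for i in range(10)]
            pvals.append(conservation_regression(stats)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSubsPerSite:
    def test_star_tree_zero(self):
        root = Node()
        for n in "abc":
            root.add(Node(n, 0.0))
        assert subs_per_site(Tree(root)) == 0.0

    def test_three_taxon_sum(self):
        root = Node()
        for n, l in zip("abc", (0.1, 0.2, 0.3)):
            root.add(Node(n, l))
        assert subs_per_site(Tree(root)) == pytest.approx(0.6)
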