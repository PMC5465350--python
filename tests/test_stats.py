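import numpy as np
import pandas as pd
import pytest

from shapealign.alignment import AlignmentConfig
from shapealign.intervals import Site
from shapealign.stats import (
    assign_genes,
    association_enrichment,
    benjamini_hochberg,
    compare_class_averages,
    compare_score_distributions,
    fisher_exact_2x2,
)

from naive_oracles import exact_fisher_two_sided, exact_mannwhitney_two_sided


class TestPearsonComparison:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(0)
        avg = rng.normal(size=(4, 90))
        cmp = compare_class_averages(avg, avg)
        assert cmp.statistic == pytest.approx(1.0)
        assert cmp.pvalue < 1e-100

    def test_negated_average_is_minus_one(self):
        rng = np.random.default_rng(1)
        avg = rng.normal(size=(4, 90))
        cmp = compare_class_averages(avg, -avg)
        assert cmp.statistic == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(4, 90)), rng.normal(size=(4, 90))
        assert compare_class_averages(a, b).statistic == \
            pytest.approx(compare_class_averages(b, a).statistic)

    def test_constant_input_reported_as_undefined(self):
        cmp = compare_class_averages(np.ones((4, 90)), np.zeros((4, 90)))
        assert np.isnan(cmp.statistic) and np.isnan(cmp.pvalue)

    def test_center_exclusion_positions_ignored(self):
        """Values at the masked centre cannot influence the comparison."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 90))
        b = a.copy()
        config = AlignmentConfig()
        b[:, config.half - 2:config.half + 3] = 99.0
        assert compare_class_averages(a, b, config=config).statistic == pytest.approx(1.0)

    def test_per_feature_mode(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(4, 90))
        out = compare_class_averages(a, a, per_feature=True)
        assert [c.statistic_name for c in out] == \
            ["pearson_r[MGW]", "pearson_r[ProT]", "pearson_r[HelT]", "pearson_r[Roll]"]
        assert all(c.statistic == pytest.approx(1.0) for c in out)


class TestMannWhitney:
    def test_identical_multisets(self):
        scores = [0.1, 0.4, 0.4, 0.9]
        cmp = compare_score_distributions(scores, scores)
        assert cmp.statistic == pytest.approx(len(scores) ** 2 / 2)
        assert cmp.pvalue == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_small_p(self):
        a = np.linspace(0, 1, 20)
        b = np.linspace(2, 3, 20)
        cmp = compare_score_distributions(a, b)
        assert cmp.statistic == 0.0
        assert cmp.pvalue < 1e-6

    def test_all_tied_degenerate(self):
        cmp = compare_score_distributions([1.0] * 5, [1.0] * 7)
        assert cmp.pvalue == 1.0
        assert cmp.statistic == pytest.approx(5 * 7 / 2)

    def test_exact_path_matches_enumeration(self):
        """Small untied samples use exact enumeration; verify against brute force."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            cmp = compare_score_distributions(a, b)
            assert cmp.extras["method"] == "exact"
            _, p_exact = exact_mannwhitney_two_sided(a, b)
            assert cmp.pvalue == pytest.approx(p_exact, rel=1e-9)

    def test_normal_approximation_tracks_exact_for_moderate_p(self):
        """Tie-corrected normal approximation stays within 10% of enumeration
        away from the extreme tails."""
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, p_exact = exact_mannwhitney_two_sided(a, b)
            if p_exact < 0.05:
                continue
            approx = compare_score_distributions(a, b, exact_max_n=0)
            assert approx.extras["method"] == "asymptotic"
            assert approx.pvalue == pytest.approx(p_exact, rel=0.10)
            checked += 1
        assert checked >= 10

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compare_score_distributions([], [1.0])


GENES = pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr1"],
    "start": [10_000, 20_000, 30_000],
    "end": [11_000, 21_000, 31_000],
    "gene_id": ["gA", "gB", "gC"],
    "strand": ["+", "-", "+"],
})


class TestAssignGenes:
    def test_nearby_gene_wins_over_distant(self):
        sites = [Site("chr1", 9_500, "fast", "s1")]  # 500 bp from gA, 10.5 kb from gB
        out = assign_genes(sites, GENES)
        assert out.loc[0, "gene_id"] == "gA"
        assert out.loc[0, "distance"] == 500

    def test_beyond_one_kilobase_unassigned(self):
        sites = [Site("chr1", 8_500, "fast", "s1")]  # 1.5 kb from gA
        out = assign_genes(sites, GENES)
        assert out.loc[0, "gene_id"] is None

    def test_inside_gene_body_distance_zero(self):
        sites = [Site("chr1", 10_400, "fast", "s1")]
        out = assign_genes(sites, GENES)
        assert out.loc[0, "gene_id"] == "gA"
        assert out.loc[0, "distance"] == 0

    def test_tie_breaks_to_leftmost_gene_start(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [1_000, 3_000],
            "end": [1_500, 3_500],
            "gene_id": ["left", "right"],
        })
        sites = [Site("chr1", 2_249, "fast", "s1")]  # 750 bp from both boundaries
        out = assign_genes(sites, genes)
        assert out.loc[0, "gene_id"] == "left"

    def test_empty_annotation_warns_and_assigns_none(self, caplog):
        sites = [Site("chr1", 100, "fast", "s1")]
        out = assign_genes(sites, pd.DataFrame(columns=GENES.columns))
        assert out["gene_id"].isna().all()

    def test_tss_only_mode_uses_strand(self):
        sites = [Site("chr1", 21_500, "fast", "s1")]
        # gB is on '-': TSS at end-1 = 20,999 (501 bp); gene-body distance is 500
        out = assign_genes(sites, GENES, tss_only=True)
        assert out.loc[0, "gene_id"] == "gB"
        assert out.loc[0, "distance"] == 501


class TestFisher:
    def test_balanced_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184_756, rel=1e-6)  # 2 / C(20, 10)

    def test_row_swap_inverts_odds_ratio(self):
        odds_a, p_a = fisher_exact_2x2([[8, 2], [3, 7]])
        odds_b, p_b = fisher_exact_2x2([[3, 7], [8, 2]])
        assert odds_a == pytest.approx(1 / odds_b)
        assert p_a == pytest.approx(p_b)

    def test_matches_exact_enumeration_on_small_tables(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b == 0 or c + d == 0:
                            continue
                        _, p = fisher_exact_2x2([[a, b], [c, d]])
                        assert p == pytest.approx(
                            exact_fisher_two_sided(a, b, c, d), rel=1e-6, abs=1e-12)


class TestAssociationEnrichment:
    def make_inputs(self):
        rows, associated = [], []
        for klass, n_assoc, n_total in (("fast", 8, 10), ("slow", 7, 10),
                                        ("free_mnase", 2, 10), ("random", 1, 10)):
            for i in range(n_total):
                gene = f"{klass}_g{i}"
                rows.append((f"{klass}_{i}", klass, gene, 100.0))
                if i < n_assoc:
                    associated.append(gene)
        assignments = pd.DataFrame(rows, columns=["site_id", "class_label",
                                                  "gene_id", "distance"])
        table = pd.DataFrame({"gene_id": associated, "tf": "TF1",
                              "evidence": "documented"})
        return assignments, table

    def test_enriched_classes_flagged(self):
        assignments, table = self.make_inputs()
        out = association_enrichment(assignments, table, "TF1")
        assert len(out) == 4  # fast/slow x free_mnase/random
        assert (out["test_proportion"] > out["control_proportion"]).all()

    def test_missing_class_skipped_with_warning(self, caplog):
        assignments, table = self.make_inputs()
        assignments = assignments[assignments["class_label"] != "random"]
        out = association_enrichment(assignments, table, "TF1")
        assert set(out["control_class"]) == {"free_mnase"}


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adjusted = benjamini_hochberg(p)
    assert (np.diff(adjusted) >= 0).all()
    assert (adjusted >= np.asarray(p)).all()
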