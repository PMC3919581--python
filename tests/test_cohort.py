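"""Cohort-level hypergeometric/binomial tests and the enrichment curve."""

import itertools
import math

import pytest

from mutbind.cohortstats import (
    assemble_counts,
    binding_fraction,
    binomial_frequency_test,
    ccg_enrichment_curve,
    enrichment_ratio,
    hypergeom_tail,
)
from mutbind.types import GlobalCounts, MappedBindingSite, ProteinMutation, SiteTestResult


def mk_site(positions, gene="G1", category="SMI", site_id="SMI_1"):
    return MappedBindingSite(
        gene, site_id, category, frozenset(positions), {p: 1.0 for p in positions}
    )


def mk_var(pos, gene="G1", var_class="missense", sample="s1"):
    ref, alt = ("A", "V") if var_class != "synonymous" else ("A", "A")
    return ProteinMutation(gene, f"{gene}.1", pos, ref, alt, sample, "SIM", var_class)


class TestAssembleCounts:
    def test_positions_counted_once(self):
        sites = [mk_site({1, 2, 3})]
        structural = {"G1": set(range(1, 11))}
        variants = [mk_var(2), mk_var(2, sample="s2"), mk_var(7)]
        counts = assemble_counts(sites, structural, variants, "missense")
        assert (counts.N, counts.K, counts.n, counts.k) == (10, 3, 2, 1)

    def test_no_variants(self):
        counts = assemble_counts([mk_site({1})], {"G1": {1, 2}}, [], "missense")
        assert (counts.n, counts.k) == (0, 0)

    def test_pooling_over_refseqs_is_additive(self):
        sites = [mk_site({1, 2, 3}, "G1"), mk_site({1, 2}, "G2", site_id="SMI_1")]
        structural = {"G1": set(range(1, 11)), "G2": set(range(1, 6))}
        variants = [mk_var(2, "G1"), mk_var(7, "G1"), mk_var(1, "G2")]
        counts = assemble_counts(sites, structural, variants, "missense")
        assert (counts.N, counts.K, counts.n, counts.k) == (15, 5, 3, 2)

    def test_category_restriction_keeps_global_background(self):
        sites = [
            mk_site({1, 2}, category="SMI", site_id="SMI_1"),
            mk_site({5, 6}, category="NUC", site_id="NUC_1"),
        ]
        structural = {"G1": set(range(1, 11))}
        variants = [mk_var(1), mk_var(5)]
        smi = assemble_counts(sites, structural, variants, "missense", category="SMI")
        assert (smi.N, smi.K, smi.n, smi.k) == (10, 2, 2, 1)

    def test_variants_outside_structural_ignored(self):
        counts = assemble_counts(
            [mk_site({1})], {"G1": set(range(1, 6))}, [mk_var(9)], "missense"
        )
        assert counts.n == 0


def enumerate_tail(N, K, n, k, tail):
    """Oracle: enumerate all C(N, n) draws of hit positions."""
    hits = total = 0
    binding = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        overlap = len(binding & set(draw))
        if (tail == "upper" and overlap >= k) or (tail == "lower" and overlap <= k):
            hits += 1
    return hits / total


class TestHypergeom:
    def test_upper_tail_example(self):
        p = hypergeom_tail(GlobalCounts(10, 3, 4, 2), "upper")
        assert p == pytest.approx(enumerate_tail(10, 3, 4, 2, "upper"))
        assert p == pytest.approx(1 / 3)

    def test_lower_tail_example(self):
        p = hypergeom_tail(GlobalCounts(10, 3, 4, 0), "lower")
        assert p == pytest.approx(enumerate_tail(10, 3, 4, 0, "lower"))
        assert p == pytest.approx(1 / 6)

    def test_no_binding_positions_gives_p_one(self):
        assert hypergeom_tail(GlobalCounts(10, 0, 4, 0), "upper") == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [4, 7, 9])
    def test_matches_enumeration_everywhere(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    counts = GlobalCounts(N, K, n, k)
                    for tail in ("upper", "lower"):
                        assert hypergeom_tail(counts, tail) == pytest.approx(
                            enumerate_tail(N, K, n, k, tail), abs=1e-12
                        ), (N, K, n, k, tail)

    def test_tails_are_complementary(self):
        for k in range(1, 4):
            upper = hypergeom_tail(GlobalCounts(12, 4, 6, k), "upper")
            lower = hypergeom_tail(GlobalCounts(12, 4, 6, k - 1), "lower")
            assert upper + lower == pytest.approx(1.0)

    def test_upper_tail_monotone_in_k(self):
        ps = [hypergeom_tail(GlobalCounts(20, 6, 8, k), "upper") for k in range(7)]
        assert ps == sorted(ps, reverse=True)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            GlobalCounts(10, 3, 4, 5)


class TestBinomial:
    def test_closed_form_example(self):
        assert binomial_frequency_test(4, 4, 0.5) == pytest.approx(1 / 16)

    def test_zero_hits_gives_one(self):
        assert binomial_frequency_test(0, 12, 0.3) == pytest.approx(1.0)

    def test_exact_tail_sum(self):
        expected = sum(
            math.comb(10, i) * 0.2**i * 0.8 ** (10 - i) for i in range(5, 11)
        )
        assert binomial_frequency_test(5, 10, 0.2) == pytest.approx(expected)
        assert expected == pytest.approx(0.0328, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_frequency_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_frequency_test(1, 4, 1.5)

    def test_binding_fraction(self):
        sites = [mk_site({1, 2})]
        assert binding_fraction(sites, {"G1": set(range(1, 9))}) == pytest.approx(0.25)


def mk_result(gene, p, site_id="SMI_1", mutated=1):
    return SiteTestResult(gene, site_id, "SMI", "ALL", 4, mutated, 5, 1.0, p, p)


class TestEnrichment:
    def test_ratio_matches_direct_arithmetic(self):
        assert enrichment_ratio(4, 2, 100, 10) == pytest.approx(5.0)

    def test_all_genes_ccg_gives_unity(self):
        results = [mk_result(f"G{i}", 0.01 * (i + 1)) for i in range(5)]
        ccg = {f"G{i}" for i in range(5)}
        for point in ccg_enrichment_curve(results, ccg, thresholds=[0.02, 0.05]):
            assert point.enrichment_ratio == pytest.approx(1.0)

    def test_zero_selected_emits_absent_ratio(self):
        results = [mk_result("G1", 0.5)]
        (point,) = ccg_enrichment_curve(results, {"G1"}, thresholds=[0.001])
        assert point.selected_genes == 0 and point.enrichment_ratio is None

    def test_sites_without_mutations_excluded_from_background(self):
        results = [mk_result("G1", 0.01), mk_result("G2", 0.5, mutated=0)]
        (point,) = ccg_enrichment_curve(results, {"G1"}, thresholds=[0.05])
        assert point.total_genes == 1  # only the mutated site counts

    def test_background_unit_genes_vs_sites(self):
        results = [
            mk_result("G1", 0.01),
            mk_result("G1", 0.2, site_id="SMI_2"),
            mk_result("G2", 0.3),
        ]
        (by_sites,) = ccg_enrichment_curve(results, {"G1"}, thresholds=[0.05])
        (by_genes,) = ccg_enrichment_curve(
            results, {"G1"}, thresholds=[0.05], background_unit="genes"
        )
        assert (by_sites.total_genes, by_sites.ccg_total) == (3, 2)
        assert (by_genes.total_genes, by_genes.ccg_total) == (2, 1)

    def test_selection_is_per_gene_best_site(self):
        results = [
            mk_result("G1", 0.001),
            mk_result("G1", 0.9, site_id="SMI_2"),
            mk_result("G2", 0.9),
        ]
        (point,) = ccg_enrichment_curve(results, {"G1"}, thresholds=[0.01])
        assert point.selected_genes == 1 and point.ccg_in_selected == 1
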