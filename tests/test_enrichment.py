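"""Regulatory domains, binomial enrichment and Jaccard specificity."""

import math

import numpy as np
import pandas as pd
import pytest

from degas import enrichment as enr
from degas import scores as sc


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def _exact_binomial_tail(n, pi, hits):
    """Independent oracle: direct summation of the binomial upper tail."""
    return sum(
        math.comb(n, x) * pi**x * (1 - pi) ** (n - x) for x in range(hits, n + 1)
    )


class TestTopVariants:
    @pytest.fixture
    def table(self):
        frame = pd.DataFrame(
            {"PC1": [0.05, 0.3, 0.1, 0.25, 0.1, 0.2]},
            index=[f"v{j}" for j in range(6)],
        )
        return sc.ScoreTable(frame, "variant", "contribution")

    def test_top_n_by_contribution(self, table):
        assert enr.select_top_variants(table, "PC1", 3) == ["v1", "v3", "v5"]

    def test_equal_scores_lexicographic(self):
        frame = pd.DataFrame({"PC1": [0.25] * 4}, index=["d", "b", "c", "a"])
        t = sc.ScoreTable(frame, "variant", "contribution")
        assert enr.select_top_variants(t, "PC1", 2) == ["a", "b"]

    def test_default_n_is_5000(self, table):
        import inspect

        assert inspect.signature(enr.select_top_variants).parameters["n"].default == 5000


class TestRegulatoryDomains:
    SIZES = {"1": 10_000_000}

    def test_single_gene_extension_both_sides(self):
        tss = pd.DataFrame(
            {"gene": ["A"], "chrom": ["1"], "tss": [2_000_000], "strand": ["+"]}
        )
        (dom,) = enr.build_regulatory_domains(tss, self.SIZES)
        assert (dom.start, dom.end) == (1_000_000, 3_000_000)

    def test_adjacent_genes_meet_at_basal_edges(self):
        tss = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "chrom": ["1", "1"],
                "tss": [2_000_000, 2_500_000],
                "strand": ["+", "+"],
            }
        )
        doms = {d.gene: d for d in enr.build_regulatory_domains(tss, self.SIZES)}
        # A extends right until B's basal start (2,500,000 - 5,000)
        assert doms["A"].end == 2_495_000
        # B extends left until A's basal end (2,000,000 + 1,000)
        assert doms["B"].start == 2_001_000

    def test_clip_at_chromosome_start(self):
        tss = pd.DataFrame({"gene": ["A"], "chrom": ["1"], "tss": [3000], "strand": ["+"]})
        (dom,) = enr.build_regulatory_domains(tss, self.SIZES)
        assert dom.start == 0

    def test_minus_strand_basal_orientation(self):
        tss = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "chrom": ["1", "1"],
                "tss": [2_000_000, 2_500_000],
                "strand": ["-", "-"],
            }
        )
        doms = {d.gene: d for d in enr.build_regulatory_domains(tss, self.SIZES)}
        # minus strand basal is [tss-1000, tss+5000)
        assert doms["A"].end == 2_499_000
        assert doms["B"].start == 2_005_000

    def test_duplicate_gene_symbol_rejected(self):
        tss = pd.DataFrame(
            {"gene": ["A", "A"], "chrom": ["1", "1"], "tss": [1, 2], "strand": ["+", "+"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            enr.build_regulatory_domains(tss, self.SIZES)

    def test_coverage_bounded_and_order_invariant(self, rng):
        tss = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(12)],
                "chrom": ["1"] * 12,
                "tss": sorted(rng.integers(10_000, 9_990_000, size=12).tolist()),
                "strand": ["+", "-"] * 6,
            }
        )
        doms = enr.build_regulatory_domains(tss, self.SIZES)
        cov = enr._covered_bp(enr._coverage_by_chrom(doms))
        assert cov <= self.SIZES["1"]
        shuffled = enr._coverage_by_chrom(list(reversed(doms)))
        assert enr._covered_bp(shuffled) == cov


class TestBinomialEnrichment:
    GENOME = 1_000_000

    def _domains(self, spans, gene="A"):
        return [enr.RegulatoryDomain(gene, "1", lo, hi) for lo, hi in spans]

    def test_whole_genome_term_is_unenriched(self):
        domains = self._domains([(0, self.GENOME)])
        regions = _bed([("1", p, p + 1, f"r{p}", 0.0) for p in range(0, 1000, 100)])
        (res,) = enr.binomial_region_enrichment(
            regions, domains, {"T": {"A"}}, self.GENOME
        )
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_tail_example(self):
        # 10 regions, term covering 10% of the genome, 5 hits
        domains = self._domains([(0, 100_000)])
        inside = [("1", 1000 * i, 1000 * i + 1, f"in{i}", 0.0) for i in range(5)]
        outside = [("1", 500_000 + 1000 * i, 500_000 + 1000 * i + 1, f"out{i}", 0.0) for i in range(5)]
        (res,) = enr.binomial_region_enrichment(
            _bed(inside + outside), domains, {"T": {"A"}}, self.GENOME
        )
        assert res.n_hits == 5
        assert res.fold == pytest.approx(5.0)
        assert res.p_value == pytest.approx(_exact_binomial_tail(10, 0.1, 5), abs=1e-12)

    def test_no_hits_gives_fold_zero_p_one(self):
        domains = self._domains([(900_000, 910_000)])
        regions = _bed([("1", 10, 11, "r", 0.0)])
        (res,) = enr.binomial_region_enrichment(regions, domains, {"T": {"A"}}, self.GENOME)
        assert res.fold == 0.0 and res.p_value == 1.0

    def test_term_without_domains_has_zero_coverage(self):
        regions = _bed([("1", 10, 11, "r", 0.0)])
        (res,) = enr.binomial_region_enrichment(regions, [], {"T": {"A"}}, self.GENOME)
        assert res.fold == 0.0 and res.p_value == 1.0

    def test_pvalues_match_exact_summation(self, rng):
        """Kernel tail probabilities agree with direct summation for n <= 50."""
        for _ in range(25):
            n = int(rng.integers(1, 51))
            pi = float(rng.uniform(0.01, 0.9))
            hits = int(rng.integers(1, n + 1))
            from scipy import stats

            p_kernel = float(stats.binom.sf(hits - 1, n, pi))
            assert p_kernel == pytest.approx(_exact_binomial_tail(n, pi, hits), abs=1e-12)


class TestSignificanceFilters:
    def _res(self, p, fold):
        return enr.EnrichmentResult("PC1", "T", fold, p, 1, 1)

    @pytest.mark.parametrize(
        "p,fold,in_table,in_plot",
        [
            (1e-6, 1.5, True, False),
            (1e-5, 3.0, False, False),
            (1e-8, 3.0, True, True),
            (1e-8, 1.9, True, False),
            (4.9e-6, 2.5, True, False),
        ],
    )
    def test_modes(self, p, fold, in_table, in_plot):
        r = self._res(p, fold)
        assert (r in enr.filter_significant([r], "table")) == in_table
        assert (r in enr.filter_significant([r], "plot")) == in_plot

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            enr.filter_significant([], "poster")


class TestJaccard:
    TERMS = {
        "TA": {"a", "b", "c"},
        "TB": {"b", "c", "d"},
        "TC": {"x", "y"},
        "TD": set(),
    }

    def test_identity(self):
        assert enr.jaccard_similarity(["TA"], ["TA"], self.TERMS) == 1.0

    def test_disjoint(self):
        assert enr.jaccard_similarity(["TA"], ["TC"], self.TERMS) == 0.0

    def test_partial_overlap(self):
        assert enr.jaccard_similarity(["TA"], ["TB"], self.TERMS) == pytest.approx(0.5)

    def test_union_over_term_sets(self):
        # gene set of {TA, TC} is {a,b,c,x,y}; vs {TB}: overlap {b,c} of 6
        assert enr.jaccard_similarity(["TA", "TC"], ["TB"], self.TERMS) == pytest.approx(2 / 6)

    def test_symmetry_and_bounds(self, rng):
        keys = list(self.TERMS)
        for _ in range(20):
            a = list(rng.choice(keys, size=2, replace=False))
            b = list(rng.choice(keys, size=2, replace=False))
            j1 = enr.jaccard_similarity(a, b, self.TERMS)
            assert j1 == enr.jaccard_similarity(b, a, self.TERMS)
            assert 0.0 <= j1 <= 1.0

    def test_both_empty_defined_as_zero(self):
        assert enr.jaccard_similarity(["TD"], ["TD"], self.TERMS) == 0.0

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            enr.jaccard_similarity(["nope"], ["TA"], self.TERMS)


class TestSpecificityProfile:
    # gene sets with hand-computable pairwise similarities:
    # J(A,B) = |{g4,g5}| / |{g1..g8}| = 0.25
    # J(A,C) = 5/10 = 0.5 ; J(B,C) = 5/10 = 0.5  -> median 0.5
    TERMS = {
        "A": {f"g{i}" for i in range(1, 6)},
        "B": {f"g{i}" for i in range(4, 9)},
        "C": {f"g{i}" for i in range(1, 11)},
    }

    def _enr(self, comp, term, fold):
        return enr.EnrichmentResult(comp, term, fold, 1e-9, 5, 100)

    def test_identical_components_median_one(self):
        e = {c: [self._enr(c, "A", 3.0)] for c in ("PC1", "PC2")}
        prof = enr.component_specificity_profile(e, self.TERMS, k_values=[2])
        assert prof["median_jaccard"].iloc[0] == 1.0

    def test_disjoint_components_median_zero(self):
        terms = {"A": {"a"}, "B": {"b"}}
        e = {"PC1": [self._enr("PC1", "A", 3.0)], "PC2": [self._enr("PC2", "B", 3.0)]}
        prof = enr.component_specificity_profile(e, terms, k_values=[2])
        assert prof["median_jaccard"].iloc[0] == 0.0

    def test_three_component_median(self):
        e = {
            "PC1": [self._enr("PC1", "A", 3.0)],
            "PC2": [self._enr("PC2", "B", 3.0)],
            "PC3": [self._enr("PC3", "C", 3.0)],
        }
        prof = enr.component_specificity_profile(e, self.TERMS, k_values=[3])
        row = prof.iloc[0]
        assert row["n_pairs"] == 3
        assert row["median_jaccard"] == pytest.approx(0.5)

    def test_top_terms_sorted_by_fold(self):
        results = [
            self._enr("PC1", "A", 2.0),
            self._enr("PC1", "B", 9.0),
            self._enr("PC1", "C", 5.0),
        ]
        assert enr.top_terms_by_fold(results, n=2) == ["B", "C"]

    def test_component_without_terms_skipped(self):
        e = {"PC1": [self._enr("PC1", "A", 3.0)], "PC2": [], "PC3": [self._enr("PC3", "B", 3.0)]}
        prof = enr.component_specificity_profile(e, self.TERMS, k_values=[2])
        assert prof["n_pairs"].iloc[0] == 1  # only PC1 and PC3 participate


class TestPlantedEnrichmentRecovery:
    def _results(self, enrichment_fixture, n_top=40):
        fx = enrichment_fixture
        top = enr.select_top_variants(fx["variant_contribution"], "PC1", n=n_top)
        bed = enr.variants_to_bed(
            top, fx["annotations"], fx["variant_contribution"].frame["PC1"].to_dict()
        )
        domains = enr.build_regulatory_domains(fx["tss"], fx["chrom_sizes"])
        return enr.binomial_region_enrichment(
            bed, domains, fx["terms"], sum(fx["chrom_sizes"].values()), "PC1"
        )

    def test_planted_term_attains_top_fold(self, enrichment_fixture):
        results = self._results(enrichment_fixture)
        assert enr.top_terms_by_fold(results, 1) == [enrichment_fixture["planted_term"]]

    def test_planted_term_passes_table_filter(self, enrichment_fixture):
        results = self._results(enrichment_fixture)
        kept = {r.term_id for r in enr.filter_significant(results, "table")}
        assert enrichment_fixture["planted_term"] in kept

    def test_bed_is_zero_based_single_base(self, enrichment_fixture):
        fx = enrichment_fixture
        top = enr.select_top_variants(fx["variant_contribution"], "PC1", n=10)
        bed = enr.variants_to_bed(top, fx["annotations"])
        assert (bed["end"] - bed["start"] == 1).all()
        v = fx["annotations"][bed["name"].iloc[0]]
        assert bed["start"].iloc[0] == v.pos - 1
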