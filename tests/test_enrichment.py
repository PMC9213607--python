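"""Fisher exact machinery, set intersection, cis gene mapping, FC correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_storm.assignment import TELocus
from te_storm.enrichment import (
    cis_genes,
    class_enrichment,
    fisher_exact_2x2,
    fold_change_correlation,
    intersection_test,
)
from te_storm.errors import ConsistencyError, UsageError


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided p by direct log-factorial enumeration of fixed-margin tables."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0

    def logp(k):
        return (math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
                + math.lgamma(n - r1 + 1) - math.lgamma(c1 - k + 1)
                - math.lgamma(n - r1 - c1 + k + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    lp_obs = logp(a)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = logp(k)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


class TestFisher:
    def test_classic_table_matches_enumeration(self):
        oratio, p = fisher_exact_2x2(1, 9, 11, 3)
        assert p == pytest.approx(fisher_enumeration_oracle(1, 9, 11, 3),
                                  rel=1e-9)
        assert p == pytest.approx(0.0027594561852, rel=1e-9)
        assert oratio == pytest.approx((1 * 3) / (9 * 11))

    def test_perfect_diagonal_counts_both_extremes(self):
        # the (5,0,0,5) and (0,5,5,0) tables are equally most extreme, so
        # the point-probability rule sums both point masses: 2 / C(10,5)
        oratio, p = fisher_exact_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)
        assert oratio == np.inf

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(0, 0, 3, 7)[1] == 1.0
        assert fisher_exact_2x2(0, 5, 0, 7)[1] == 1.0

    def test_odds_ratio_conventions(self):
        assert fisher_exact_2x2(2, 3, 4, 5)[0] == pytest.approx(10 / 12)
        assert fisher_exact_2x2(0, 3, 4, 5)[0] == 0.0
        assert np.isnan(fisher_exact_2x2(0, 3, 0, 5)[0])  # 0/0 indeterminate

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            p_sp = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(p_sp, rel=1e-9, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(UsageError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestClassEnrichment:
    def make_background(self, rng, n=500, frac_line=0.2):
        ids = [f"L{i:04d}" for i in range(n)]
        classes = rng.choice(["LINE", "SINE"], p=[frac_line, 1 - frac_line],
                             size=n)
        return ids, dict(zip(ids, classes))

    def test_planted_line_excess_flagged(self, rng):
        ids, class_of = self.make_background(rng)
        lines = [i for i in ids if class_of[i] == "LINE"]
        others = [i for i in ids if class_of[i] != "LINE"]
        de = lines[:40] + others[:10]  # 80% LINE vs 20% background
        out = class_enrichment(de, ids, class_of)
        row = out.set_index("label").loc["LINE"]
        assert row["significant"] and row["direction"] == "enriched"

    def test_de_equal_background_is_null(self, rng):
        ids, class_of = self.make_background(rng)
        out = class_enrichment(ids, ids, class_of)
        assert (out["odds_ratio"].isin([1.0]) | out["odds_ratio"].isna()).all()
        assert not out["significant"].any()

    def test_empty_de_set_is_empty_result_not_error(self, rng):
        ids, class_of = self.make_background(rng)
        out = class_enrichment([], ids, class_of)
        assert not out["significant"].any()
        assert (out["a"] == 0).all()

    def test_de_outside_background_rejected(self, rng):
        ids, class_of = self.make_background(rng)
        with pytest.raises(ConsistencyError):
            class_enrichment(["notthere"], ids, class_of)

    def test_grouping_level_recorded_and_validated(self, rng):
        ids, class_of = self.make_background(rng)
        out = class_enrichment(ids[:20], ids, class_of, by="family")
        assert (out["by"] == "family").all()
        with pytest.raises(UsageError):
            class_enrichment(ids[:20], ids, class_of, by="order")

    def test_permutation_pvalues_are_conservative_uniform(self, rng):
        """Random DE draws: P(p <= alpha) <= alpha (+MC noise) for exact tests."""
        ids, class_of = self.make_background(rng, n=400, frac_line=0.3)
        ps = []
        for _ in range(300)        :
            de = rng.choice(ids, size=60, replace=False)
            out = class_enrichment(de, ids, class_of).set_index("label")
            ps.append(out.loc["LINE", "p"])
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            frac = (ps <= alpha).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(ps))


class TestIntersection:
    def test_disjoint_sets_p_one(self):
        u = [f"x{i}" for i in range(100)]
        out = intersection_test(u[:10], u[50:60], u)
        assert out["overlap"] == 0 and out["p"] == 1.0

    def test_identical_sets_tiny_p(self):
        u = [f"x{i}" for i in range(1000)]
        s = u[:10]
        out = intersection_test(s, s, u)
        assert out["overlap"] == 10
        assert out["p"] < 1e-15
        # hypergeometric point check: P(X >= 10) with N=1000, K=n=10
        assert out["p"] == pytest.approx(
            stats.hypergeom.sf(9, 1000, 10, 10), rel=1e-9)

    def test_direction_concordance_table(self):
        u = [f"x{i}" for i in range(50)]
        d1 = {"x0": "up", "x1": "down", "x2": "up"}
        d2 = {"x0": "up", "x1": "up", "x2": "up"}
        out = intersection_test(list(d1), list(d2), u, d1, d2)
        assert out["direction_table"].loc["up", "up"] == 2
        assert out["direction_table"].loc["down", "up"] == 1
        assert out["direction_concordance"] == pytest.approx(2 / 3)

    def test_empty_universe_rejected(self):
        with pytest.raises(UsageError):
            intersection_test([], [], [])


def make_locus(lid, start, end, chrom="chr1", strand="+"):
    return TELocus(locus_id=lid, chrom=chrom, start=start, end=end,
                   strand=strand, family="L1HS", te_class="LINE",
                   consensus_len=end - start)


class TestCisGenes:
    def gene_frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])

    def test_window_boundary_4999_in_5001_out(self):
        locus = make_locus("L1", 10_000, 11_000)
        genes = self.gene_frame([
            ("chr1", 11_000 + 4_999, 11_000 + 6_000, "near", 0, "+"),
            ("chr1", 11_000 + 5_001, 11_000 + 7_000, "far", 0, "+"),
        ])
        out = cis_genes([locus], genes, window=5000)
        assert set(out["gene_id"]) == {"near"}
        # half-open: a gene starting exactly at end+window is outside
        genes2 = self.gene_frame([
            ("chr1", 11_000 + 5_000, 11_000 + 6_000, "edge", 0, "+")])
        assert cis_genes([locus], genes2, window=5000).empty

    def test_overlap_and_strand_aware_relations(self):
        locus = make_locus("L1", 10_000, 11_000, strand="-")
        genes = self.gene_frame([
            ("chr1", 10_500, 10_800, "inside", 0, "+"),
            ("chr1", 8_000, 9_000, "leftof", 0, "+"),
            ("chr1", 12_000, 13_000, "rightof", 0, "+"),
        ])
        out = cis_genes([locus], genes, window=5000).set_index("gene_id")
        assert out.loc["inside", "relation"] == "overlap"
        # minus-strand locus: genomic right is its upstream side
        assert out.loc["rightof", "relation"] == "upstream"
        assert out.loc["leftof", "relation"] == "downstream"
        assert out.loc["leftof", "distance"] == 1_000

    def test_matches_bruteforce_all_pairs_scan(self, rng):
        loci = [make_locus(f"L{i}", int(s), int(s) + 500)
                for i, s in enumerate(rng.integers(0, 100_000, size=40))]
        genes = self.gene_frame([
            ("chr1", int(s), int(s) + 800, f"G{i}", 0, "+")
            for i, s in enumerate(rng.integers(0, 100_000, size=60))
        ])
        out = cis_genes(loci, genes, window=5000)
        got = set(zip(out["locus_id"], out["gene_id"]))
        expected = set()
        for l in loci:
            for _, g in genes.iterrows():
                if g["start"] < l.end + 5000 and g["end"] > l.start - 5000:
                    expected.add((l.locus_id, g["name"]))
        assert got == expected

    def test_window_monotonicity(self, rng):
        loci = [make_locus(f"L{i}", int(s), int(s) + 300)
                for i, s in enumerate(rng.integers(0, 50_000, size=20))]
        genes = self.gene_frame([
            ("chr1", int(s), int(s) + 400, f"G{i}", 0, "+")
            for i, s in enumerate(rng.integers(0, 50_000, size=30))
        ])
        small = set(map(tuple, cis_genes(loci, genes, 1000)[
            ["locus_id", "gene_id"]].to_numpy()))
        big = set(map(tuple, cis_genes(loci, genes, 8000)[
            ["locus_id", "gene_id"]].to_numpy()))
        assert small <= big

    def test_chromosome_mismatch_warns(self):
        locus = make_locus("L1", 0, 100, chrom="chr9")
        genes = self.gene_frame([("chr1", 0, 50, "G1", 0, "+")])
        with pytest.warns(UserWarning):
            out = cis_genes([locus], genes)
        assert out.empty


class TestFoldChangeCorrelation:
    def frame(self, lfc, ids=None):
        ids = ids or [f"x{i}" for i in range(len(lfc))]
        return pd.DataFrame({"logFC": lfc}, index=ids)

    def test_self_correlation_is_one(self, rng):
        r = self.frame(rng.normal(size=50))
        out = fold_change_correlation(r, r)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_independent_null_near_zero(self, rng):
        a = self.frame(rng.normal(size=2000))
        b = self.frame(rng.normal(size=2000))
        out = fold_change_correlation(a, b)
        assert abs(out["pearson_r"]) < 0.1

    def test_too_few_shared_gives_nan_with_warning(self):
        a = self.frame([1.0, 2.0], ids=["a", "b"])
        b = self.frame([1.0, 2.0], ids=["b", "c"])
        with pytest.warns(UserWarning):
            out = fold_change_correlation(a, b)
        assert np.isnan(out["pearson_r"])
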