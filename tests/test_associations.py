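"""Regulatory regions, hypergeometric overlap tests, support labels, bias analysis."""

import itertools
import math

import numpy as np
import pytest

from regmap.core_tracks import AccessibilityMask, WindowTrack, tile_genome, apply_mask
from regmap.associations import (
    AssociationResult,
    ExpressionAtlas,
    GeneModel,
    RegulatoryRegionSet,
    associate,
    bonferroni_level,
    build_regulatory_regions,
    evaluate_vs_expression,
    expression_support,
    filter_significant,
    gene_motif_score,
    gene_scores,
    hypergeom_sf,
    region_class_bias,
    tf_target_set,
)


def brute_force_hypergeom_sf(x, N, K, n):
    """P(X >= x) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    successes = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) >= x:
            hits += 1
    return hits / total


@pytest.fixture()
def atlas():
    return ExpressionAtlas(
        gene_domains={
            "g1": {"D1"},
            "g2": {"D1", "D2"},
            "g3": {"D2"},
            "g4": set(),
            "tfA": {"D1"},
            "tfB": {"Droot"},
            "tfC": set(),
        },
        domain_stage={"D1": "s1", "D2": "s2", "Droot": "s1", "Dother": "s2"},
        ontology_edges=[("Droot", "D1"), ("Droot", "Dother")],
        tf_genes=["tfA", "tfB", "tfC"],
        ubiquitous={"tfC": {"s1"}},
    )


class TestBuildRegulatoryRegions:
    def test_upstream_plus_strand(self):
        g = GeneModel("g", "c", "+", 10_000, 10_000, 11_000)
        rs = build_regulatory_regions([g], "p1K")
        assert rs.intervals["g"] == [("c", 9000, 10_000)]

    def test_upstream_minus_strand(self):
        g = GeneModel("g", "c", "-", 10_000, 9000, 10_000)
        rs = build_regulatory_regions([g], "p1K")
        assert rs.intervals["g"] == [("c", 10_000, 11_000)]

    def test_p5k_length(self):
        g = GeneModel("g", "c", "+", 20_000, 20_000, 21_000)
        rs = build_regulatory_regions([g], "p5K")
        (chrom, s, e), = rs.intervals["g"]
        assert e - s == 5000

    def test_clipping_at_chromosome_start(self):
        g = GeneModel("g", "c", "+", 300, 300, 800)
        rs = build_regulatory_regions([g], "p1K", chrom_sizes={"c": 5000})
        assert rs.intervals["g"] == [("c", 0, 300)]

    def test_ig_truncated_by_insulator(self):
        g = GeneModel("g", "c", "+", 30_000, 30_000, 32_000)
        rs = build_regulatory_regions(
            [g], "IG", insulators=[("c", 40_000, 40_100)], chrom_sizes={"c": 200_000}
        )
        (chrom, s, e), = rs.intervals["g"]
        assert e == 40_000  # right extension stops at the insulator
        assert s == 0  # left extension clipped at chromosome start

    def test_ig_untruncated_extension(self):
        g = GeneModel("g", "c", "+", 60_000, 60_000, 62_000)
        rs = build_regulatory_regions([g], "IG", chrom_sizes={"c": 500_000})
        (chrom, s, e), = rs.intervals["g"]
        assert (s, e) == (10_000, 112_000)


class TestGeneScores:
    def test_max_over_windows(self, small_grid):
        vals = np.zeros(small_grid.n_windows)
        vals[3] = 9.0
        vals[4] = 4.0
        track = WindowTrack(small_grid, vals)
        rs = RegulatoryRegionSet("p1K", {"g": [("chr1", 150, 400)]})
        # windows overlapping [150,400) on chr1 include window 3 (150-650)
        assert gene_motif_score(track, rs, "g") == 9.0

    def test_no_overlap_scores_zero(self, small_grid):
        track = WindowTrack(small_grid, np.ones(small_grid.n_windows))
        rs = RegulatoryRegionSet("p1K", {"g": [("chrZ", 0, 100)]})
        assert gene_motif_score(track, rs, "g") == 0.0

    def test_unknown_gene_errors(self, small_grid):
        track = WindowTrack(small_grid, np.ones(small_grid.n_windows))
        rs = RegulatoryRegionSet("p1K", {"g": [("chr1", 0, 100)]})
        with pytest.raises(KeyError):
            gene_motif_score(track, rs, "nope")

    def test_batch_matches_single(self, small_grid, rng):
        track = WindowTrack(small_grid, rng.uniform(0, 5, small_grid.n_windows))
        rs = RegulatoryRegionSet(
            "p5K",
            {
                f"g{i}": [("chr1", int(s), int(s) + 700)]
                for i, s in enumerate(rng.integers(0, 2000, size=8))
            },
        )
        batch = gene_scores(track, rs)
        for g in rs.intervals:
            assert batch[g] == gene_motif_score(track, rs, g)


class TestTfTargetSet:
    def test_top_k(self):
        assert tf_target_set({"a": 5, "b": 3, "c": 1}, 2) == {"a", "b"}

    def test_k_exceeds_positive_genes(self):
        assert tf_target_set({"a": 5, "b": 0, "c": 1}, 5) == {"a", "c"}

    def test_lexicographic_tie_break(self):
        assert tf_target_set({"c": 5, "a": 5, "b": 5}, 2) == {"a", "b"}

    def test_zero_scores_excluded(self):
        assert tf_target_set({"a": 0.0, "b": 0.0}, 3) == frozenset()


class TestHypergeomSf:
    def test_zero_overlap_is_one(self):
        assert hypergeom_sf(0, 100, 10, 5) == 1.0

    def test_hand_enumeration(self):
        # N=10, K=5, n=4, x=4: C(5,4)/C(10,4) = 5/210
        assert hypergeom_sf(4, 10, 5, 4) == pytest.approx(5 / 210)

    def test_forced_full_overlap(self):
        assert hypergeom_sf(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(6, 10, 5, 5)

    def test_matches_exhaustive_enumeration_full_grid(self):
        """Survival function equals draw enumeration for every N <= 12 case."""
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for x in range(0, min(K, n) + 1):
                        expected = brute_force_hypergeom_sf(x, N, K, n)
                        assert hypergeom_sf(x, N, K, n) == pytest.approx(
                            expected, abs=1e-12
                        ), (x, N, K, n)


def _make_assoc_inputs(small_grid, rng, gene_values):
    """Region sets + masked tracks where gene g_i sees score gene_values[i]."""
    genes = []
    for i in range(len(gene_values)):
        tss = 500 + i * 240
        genes.append(GeneModel(f"g{i:02d}", "chr1", "+", tss, tss, tss + 100))
    region_sets = {
        m: build_regulatory_regions(genes, m, chrom_sizes={"chr1": 3000, "chr2": 2000})
        for m in ("p1K", "p5K", "IG")
    }
    return genes, region_sets


class TestAssociate:
    # gene intervals separated by >= 600 bp so no 500 bp window spans two
    _POSITIONS = {
        "g0": ("chr1", 0),
        "g1": ("chr1", 700),
        "g2": ("chr1", 1400),
        "g3": ("chr1", 2100),
        "g4": ("chr1", 2800),
        "g5": ("chr2", 0),
        "g6": ("chr2", 700),
        "g7": ("chr2", 1400),
    }
    _DOMAIN = {"g0", "g2", "g4", "g6"}

    def _atlas_and_inputs(self, small_grid):
        genes = {
            g: [(chrom, pos, pos + 100)] for g, (chrom, pos) in self._POSITIONS.items()
        }
        region_sets = {
            m: RegulatoryRegionSet(m, dict(genes)) for m in ("p1K", "p5K", "IG")
        }
        atlas = ExpressionAtlas(
            gene_domains={
                g: ({"D"} if g in self._DOMAIN else set()) for g in self._POSITIONS
            },
            domain_stage={"D": "s1"},
            tf_genes=["g7"],
        )
        return region_sets, atlas

    def test_strong_overlap_significant(self, small_grid):
        region_sets, atlas = self._atlas_and_inputs(small_grid)
        vals = np.zeros(small_grid.n_windows)
        for g in self._DOMAIN:
            chrom, pos = self._POSITIONS[g]
            for w in small_grid.overlapping_windows(chrom, pos, pos + 100):
                vals[w] = 5.0
        track = WindowTrack(small_grid, vals)
        res = associate(
            "tf", "D", {m: track for m in ("p1K", "p5K", "IG")}, region_sets, atlas, k=4
        )
        # all 4 domain genes recovered: P(X >= 4) = 1 / C(8, 4)
        assert (res.x, res.K, res.n, res.N) == (4, 4, 4, 8)
        assert res.p_value == pytest.approx(1 / 70)
        assert res.S == pytest.approx(-math.log10(res.p_value))

    def test_empty_target_set_gives_p_one(self, small_grid):
        region_sets, atlas = self._atlas_and_inputs(small_grid)
        track = WindowTrack(small_grid, np.zeros(small_grid.n_windows))
        res = associate(
            "tf", "D", {m: track for m in ("p1K", "p5K", "IG")}, region_sets, atlas, k=4
        )
        assert res.p_value == 1.0
        assert res.S == 0.0

    def test_mode_tie_precedence(self, small_grid):
        region_sets, atlas = self._atlas_and_inputs(small_grid)
        track = WindowTrack(small_grid, np.zeros(small_grid.n_windows))
        res = associate(
            "tf", "D", {m: track for m in ("p1K", "p5K", "IG")}, region_sets, atlas, k=4
        )
        # all three modes tie at p=1: declared precedence picks p1K
        assert res.mode == "p1K"
        assert res.p_value == min(res.per_mode_p.values())


class TestFilterSignificant:
    def test_published_bonferroni_arithmetic(self):
        level = bonferroni_level(1e-7, 325, 195)
        assert level == pytest.approx(0.0063375)
        assert level < 0.0064

    def test_alpha_one_keeps_all(self):
        results = [
            AssociationResult("t", f"d{i}", "p1K", 1, 1, 0, 10, p_value=0.5)
            for i in range(3)
        ]
        kept, _ = filter_significant(results, 1.0)
        assert len(kept) == 3

    def test_empty_input(self):
        kept, level = filter_significant([], 0.01)
        assert kept == [] and level == 0.0

    def test_threshold_applied(self):
        results = [
            AssociationResult("t", "d1", "p1K", 1, 1, 1, 10, p_value=1e-9),
            AssociationResult("t", "d2", "p1K", 1, 1, 0, 10, p_value=0.2),
        ]
        kept, _ = filter_significant(results, 1e-7)
        assert [r.domain for r in kept] == ["d1"]


class TestExpressionSupport:
    def test_specific(self, atlas):
        assert expression_support("tfA", "D1", atlas) == "specific"

    def test_related_via_parent_same_stage(self, atlas):
        # tfB annotated with Droot, parent of D1, both stage s1
        assert expression_support("tfB", "D1", atlas) == "related"

    def test_ubiquitous(self, atlas):
        assert expression_support("tfC", "D1", atlas) == "ubiquitous"

    def test_none_when_stage_differs(self, atlas):
        # tfC ubiquitous only in s1; D2 is stage s2
        assert expression_support("tfC", "D2", atlas) == "none"

    def test_unknown_domain_errors(self, atlas):
        with pytest.raises(KeyError):
            expression_support("tfA", "Dmissing", atlas)

    def test_non_tf_gene_rejected(self, atlas):
        with pytest.raises(KeyError):
            expression_support("g1", "D1", atlas)


class TestEvaluateVsExpression:
    def _results(self, pvals):
        return [
            AssociationResult("t", f"d{i}", "p1K", 1, 1, 0, 10, p_value=p)
            for i, p in enumerate(pvals)
        ]

    def test_perfect_separation(self):
        res = self._results([1e-9, 1e-8, 0.5, 0.9])
        auroc, _ = evaluate_vs_expression(
            res, {("t", "d0"), ("t", "d1")}
        )
        assert auroc == 1.0

    def test_truth_outside_grid_rejected(self):
        res = self._results([0.1])
        with pytest.raises(ValueError):
            evaluate_vs_expression(res, {("t", "zzz")})

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_vs_expression(self._results([0.1]), set())


class TestRegionClassBias:
    def _result(self, tf, dom, p1k, pig):
        return AssociationResult(
            tf, dom, "p1K", 1, 1, 0, 10,
            p_value=min(p1k, pig),
            per_mode_p={"p1K": p1k, "p5K": 1.0, "IG": pig},
        )

    def test_p1k_specific_detected(self):
        by_tf, _ = region_class_bias(
            [self._result("t", "d", 1e-9, 0.5)], alpha_sig=1e-7, alpha_null=1e-3
        )
        assert by_tf.loc["t", "p1k_specific"] == 1
        assert by_tf.loc["t", "ig_specific"] == 0

    def test_both_significant_is_neither(self):
        by_tf, _ = region_class_bias(
            [self._result("t", "d", 1e-9, 1e-8)], alpha_sig=1e-7, alpha_null=1e-3
        )
        assert by_tf.loc["t", "p1k_specific"] == 0
        assert by_tf.loc["t", "ig_specific"] == 0

    def test_exact_binomial_p(self):
        results = [self._result("t", f"d{i}", 1e-9, 0.5) for i in range(10)]
        by_tf, _ = region_class_bias(results)
        assert by_tf.loc["t", "binomial_p"] == pytest.approx(2 * 0.5**10)

    def test_alpha_order_enforced(self):
        with pytest.raises(ValueError):
            region_class_bias([], alpha_sig=1e-3, alpha_null=1e-7)


class TestMonotonicity:
    def test_shared_gene_never_increases_p(self, rng):
        """Adding a gene to both target and domain sets cannot weaken the overlap."""
        for _ in range(50):
            N = int(rng.integers(20, 60))
            K = int(rng.integers(1, N // 2))
            n = int(rng.integers(1, N // 2))
            x = int(rng.integers(0, min(K, n)))
            p_before = hypergeom_sf(x, N, K, n)
            p_after = hypergeom_sf(x + 1, N, K + 1, n + 1)
            assert p_after <= p_before + 1e-12
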