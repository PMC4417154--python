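"""Open-region construction, training sets, the linear activity model, gating, ranking."""

import numpy as np
import pytest

from regmap.core_tracks import AccessibilityMask, WindowTrack, tile_genome
from regmap.associations import ExpressionAtlas, GeneModel
from regmap.binding_eval import roc_auc
from regmap.enhancer_models import (
    EnhancerModel,
    InsufficientTrainingData,
    OpenRegion,
    ReferenceEnhancer,
    TFRecord,
    annotate_genome_wide,
    assign_candidate_domains,
    build_open_regions,
    build_training_sets,
    featurize_regions,
    good_model_gate,
    rank_statistic,
    read_model,
    score_percentiles,
    score_regions,
    train_enhancer_model,
    write_model,
)


STAGES = ["sA", "sB"]


def _region(widx, chrom="chr1", start=0, acc=(1.0, 1.0), stages=("sA",), **kw):
    return OpenRegion(
        window_idx=widx,
        chrom=chrom,
        start=start,
        end=start + 500,
        accessibility=np.asarray(acc, float),
        accessible_stages=frozenset(stages),
        **kw,
    )


class TestBuildOpenRegions:
    @pytest.fixture()
    def grid(self):
        return tile_genome({"chr1": 10_000}, 500, 50)

    def _tracks(self, grid, acc_values):
        masks, accs = {}, {}
        for st in STAGES:
            vals = np.asarray(acc_values[st], float)
            accs[st] = WindowTrack(grid, vals)
            m = np.zeros(grid.n_windows, bool)
            m[vals > 0] = True
            masks[st] = AccessibilityMask(grid, m, st)
        return masks, accs

    def test_greedy_keeps_strongest_of_overlap(self, grid):
        a = np.zeros(grid.n_windows)
        a[10] = 8.0
        a[12] = 9.0  # overlaps window 10 (within 10 windows)
        masks, accs = self._tracks(grid, {"sA": a, "sB": np.zeros(grid.n_windows)})
        regions = build_open_regions(masks, accs, {}, None, stages=STAGES)
        assert [r.window_idx for r in regions] == [12]

    def test_disjoint_windows_all_kept(self, grid):
        a = np.zeros(grid.n_windows)
        a[10] = 5.0
        a[40] = 6.0
        a[80] = 7.0
        masks, accs = self._tracks(grid, {"sA": a, "sB": np.zeros(grid.n_windows)})
        regions = build_open_regions(masks, accs, {}, None, stages=STAGES)
        assert [r.window_idx for r in regions] == [10, 40, 80]

    def test_output_pairwise_non_overlapping(self, grid, rng):
        a = rng.uniform(0, 10, grid.n_windows)
        b = rng.uniform(0, 10, grid.n_windows)
        masks, accs = self._tracks(grid, {"sA": a, "sB": b})
        # only top half accessible
        for st in STAGES:
            masks[st].values[:] = accs[st].values > 5
        regions = build_open_regions(masks, accs, {}, None, stages=STAGES)
        ivs = sorted((r.start, r.end) for r in regions)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_motif_content_filter_drops_zero_signal(self, grid, rng):
        a = np.zeros(grid.n_windows)
        a[10] = 5.0  # motif-rich
        a[80] = 6.0  # motif-dead
        masks, accs = self._tracks(grid, {"sA": a, "sB": np.zeros(grid.n_windows)})
        motif_vals = np.zeros(grid.n_windows)
        motif_vals[8:13] = 7.0
        motif = {"m": WindowTrack(grid, motif_vals)}
        refs = [ReferenceEnhancer("chr1", 450, 950, frozenset({"D"}))]
        regions = build_open_regions(masks, accs, motif, refs, stages=STAGES)
        assert [r.window_idx for r in regions] == [10]
        assert regions[0].overlaps_reference

    def test_no_accessible_windows_errors(self, grid):
        z = np.zeros(grid.n_windows)
        masks, accs = self._tracks(grid, {"sA": z, "sB": z})
        with pytest.raises(ValueError):
            build_open_regions(masks, accs, {}, None, stages=STAGES)


class TestAssignCandidateDomains:
    @pytest.fixture()
    def genes(self):
        return [
            GeneModel("gA", "chr1", "+", 1000, 1000, 2000),
            GeneModel("gB", "chr1", "+", 5000, 5000, 6000),
            GeneModel("gC", "chr1", "+", 20_000, 20_000, 21_000),
        ]

    @pytest.fixture()
    def atlas(self):
        return ExpressionAtlas(
            gene_domains={"gA": {"d1", "d2"}, "gB": {"d2", "d3"}, "gC": set()},
            domain_stage={"d1": "sA", "d2": "sA", "d3": "sB"},
        )

    def test_union_of_neighbor_domains(self, genes, atlas):
        region = _region(0, start=3000)
        out = assign_candidate_domains([region], genes, atlas)
        assert out[0].candidate_domains == {"d1", "d2", "d3"}
        assert {g for g, _ in out[0].neighbors} == {"gA", "gB"}

    def test_unannotated_neighbors_discarded(self, genes, atlas):
        region = _region(0, start=19_000)  # nearest: gC (unannotated), gB
        out = assign_candidate_domains([region], genes, atlas)
        # gB is second nearest and annotated, so the region survives
        assert out and "d2" in out[0].candidate_domains
        far = _region(0, chrom="chrZ", start=0)
        assert assign_candidate_domains([far], genes, atlas) == []

    def test_overlapping_gene_distance_zero(self, genes, atlas):
        region = _region(0, start=1200)
        out = assign_candidate_domains([region], genes, atlas)
        assert dict(out[0].neighbors)["gA"] == 0


class TestBuildTrainingSets:
    def _atlas(self):
        return ExpressionAtlas(
            gene_domains={"gA": {"D"}, "gB": set()},
            domain_stage={"D": "sA"},
        )

    def _regions(self, n_pos, n_neg):
        regions = []
        for i in range(n_pos):
            regions.append(
                _region(
                    i * 20,
                    start=i * 1000,
                    neighbors=[("gA", 100)],
                    candidate_domains=frozenset({"D"}),
                )
            )
        for i in range(n_neg):
            regions.append(
                _region(
                    1000 + i * 20,
                    start=100_000 + i * 1000,
                    neighbors=[("gB", 100)],
                    candidate_domains=frozenset(),
                )
            )
        return regions

    def test_split_arithmetic(self):
        ts = build_training_sets("D", self._regions(80, 120), self._atlas(), "sA", seed=0)
        assert len(ts.pos_train) == 60 and len(ts.pos_test) == 20
        assert len(ts.neg_train) == 60 and len(ts.neg_test) == 20

    def test_positive_cap(self):
        ts = build_training_sets(
            "D", self._regions(600, 700), self._atlas(), "sA", seed=0, max_positives=500
        )
        assert len(ts.pos_train) + len(ts.pos_test) == 500

    def test_reference_overlap_excluded(self):
        regions = self._regions(15, 15)
        for r in regions[:3]:
            r.overlaps_reference = True
        ts = build_training_sets("D", regions, self._atlas(), "sA", seed=0)
        assert len(ts.pos_train) + len(ts.pos_test) == 12

    def test_distance_beyond_5kb_not_positive(self):
        regions = self._regions(16, 16)
        for r in regions[:3]:
            r.neighbors = [("gA", 7000)]  # annotated but too far: not a positive
        ts = build_training_sets("D", regions, self._atlas(), "sA", seed=0)
        assert len(ts.pos_train) + len(ts.pos_test) == 13

    def test_insufficient_positives_raises(self):
        with pytest.raises(InsufficientTrainingData):
            build_training_sets("D", self._regions(5, 50), self._atlas(), "sA", seed=0)

    def test_seeded_determinism(self):
        regions = self._regions(40, 200)
        a = build_training_sets("D", regions, self._atlas(), "sA", seed=3)
        b = build_training_sets("D", regions, self._atlas(), "sA", seed=3)
        assert [r.window_idx for r in a.neg_train] == [r.window_idx for r in b.neg_train]


class TestFeaturize:
    def _inputs(self, grid, S=3.0, support="specific", fpkm=0.5, z=2.0):
        from regmap.associations import AssociationResult

        track = WindowTrack(grid, np.full(grid.n_windows, z))
        rec = TFRecord("tf", "m", {"sA": fpkm, "sB": 1.0})
        res = AssociationResult("tf", "D", "p1K", 1, 1, 1, 10, p_value=10.0 ** (-S))
        return (
            {"m": track},
            {("tf", "D"): res},
            {("tf", "D"): support},
            [rec],
        )

    def test_product_structure(self, small_grid):
        tracks, assoc, supports, recs = self._inputs(small_grid, S=3, fpkm=0.5, z=2)
        region = _region(0, acc=(0.7, 0.2))
        X = featurize_regions([region], "D", tracks, assoc, supports, recs, "sA")
        assert X.shape == (1, 3)
        assert X[0, 0] == pytest.approx(2 * 3 * 1 * 0.5)  # Z*S*E*R
        assert X[0, 1:].tolist() == [0.7, 0.2]

    def test_unsupported_tf_zeroes_feature(self, small_grid):
        tracks, assoc, supports, recs = self._inputs(small_grid, support="none")
        region = _region(0)
        X = featurize_regions([region], "D", tracks, assoc, supports, recs, "sA")
        assert X[0, 0] == 0.0

    def test_missing_association_zeroes_feature(self, small_grid):
        tracks, _, supports, recs = self._inputs(small_grid)
        region = _region(0)
        X = featurize_regions([region], "D", tracks, {}, supports, recs, "sA")
        assert X[0, 0] == 0.0

    def test_features_nonnegative(self, small_grid, rng):
        tracks, assoc, supports, recs = self._inputs(small_grid)
        regions = [_region(i, acc=tuple(rng.uniform(0, 5, 2))) for i in range(5)]
        X = featurize_regions(regions, "D", tracks, assoc, supports, recs, "sA")
        assert np.all(X >= 0)

    def test_unknown_motif_errors(self, small_grid):
        tracks, assoc, supports, _ = self._inputs(small_grid)
        recs = [TFRecord("tf", "missing", {"sA": 1.0})]
        with pytest.raises(KeyError):
            featurize_regions([_region(0)], "D", tracks, assoc, supports, recs, "sA")


class TestTrainAndScore:
    def test_noise_free_labels_recovered(self, rng):
        """A linear rule is learned exactly: held-out AUROC 1, near-zero residuals."""
        n, p = 120, 6
        X = rng.uniform(0, 3, size=(n, p))
        y = (rng.random(n) < 0.5).astype(float)
        # the first feature carries the label exactly: the generating model
        # is y = 1*x0 + 0*rest, so an exact linear fit exists
        X[:, 0] = y + 0.0
        n_train = int(0.75 * n)
        model = train_enhancer_model(
            X[:n_train], y[:n_train], [f"m{i}" for i in range(4)], ["sA", "sB"],
            ridge_lambda=1e-8,
        )
        scores = score_regions(model, X[n_train:])
        auroc, _ = roc_auc(scores, y[n_train:].astype(bool))
        assert auroc == 1.0
        assert np.allclose(scores, y[n_train:], atol=1e-4)

    def test_regression_targets_interpolated(self, rng):
        n, p = 50, 5
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + 2.0
        model = train_enhancer_model(
            X, y, [f"m{i}" for i in range(3)], ["sA", "sB"], ridge_lambda=1e-10
        )
        assert np.allclose(score_regions(model, X), y, atol=1e-5)

    def test_all_zero_features_predict_label_mean(self):
        X = np.zeros((10, 3))
        y = np.array([1.0] * 4 + [0.0] * 6)
        model = train_enhancer_model(X, y, ["m0"], STAGES, ridge_lambda=1e-6)
        assert model.beta == pytest.approx(0.4)
        assert np.allclose(model.coef, 0.0)

    def test_determinism_under_duplication(self, rng):
        X = rng.uniform(size=(20, 4))
        y = (rng.random(20) < 0.5).astype(float)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        m1 = train_enhancer_model(np.vstack([X, X]), np.r_[y, y], ["m0", "m1"], STAGES)
        m2 = train_enhancer_model(np.vstack([X, X]), np.r_[y, y], ["m0", "m1"], STAGES)
        assert np.array_equal(m1.coef, m2.coef) and m1.beta == m2.beta

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_enhancer_model(np.eye(4), np.ones(4), ["m0", "m1"], STAGES)

    def test_nonfinite_features_rejected(self):
        X = np.zeros((4, 4))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            train_enhancer_model(X, np.array([0, 1, 0, 1.0]), ["m0", "m1"], STAGES)

    def test_dimension_mismatch_on_scoring(self):
        model = EnhancerModel("D", ["m0"], STAGES, np.array([1.0]), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            score_regions(model, np.zeros((3, 5)))

    def test_score_batch_equals_loop(self, rng):
        model = EnhancerModel(
            "D", ["m0", "m1"], STAGES, rng.normal(size=2), rng.normal(size=2), 0.3
        )
        X = rng.normal(size=(7, 4))
        batch = score_regions(model, X)
        singles = [score_regions(model, X[i : i + 1])[0] for i in range(7)]
        assert np.allclose(batch, singles)


class TestGoodModelGate:
    @pytest.mark.parametrize(
        "test_auc,rfvo,expected",
        [
            (0.55, 0.72, True),
            (0.59, 0.65, False),
            (0.61, None, True),
            (None, 0.71, True),
            (0.60, 0.70, False),  # strict inequalities
        ],
    )
    def test_threshold_rule(self, test_auc, rfvo, expected):
        assert good_model_gate(test_auc, rfvo) is expected

    def test_requires_one_metric(self):
        with pytest.raises(ValueError):
            good_model_gate(None, None)


class TestAnnotateGenomeWide:
    def _setup(self, rng, n=40):
        atlas = ExpressionAtlas(
            gene_domains={"gA": {"D"}, "gB": set()},
            domain_stage={"D": "sA"},
        )
        regions = []
        for i in range(n):
            neighbor = "gA" if i % 2 == 0 else "gB"
            regions.append(
                _region(i, start=i * 1000, neighbors=[(neighbor, 100)])
            )
        scores = np.arange(n, dtype=float)
        return atlas, regions, {"D": scores}

    def test_top_percentile_and_neighbor_condition(self, rng):
        atlas, regions, scores = self._setup(rng)
        df = annotate_genome_wide(scores, regions, atlas, top_percent=5.0)
        # threshold at the 95th percentile of 0..39; only even (gA) regions
        assert set(df["window_idx"]) == {38}
        assert (df["percentile"] >= 95).all()

    def test_below_percentile_not_assigned(self, rng):
        atlas, regions, scores = self._setup(rng)
        df = annotate_genome_wide(scores, regions, atlas, top_percent=5.0)
        assert 0 not in set(df["window_idx"])

    def test_multiple_domains_per_region(self, rng):
        atlas = ExpressionAtlas(
            gene_domains={"gA": {"D1", "D2"}},
            domain_stage={"D1": "sA", "D2": "sA"},
        )
        regions = [_region(i, start=i * 1000, neighbors=[("gA", 50)]) for i in range(10)]
        scores = {"D1": np.arange(10.0), "D2": np.arange(10.0)}
        df = annotate_genome_wide(scores, regions, atlas, top_percent=10.0)
        assert sorted(df[df["window_idx"] == 9]["domain"]) == ["D1", "D2"]


class TestRankStatistic:
    def test_rank_first_is_one(self):
        pct = {"D1": 99.0, "D2": 50.0, "D3": 10.0, "D4": 5.0, "D5": 1.0}
        assert rank_statistic(pct, "D1") == 1.0

    def test_rank_last_is_zero(self):
        pct = {"D1": 99.0, "D2": 50.0, "D3": 10.0, "D4": 5.0, "D5": 1.0}
        assert rank_statistic(pct, "D5") == 0.0

    def test_middle_rank(self):
        pct = {"D1": 99.0, "D2": 50.0, "D3": 10.0}
        assert rank_statistic(pct, "D2") == pytest.approx(0.5)

    def test_single_candidate(self):
        assert rank_statistic({"D1": 10.0}, "D1") == 1.0

    def test_absent_true_domain(self):
        assert rank_statistic({"D1": 10.0}, "D9") is None


class TestModelSerialization:
    def test_round_trip(self, tmp_path, rng):
        model = EnhancerModel(
            "D",
            [f"m{i}" for i in range(5)],
            STAGES,
            rng.normal(size=5),
            rng.normal(size=2),
            float(rng.normal()),
            metadata={"seed": 1},
        )
        write_model(model, tmp_path / "m.tsv", tmp_path / "m.json")
        back = read_model(tmp_path / "m.tsv", tmp_path / "m.json")
        assert back.domain == "D"
        assert np.allclose(back.coef, model.coef)
        assert back.beta == pytest.approx(model.beta)


def test_score_percentiles_inclusive():
    pct = score_percentiles(np.array([1.0, 2.0, 2.0, 5.0]))
    assert pct.tolist() == [25.0, 75.0, 75.0, 100.0]
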