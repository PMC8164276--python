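"""Heatmap construction, pixel-to-gene mapping, and leader-gene extraction rules."""

import numpy as np
import pytest

import genecam as g
from genecam.attribution import (
    GeneRanking,
    GeneScore,
    Heatmap,
    extract_leader_genes_pairwise,
    pixel_to_gene_scores,
    upsample_heatmap,
)
from genecam.preprocessing import PAD, GeneLayout


def _ranking(genes, cls="class0"):
    return GeneRanking(cls, "pairwise", [GeneScore(gene, 1.0, i) for i, gene in enumerate(genes)])


class TestUpsampling:
    def test_constant_map_stays_constant(self):
        hm = upsample_heatmap(Heatmap("s", 0, np.full(4, 0.7)), 16)
        np.testing.assert_allclose(hm.upsampled, 0.7)

    def test_two_point_ramp_is_monotone(self):
        hm = upsample_heatmap(Heatmap("s", 0, np.array([0.0, 1.0])), 4)
        assert (np.diff(hm.upsampled) >= 0).all()
        assert hm.upsampled[0] == 0.0 and hm.upsampled[-1] == 1.0

    def test_peak_lands_at_middle_coarse_center(self):
        hm = upsample_heatmap(Heatmap("s", 0, np.array([0.0, 1.0, 0.0])), 6)
        # the middle coarse center sits between pixels 2 and 3
        peak = np.flatnonzero(hm.upsampled == hm.upsampled.max())
        assert set(peak) == {2, 3}

    def test_range_preserved(self):
        rng = np.random.default_rng(0)
        hm = upsample_heatmap(Heatmap("s", 0, rng.uniform(0, 1, 7)), 50)
        assert hm.upsampled.min() >= 0 and hm.upsampled.max() <= 1


class TestPixelToGene:
    def _layout(self):
        return GeneLayout(["gA", "gB", PAD, "gC"])

    def test_hot_pixel_maps_to_its_gene(self):
        hm = Heatmap("s", 0, None, upsampled=np.array([0.1, 0.9, 0.5, 0.2]))
        scores = pixel_to_gene_scores(hm, self._layout())
        best = max(scores, key=lambda s: s.score)
        assert best.gene_id == "gB" and best.pixel_index == 1

    def test_padding_pixels_are_skipped(self):
        hm = Heatmap("s", 0, None, upsampled=np.array([0.1, 0.9, 0.5, 0.2]))
        scores = pixel_to_gene_scores(hm, self._layout())
        assert len(scores) == 3
        assert all(s.gene_id != PAD for s in scores)

    def test_layout_permutation_permutes_scores(self):
        hm = Heatmap("s", 0, None, upsampled=np.array([0.1, 0.9, 0.5, 0.2]))
        base = {s.gene_id: s.score for s in pixel_to_gene_scores(hm, self._layout())}
        permuted_layout = GeneLayout(["gC", "gA", PAD, "gB"])
        permuted = {s.gene_id: s.score for s in pixel_to_gene_scores(hm, permuted_layout)}
        assert permuted == {"gC": 0.1, "gA": 0.9, "gB": 0.2}
        assert base == {"gA": 0.1, "gB": 0.9, "gC": 0.2}

    def test_length_mismatch_is_an_error(self):
        hm = Heatmap("s", 0, None, upsampled=np.zeros(3))
        with pytest.raises(ValueError, match="length"):
            pixel_to_gene_scores(hm, self._layout())


class TestPairwiseIntersection:
    def test_identical_rankings_give_their_prefix(self):
        r = _ranking(["g1", "g2", "g3", "g4"])
        out = extract_leader_genes_pairwise([r, r], top_n=3, pool_depth=4)
        assert out.genes == ["g1", "g2", "g3"]

    def test_disjoint_rankings_give_empty_result_with_warning(self):
        with pytest.warns(UserWarning, match="intersection"):
            out = extract_leader_genes_pairwise(
                [_ranking(["g1", "g2"]), _ranking(["g3", "g4"])], top_n=2, pool_depth=2
            )
        assert out.genes == []

    def test_mean_rank_with_lexicographic_tie_break(self):
        # mean ranks are all 2; lexicographic order decides: g1, g2
        a, b = _ranking(["g1", "g2", "g3"]), _ranking(["g3", "g2", "g1"])
        out = extract_leader_genes_pairwise([a, b], top_n=2, pool_depth=3)
        assert out.genes == ["g1", "g2"]
        assert [s.score for s in out.scores] == [2.0, 2.0]

    def test_pool_depth_limits_candidates(self):
        a, b = _ranking(["g1", "g2", "g3"]), _ranking(["g2", "g3", "g1"])
        with pytest.warns(UserWarning):
            out = extract_leader_genes_pairwise([a, b], top_n=3, pool_depth=1)
        assert out.genes == []  # top-1 pools {g1} and {g2} do not intersect

    def test_mixed_focal_classes_are_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            extract_leader_genes_pairwise(
                [_ranking(["g1"], "class0"), _ranking(["g1"], "class1")]
            )


@pytest.fixture(scope="module")
def trained(tiny_dataset, tiny_configs):
    pconfig, cconfig, tconfig = tiny_configs
    images, layout, _ = g.preprocess_dataset(tiny_dataset.expression, pconfig)
    names = sorted(tiny_dataset.labels.unique())
    y = np.array([names.index(tiny_dataset.labels[img.sample_id]) for img in images])
    model = g.build_model(cconfig, seed=1, layout=layout)
    g.train_fold(model, images, y, tconfig)
    return model, images, layout


class TestWithTrainedModel:

    def test_coarse_map_length_follows_pooling(self, trained):
        model, images, layout = trained
        hm = g.compute_cam(model, images[0], 0)
        assert len(hm.coarse) == layout.image_length // 2 // 2 // 2

    def test_heatmap_normalized_to_unit_max(self, trained):
        model, images, _ = trained
        hm = g.compute_cam(model, images[0], 0)
        assert 0 <= hm.coarse.min() and hm.coarse.max() == pytest.approx(1.0)

    def test_zero_head_yields_zero_heatmap(self, trained):
        model, images, _ = trained
        saved = model.net.head.W.value.copy(), model.net.head.b.value.copy()
        model.net.head.W.value[...] = 0.0
        model.net.head.b.value[...] = 0.0
        try:
            hm = g.compute_cam(model, images[0], 0)
            np.testing.assert_array_equal(hm.coarse, 0.0)
        finally:
            model.net.head.W.value[...] = saved[0]
            model.net.head.b.value[...] = saved[1]

    def test_invalid_target_class_is_an_error(self, trained):
        model, images, _ = trained
        with pytest.raises(ValueError, match="class"):
            g.compute_cam(model, images[0], 99)

    def test_occlusion_of_padding_pixel_is_exactly_zero(self, trained):
        model, images, layout = trained
        imp = g.occlusion_importance(model, images[0], 0)
        assert len(imp) == layout.image_length
        pad_positions = np.flatnonzero(layout.is_padding())
        if len(pad_positions):
            np.testing.assert_array_equal(imp[pad_positions], 0.0)

    def test_occlusion_window_arithmetic(self, trained):
        model, images, layout = trained
        imp = g.occlusion_importance(model, images[0], 0, window=5)
        assert len(imp) == layout.image_length - 5 + 1


class TestAggregation:
    def test_single_sample_aggregate_equals_its_scores(self, tiny_dataset, tiny_cv):
        cls = tiny_cv.class_names[0]
        cls_idx = 0
        fr = next(
            fr for fr in tiny_cv.folds if (fr.y_true == cls_idx).sum() > 0
        )
        pos = int(np.flatnonzero(fr.y_true == cls_idx)[0])
        img = fr.test_images[pos]
        hm = upsample_heatmap(g.compute_cam(fr.model, img, cls_idx), img.layout.image_length)
        single = {s.gene_id: s.score for s in pixel_to_gene_scores(hm, img.layout)}
        mini_cv = g.CVResult(
            class_names=tiny_cv.class_names,
            folds=[type(fr)(fr.fold, [img.sample_id], [img],
                            np.array([cls_idx]), np.array([cls_idx]),
                            fr.probabilities[pos : pos + 1], fr.model)],
            layout=tiny_cv.layout,
        )
        agg = g.aggregate_class_scores(mini_cv, tiny_dataset, cls)
        assert {k: pytest.approx(v) for k, v in agg.items()} == single

    def test_aggregate_scores_in_unit_interval(self, tiny_dataset, tiny_cv):
        agg = g.aggregate_class_scores(tiny_cv, tiny_dataset, "class0")
        assert ((agg >= 0) & (agg <= 1)).all()

    def test_multiwise_ranking_is_deterministic(self, tiny_dataset, tiny_cv):
        r1 = g.extract_leader_genes_multiwise(tiny_cv, tiny_dataset, "class0", top_n=10)
        r2 = g.extract_leader_genes_multiwise(tiny_cv, tiny_dataset, "class0", top_n=10)
        assert r1.genes == r2.genes
        assert [s.score for s in r1.scores] == [s.score for s in r2.scores]

    def test_top_n_truncates_to_retained_genes_with_warning(self, tiny_dataset, tiny_cv):
        with pytest.warns(UserWarning, match="retained"):
            r = g.extract_leader_genes_multiwise(tiny_cv, tiny_dataset, "class0", top_n=10_000)
        assert len(r.genes) == len(tiny_cv.layout.genes)

    def test_unknown_class_is_an_error(self, tiny_dataset, tiny_cv):
        with pytest.raises(ValueError, match="unknown"):
            g.aggregate_class_scores(tiny_cv, tiny_dataset, "not-a-class")
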