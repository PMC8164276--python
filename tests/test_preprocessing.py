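"""Transform, filter, layout and embedding contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genecam as g
from genecam.preprocessing import (
    PAD,
    GeneLayout,
    IntensityScaler,
    TransformedMatrix,
    ValidationError,
    build_gene_layout,
    embed_samples,
    fit_intensity_scaler,
    log_transform,
    variance_filter,
)


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


class TestLogTransform:
    @pytest.mark.parametrize("x, y", [(0, 0), (3, 2), (1023, 10), (1, 1), (7, 3)])
    def test_known_values(self, x, y):
        out = log_transform(_matrix([[x]]))
        assert out.values.iloc[0, 0] == pytest.approx(y, abs=1e-12)

    def test_matches_formula_on_grid(self):
        grid = np.concatenate([np.linspace(0, 10, 101), np.logspace(0, 6, 50)])
        out = log_transform(_matrix(grid[:, None]))
        np.testing.assert_allclose(
            out.values.to_numpy().ravel(), np.log2(grid + 1.0), atol=1e-12
        )

    def test_negative_value_names_gene_and_sample(self):
        with pytest.raises(ValidationError, match=r"gB.*s1"):
            log_transform(_matrix([[1, 2], [3, -0.5]], genes=["gA", "gB"]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e9), min_size=1, max_size=20))
    def test_non_negative_and_monotone(self, xs):
        out = log_transform(_matrix(np.array(xs)[:, None])).values.to_numpy().ravel()
        assert (out >= 0).all()
        order = np.argsort(xs)
        assert (np.diff(out[order]) >= 0).all()


class TestVarianceFilter:
    def test_constant_gene_removed(self):
        tm = TransformedMatrix(_matrix([[5, 5, 5, 5], [0, 2, 4, 6]]))
        _, retained = variance_filter(tm, g.PreprocessConfig())
        assert retained == ["g1"]

    def test_population_variance_boundary(self):
        # g0: population variance 8/3 > 1 -> retained
        # g1: population variance exactly 1.0 (floating-point exact) -> removed (strict >)
        tm = TransformedMatrix(_matrix([[0, 2, 4, 2], [2, 2, 4, 4]]))
        assert tm.values.iloc[1].var(ddof=0) == 1.0
        _, retained = variance_filter(tm, g.PreprocessConfig(variance_threshold=1.0))
        assert retained == ["g0"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tm = TransformedMatrix(_matrix(rng.uniform(0, 8, size=(30, 6))))
        once, retained1 = variance_filter(tm, g.PreprocessConfig())
        twice, retained2 = variance_filter(once, g.PreprocessConfig())
        assert retained1 == retained2
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError, match="2 samples"):
            variance_filter(TransformedMatrix(_matrix([[1.0]])), g.PreprocessConfig())


class TestGeneLayout:
    def test_three_genes_pad_to_four(self):
        tm = TransformedMatrix(_matrix([[0, 9], [0, 5], [0, 7]]))
        layout = build_gene_layout(tm, ["g0", "g1", "g2"], g.PreprocessConfig(image_length=4))
        assert layout.pixels == ["g0", "g2", "g1", PAD]  # variance-descending
        assert layout.n_padding == 1

    def test_truncation_drops_lowest_variance(self):
        values = np.array([[0, v] for v in (6, 5.2, 4.4, 3.4, 2)], dtype=float)
        tm = TransformedMatrix(_matrix(values))
        layout = build_gene_layout(tm, [f"g{i}" for i in range(5)], g.PreprocessConfig(image_length=4))
        assert "g4" not in layout.pixels
        assert len(layout.genes) == 4

    def test_deterministic_with_lexicographic_ties(self):
        tm = TransformedMatrix(_matrix([[0, 4], [0, 4], [0, 4]], genes=["b", "c", "a"]))
        cfg = g.PreprocessConfig(image_length=4)
        layout1 = build_gene_layout(tm, ["b", "c", "a"], cfg)
        layout2 = build_gene_layout(tm, ["b", "c", "a"], cfg)
        assert layout1.pixels == layout2.pixels == ["a", "b", "c", PAD]

    def test_empty_retained_advises_lower_threshold(self):
        tm = TransformedMatrix(_matrix([[1, 1]]))
        with pytest.raises(ValidationError, match="threshold"):
            build_gene_layout(tm, [], g.PreprocessConfig())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_pixel_gene_bijection(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(1, 30))
        length = int(rng.integers(n_genes, n_genes + 10))
        genes = [f"g{i:03d}" for i in range(n_genes)]
        pixels = list(rng.permutation(genes)) + [PAD] * (length - n_genes)
        layout = GeneLayout(pixels)
        for gene, pixel in layout.gene_to_pixel.items():
            assert layout.pixels[pixel] == gene
        assert sorted(layout.genes) == genes


class TestEmbedding:
    def test_worked_min_max_example(self):
        tm = TransformedMatrix(_matrix([[0, 2], [4, 2]]))
        cfg = g.PreprocessConfig(image_length=2)
        layout = GeneLayout(["g1", "g0"])  # g1 has higher variance
        images = embed_samples(tm, layout, cfg)
        np.testing.assert_allclose(images[0].intensities, [1.0, 0.0])
        np.testing.assert_allclose(images[1].intensities, [0.5, 0.5])

    def test_degenerate_range_maps_to_lower_bound(self):
        tm = TransformedMatrix(_matrix([[3.0, 3.0], [3.0, 3.0]]))
        layout = GeneLayout(["g0", "g1", PAD])
        images = embed_samples(tm, layout, g.PreprocessConfig(image_length=3))
        np.testing.assert_allclose(images[0].intensities, [0.0, 0.0, 0.0])

    def test_padding_gets_scaled_zero(self):
        tm = TransformedMatrix(_matrix([[2.0, 6.0], [4.0, 8.0]]))
        layout = GeneLayout(["g0", "g1", PAD])
        images = embed_samples(tm, layout, g.PreprocessConfig(image_length=3))
        scaler = fit_intensity_scaler(tm, ["g0", "g1"], g.PreprocessConfig(image_length=3))
        assert images[0].intensities[2] == scaler.pad_value
        # y=0 lies below the fitted minimum here, so the scaled zero clips to 0
        assert scaler.pad_value == 0.0

    def test_global_max_hits_upper_bound(self):
        tm = TransformedMatrix(_matrix([[1.0, 5.0]]))
        layout = GeneLayout(["g0"])
        images = embed_samples(tm, layout, g.PreprocessConfig(image_length=1))
        assert images[1].intensities[0] == 1.0

    def test_out_of_range_values_clip(self):
        tm = TransformedMatrix(_matrix([[1.0, 5.0]]))
        cfg = g.PreprocessConfig(image_length=1)
        layout = GeneLayout(["g0"])
        scaler = IntensityScaler(2.0, 4.0)
        images = embed_samples(tm, layout, cfg, scaler=scaler)
        assert images[0].intensities[0] == 0.0
        assert images[1].intensities[0] == 1.0

    def test_missing_layout_gene_is_an_error(self):
        tm = TransformedMatrix(_matrix([[1.0, 2.0]]))
        layout = GeneLayout(["nope"])
        with pytest.raises(ValidationError, match="nope"):
            embed_samples(tm, layout, g.PreprocessConfig(image_length=1))

    def test_monotone_in_raw_counts(self):
        cfg = g.PreprocessConfig(image_length=2)
        base = _matrix([[4.0, 9.0], [1.0, 20.0]])
        bumped = base.copy()
        bumped.iloc[0, 0] = 7.0
        tm, tm2 = log_transform(base), log_transform(bumped)
        layout = build_gene_layout(tm, list(tm.genes), cfg)
        scaler = fit_intensity_scaler(tm, layout.genes, cfg)
        before = embed_samples(tm, layout, cfg, scaler=scaler)
        after = embed_samples(tm2, layout, cfg, scaler=scaler)
        pix = layout.gene_to_pixel["g0"]
        assert after[0].intensities[pix] >= before[0].intensities[pix]

    def test_images_always_have_configured_length(self):
        ds = g.generate_dataset(
            g.SyntheticSpec(n_genes=50, n_classes=2, samples_per_class=(4, 4), n_markers_per_class=5, seed=3)
        )
        for length in (16, 64, 200):
            images, layout, _ = g.preprocess_dataset(
                ds.expression, g.PreprocessConfig(image_length=length)
            )
            assert layout.image_length == length
            assert all(len(img.intensities) == length for img in images)
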