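"""Dense expansion: mirror-pad geometry, weight transplantation, heatmap
invariants, and equivalence with sliding-window patch inference.

The fast equivalence check here runs on a reduced 488-px frame (which
pads to a 512-px canvas); the full-frame check is part of the acceptance
suite.
"""

import numpy as np
import pytest

import rcmseg as r
from rcmseg.dense import ExpansionConfig, mirror_pad, oracle_grid_offset

from conftest import SMALL


@pytest.fixture(scope="module")
def random_model():
    """Randomly initialized (untrained-weights) float64 classifier, marked
    trained so the inference paths accept it."""
    m = r.build_model(r.BackboneSpec.tiny(), seed=9, dtype=np.float64)
    m.trained = True
    return m


@pytest.fixture(scope="module")
def reduced_slice():
    p = r.GeneratorParams(**{**SMALL, "image_height": 488, "image_width": 488},
                          seed=12)
    return r.generate_slice(p, r.slice_rng(p, 0, 0, 0))


class TestMirrorPad:
    def test_1000_becomes_1024(self):
        out = mirror_pad(np.zeros((1000, 1000)))
        assert out.shape == (1024, 1024)

    def test_constant_stays_constant(self):
        out = mirror_pad(np.full((1000, 1000), 7.0))
        assert np.all(out == 7.0)

    def test_symmetric_reflection_indices(self):
        """With a 12-px pad, padded row i equals original row 11 - i."""
        ramp = np.arange(1000, dtype=float)[:, None] * np.ones((1, 1000))
        out = mirror_pad(ramp)
        for i in range(12):
            assert np.array_equal(out[i, 12:-12], ramp[11 - i])
        assert np.array_equal(out[12:-12, 12:-12], ramp)

    def test_divisibility_error_suggests_pad(self):
        with pytest.raises(ValueError, match="suggested"):
            mirror_pad(np.zeros((1000, 1000)),
                       ExpansionConfig(mirror_pad_total=10))

    def test_crop_round_trip(self, reduced_slice):
        hm_geom = r.Heatmap(
            probabilities=np.dstack([mirror_pad(reduced_slice.image.astype(float))] * 2),
            pad_per_side=12, original_shape=reduced_slice.image.shape)
        assert np.array_equal(hm_geom.crop()[..., 0], reduced_slice.image)


class TestExpand:
    def test_requires_trained_model(self):
        m = r.build_model(r.BackboneSpec.tiny(), seed=0)
        with pytest.raises(RuntimeError, match="trained"):
            r.expand(m)

    def test_grid_shape_at_full_frame(self, random_model, full_slice):
        dm = r.expand(random_model, ExpansionConfig())
        grid = dm.predict_grid(full_slice.image)
        assert grid.shape == (32, 32, 2)

    def test_zero_weights_give_bias_softmax(self, random_model, reduced_slice):
        """With an all-zero head weight matrix, every grid cell carries
        softmax of the biases, independent of the input."""
        dm = r.expand(random_model, ExpansionConfig())
        dm.conv_w[...] = 0.0
        dm.conv_b[...] = (0.3, -0.2)
        grid = dm.predict_grid(reduced_slice.image)
        expected = np.exp([0.3, -0.2]) / np.exp([0.3, -0.2]).sum()
        assert np.allclose(grid, expected, atol=1e-12)

    def test_transplanted_weights_match_head(self, random_model):
        dm = r.expand(random_model, ExpansionConfig())
        assert np.array_equal(dm.conv_w, random_model.head.params["w"])
        assert np.array_equal(dm.conv_b, random_model.head.params["b"])


class TestHeatmap:
    def test_channel_sums_one_everywhere(self, random_model, reduced_slice):
        hm = r.predict_heatmap(r.expand(random_model, ExpansionConfig()),
                               reduced_slice.image)
        assert hm.probabilities.shape == (512, 512, 2)
        assert np.allclose(hm.probabilities.sum(axis=-1), 1.0, atol=1e-6)

    def test_nearest_upsampling_is_blockwise_exact(self, random_model,
                                                   reduced_slice):
        cfg = ExpansionConfig(upsample_method="nearest")
        dm = r.expand(random_model, cfg)
        grid = dm.predict_grid(reduced_slice.image)
        hm = r.predict_heatmap(dm, reduced_slice.image)
        assert np.allclose(hm.probabilities[::32, ::32], grid, atol=1e-12)
        # every pixel equals its source cell
        assert np.allclose(hm.probabilities[35, 67], grid[1, 2], atol=1e-12)

    def test_constant_grid_upsamples_to_constant(self, random_model,
                                                 reduced_slice):
        dm = r.expand(random_model, ExpansionConfig())
        dm.conv_w[...] = 0.0
        hm = r.predict_heatmap(dm, reduced_slice.image)
        assert np.allclose(hm.probabilities, hm.probabilities[0, 0], atol=1e-9)

    def test_crop_returns_original_frame(self, random_model, reduced_slice):
        hm = r.predict_heatmap(r.expand(random_model, ExpansionConfig()),
                               reduced_slice.image)
        assert hm.crop().shape == (488, 488, 2)


class TestOracleEquivalence:
    def test_window_count_and_alignment(self, random_model, full_slice):
        cfg = ExpansionConfig(avgpool_kernel=8)
        grid = r.sliding_window_oracle(random_model, full_slice.image, 32, cfg)
        assert grid.shape == (25, 25, 2)  # (1024 - 256)/32 + 1 per axis
        assert oracle_grid_offset(cfg) == 4

    def test_constant_image_gives_constant_grid(self, random_model):
        img = np.full((488, 488), 55, np.uint8)
        grid = r.sliding_window_oracle(random_model, img, 32,
                                       ExpansionConfig(avgpool_kernel=8))
        assert np.allclose(grid, grid[0, 0], atol=1e-12)

    def test_dense_matches_sliding_window_with_pool8(self, random_model,
                                                     reduced_slice):
        """Pool kernel 8 makes the dense grid reproduce patch-classifier
        probabilities at every aligned window."""
        cfg = ExpansionConfig(avgpool_kernel=8)
        dm = r.expand(random_model, cfg)
        grid = dm.predict_grid(reduced_slice.image)
        oracle = r.sliding_window_oracle(random_model, reduced_slice.image,
                                         32, cfg)
        off = oracle_grid_offset(cfg)
        n = oracle.shape[0]
        delta = np.abs(oracle - grid[off:off + n, off:off + n])
        assert delta.max() <= 1e-5
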