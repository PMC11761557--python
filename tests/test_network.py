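"""Architecture contracts: shapes, decoder counts, attention algebra,
patch round-trips, branch independence, and trainability."""

import numpy as np
import pytest

from pointseg import autograd as ag
from pointseg.autograd import Tensor
from pointseg.network import (
    ModelConfig,
    PointGuidedAttention,
    SelfAttention,
    attention_core,
    build_model,
    patchify,
    unpatchify,
)


class TestConfig:
    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ModelConfig(backbone="vgg")
        with pytest.raises(ValueError):
            ModelConfig(n_gauss_branches=-1)
        with pytest.raises(ValueError):
            ModelConfig(patch_grid=0)
        with pytest.raises(ValueError):
            ModelConfig(pretrained=True)

    def test_default_backbone_is_34_layer_residual(self):
        cfg = ModelConfig()
        assert cfg.stage_blocks == (3, 4, 6, 3)
        assert cfg.channels == 64
        assert cfg.n_gauss_branches == 4
        assert cfg.patch_grid == 7


class TestForwardContracts:
    def test_output_shapes(self, tiny_model_config):
        model = build_model(tiny_model_config)
        x = Tensor(np.random.default_rng(0).random((1, 3, 32, 32)))
        seg, gauss = model.forward(x)
        assert seg.shape == (1, 2, 32, 32)
        assert gauss.shape == (1, tiny_model_config.n_gauss_branches, 32, 32)
        # softmax head: class probabilities sum to one
        assert np.allclose(seg.data.sum(axis=1), 1.0)
        assert gauss.data.min() >= 0 and gauss.data.max() <= 1

    def test_decoder_count_is_k_plus_one(self):
        model = build_model(ModelConfig(n_gauss_branches=1, backbone="tiny", patch_grid=2))
        assert len(model.gauss_decoders) + 1 == 2

    def test_predict_deterministic(self, tiny_model_config):
        model = build_model(tiny_model_config)
        img = np.random.default_rng(1).integers(0, 255, (40, 52, 3), dtype=np.uint8)
        a = model.predict(img)
        b = model.predict(img)
        assert np.array_equal(a.seg_prob, b.seg_prob)
        assert np.array_equal(a.gauss_maps, b.gauss_maps)
        assert a.seg_prob.shape == (40, 52)

    def test_gauss_branches_independent(self, tiny_model_config):
        """Zeroing one Gaussian decoder's parameters leaves the other
        Gaussian maps untouched."""
        model = build_model(tiny_model_config)
        img = np.random.default_rng(2).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        before = model.predict(img).gauss_maps.copy()
        for p in model.gauss_decoders[0].parameters():
            p.data[:] = 0.0
        after = model.predict(img).gauss_maps
        assert not np.array_equal(before[0], after[0])
        assert np.array_equal(before[1], after[1])

    def test_checkpoint_round_trip(self, tiny_model_config, tmp_path):
        model = build_model(tiny_model_config)
        model.save(tmp_path / "m.npz")
        clone = build_model(tiny_model_config)
        clone.load(tmp_path / "m.npz")
        img = np.random.default_rng(3).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        assert np.array_equal(model.predict(img).seg_prob, clone.predict(img).seg_prob)


class TestPatchify:
    def test_56_map_grid7_gives_49_patches_of_8(self):
        fm = np.arange(56 * 56, dtype=float).reshape(1, 56, 56)
        patches, orig = patchify(fm, grid=7)
        assert patches.shape == (49, 1, 8, 8)
        assert np.array_equal(unpatchify(patches, orig), fm)

    def test_57_map_padded_to_63(self):
        fm = np.random.default_rng(0).random((2, 57, 57))
        patches, orig = patchify(fm, grid=7)
        assert patches.shape == (49, 2, 9, 9)  # padded to 63 then split
        assert np.array_equal(unpatchify(patches, orig), fm)

    @pytest.mark.parametrize("shape,grid", [((1, 12, 12), 3), ((3, 20, 10), 4)])
    def test_round_trip(self, shape, grid):
        fm = np.random.default_rng(1).random(shape)
        patches, orig = patchify(fm, grid=grid)
        assert np.array_equal(unpatchify(patches, orig), fm)


class TestAttention:
    def _block(self, channels=6, grid=2, seed=0):
        return PointGuidedAttention(channels, grid, 2, np.random.default_rng(seed))

    def test_zero_guidance_gives_uniform_attention(self):
        """Zero Gaussian tokens and zero projection biases make Q=K=0, so
        softmax weights are uniform and each output token is the mean of
        the Value tokens."""
        blk = self._block()
        t, c = 4, 6
        rng = np.random.default_rng(5)
        seg_tokens = Tensor(rng.normal(size=(1, t, c)))
        zero_g = Tensor(np.zeros((1, t, c)))
        out = attention_core(seg_tokens, zero_g, blk.lq, blk.lk, blk.lv, c)
        v = blk.lv(seg_tokens).data
        expected = np.repeat(v.mean(axis=1, keepdims=True), t, axis=1)
        assert np.allclose(out.data, expected)

    def test_attention_rows_sum_to_one(self):
        blk = self._block()
        rng = np.random.default_rng(6)
        q = blk.lq(Tensor(rng.normal(size=(1, 5, 6))))
        k = blk.lk(Tensor(rng.normal(size=(1, 5, 6))))
        scores = ag.softmax(ag.matmul(q, ag.transpose(k, (0, 2, 1))) * (1 / np.sqrt(6)), axis=-1)
        assert np.allclose(scores.data.sum(axis=-1), 1.0)

    def test_branch_permutation_invariance(self):
        blk = self._block(channels=4, grid=2)
        rng = np.random.default_rng(7)
        seg = Tensor(rng.normal(size=(1, 4, 8, 8)))
        gs = [Tensor(rng.normal(size=(1, 4, 8, 8))) for _ in range(3)]
        out1 = blk(seg, gs)
        out2 = blk(seg, [gs[2], gs[0], gs[1]])
        assert np.allclose(out1.data, out2.data)

    def test_single_token_grid_output_is_own_value(self):
        blk = self._block(channels=3, grid=1)
        rng = np.random.default_rng(8)
        seg_tokens = Tensor(rng.normal(size=(1, 1, 3)))
        g_tokens = Tensor(rng.normal(size=(1, 1, 3)))
        out = attention_core(seg_tokens, g_tokens, blk.lq, blk.lk, blk.lv, 3)
        assert np.allclose(out.data, blk.lv(seg_tokens).data)

    def test_mismatched_shapes_rejected(self):
        blk = self._block(channels=4, grid=2)
        seg = Tensor(np.zeros((1, 4, 8, 8)))
        with pytest.raises(ValueError):
            blk(seg, [Tensor(np.zeros((1, 4, 6, 6)))])
        with pytest.raises(ValueError):
            blk(seg, [])

    def test_self_attention_runs_and_preserves_shape(self):
        blk = SelfAttention(4, 2, 2, np.random.default_rng(9))
        fm = Tensor(np.random.default_rng(10).normal(size=(1, 4, 10, 10)))
        assert blk(fm).shape == (1, 4, 10, 10)


def test_few_steps_decrease_loss(tiny_model_config):
    """End-to-end trainability: Adam on one synthetic batch strictly
    decreases the total loss within a few steps."""
    from pointseg.losses import total_loss
    from pointseg.autograd import Adam

    model = build_model(tiny_model_config)
    rng = np.random.default_rng(0)
    x = Tensor(rng.random((2, 3, 32, 32)))
    vor = rng.integers(0, 3, (2, 32, 32))
    clu = rng.integers(0, 3, (2, 32, 32))
    gm = rng.random((2, tiny_model_config.n_gauss_branches, 32, 32))
    opt = Adam(model.parameters(), lr=1e-3)
    losses = []
    for _ in range(5):
        seg, gauss = model.forward(x)
        loss, _ = total_loss(seg, vor, clu, gauss, gm)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert losses[-1] < losses[0]
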