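import math

import numpy as np
import pytest

from lungcbir.pairs import PairSample, make_contour_pairs
from lungcbir.simnet import (ContourNet, DetailNet, NetConfig,
                             ScoreFusionConfig, ValidationError,
                             build_cs_calculator, build_ds_calculator,
                             distance, load_checkpoint, pair_loss,
                             save_checkpoint, sigmoid, sim_c, sim_d, sscore,
                             train_calculator)


class TestSigmoid:
    def test_zero_is_half(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry_identity(self, rng):
        x = rng.normal(0, 10, 50)
        np.testing.assert_allclose(sigmoid(x), 1 - sigmoid(-x), atol=1e-15)

    def test_no_overflow_large_negative(self):
        v = sigmoid(-1000.0)
        assert 0 <= v < 1e-6

    def test_no_overflow_large_positive(self):
        assert 1 - sigmoid(1000.0) < 1e-6


class TestPairLoss:
    def test_chance_level_is_ln2(self):
        assert pair_loss([0.0], [1]) == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_prediction_goes_to_zero(self):
        assert pair_loss([30.0], [1]) < 1e-9
        assert pair_loss([-30.0], [0]) < 1e-9

    def test_antisymmetric_batch_equals_single(self, rng):
        """g(-s) = 1 - g(s) makes the batch {(s,1), (-s,0)} cost exactly
        what the single sample (s,1) costs."""
        for s in rng.normal(0, 3, 20):
            both = pair_loss([s, -s], [1, 0])
            one = pair_loss([s], [1])
            assert both == pytest.approx(one, abs=1e-12)

    def test_matches_per_sample_hand_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            s = rng.normal(0, 4, n)
            y = rng.integers(0, 2, n).astype(float)
            hand = np.mean([-yi * math.log(1 / (1 + math.exp(-si)))
                            - (1 - yi) * math.log(1 - 1 / (1 + math.exp(-si)))
                            for si, yi in zip(s, y)])
            assert pair_loss(s, y) == pytest.approx(hand, abs=1e-10)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValidationError):
            pair_loss([0.0], [2])
        with pytest.raises(ValidationError):
            pair_loss([], [])


class TestArchitectures:
    def test_cs_forward_shape_and_determinism(self, tiny_net_config, rng):
        model = build_cs_calculator(tiny_net_config)
        x = rng.normal(-700, 200, (4, 2, 32, 32))
        out = model.forward(x)
        assert out.shape == (4,) and np.isfinite(out).all()
        np.testing.assert_array_equal(out, model.forward(x))
        # identical constant pairs give identical logits
        c = np.full((2, 2, 32, 32), -500.0)
        o = model.forward(c)
        assert o[0] == pytest.approx(o[1], abs=1e-12)

    def test_cs_seed_reproducibility(self, tiny_net_config, rng):
        x = rng.normal(-700, 200, (2, 2, 32, 32))
        a = build_cs_calculator(tiny_net_config).forward(x)
        b = build_cs_calculator(tiny_net_config).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_cs_positional_encoding_breaks_patch_permutation(self,
                                                             tiny_net_config,
                                                             rng):
        """Swapping two 8x8 blocks of the input changes the logit: the
        positional embedding makes token order matter."""
        model = build_cs_calculator(tiny_net_config)
        x = rng.normal(-700, 200, (1, 2, 32, 32))
        xs = x.copy()
        xs[:, :, :8, :8], xs[:, :, :8, 8:16] = \
            x[:, :, :8, 8:16].copy(), x[:, :, :8, :8].copy()
        assert abs(model.forward(x)[0] - model.forward(xs)[0]) > 1e-8

    def test_ds_forward_shape(self, tiny_net_config, rng):
        model = build_ds_calculator(tiny_net_config)
        out = model.forward(rng.normal(-700, 200, (3, 2, 32, 32)))
        assert out.shape == (3,) and np.isfinite(out).all()

    def test_ds_residual_surgery(self, tiny_net_config, rng):
        """Zeroing a basic block's residual branch (its second conv and
        batch-norm affine) makes the block the identity-plus-shortcut
        map: ReLU(shortcut(x))."""
        model = build_ds_calculator(tiny_net_config)
        blk = model.blocks[0]          # stride-1, equal-width block
        blk.conv2.w.value[...] = 0.0
        blk.conv2.b.value[...] = 0.0
        blk.bn2.beta.value[...] = 0.0  # branch output identically zero
        x = rng.normal(0, 1, (2, tiny_net_config.widths[0], 8, 8))
        out = blk.forward(x, train=False)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)

    def test_ds_conv_head_more_position_sensitive_than_gap(self, rng):
        """Translating a bright blob in one channel must move the
        full-extent-conv head's logit much more than a global-average-
        pooling ablation sharing the same trunk weights. Shifts are
        multiples of the total stride (16) so the feature map shifts
        exactly; deltas are normalized by each head's response scale."""
        cfg = NetConfig(image_size=64, block_size=8, embed_dim=16, depth=1,
                        heads=2, widths=(4, 8, 8, 8), seed=0)
        conv_model = build_ds_calculator(cfg, head_mode="conv")
        gap_model = build_ds_calculator(cfg, head_mode="gap")
        for p_c, p_g in zip(conv_model.params()[:-2], gap_model.params()[:-2]):
            p_g.value[...] = p_c.value          # share the trunk
        xs = rng.normal(-700, 150, (16, 2, 64, 64))
        scale_c = conv_model.forward(xs).std()
        scale_g = gap_model.forward(xs).std()
        base = np.full((2, 64, 64), -700.0)
        for shift in (16, 32):
            a = base.copy()
            a[0, 8:16, 8:16] = 0.0
            b = base.copy()
            b[0, 8:16, 8 + shift:16 + shift] = 0.0
            dc = abs(conv_model.forward(a[None])[0]
                     - conv_model.forward(b[None])[0]) / scale_c
            dg = abs(gap_model.forward(a[None])[0]
                     - gap_model.forward(b[None])[0]) / scale_g
            assert dc > 1e-9           # the logit does change
            assert dc > 3 * dg         # and far more than the ablation's

    def test_config_validation(self):
        with pytest.raises(Exception):
            NetConfig(image_size=60, block_size=8).validate()
        with pytest.raises(Exception):
            NetConfig(learning_rate=-1.0).validate()


class TestTraining:
    def _toy_pairs(self, rng, n=12, size=32):
        out = []
        for i in range(n):
            a = rng.normal(-700, 100, (size, size))
            if i % 2:
                out.append(PairSample(np.stack([a, a + rng.normal(0, 5, a.shape)]),
                                      1, "contour", ("t", 0, "t", 0)))
            else:
                out.append(PairSample(np.stack([a, rng.normal(0, 100, a.shape)]),
                                      0, "contour", ("t", 0, "t", 1)))
        return out

    def test_zero_lr_keeps_loss_constant(self, tiny_net_config, rng):
        import dataclasses
        cfg = dataclasses.replace(tiny_net_config, learning_rate=0.0, epochs=3)
        model = build_cs_calculator(cfg)
        _, hist = train_calculator(model, self._toy_pairs(rng), cfg)
        assert hist[0] == pytest.approx(hist[-1], abs=1e-9)

    def test_overfits_single_repeated_positive(self, tiny_net_config, rng):
        import dataclasses
        cfg = dataclasses.replace(tiny_net_config, epochs=50, batch_size=1,
                                  learning_rate=0.01)
        a = rng.normal(-700, 100, (32, 32))
        pair = PairSample(np.stack([a, a]), 1, "contour", ("t", 0, "t", 0))
        model = build_cs_calculator(cfg)
        _, hist = train_calculator(model, [pair], cfg)
        assert hist[-1] < 0.01

    def test_training_reduces_loss_on_phantom_contour_task(self, phantom_cases):
        cfg = NetConfig(image_size=64, block_size=8, embed_dim=32, depth=2,
                        heads=2, batch_size=16, epochs=5, seed=1)
        pairs = make_contour_pairs(phantom_cases, 64, seed=9)
        model = build_cs_calculator(cfg)
        _, hist = train_calculator(model, pairs, cfg)
        assert hist[-1] < hist[0]

    def test_trained_cs_orders_identical_above_distant(self, phantom_cases):
        """After contour training, the identical pair (A, A) scores at
        least the median of (A, distant-layer) pairs, and the chance
        bar is cleared: mean loss < 0.5 within 10 epochs at 64x64."""
        cfg = NetConfig(image_size=64, epochs=10, seed=2)
        pairs = make_contour_pairs(phantom_cases, 120, seed=2)
        model, hist = train_calculator(build_cs_calculator(cfg), pairs, cfg)
        assert min(hist) < 0.5
        a = phantom_cases[0].slices[10]
        distant = [sim_c(model, a, c.slices[r])
                   for c in phantom_cases for r in (2, 17)]
        assert sim_c(model, a, a) >= np.median(distant)

    def test_empty_dataset_rejected(self, tiny_net_config):
        with pytest.raises(ValidationError):
            train_calculator(build_cs_calculator(tiny_net_config), [],
                             tiny_net_config)


@pytest.fixture(scope="module")
def models(tiny_net_config):
    return (build_cs_calculator(tiny_net_config),
            build_ds_calculator(tiny_net_config))


class TestScoring:

    def test_scores_in_unit_interval(self, models, rng):
        cs, ds = models
        a, b = rng.normal(-700, 200, (2, 32, 32))
        assert 0 <= sim_c(cs, a, b) <= 1
        assert 0 <= sim_d(ds, a, b) <= 1

    def test_shape_mismatch_rejected(self, models):
        cs, _ = models
        with pytest.raises(ValidationError):
            sim_c(cs, np.zeros((32, 32)), np.zeros((16, 16)))

    def test_sscore_arithmetic(self, models, monkeypatch):
        import lungcbir.simnet as sn
        cs, ds = models
        monkeypatch.setattr(sn, "sim_c", lambda *a: 0.8)
        monkeypatch.setattr(sn, "sim_d", lambda *a: 0.4)
        assert sn.sscore(None, None, cs, ds, ScoreFusionConfig(0.5)) == \
            pytest.approx(0.6)

    def test_alpha_endpoints(self, models, rng):
        cs, ds = models
        a, b = rng.normal(-700, 200, (2, 32, 32))
        assert sscore(a, b, cs, ds, ScoreFusionConfig(1.0)) == \
            pytest.approx(sim_c(cs, a, b))
        assert sscore(a, b, cs, ds, ScoreFusionConfig(0.0)) == \
            pytest.approx(sim_d(ds, a, b))

    def test_sscore_is_affine_combination(self, models, rng):
        cs, ds = models
        for _ in range(5):
            a, b = rng.normal(-700, 200, (2, 32, 32))
            sc, sd = sim_c(cs, a, b), sim_d(ds, a, b)
            s = sscore(a, b, cs, ds, ScoreFusionConfig(0.3))
            assert min(sc, sd) - 1e-12 <= s <= max(sc, sd) + 1e-12

    def test_distance_is_complement(self, models, rng):
        cs, ds = models
        a, b = rng.normal(-700, 200, (2, 32, 32))
        assert distance(a, b, cs, ds) == pytest.approx(
            1 - sscore(a, b, cs, ds))

    def test_alpha_out_of_range(self, models):
        cs, ds = models
        with pytest.raises(ValidationError):
            sscore(None, None, cs, ds, ScoreFusionConfig(1.5))


def test_checkpoint_round_trip(tiny_net_config, tmp_path, rng):
    x = rng.normal(-700, 200, (2, 2, 32, 32))
    for kind, builder in (("cs", build_cs_calculator), ("ds", build_ds_calculator)):
        model = builder(tiny_net_config)
        before = model.forward(x)
        save_checkpoint(tmp_path / f"{kind}.npz", model, kind)
        loaded = load_checkpoint(tmp_path / f"{kind}.npz")
        np.testing.assert_array_equal(before, loaded.forward(x))
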