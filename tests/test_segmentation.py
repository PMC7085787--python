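import numpy as np
import pytest
from skimage.measure import label

from pentascore import nn
from pentascore.config import RunConfig
from pentascore.segmentation import (
    EmptyReferenceError,
    UNetConfig,
    build_unet,
    compute_segmentation,
    oracle_segment,
    overlap_percentage,
    rasterize_trace,
    train_model,
)
from pentascore.sensor_io import interlock_endpoints, split_figures
from pentascore.synthgen import DrawingSpec, generate_trace

from conftest import make_trace


class TestRasterize:
    def test_pen_up_trace_leaves_no_ink(self, cfg):
        trace = make_trace([1] * 6, x=np.linspace(100, 700, 6), y=np.full(6, 400.0))
        img = rasterize_trace(trace, cfg)
        assert not img.any()

    def test_single_stroke_is_one_connected_component(self, cfg):
        n = 30
        trace = make_trace(
            [-1] + [0] * (n - 1),
            x=np.linspace(200, 1200, n),
            y=np.linspace(300, 900, n),
        )
        img = rasterize_trace(trace, cfg)
        assert img.any()
        assert label(img, connectivity=2).max() == 1

    def test_perfect_drawing_matches_its_own_masks(self, cfg, perfect_drawing):
        trace, truth = perfect_drawing
        split = split_figures(trace)
        interlock_endpoints(trace, split)
        masks = oracle_segment(truth, cfg)
        seg = compute_segmentation(trace, split, cfg, masks)
        assert seg.pf1 == pytest.approx(100.0, abs=1.0)
        assert seg.pf2 == pytest.approx(100.0, abs=1.0)
        assert seg.pL == pytest.approx(100.0, abs=2.0)


class TestOracleMasks:
    def test_non_pentagon_figure_mask_empty(self, cfg):
        _, truth = generate_trace(DrawingSpec(seed=2, vertices_fig1=4), cfg)
        masks = oracle_segment(truth, cfg)
        assert not masks.mask_fig1.any()
        assert masks.mask_fig2.any()

    def test_gap_mode_interlock_mask_empty(self, cfg):
        _, truth = generate_trace(DrawingSpec(seed=2, interlock_mode="gap", gap_cm=1.2), cfg)
        assert not oracle_segment(truth, cfg).mask_interlock.any()


class TestOverlapPercentage:
    def test_identity_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:5, 2:5] = True
        assert overlap_percentage(a, a) == 100.0
        b = np.zeros((10, 10), bool)
        b[7:9, 7:9] = True
        assert overlap_percentage(a, b) == 0.0

    def test_constructed_half_overlap(self):
        ref = np.zeros((10, 10), bool)
        ref[0:4, 0:10] = True  # 40 pixels
        mask = np.zeros((10, 10), bool)
        mask[0:2, 0:10] = True  # covers 20 of them
        assert overlap_percentage(mask, ref) == 50.0

    def test_empty_reference_raises(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(EmptyReferenceError):
            overlap_percentage(m, np.zeros((4, 4), bool))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            overlap_percentage(np.ones((3, 3), bool), np.ones((4, 4), bool))

    def test_monotone_in_intersection(self):
        ref = np.zeros((8, 8), bool)
        ref[:4] = True
        prev = -1.0
        mask = np.zeros((8, 8), bool)
        for r in range(4):
            mask[r] = True
            p = overlap_percentage(mask, ref)
            assert p > prev
            prev = p


class TestUNetArchitecture:
    def test_conv_layer_count_is_23(self):
        net = build_unet(UNetConfig())
        assert net.conv_layer_count() == 23

    def test_channel_progression_doubles_from_16(self):
        net = build_unet(UNetConfig())
        assert net.channel_progression == [16, 32, 64, 128, 256]

    def test_output_shape_matches_input(self):
        net = build_unet(UNetConfig())
        x = np.zeros((1, 1, 128, 128), np.float32)
        assert net.forward(x).shape == (1, 1, 128, 128)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_unet(UNetConfig(input_size=100))
        with pytest.raises(ValueError):
            build_unet(UNetConfig(base_channels=0))

    def test_gradients_match_finite_differences(self):
        """Backprop agrees with central differences on a reduced network."""
        net = nn.UNet(base_channels=2, depth=2, seed=0)
        rng = np.random.default_rng(1)
        # move biases off zero so no activation sits exactly on a ReLU kink
        for layer in net.layers():
            if hasattr(layer, "params"):
                layer.b = layer.b + rng.uniform(0.01, 0.1, layer.b.shape).astype(np.float32)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 1, 8, 8)) > 0.7).astype(np.float32)

        def loss():
            return nn.bce_with_logits(net.forward(x), y, pos_weight=2.0)[0]

        z = net.forward(x)
        _, dz = nn.bce_with_logits(z, y, pos_weight=2.0)
        net.backward(dz)
        for layer in net.layers():
            if not hasattr(layer, "params"):
                continue
            for k, p in layer.params().items():
                g = getattr(layer, "d" + k)
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps = 1e-2
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                # float32 forward passes put a ~1e-3 absolute floor on the
                # numerical derivative; ReLU kinks add occasional slack
                assert abs(num - g[idx]) < 3e-3 + 0.05 * (abs(num) + abs(g[idx]))


class TestTraining:
    def test_memorizes_single_image(self):
        """Training on one image drives its pixel accuracy towards 1."""
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64), np.float32)
        img[20:44, 30:34] = 1.0
        mask = np.zeros((64, 64), np.float32)
        mask[18:46, 28:36] = 1.0
        ucfg = UNetConfig(
            input_size=64, base_channels=4, depth=2, epochs=30, batch_size=1,
            learning_rate=3e-3,
        )
        model = train_model(img[None], mask[None], ucfg, seed=0)
        prob = model.net.predict_proba(img[None])
        assert nn.pixel_accuracy(prob, mask[None]) >= 0.98

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model(np.empty((0, 64, 64)), np.empty((0, 64, 64)), UNetConfig())

    def test_save_load_predict_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        img = (rng.random((2, 32, 32)) > 0.8).astype(np.float32)
        mask = img.copy()
        ucfg = UNetConfig(input_size=32, base_channels=2, depth=2, epochs=1, batch_size=2)
        model = train_model(img, mask, ucfg, seed=1)
        before = model.net.predict_proba(img)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = nn.UNet.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(img), before)

    def test_training_history_is_seed_deterministic(self):
        rng = np.random.default_rng(4)
        img = (rng.random((4, 32, 32)) > 0.8).astype(np.float32)
        ucfg = UNetConfig(input_size=32, base_channels=2, depth=2, epochs=2, batch_size=2)
        h1 = train_model(img, img, ucfg, seed=5).history
        h2 = train_model(img, img, ucfg, seed=5).history
        assert h1 == h2
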