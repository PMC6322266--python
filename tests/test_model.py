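"""Network shape contracts, preprocessing geometry, inference rules."""

import numpy as np
import pytest

from aortaflow.io import PCSeries
from aortaflow.model import (
    ModelConfig,
    ResidualUNet,
    inverse_map_masks,
    load_checkpoint,
    preprocess,
    preprocess_frames,
    save_checkpoint,
    segment,
)
from aortaflow.nn import weighted_softmax_ce


def series_from_frames(frames):
    frames = np.asarray(frames, dtype=float)
    return PCSeries(
        magnitude=frames, phase=np.zeros_like(frames), venc=150.0,
        recon_scale=1.0, pixel_area=0.01, frame_interval=0.04,
    )


class TestModelConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=1)
        with pytest.raises(ValueError):
            ModelConfig(base_filters=2)
        with pytest.raises(ValueError):
            ModelConfig(out_classes=3)
        with pytest.raises(ValueError):
            ModelConfig(depth=4, input_size=100)  # 100 not divisible by 8


class TestResidualUNet:
    def test_output_shape_contract(self):
        model = ResidualUNet(ModelConfig(depth=3, base_filters=8, input_size=64), seed=0)
        x = np.zeros((2, 1, 64, 64), dtype=np.float32)
        assert model.forward(x, train=False).shape == (2, 2, 64, 64)

    def test_seeded_init_bit_identical(self):
        cfg = ModelConfig.reduced()
        a = ResidualUNet(cfg, seed=42).state_dict()
        b = ResidualUNet(cfg, seed=42).state_dict()
        assert set(a) == set(b)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_indivisible_input_rejected(self):
        model = ResidualUNet(ModelConfig(depth=3, base_filters=8, input_size=64), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 65, 65), dtype=np.float32))

    def test_layer_gradients_match_finite_differences(self):
        """Each layer's backward pass agrees with numerical gradients.

        Layers are promoted to float64 for the check; max-pool input avoids
        exact ties, where the subgradient and a central difference may
        legitimately disagree.
        """
        from aortaflow.nn import Conv2d, MaxPool2x2, ReLU, Upsample2x

        rng = np.random.default_rng(0)

        def check(layer, x, params=(), eps=1e-5):
            weights = rng.normal(size=layer.forward(x, train=False).shape)

            def objective():
                return float((layer.forward(x, train=False) * weights).sum())

            layer.forward(x, train=True)
            for p, g in params:
                g[...] = 0.0
            dx = layer.backward(weights)
            targets = [(x, dx)] + list(params)
            for arr, grad in targets:
                for flat in rng.integers(0, arr.size, 4):
                    idx = np.unravel_index(flat, arr.shape)
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    fp = objective()
                    arr[idx] = orig - eps
                    fm = objective()
                    arr[idx] = orig
                    assert grad[idx] == pytest.approx(
                        (fp - fm) / (2 * eps), rel=1e-4, abs=1e-7
                    )

        x = rng.normal(size=(2, 3, 8, 8))
        for kernel in (3, 1):
            conv = Conv2d(3, 4, kernel, rng, "c")
            conv.W = conv.W.astype(np.float64)
            conv.b = conv.b.astype(np.float64)
            conv.dW = np.zeros_like(conv.W)
            conv.db = np.zeros_like(conv.b)
            check(conv, x.copy(), [(conv.W, conv.dW), (conv.b, conv.db)])
        check(ReLU(), x + 0.01)  # keep clear of the kink at zero
        check(MaxPool2x2(), rng.normal(size=(2, 3, 8, 8)) * 10)  # tie-free
        check(Upsample2x(), x.copy())

    def test_end_to_end_head_gradient_matches_finite_differences(self):
        """Full forward/backward agrees with numerical gradients on the head.

        The head's parameter gradients do not route through max-pool
        switches, so the comparison is exact up to float32 noise.
        """
        cfg = ModelConfig(depth=2, base_filters=4, input_size=8)
        model = ResidualUNet(cfg, seed=3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        t = (rng.random((1, 8, 8)) < 0.3).astype(np.uint8)
        w = np.array([0.2, 0.8])

        logits = model.forward(x, train=True)
        _, dlogits = weighted_softmax_ce(logits, t, w)
        for _, p, g in model.parameters():
            g[...] = 0.0
        model.backward(dlogits)

        head_params = {name: (p, g) for name, p, g in model.head.parameters()}
        eps = 1e-2
        for name, (p, g) in head_params.items():
            idx = (0,) * p.ndim
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = weighted_softmax_ce(model.forward(x, train=False), t, w)
            p[idx] = orig - eps
            lm, _ = weighted_softmax_ce(model.forward(x, train=False), t, w)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(numeric, rel=2e-2, abs=1e-5)

    def test_plain_unet_profile_also_runs(self):
        cfg = ModelConfig(depth=2, base_filters=4, input_size=8, use_residual=False)
        model = ResidualUNet(cfg, seed=0)
        out = model.forward(np.zeros((1, 1, 8, 8), dtype=np.float32), train=False)
        assert out.shape == (1, 2, 8, 8)


class TestPreprocess:
    def test_pads_to_target_centered(self):
        frames = np.ones((2, 200, 190))
        frames[:, 0, 0] = 0.0  # anchor the intensity range so content stays at 1
        out, geom = preprocess_frames(frames, target=256)
        assert out.shape == (2, 256, 256)
        assert geom.pad_top == 28 and geom.pad_left == 33
        assert out[0, 27, 128] == 0.0 and out[0, 28, 128] == 1.0
        # odd gap: extra zero row/column lands on the bottom/right
        assert out[0, 227, 128] == 1.0 and out[0, 228, 128] == 0.0

    def test_oversized_frames_resampled_down(self):
        frames = np.random.default_rng(0).random((1, 512, 300))
        out, geom = preprocess_frames(frames, target=256)
        assert out.shape == (1, 256, 256)
        assert geom.zoom == pytest.approx(0.5)

    def test_rescaled_to_unit_interval(self):
        frames = np.random.default_rng(1).uniform(100, 900, (3, 60, 60))
        out, _ = preprocess_frames(frames, target=64)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_stack_maps_to_zero(self):
        out, _ = preprocess_frames(np.full((2, 40, 40), 7.0), target=64)
        assert np.all(out == 0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frames(np.zeros((0, 8, 8)), target=64)

    def test_mask_inverse_map_round_trip(self):
        rng = np.random.default_rng(2)
        native = (rng.random((2, 50, 40)) < 0.3).astype(np.uint8)
        frames = native.astype(float)
        _, geom = preprocess_frames(frames, target=64)
        padded = np.zeros((2, 64, 64), dtype=np.uint8)
        padded[:, geom.pad_top : geom.pad_top + 50, geom.pad_left : geom.pad_left + 40] = native
        back = inverse_map_masks(padded, geom)
        np.testing.assert_array_equal(back, native)


class TestSegment:
    def test_all_negative_valve_logit_gives_empty_mask(self, small_exam):
        series, _, _ = small_exam
        cfg = ModelConfig.reduced()
        model = ResidualUNet(cfg, seed=0)
        # force the valve logit far below the background logit everywhere
        name, b, _ = [p for p in model.head.parameters() if p[0].endswith(".b")][0]
        b[...] = np.array([100.0, -100.0], dtype=np.float32)
        for _, W, _ in model.head.parameters():
            if W.ndim == 4:
                W[...] = 0.0
        mask = segment(series, model)
        assert mask.masks.sum() == 0

    def test_exact_logit_tie_resolves_to_non_valve(self, small_exam):
        series, _, _ = small_exam
        model = ResidualUNet(ModelConfig.reduced(), seed=0)
        for _, p, _ in model.parameters():
            p[...] = 0.0  # every logit identical -> tie everywhere
        assert segment(series, model).masks.sum() == 0

    def test_inference_deterministic(self, small_exam):
        series, _, _ = small_exam
        model = ResidualUNet(ModelConfig.reduced(), seed=7)
        a = segment(series, model).masks
        b = segment(series, model).masks
        np.testing.assert_array_equal(a, b)

    def test_wrong_model_type_rejected(self, small_exam):
        series, _, _ = small_exam
        with pytest.raises(TypeError):
            segment(series, object())


class TestCheckpoints:
    def test_round_trip_preserves_parameters_and_config(self, tmp_path):
        cfg = ModelConfig.reduced()
        model = ResidualUNet(cfg, seed=9)
        path = save_checkpoint(model, tmp_path / "m.npz", metadata={"note": "t"})
        loaded, meta = load_checkpoint(path)
        assert loaded.cfg == cfg
        assert meta == {"note": "t"}
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(loaded.state_dict()[k], v)

    def test_non_checkpoint_rejected(self, tmp_path):
        p = tmp_path / "junk.npz"
        np.savez(p, a=np.zeros(3))
        with pytest.raises(ValueError):
            load_checkpoint(p)
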