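"""Loss closed forms, augmentation, training loop, cross-validation."""

import math

import numpy as np
import pytest

from aortaflow.io import SegmentationMap
from aortaflow.model import ModelConfig
from aortaflow.phantom import PhantomSpec, generate_cohort
from aortaflow.training import (
    TrainConfig,
    augment,
    cross_validate,
    make_folds,
    train,
    weighted_ce_loss,
)
from aortaflow.nn import weighted_softmax_ce


def scalar_loss_oracle(logits, truth, w):
    """Per-pixel scalar-loop evaluation of the weighted CE definition."""
    n, c, h, w_ = logits.shape
    total = 0.0
    for b in range(n):
        for r in range(h):
            for col in range(w_):
                x = logits[b, :, r, col].astype(float)
                i = int(truth[b, r, col])
                total += -w[i] * math.log(math.exp(x[i]) / np.exp(x).sum())
    return total / (n * h * w_)


REDUCED_MODEL = ModelConfig.reduced()


def tiny_cohort(n, seed, n_frames=4):
    base = PhantomSpec(n_frames=n_frames)
    return [(s, g) for _, s, g, _ in generate_cohort(n, seed=seed, base_spec=base)]


class TestWeightedCELoss:
    def test_zero_logits_closed_form(self):
        # all-valve truth at zero logits: loss = w[1] * ln 2 = 0.8 ln 2
        logits = np.zeros((1, 2, 4, 4))
        truth = np.ones((1, 4, 4), dtype=np.uint8)
        got = weighted_ce_loss(logits, truth, (0.2, 0.8))
        assert got == pytest.approx(0.8 * math.log(2), abs=1e-6)

    def test_zero_logits_mixed_truth(self):
        # half valve, half background: mean of 0.8 ln2 and 0.2 ln2
        logits = np.zeros((1, 2, 2, 2))
        truth = np.array([[[0, 1], [0, 1]]], dtype=np.uint8)
        assert weighted_ce_loss(logits, truth) == pytest.approx(
            0.5 * (0.8 + 0.2) * math.log(2), abs=1e-9
        )

    def test_confident_true_logit_drives_loss_to_zero(self):
        logits = np.zeros((1, 2, 3, 3))
        logits[0, 1] = 50.0
        truth = np.ones((1, 3, 3), dtype=np.uint8)
        assert weighted_ce_loss(logits, truth) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_annihilates(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(1, 2, 4, 4))
        truth = np.ones((1, 4, 4), dtype=np.uint8)
        assert weighted_ce_loss(logits, truth, (0.7, 0.0)) == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_ce_loss(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 2), dtype=np.uint8), (-1, 1))

    def test_matches_scalar_loop_oracle(self, rng):
        """Vectorized loss == per-pixel scalar oracle to 1e-6 relative."""
        for _ in range(10):
            logits = rng.normal(0, 3, (2, 2, 8, 8))
            truth = (rng.random((2, 8, 8)) < 0.4).astype(np.uint8)
            w = (0.2, 0.8)
            got = weighted_ce_loss(logits, truth, w)
            want = scalar_loss_oracle(logits, truth, w)
            assert got == pytest.approx(want, rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(0, 2, (1, 2, 4, 4))
        truth = (rng.random((1, 4, 4)) < 0.5).astype(np.uint8)
        w = np.array([0.2, 0.8])
        _, grad = weighted_softmax_ce(logits, truth, w)
        eps = 1e-5
        for idx in [(0, 0, 1, 2), (0, 1, 3, 0)]:
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (
                weighted_softmax_ce(lp, truth, w)[0] - weighted_softmax_ce(lm, truth, w)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestAugment:
    def _pair(self, size=64):
        rng = np.random.default_rng(4)
        img = rng.random((size, size)).astype(np.float32)
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[20:30, 25:35] = 1
        return img, mask

    def test_null_transform_is_identity(self):
        img, mask = self._pair()
        cfg = TrainConfig(
            crop_size=64, zoom_range=(1.0, 1.0), rotation_range_deg=0.0,
            flip_probability=0.0, noise_sigma=0.0,
        )
        out_img, out_mask = augment(img, mask, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_same_rng_state_reproduces_pair(self):
        img, mask = self._pair()
        cfg = TrainConfig.reduced()
        a = augment(img, mask, cfg, np.random.default_rng(77))
        b = augment(img, mask, cfg, np.random.default_rng(77))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_geometric_transform_shared_and_mask_binary(self):
        img, mask = self._pair()
        cfg = TrainConfig.reduced(noise_sigma=0.0)
        out_img, out_mask = augment(img, mask, cfg, np.random.default_rng(5))
        assert out_img.shape == out_mask.shape == (56, 56)
        assert set(np.unique(out_mask)) <= {0, 1}
        # valve area roughly preserved under zoom<=1.1, rotation, crop
        assert 0 < out_mask.sum() < 3 * mask.sum()

    def test_flip_preserves_masked_values(self):
        img, mask = self._pair()
        cfg = TrainConfig(
            crop_size=64, zoom_range=(1.0, 1.0), rotation_range_deg=0.0,
            flip_probability=1.0, noise_sigma=0.0,
        )
        out_img, out_mask = augment(img, mask, cfg, np.random.default_rng(0))
        assert out_img[out_mask == 1].sum() == pytest.approx(img[mask == 1].sum(), rel=1e-6)

    def test_oversized_crop_rejected(self):
        img, mask = self._pair(32)
        with pytest.raises(ValueError, match="crop"):
            augment(img, mask, TrainConfig(crop_size=64), np.random.default_rng(0))


class TestMakeFolds:
    def test_150_cases_k6_gives_six_folds_of_25(self):
        plan = make_folds([f"c{i}" for i in range(150)], k=6, seed=0)
        sizes = [len(plan.fold_cases(f)) for f in range(6)]
        assert sizes == [25] * 6

    def test_balance_rule_with_remainder(self):
        plan = make_folds([f"c{i}" for i in range(7)], k=6, seed=1)
        sizes = sorted(len(plan.fold_cases(f)) for f in range(6))
        assert sizes == [1, 1, 1, 1, 1, 2]

    def test_partition_is_exhaustive_and_disjoint(self):
        ids = [f"c{i}" for i in range(23)]
        plan = make_folds(ids, k=4, seed=3)
        all_cases = [c for f in range(4) for c in plan.fold_cases(f)]
        assert sorted(all_cases) == sorted(ids)

    def test_seeded_determinism(self):
        ids = [f"c{i}" for i in range(30)]
        assert make_folds(ids, 5, seed=9).fold_assignments == make_folds(
            ids, 5, seed=9
        ).fold_assignments

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=6, seed=0)


class TestTrainLoop:
    def test_overfit_single_case(self):
        """One exam, tiny net: training Dice must exceed 0.95 (overfit oracle)."""
        dataset = tiny_cohort(1, seed=21, n_frames=4)
        cfg = TrainConfig.reduced(max_epochs=25, plateau_patience=24, seed=2)
        model, history = train(dataset, cfg, REDUCED_MODEL)
        dices = [h["train_dice"] for h in history]
        assert max(dices) > 0.95
        # non-decreasing trend: late mean beats early mean
        assert np.mean(dices[len(dices) // 2 :]) > np.mean(dices[: len(dices) // 2])

    def test_same_seed_reproduces_parameters(self):
        dataset = tiny_cohort(2, seed=13, n_frames=3)
        cfg = TrainConfig.reduced(max_epochs=2, seed=5)
        m1, h1 = train(dataset, cfg, REDUCED_MODEL)
        m2, h2 = train(dataset, cfg, REDUCED_MODEL)
        assert h1 == h2
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k])

    def test_zero_patience_stops_at_first_non_improving_epoch(self):
        dataset = tiny_cohort(1, seed=17, n_frames=3)
        cfg = TrainConfig.reduced(
            max_epochs=40, plateau_patience=0, plateau_delta=1.0, seed=1,
        )
        # delta=1.0 means no epoch can ever "improve"; stop after epoch 1
        _, history = train(dataset, cfg, REDUCED_MODEL)
        assert len(history) == 2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig.reduced(), REDUCED_MODEL)

    def test_history_csv_written(self, tmp_path):
        dataset = tiny_cohort(1, seed=19, n_frames=2)
        cfg = TrainConfig.reduced(max_epochs=1, seed=0)
        _, history = train(dataset, cfg, REDUCED_MODEL, history_path=tmp_path / "h.csv")
        text = (tmp_path / "h.csv").read_text()
        assert text.splitlines()[0] == "epoch,loss,train_dice"
        assert len(text.splitlines()) == len(history) + 1


class TestCrossValidate:
    def test_k2_bookkeeping_and_leakage(self):
        pairs = tiny_cohort(4, seed=31, n_frames=2)
        dataset = {s.exam_id: (s, g) for s, g in pairs}
        plan = make_folds(sorted(dataset), k=2, seed=0)
        cfg = TrainConfig.reduced(max_epochs=2, seed=3)
        result = cross_validate(dataset, plan, cfg, REDUCED_MODEL)
        assert len(result["models"]) == 2
        assert len(result["reports"]) == 4
        assert sorted(r.per_case_id for r in result["reports"]) == sorted(dataset)
        for fold in range(2):
            assert not set(plan.fold_cases(fold)) & set(plan.train_cases(fold))
        # per-case mean equals mean of concatenated per-case metrics
        dices = [r.dice for r in result["reports"]]
        assert result["summary"]["dice"]["mean"] == pytest.approx(np.mean(dices))

    def test_plan_dataset_mismatch_rejected(self):
        pairs = tiny_cohort(4, seed=37, n_frames=2)
        dataset = {s.exam_id: (s, g) for s, g in pairs}
        plan = make_folds(sorted(dataset)[:3] + ["ghost"], k=2, seed=0)
        with pytest.raises(ValueError, match="ghost"):
            cross_validate(dataset, plan, TrainConfig.reduced(max_epochs=1), REDUCED_MODEL)
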