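"""Objective functions against scalar-loop oracles, and the evaluation
metrics (confusion counts, precision/recall, dice, composite dice)."""

import numpy as np
import pytest

from ctseg.losses import (cross_entropy_loss, dice_loss, one_hot,
                          total_loss, DICE_EPS)
from ctseg.metrics import (composite_dice, confusion, dice_score,
                           evaluate_masks, precision_recall)
from ctseg.nn.tensor import Tensor


def random_softmax(rng, shape):
    z = rng.normal(size=shape)
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def oracle_dice_loss(u, v, eps=DICE_EPS):
    b, c = u.shape[:2]
    total = 0.0
    for s in range(b):
        acc = 0.0
        for k in range(c):
            num = den = 0.0
            for idx in np.ndindex(u.shape[2:]):
                num += u[(s, k) + idx] * v[(s, k) + idx]
                den += u[(s, k) + idx] + v[(s, k) + idx]
            acc += num / (den + eps)
        total += -2.0 / c * acc
    return total / b


def oracle_ce(u, v):
    total = 0.0
    n = 0
    for s in range(u.shape[0]):
        for idx in np.ndindex(u.shape[2:]):
            n += 1
            for k in range(u.shape[1]):
                total -= v[(s, k) + idx] * np.log(max(u[(s, k) + idx], 1e-7))
    return total / n


class TestDiceLoss:
    def test_perfect_one_hot_scores_minus_one(self):
        labels = np.array([[[[0, 1], [2, 1]], [[0, 0], [2, 2]]]])
        v = one_hot(labels, 3)
        val = dice_loss(Tensor(v), v).item()
        assert val == pytest.approx(-1.0, abs=1e-4)

    def test_disjoint_supports_score_zero(self):
        u = np.zeros((1, 2, 2, 2, 2), np.float32)
        u[:, 0] = 1.0
        v = np.zeros_like(u)
        v[:, 1] = 1.0
        assert dice_loss(Tensor(u), v).item() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        u = random_softmax(rng, (2, 3, 5, 5, 5))
        v = one_hot((rng.random((2, 5, 5, 5)) * 3).astype(int), 3)
        val = dice_loss(Tensor(u), v).item()
        assert val == pytest.approx(oracle_dice_loss(u, v), abs=1e-5)
        assert -1.0 <= val <= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(Tensor(np.zeros((1, 3, 2, 2, 2))),
                      np.zeros((1, 3, 4, 4, 4)))


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((1, 2, 2, 2), int)
        v = one_hot(labels, 3)
        assert cross_entropy_loss(Tensor(v), v).item() < 1e-6

    def test_uniform_prediction_is_log_c(self):
        v = one_hot(np.zeros((1, 4, 4, 4), int), 3)
        u = np.full_like(v, 1.0 / 3.0)
        assert cross_entropy_loss(Tensor(u), v).item() == \
            pytest.approx(np.log(3.0), rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        u = random_softmax(rng, (2, 3, 4, 4, 4))
        v = one_hot((rng.random((2, 4, 4, 4)) * 3).astype(int), 3)
        assert cross_entropy_loss(Tensor(u), v).item() == \
            pytest.approx(oracle_ce(u, v), rel=1e-6)

    def test_sum_reduction(self, rng):
        u = random_softmax(rng, (1, 3, 2, 2, 2))
        v = one_hot((rng.random((1, 2, 2, 2)) * 3).astype(int), 3)
        mean = cross_entropy_loss(Tensor(u), v, "mean").item()
        total = cross_entropy_loss(Tensor(u), v, "sum").item()
        assert total == pytest.approx(mean * 8, rel=1e-6)


class TestTotalLoss:
    def test_components_sum_exactly(self, rng):
        u = random_softmax(rng, (2, 3, 3, 3, 3)).astype(np.float32)
        v = one_hot((rng.random((2, 3, 3, 3)) * 3).astype(int), 3)
        loss, ld, lc = total_loss(Tensor(u), v)
        assert loss.item() == np.float32(ld) + np.float32(lc)

    def test_perfect_prediction_totals_minus_one(self):
        v = one_hot(np.array([[[[0, 1], [2, 0]], [[1, 1], [2, 2]]]]), 3)
        loss, _, _ = total_loss(Tensor(v), v)
        assert loss.item() == pytest.approx(-1.0, abs=1e-4)

    def test_decreases_over_optimizer_steps(self, rng):
        # 50 Adam steps on a fixed toy batch must reduce the objective
        from ctseg.nn import Adam
        from ctseg.nn import functional as F
        from _helpers import topo_backward

        logits = Tensor(rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32),
                        requires_grad=True)
        v = one_hot((rng.random((1, 4, 4, 4)) * 3).astype(int), 3)
        opt = Adam([logits], lr=5e-2)
        losses = []
        for _ in range(50):
            u = F.softmax_channels(logits)
            loss, _, _ = total_loss(u, v)
            losses.append(loss.item())
            logits.grad = None
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])


class TestConfusionAndScores:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.random((6, 6, 6)) * 3).astype(int)
        for c in (0, 1, 2):
            counts = confusion(m, m, c)
            assert counts.fp == counts.fn == 0

    def test_hand_counted_toy(self):
        pred = np.array([[[1, 1, 0]]])
        true = np.array([[[1, 0, 0]]])
        c = confusion(pred, true, 1)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_partition_the_volume(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((5, 5, 5)) * 3).astype(int)
        true = (rng.random((5, 5, 5)) * 3).astype(int)
        for cls in (0, 1, 2):
            assert confusion(pred, true, cls).total == 125

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            confusion(np.zeros((2, 2, 2), int), np.zeros((2, 2, 2), int), 7)

    def test_precision_recall_examples(self):
        from ctseg.metrics import ConfusionCounts
        p, r = precision_recall(ConfusionCounts(3, 1, 0, 10))
        assert p == pytest.approx(75.0)
        assert r == pytest.approx(100.0)
        p, _ = precision_recall(ConfusionCounts(0, 0, 5, 10))
        assert p == 0.0  # no positive predictions

    def test_dice_examples(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[:2, 0, 0] = 1
        b[:2, 0, 0] = 1
        assert dice_score(a, b, 1) == 100.0
        b[:] = 0
        b[2:, 1, 0] = 1
        assert dice_score(a, b, 1) == 0.0
        # |U|=4, |V|=4, |U∩V|=2 -> 50
        a[:] = 0
        b[:] = 0
        a[0, 0, :4] = 1
        b[0, 0, 2:4] = 1
        b[0, 1, :2] = 1
        assert dice_score(a, b, 1) == pytest.approx(50.0)

    def test_dice_symmetry_and_duality(self, rng):
        pred = (rng.random((6, 6, 6)) * 3).astype(int)
        true = (rng.random((6, 6, 6)) * 3).astype(int)
        for cls in (1, 2):
            assert dice_score(pred, true, cls) == dice_score(true, pred, cls)
            p1, r1 = precision_recall(confusion(pred, true, cls))
            p2, r2 = precision_recall(confusion(true, pred, cls))
            assert p1 == pytest.approx(r2)
            assert r1 == pytest.approx(p2)

    def test_empty_masks_score_hundred_with_flag(self):
        empty = np.zeros((3, 3, 3), int)
        assert dice_score(empty, empty, 2) == 100.0
        report = evaluate_masks(empty, empty)
        assert any("empty-masks" in f for f in report.flags)

    def test_loss_and_metric_agree_on_hard_masks(self, rng):
        # a one-hot "prediction" makes the soft dice equal the hard dice
        pred = (rng.random((1, 6, 6, 6)) * 3).astype(int)
        true = (rng.random((1, 6, 6, 6)) * 3).astype(int)
        u = one_hot(pred, 3)
        v = one_hot(true, 3)
        soft = -dice_loss(Tensor(u), v).item()
        hard = np.mean([dice_score(pred[0], true[0], c) for c in range(3)])
        assert soft * 100 == pytest.approx(hard, abs=0.05)


class TestCompositeDice:
    @pytest.mark.parametrize("values,expected", [
        ((97.37, 85.09), 91.23),
        ((81.22, 52.99), 67.11),
        ((95.43, 61.82), 78.63),
        ((42.0,), 42.0),
    ])
    def test_aggregation(self, values, expected):
        assert composite_dice(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composite_dice([])

    def test_all_scores_in_range(self, rng):
        pred = (rng.random((8, 8, 8)) * 3).astype(int)
        true = (rng.random((8, 8, 8)) * 3).astype(int)
        report = evaluate_masks(pred, true)
        for d in (report.precision, report.recall, report.dice):
            for v in d.values():
                assert 0.0 <= v <= 100.0
        assert 0.0 <= report.composite <= 100.0
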