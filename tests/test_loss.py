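"""Masked weighted BCE against an independent per-pixel oracle, plus the
positive-weight schemes."""
import math

import numpy as np
import pytest

from implyseg import (
    ClassCatalog,
    ClassWeights,
    ConfigurationError,
    ImpliedTarget,
    ValidationError,
    masked_weighted_bce,
    masked_weighted_bce_with_grad,
    pos_weight_neg_pos_ratio,
    pos_weight_softmax_negated,
    imply_from_binary,
    BinarySampleAnnotation,
)


def bce_oracle(batch_logits, batch_targets, weights, names):
    """Literal per-pixel double-loop evaluation of the masked weighted BCE."""
    per_class_sum = {n: 0.0 for n in names}
    per_class_cnt = {n: 0 for n in names}
    for z, t in zip(batch_logits, batch_targets):
        for ci, name in enumerate(names):
            for i in range(z.shape[1]):
                for j in range(z.shape[2]):
                    if t.validity[ci, i, j] == 0:
                        continue
                    zz = float(z[ci, i, j])
                    y = float(t.targets[ci, i, j])
                    s = 1.0 / (1.0 + math.exp(-zz))
                    term = -(
                        weights[name] * y * math.log(s)
                        + (1.0 - y) * math.log(1.0 - s)
                    )
                    per_class_sum[name] += term
                    per_class_cnt[name] += 1
    per_class = {
        n: per_class_sum[n] / per_class_cnt[n]
        for n in names
        if per_class_cnt[n] > 0
    }
    total = sum(per_class.values()) / len(per_class) if per_class else 0.0
    return per_class, total


def random_instance(rng, n_classes, shape=(8, 8), batch=2):
    names = tuple("ABCD"[:n_classes])
    catalog = ClassCatalog(names)
    logits, targets = [], []
    for b in range(batch):
        z = rng.normal(scale=3.0, size=(n_classes,) + shape)
        y = rng.integers(0, 2, size=(n_classes,) + shape).astype(np.uint8)
        lam = rng.integers(0, 2, size=(n_classes,) + shape).astype(np.uint8)
        logits.append(z)
        targets.append(ImpliedTarget(f"im{b}", y, lam))
    w = ClassWeights({n: float(rng.uniform(0.2, 5.0)) for n in names})
    return catalog, logits, targets, w


class TestMaskedWeightedBce:
    def test_uniform_logits_give_ln2(self):
        catalog = ClassCatalog(("A",))
        t = ImpliedTarget("x", np.array([[[1, 0]]], dtype=np.uint8),
                          np.array([[[1, 1]]], dtype=np.uint8))
        out = masked_weighted_bce(
            [np.zeros((1, 1, 2))], [t], ClassWeights({"A": 1.0}), catalog
        )
        assert out.total == pytest.approx(math.log(2), abs=1e-12)

    def test_fully_masked_class_contributes_zero(self):
        catalog = ClassCatalog(("A",))
        t = ImpliedTarget("x", np.array([[[1, 0]]], dtype=np.uint8),
                          np.zeros((1, 1, 2), dtype=np.uint8))
        out = masked_weighted_bce(
            [np.zeros((1, 1, 2))], [t], ClassWeights({"A": 1.0}), catalog
        )
        assert out.total == 0.0
        assert out.term_counts["A"] == 0
        assert out.per_class["A"] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            n_classes = int(rng.integers(1, 5))
            catalog, logits, targets, w = random_instance(rng, n_classes)
            out = masked_weighted_bce(logits, targets, w, catalog)
            per_class, total = bce_oracle(
                logits, targets, w, catalog.foreground_names
            )
            assert out.total == pytest.approx(total, abs=1e-6)
            for n, v in per_class.items():
                assert out.per_class[n] == pytest.approx(v, abs=1e-6)

    def test_batch_duplication_leaves_loss_unchanged(self, rng):
        catalog, logits, targets, w = random_instance(rng, 3)
        once = masked_weighted_bce(logits, targets, w, catalog)
        twice = masked_weighted_bce(logits * 2, targets * 2, w, catalog)
        assert twice.total == pytest.approx(once.total, abs=1e-9)

    def test_worse_prediction_increases_loss(self, rng):
        """Pushing a valid pixel's probability away from its target strictly
        increases that class's loss."""
        catalog, logits, targets, w = random_instance(rng, 2)
        base = masked_weighted_bce(logits, targets, w, catalog)
        # find a valid pixel with target 1 and push its logit down
        t = targets[0]
        ci, i, j = np.argwhere((t.validity == 1) & (t.targets == 1))[0]
        worse = [z.copy() for z in logits]
        worse[0][ci, i, j] -= 2.0
        out = masked_weighted_bce(worse, targets, w, catalog)
        name = catalog.foreground_names[ci]
        assert out.per_class[name] > base.per_class[name]

    def test_gradient_matches_finite_difference(self, rng):
        catalog, logits, targets, w = random_instance(rng, 2, shape=(4, 4))
        _, grad = masked_weighted_bce_with_grad(logits, targets, w, catalog)
        eps = 1e-5
        for _ in range(10):
            b = int(rng.integers(0, len(logits)))
            c, i, j = (int(rng.integers(0, s)) for s in logits[b].shape)
            lp = [z.copy() for z in logits]
            lm = [z.copy() for z in logits]
            lp[b][c, i, j] += eps
            lm[b][c, i, j] -= eps
            num = (
                masked_weighted_bce(lp, targets, w, catalog).total
                - masked_weighted_bce(lm, targets, w, catalog).total
            ) / (2 * eps)
            assert grad[b, c, i, j] == pytest.approx(num, abs=1e-4)

    def test_shape_mismatch_rejected(self, catalog2):
        t = ImpliedTarget("x", np.zeros((2, 2, 2), np.uint8), np.ones((2, 2, 2), np.uint8))
        with pytest.raises(ValidationError):
            masked_weighted_bce(
                [np.zeros((2, 3, 3))], [t], ClassWeights({"A": 1, "B": 1}), catalog2
            )

    def test_missing_weight_rejected(self, catalog2):
        t = ImpliedTarget("x", np.zeros((2, 2, 2), np.uint8), np.ones((2, 2, 2), np.uint8))
        with pytest.raises(ConfigurationError):
            masked_weighted_bce(
                [np.zeros((2, 2, 2))], [t], ClassWeights({"A": 1.0}), catalog2
            )


class TestNegPosRatioWeights:
    def test_quarter_positive_mask_gives_three(self, catalog2):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[:2, :2] = 1  # 25% positive
        t = imply_from_binary(BinarySampleAnnotation("x", "A", mask), catalog2)
        w = pos_weight_neg_pos_ratio([t], catalog2, include_implied=False)
        assert w["A"] == pytest.approx(3.0)

    def test_balanced_mask_gives_one(self, catalog2):
        mask = np.zeros((2, 2), dtype=np.uint8)
        mask[0] = 1
        t = imply_from_binary(BinarySampleAnnotation("x", "A", mask), catalog2)
        w = pos_weight_neg_pos_ratio([t], catalog2, include_implied=False)
        assert w["A"] == pytest.approx(1.0)

    def test_implied_negatives_raise_weight_by_counted_ratio(self, catalog2):
        """Frames positive for B add exactly (#B positives / #A positives) to
        A's negative-to-positive ratio when implied negatives are counted."""
        a_mask = np.zeros((4, 4), dtype=np.uint8)
        a_mask[0, :2] = 1  # 2 positive A pixels of 16
        b_mask = np.ones((4, 4), dtype=np.uint8)  # all-positive B frame
        ta = imply_from_binary(BinarySampleAnnotation("a", "A", a_mask), catalog2)
        tb = imply_from_binary(BinarySampleAnnotation("b", "B", b_mask), catalog2)
        w_own = pos_weight_neg_pos_ratio([ta, tb], catalog2, include_implied=False)
        w_all = pos_weight_neg_pos_ratio([ta, tb], catalog2, include_implied=True)
        increment = int(b_mask.sum()) / int(a_mask.sum())
        assert w_all["A"] - w_own["A"] == pytest.approx(increment)

    def test_zero_positive_class_warns_and_defaults_to_one(self, catalog2):
        t = imply_from_binary(
            BinarySampleAnnotation("x", "A", np.zeros((2, 2), np.uint8)), catalog2
        )
        with pytest.warns(UserWarning, match="no valid positive"):
            w = pos_weight_neg_pos_ratio([t], catalog2)
        assert w["A"] == 1.0

    def test_empty_collection_rejected(self, catalog2):
        with pytest.raises(ValidationError):
            pos_weight_neg_pos_ratio([], catalog2)


class TestSoftmaxNegatedWeights:
    def test_equal_shares_give_uniform_weights(self):
        w = pos_weight_softmax_negated({c: 0.25 for c in "ABCD"})
        for c in "ABCD":
            assert w[c] == pytest.approx(0.25)

    def test_closed_form_two_class_case(self):
        w = pos_weight_softmax_negated({"A": 0.0, "B": 1.0})
        z = math.exp(0) + math.exp(-1)
        assert w["A"] == pytest.approx(math.exp(0) / z, abs=1e-12)
        assert w["B"] == pytest.approx(math.exp(-1) / z, abs=1e-12)

    def test_weights_sum_to_one(self, rng):
        shares = {f"c{i}": float(s) for i, s in enumerate(rng.uniform(0, 1, 7))}
        w = pos_weight_softmax_negated(shares)
        assert sum(w.weights.values()) == pytest.approx(1.0)

    def test_share_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            pos_weight_softmax_negated({"A": 1.2})
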