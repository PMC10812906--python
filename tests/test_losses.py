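"""Loss definitions against brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from curriseg import (StageWeights, combine, consistency_loss,
                      contrastive_loss_at_scale, decompose,
                      multiscale_contrastive_loss, supervised_loss)
from curriseg.nn.tensor import Tensor


# ------------------------------------------------------------- oracles

def consistency_oracle(global_probs, patch_probs, g):
    """Element-by-element loop computation of the consistency loss."""
    C, H, W = global_probs.shape
    ph, pw = H // g, W // g
    total = 0.0
    for idx, patch in enumerate(patch_probs):
        r, c = divmod(idx, g)
        acc, n = 0.0, 0
        for ch in range(C):
            for y in range(ph):
                for x in range(pw):
                    d = (global_probs[ch, r * ph + y, c * pw + x]
                         - patch[ch, y, x])
                    acc += d * d
                    n += 1
        total += acc / n
    return total


def contrastive_oracle(G, P, tau=1.0):
    """Pairwise enumeration of the InfoNCE terms."""
    m = len(G)
    if m == 1:
        return 0.0
    total = 0.0
    for i in range(m):
        pos = math.exp(float(np.dot(G[i], P[i])) / tau)
        neg = sum(math.exp(float(np.dot(G[i], G[j])) / tau)
                  for j in range(m) if j != i)
        total += -math.log(pos / (pos + neg))
    return total / m


def unit_rows(rng, m, d):
    v = rng.normal(size=(m, d))
    return (v / np.linalg.norm(v, axis=1, keepdims=True)).astype(np.float32)


# ------------------------------------------------------ consistency loss

class TestConsistencyLoss:
    def test_zero_when_patches_equal_crops(self, rng):
        g_map = rng.random((2, 8, 8)).astype(np.float32)
        patches = decompose(g_map, 4).patches
        assert consistency_loss(g_map, patches, (2, 2)).item() == 0.0

    def test_constant_maps_give_patch_count(self):
        g_map = np.ones((2, 8, 8), np.float32)
        patches = [np.zeros((2, 4, 4), np.float32)] * 4
        assert consistency_loss(g_map, patches, (2, 2)).item() == pytest.approx(4.0)
        assert consistency_loss(g_map, patches, (2, 2),
                                reduce="mean").item() == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [2, 4])
    def test_matches_loop_oracle(self, g, rng):
        for _ in range(25):
            g_map = rng.random((2, 4 * g, 4 * g)).astype(np.float32)
            patches = [rng.random((2, 4, 4)).astype(np.float32)
                       for _ in range(g * g)]
            got = consistency_loss(g_map, patches, (g, g)).item()
            want = consistency_oracle(g_map, patches, g)
            assert got == pytest.approx(want, rel=1e-5)

    def test_patch_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consistency_loss(np.zeros((2, 8, 8), np.float32),
                             [np.zeros((2, 4, 4), np.float32)] * 3, (2, 2))

    def test_gradients_flow_and_are_finite(self, rng):
        g_map = Tensor(rng.random((2, 8, 8)).astype(np.float32),
                       requires_grad=True)
        patches = [Tensor(rng.random((2, 4, 4)).astype(np.float32),
                          requires_grad=True) for _ in range(4)]
        loss = consistency_loss(g_map, patches, (2, 2))
        loss.backward()
        assert np.isfinite(g_map.grad).all()
        assert all(np.isfinite(p.grad).all() for p in patches)


# ------------------------------------------------------ contrastive loss

class TestContrastiveLoss:
    def test_single_position_is_zero(self, rng):
        v = unit_rows(rng, 1, 8)
        assert contrastive_loss_at_scale(v, v).item() == 0.0

    @pytest.mark.parametrize("m", [4, 16, 25])
    def test_identical_embeddings_give_log_m(self, m):
        v = np.tile(np.eye(1, 8, 0, dtype=np.float32), (m, 1))
        assert contrastive_loss_at_scale(v, v).item() == pytest.approx(
            math.log(m), rel=1e-5)

    @pytest.mark.parametrize("m", [4, 16])
    def test_matches_enumeration_oracle(self, m, rng):
        for _ in range(25):
            G, P = unit_rows(rng, m, 8), unit_rows(rng, m, 8)
            got = contrastive_loss_at_scale(G, P).item()
            assert got == pytest.approx(contrastive_oracle(G, P), rel=1e-5)

    def test_invariant_under_simultaneous_permutation(self, rng):
        G, P = unit_rows(rng, 9, 8), unit_rows(rng, 9, 8)
        perm = rng.permutation(9)
        base = contrastive_loss_at_scale(G, P).item()
        permuted = contrastive_loss_at_scale(G[perm], P[perm]).item()
        assert permuted == pytest.approx(base, rel=1e-5)

    def test_position_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss_at_scale(unit_rows(rng, 4, 8),
                                      unit_rows(rng, 5, 8))

    def test_temperature_scales_similarities(self, rng):
        G, P = unit_rows(rng, 4, 8), unit_rows(rng, 4, 8)
        got = contrastive_loss_at_scale(G, P, tau=0.5).item()
        assert got == pytest.approx(contrastive_oracle(G, P, tau=0.5),
                                    rel=1e-5)

    def test_gradients_finite(self, rng):
        G = Tensor(unit_rows(rng, 8, 8), requires_grad=True)
        P = Tensor(unit_rows(rng, 8, 8), requires_grad=True)
        contrastive_loss_at_scale(G, P).backward()
        assert np.isfinite(G.grad).all() and np.isfinite(P.grad).all()


class TestMultiScale:
    def test_sums_over_scales(self, rng):
        pairs = [(unit_rows(rng, 4, 8), unit_rows(rng, 4, 8))
                 for _ in range(3)]
        total = multiscale_contrastive_loss(pairs).item()
        parts = sum(contrastive_loss_at_scale(G, P).item() for G, P in pairs)
        assert total == pytest.approx(parts, rel=1e-6)
        one = multiscale_contrastive_loss(pairs[:1]).item()
        assert one == pytest.approx(
            contrastive_loss_at_scale(*pairs[0]).item(), rel=1e-6)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            multiscale_contrastive_loss([])


# ------------------------------------------------------- supervised loss

class TestSupervisedLoss:
    def test_perfect_onehot_prediction_is_zero(self):
        target = np.zeros((6, 6), np.uint8)
        target[2:4, 2:4] = 1
        logits = np.stack([(1 - target) * 50.0, target * 50.0]).astype(np.float32)
        assert supervised_loss(logits, target, eps=1.0).item() == pytest.approx(
            0.0, abs=1e-4)

    def test_uniform_probability_closed_form(self):
        # p_fg = 0.5 everywhere, half the pixels foreground:
        # CE = ln 2 and soft Dice loss = 0.5, so total = (ln 2 + 0.5) / 2
        H = 8
        logits = np.zeros((2, H, H), np.float32)
        target = np.zeros((H, H), np.uint8)
        target[:, :H // 2] = 1
        got = supervised_loss(logits, target, eps=0.0).item()
        assert got == pytest.approx(0.5 * (math.log(2) + 0.5), rel=1e-5)

    def test_empty_target_smoothed_dice(self):
        target = np.zeros((4, 4), np.uint8)
        logits = np.stack([np.full((4, 4), 50.0),
                           np.full((4, 4), -50.0)]).astype(np.float32)
        assert supervised_loss(logits, target, eps=1.0).item() == pytest.approx(
            0.0, abs=1e-4)

    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError):
            supervised_loss(np.zeros((2, 4, 4), np.float32),
                            np.zeros((5, 5), np.uint8))
        with pytest.raises(ValueError):
            supervised_loss(np.zeros((2, 4, 4), np.float32),
                            np.full((4, 4), 2, np.uint8))

    def test_gradients_finite_even_when_saturated(self):
        target = np.zeros((4, 4), np.uint8)
        target[0] = 1
        logits = Tensor(np.stack([np.full((4, 4), 80.0),
                                  np.full((4, 4), -80.0)]).astype(np.float32),
                        requires_grad=True)
        supervised_loss(logits, target).backward()
        assert np.isfinite(logits.grad).all()


# --------------------------------------------------------------- combine

class TestCombine:
    @pytest.mark.parametrize("alpha,beta,expected", [
        (0.0, 1.0, 5.0), (1.0, 0.0, 4.0), (0.0, 0.0, 3.0), (2.0, 0.5, 6.0),
    ])
    def test_weighted_total(self, alpha, beta, expected):
        bd = combine(1.0, 2.0, 3.0, StageWeights(alpha=alpha, beta=beta))
        assert bd.total == pytest.approx(expected)
        assert (bd.l_cc, bd.l_msc, bd.l_sup) == (1.0, 2.0, 3.0)

    def test_stage_regime(self):
        assert StageWeights.for_epoch(10, 70) == StageWeights(0.0, 1.0)
        assert StageWeights.for_epoch(70, 70) == StageWeights(1.0, 0.0)

    def test_nonfinite_term_raises(self):
        with pytest.raises(FloatingPointError, match="l_msc"):
            combine(1.0, float("nan"), 3.0, StageWeights(1.0, 1.0))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            StageWeights(alpha=-1.0, beta=0.0)
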