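import numpy as np
import pytest

from rkit.nn import (
    NetConfig,
    PairTrackNet,
    Tensor,
    flip_augment,
    ss_loss,
    train_overfit_demo,
)
from rkit.nn.autodiff import bce_with_logits, softmax
from rkit.nn.layers import OuterProductMean, TriangularUpdate
from rkit.structure import SecondaryStructure, parse_dotbracket

TINY = NetConfig(d_seq=16, d_pair=4, n_blocks=1, n_heads=2, conv_kernel=3,
                 downsample_rank=2, seed=11)


# ---------------------------------------------------------------- autodiff
class TestAutodiff:
    def test_gradients_match_finite_differences(self, rng):
        w = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        x = Tensor(rng.normal(size=(5, 4)))

        def loss_value(wdata):
            h = np.tanh(x.data @ wdata)
            return (h * h).sum()

        y = (x @ w).tanh()
        loss = (y * y).sum()
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            wp = w.data.copy()
            wp[idx] += eps
            wm = w.data.copy()
            wm[idx] -= eps
            num = (loss_value(wp) - loss_value(wm)) / (2 * eps)
            assert w.grad[idx] == pytest.approx(num, rel=1e-5)

    def test_softmax_rows_sum_to_one_and_grad_is_centered(self, rng):
        x = Tensor(rng.normal(size=(3, 6)), requires_grad=True)
        y = softmax(x)
        np.testing.assert_allclose(y.data.sum(axis=-1), 1.0)
        (y * y).sum().backward()
        # softmax gradient rows are orthogonal to the all-ones direction
        np.testing.assert_allclose(x.grad.sum(axis=-1), 0.0, atol=1e-12)

    def test_bce_with_logits_matches_naive(self, rng):
        z = rng.normal(size=(4, 4))
        t = (rng.random((4, 4)) > 0.5).astype(float)
        p = 1 / (1 + np.exp(-z))
        naive = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert bce_with_logits(Tensor(z), t).data == pytest.approx(naive)


# ---------------------------------------------------------------- layer oracles
def triangular_oracle(layer: TriangularUpdate, pair: np.ndarray) -> np.ndarray:
    """Direct three-index loop computation from the layer's own weights."""

    def lin(mod, x):
        return x @ mod.weight.data + mod.bias.data

    def sig(x):
        return 1 / (1 + np.exp(-x))

    a = sig(lin(layer.gate_a, pair)) * lin(layer.proj_a, pair)
    b = sig(lin(layer.gate_b, pair)) * lin(layer.proj_b, pair)
    B, L, _, d = pair.shape
    agg = np.zeros_like(pair)
    for n in range(B):
        for i in range(L):
            for j in range(L):
                for k in range(L):
                    if layer.direction == "outgoing":
                        agg[n, i, j] += a[n, i, k] * b[n, j, k]
                    else:
                        agg[n, i, j] += a[n, k, i] * b[n, k, j]
    return sig(lin(layer.gate_out, pair)) * lin(layer.out, agg)


def opm_oracle(layer: OuterProductMean, x: np.ndarray) -> np.ndarray:
    def lin(mod, v):
        return v @ mod.weight.data + mod.bias.data

    a = lin(layer.proj_a, x)
    b = lin(layer.proj_b, x)
    B, L, r = a.shape
    out = np.zeros((B, L, L, layer.out.weight.shape[1]))
    for n in range(B):
        for i in range(L):
            for j in range(L):
                outer = np.outer(a[n, i], b[n, j]).reshape(-1)
                out[n, i, j] = outer @ layer.out.weight.data + layer.out.bias.data
    return out


class TestLayerOracles:
    @pytest.mark.parametrize("direction", ["outgoing", "incoming"])
    def test_triangular_update_matches_loop(self, direction, rng):
        layer = TriangularUpdate(3, direction, rng)
        pair = rng.normal(size=(2, 5, 5, 3))
        got = layer(Tensor(pair)).data
        np.testing.assert_allclose(got, triangular_oracle(layer, pair), atol=1e-5)

    def test_triangular_bounded_on_zero_input(self, rng):
        layer = TriangularUpdate(3, "outgoing", rng)
        out = layer(Tensor(np.zeros((1, 4, 4, 3)))).data
        assert np.all(np.isfinite(out))
        assert out.shape == (1, 4, 4, 3)

    def test_outer_product_mean_matches_loop(self, rng):
        layer = OuterProductMean(6, 4, 2, rng)
        x = rng.normal(size=(2, 5, 6))
        np.testing.assert_allclose(layer(Tensor(x)).data, opm_oracle(layer, x), atol=1e-5)

    def test_opm_zero_input_gives_bias_only(self, rng):
        layer = OuterProductMean(6, 4, 2, rng)
        x = np.zeros((1, 3, 6))
        expect = opm_oracle(layer, x)
        np.testing.assert_allclose(layer(Tensor(x)).data, expect, atol=1e-10)
        # bias-only output is identical at every (i, j)
        np.testing.assert_allclose(expect, np.broadcast_to(expect[:, :1, :1, :], expect.shape), atol=1e-10)


# ---------------------------------------------------------------- model
class TestForward:
    def test_reactivity_head_shape(self):
        net = PairTrackNet(TINY)
        out = net.forward("ACGU" * 5)
        assert out.per_position.shape == (20, 2)

    def test_dropout_head_positive(self):
        cfg = NetConfig(**{**TINY.__dict__, "head": "dropout"})
        net = PairTrackNet(cfg)
        for seq in ("ACGUACGUACGU", "GGGGGGGGGGGG", "UUUUCCCCAAAA"):
            assert net.forward(seq).scalar > 0

    def test_ss_head_symmetric_logits(self):
        cfg = NetConfig(**{**TINY.__dict__, "head": "secondary_structure"})
        net = PairTrackNet(cfg)
        logits = net.forward("ACGU" * 6).pair_logits
        np.testing.assert_allclose(logits, logits.T)

    def test_relative_positions_clip_at_eight(self):
        net = PairTrackNet(TINY)
        clip = TINY.rel_pos_clip
        offsets = np.arange(60)[None, :] - np.arange(60)[:, None]
        idx = np.clip(offsets, -clip, clip) + clip
        emb = net.rel_pos.data[idx]
        # |i - j| = 9 and |i - j| = 50 share one embedding row
        np.testing.assert_array_equal(emb[0, 9], emb[0, 50])
        assert not np.array_equal(emb[0, 7], emb[0, 9])

    def test_deterministic_across_instances(self):
        a = PairTrackNet(TINY).forward("ACGUGGCCAAUU")
        b = PairTrackNet(TINY).forward("ACGUGGCCAAUU")
        np.testing.assert_array_equal(a.per_position, b.per_position)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            PairTrackNet(TINY).forward("ACGT")  # DNA alphabet


class TestFlipAugment:
    def test_pure_reversal(self):
        seq, labels = flip_augment("ACGG", np.array([1.0, 2.0, 3.0, 4.0]))
        assert seq == "GGCA"
        np.testing.assert_array_equal(labels, [4, 3, 2, 1])

    def test_involution(self, rng):
        seq = "ACGUGGC"
        labels = rng.normal(size=(7, 2))
        s2, l2 = flip_augment(*flip_augment(seq, labels))
        assert s2 == seq
        np.testing.assert_array_equal(l2, labels)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            flip_augment("ACGU", np.zeros(3))


class TestSsLoss:
    def test_perfect_logits_drive_loss_to_zero(self):
        s = parse_dotbracket("((....))")
        logits = np.where(s.pair_matrix() > 0, 30.0, -30.0)
        loss = ss_loss(Tensor(logits), s, length_weighting=False)
        assert loss.data < 1e-8

    def test_positive_miss_costs_double(self):
        s = SecondaryStructure(length=10, pairs=frozenset({(0, 9)}))
        base = np.where(s.pair_matrix() > 0, 30.0, -30.0)
        pos_missed = base.copy()
        pos_missed[0, 9] = pos_missed[9, 0] = 0.0  # two positive cells at p=0.5
        neg_missed = base.copy()
        neg_missed[2, 7] = neg_missed[7, 2] = 0.0  # two negative cells at p=0.5
        lp = ss_loss(Tensor(pos_missed), s, length_weighting=False).data
        ln = ss_loss(Tensor(neg_missed), s, length_weighting=False).data
        assert lp / ln == pytest.approx(2.0, rel=1e-6)

    def test_length_weighting_scales_by_l_squared(self):
        s1 = SecondaryStructure(length=10, pairs=frozenset({(0, 9)}))
        s2 = SecondaryStructure(length=20, pairs=frozenset({(0, 19)}))
        # proportional content: same mean BCE per cell
        l1 = ss_loss(Tensor(np.zeros((10, 10))), s1, length_weighting=True).data
        l2 = ss_loss(Tensor(np.zeros((20, 20))), s2, length_weighting=True).data
        m1 = ss_loss(Tensor(np.zeros((10, 10))), s1, length_weighting=False).data
        m2 = ss_loss(Tensor(np.zeros((20, 20))), s2, length_weighting=False).data
        assert l1 / m1 == pytest.approx(100.0)
        assert l2 / m2 == pytest.approx(400.0)


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path):
        net = PairTrackNet(TINY)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = PairTrackNet.load(path)
        a = net.forward("ACGUGGCCAAUUACGU")
        b = back.forward("ACGUGGCCAAUUACGU")
        np.testing.assert_array_equal(a.per_position, b.per_position)


class TestTraining:
    def test_identical_traces_for_identical_seeds(self):
        from rkit.simulate import SimConfig, simulate_reactivity, simulate_sequence, simulate_structure

        r = np.random.default_rng(2)
        cfg = SimConfig(seed=2)
        data = []
        for _ in range(4):
            s = simulate_structure(20, 0.0, r)
            data.append(
                (simulate_sequence(s, r),
                 np.stack([simulate_reactivity(s, cfg, r)] * 2, axis=1))
            )
        _, t1 = train_overfit_demo(data, TINY, epochs=5)
        _, t2 = train_overfit_demo(data, TINY, epochs=5)
        assert t1 == t2

    def test_desk_scale_limits_enforced(self):
        with pytest.raises(ValueError):
            train_overfit_demo([("A" * 61, np.zeros((61, 2)))], TINY, epochs=1)

    def test_flip_augmentation_improves_flip_equivariance(self):
        """Averaged over seeds, training with 3'-5' flip augmentation
        shrinks the gap between f(seq) and reverse(f(reverse(seq))) on
        held-out sequences."""
        from rkit.simulate import SimConfig, simulate_reactivity, simulate_sequence, simulate_structure

        def equivariance_gap(net, seqs):
            gaps = []
            for s in seqs:
                a = net.forward(s).per_position
                b = net.forward(s[::-1]).per_position[::-1]
                gaps.append(np.mean(np.abs(a - b)))
            return float(np.mean(gaps))

        plain_gaps, aug_gaps = [], []
        for seed in (1, 2, 3):
            sim = SimConfig(seed=100 + seed)
            rng = sim.rng()
            data = []
            for _ in range(20):
                s = simulate_structure(24, 0.2, rng)
                seq = simulate_sequence(s, rng)
                r = simulate_reactivity(s, sim, rng)
                data.append((seq, np.stack([r, 0.9 * r], axis=1)))
            held = [
                simulate_sequence(simulate_structure(24, 0.2, rng), rng)
                for _ in range(10)
            ]
            cfg = NetConfig(d_seq=16, d_pair=4, n_blocks=1, n_heads=2,
                            conv_kernel=3, downsample_rank=2, seed=seed,
                            learning_rate=1e-2)
            plain, _ = train_overfit_demo(data, cfg, epochs=60)
            augmented, _ = train_overfit_demo(data, cfg, epochs=60,
                                              flip_augmentation=True)
            plain_gaps.append(equivariance_gap(plain, held))
            aug_gaps.append(equivariance_gap(augmented, held))
        assert np.mean(aug_gaps) < np.mean(plain_gaps)

    def test_ss_head_overfits_and_decodes_to_training_structure(self):
        """Overfitting one structure and Hungarian-decoding the sigmoid of the
        learned pair logits recovers that structure exactly."""
        from rkit.scoring import f1_structure
        from rkit.structure import PairScoreMatrix, hungarian_decode

        s = parse_dotbracket("(((((......)))))..........")
        seq = "GGCGCAUAUAUGCGCCACGUACGUAC"
        cfg = NetConfig(d_seq=16, d_pair=4, n_blocks=1, n_heads=2, conv_kernel=3,
                        downsample_rank=2, seed=4, head="secondary_structure",
                        learning_rate=2e-2)
        net, trace = train_overfit_demo([(seq, s)], cfg, epochs=150)
        assert trace[-1] < trace[0]
        probs = 1 / (1 + np.exp(-net.forward(seq).pair_logits))
        decoded = hungarian_decode(PairScoreMatrix(probs))
        assert f1_structure(s, decoded).f1 == 1.0
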