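"""Dynamic sparse attention: mask statistics, algebraic reductions, oracle equivalence."""

import numpy as np
import pytest

from hdsnet.dsa import (
    DSABlock,
    FlatFeature,
    MemoryUnits,
    dsa_attend,
    flatten_feature,
    sample_bernoulli_mask,
    softmax_tokens,
    unflatten_feature,
)


# ---------------------------------------------------------------------------
# Bernoulli mask
# ---------------------------------------------------------------------------

class TestBernoulliMask:
    def test_degenerate_p_is_exact(self, rng):
        assert np.array_equal(sample_bernoulli_mask((2, 3), 1.0, rng), np.ones((2, 3)))
        assert np.array_equal(sample_bernoulli_mask((2, 3), 0.0, rng), np.zeros((2, 3)))

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_keep_fraction_within_99pct_binomial_interval(self, p):
        n = 10_000
        mask = sample_bernoulli_mask((n,), p, np.random.default_rng(2024))
        assert set(np.unique(mask)) <= {0.0, 1.0}
        half_width = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(mask.mean() - p) < half_width

    def test_reproducible_from_seed(self):
        a = sample_bernoulli_mask((50, 50), 0.7, np.random.default_rng(3))
        b = sample_bernoulli_mask((50, 50), 0.7, np.random.default_rng(3))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_probability_rejected(self, p, rng):
        with pytest.raises(ValueError):
            sample_bernoulli_mask((2, 2), p, rng)

    @pytest.mark.parametrize("shape", [(), (0, 3), (2, -1)])
    def test_invalid_shape_rejected(self, shape, rng):
        with pytest.raises(ValueError):
            sample_bernoulli_mask(shape, 0.5, rng)


# ---------------------------------------------------------------------------
# flatten / attend
# ---------------------------------------------------------------------------

def _oracle_attend(q, k, v, mask):
    """Straight-line scalar-loop reference: softmax over tokens, mask, times V."""
    b, c, s = q.shape
    out = np.zeros((b, c, s))
    for bi in range(b):
        for ci in range(c):
            scores = [q[bi, ci, si] * k[ci, si] for si in range(s)]
            mx = max(scores)
            exps = [np.exp(x - mx) for x in scores]
            z = sum(exps)
            for si in range(s):
                alpha = exps[si] / z * mask[bi, ci, si]
                out[bi, ci, si] = alpha * v[ci, si]
    return out


class TestDsaAttend:
    def test_flatten_unflatten_roundtrip(self, rng):
        x = rng.normal(size=(2, 5, 3, 4))
        f = flatten_feature(x)
        assert f.values.shape == (2, 5, 12)
        assert np.array_equal(unflatten_feature(f), x)

    def test_flatfeature_token_invariant(self, rng):
        with pytest.raises(ValueError):
            FlatFeature(rng.normal(size=(1, 2, 5)), height=2, width=3)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            c = int(rng.integers(1, 3))
            s = int(rng.integers(1, 5))
            h, w = (1, s)
            q = rng.normal(size=(1, c, s))
            k = rng.normal(size=(c, s))
            v = rng.normal(size=(c, s))
            mask = sample_bernoulli_mask((1, c, s), 0.6, rng)
            got = dsa_attend(FlatFeature(q, h, w), MemoryUnits(k, v), mask).values
            want = _oracle_attend(q, k, v, mask)
            assert np.max(np.abs(got - want)) <= 1e-6

    def test_uniform_scores_hand_example(self):
        # Q=[1,1], K=[0,0] -> M=[0,0], softmax uniform, out = [2, 4] for V=[4,8]
        f = FlatFeature(np.array([[[1.0, 1.0]]]), 1, 2)
        mem = MemoryUnits(np.array([[0.0, 0.0]]), np.array([[4.0, 8.0]]))
        out = dsa_attend(f, mem, np.ones((1, 1, 2))).values
        assert np.allclose(out, [[[2.0, 4.0]]])

    def test_all_ones_mask_equals_unmasked_attention(self, rng):
        q = rng.normal(size=(2, 3, 8))
        k = rng.normal(size=(3, 8))
        v = rng.normal(size=(3, 8))
        masked = dsa_attend(FlatFeature(q, 2, 4), MemoryUnits(k, v), np.ones((2, 3, 8))).values
        unmasked = softmax_tokens(q * k[None]) * v[None]
        assert np.max(np.abs(masked - unmasked)) == 0.0

    def test_all_zeros_mask_zeroes_output(self, rng):
        q = rng.normal(size=(1, 2, 6))
        out = dsa_attend(
            FlatFeature(q, 2, 3),
            MemoryUnits(rng.normal(size=(2, 6)), rng.normal(size=(2, 6))),
            np.zeros((1, 2, 6)),
        ).values
        assert np.array_equal(out, np.zeros_like(out))

    def test_premask_softmax_normalizes_over_tokens(self, rng):
        scores = rng.normal(size=(4, 3, 17)) * 10
        alpha = softmax_tokens(scores)
        assert np.allclose(alpha.sum(axis=-1), 1.0, atol=1e-5)
        assert (alpha >= 0).all()

    def test_masked_scores_bounded_by_premask(self, rng):
        q = rng.normal(size=(1, 2, 9))
        k = rng.normal(size=(2, 9))
        alpha = softmax_tokens(q * k[None])
        mask = sample_bernoulli_mask((1, 2, 9), 0.5, rng)
        masked = alpha * mask
        assert (masked >= 0).all() and (masked <= alpha).all()

    def test_shape_mismatch_is_structural_error(self, rng):
        f = FlatFeature(rng.normal(size=(1, 2, 6)), 2, 3)
        with pytest.raises(ValueError):
            dsa_attend(f, MemoryUnits(rng.normal(size=(2, 5)), rng.normal(size=(2, 5))), np.ones((1, 2, 6)))
        with pytest.raises(ValueError):
            dsa_attend(f, MemoryUnits(rng.normal(size=(2, 6)), rng.normal(size=(2, 6))), np.ones((1, 2, 5)))

    def test_nan_input_reported(self, rng):
        q = rng.normal(size=(1, 1, 4))
        q[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            dsa_attend(FlatFeature(q, 1, 4), MemoryUnits(np.ones((1, 4)), np.ones((1, 4))), np.ones((1, 1, 4)))


# ---------------------------------------------------------------------------
# full block
# ---------------------------------------------------------------------------

class TestDSABlock:
    def _block(self, p=0.9, seed=0):
        return DSABlock(6, 4, 4, p=p, rng=np.random.default_rng(seed))

    def test_output_shape_equals_input_shape(self, rng):
        blk = self._block()
        x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
        assert blk(x).shape == x.shape

    def test_eval_mode_is_deterministic(self, rng):
        blk = self._block().eval()
        x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
        assert np.array_equal(blk(x), blk(x))

    def test_train_mode_resamples_mask(self, rng):
        blk = self._block(p=0.5).train()
        x = rng.normal(size=(1, 6, 4, 4)).astype(np.float32)
        assert not np.array_equal(blk(x), blk(x))

    def test_p1_train_equals_eval(self, rng):
        blk = self._block(p=1.0)
        x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
        y_train = blk.train()(x)
        y_eval = blk.eval()(x)
        assert np.array_equal(y_train, y_eval)

    def test_wrong_resolution_raises_actionable_error(self, rng):
        blk = self._block()
        with pytest.raises(ValueError, match="memory-unit token count"):
            blk(rng.normal(size=(1, 6, 8, 8)).astype(np.float32))

    def test_invalid_sparse_ratio_rejected(self):
        with pytest.raises(ValueError):
            DSABlock(4, 2, 2, p=1.2, rng=np.random.default_rng(0))
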