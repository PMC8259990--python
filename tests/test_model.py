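"""Transformer primitives, full forward pass, loss, and checkpointing."""

import math
import random

import numpy as np
import pytest

from condlm import model as M
from condlm.autograd import Tensor
from condlm.corpus import TrainingWindow


def tiny_config(**kw):
    defaults = dict(embed_dim=16, heads=2, encoder_layers=1, decoder_layers=2,
                    ff_dim=32, dropout=0.1, max_seq=16, vocab_size=20,
                    n_conditions=8)
    defaults.update(kw)
    return M.ModelConfig(**defaults)


def window(input_ids, conds=(5, 2, 3)):
    n = len(input_ids)
    return TrainingWindow(input_ids=list(input_ids),
                          token_targets=list(input_ids[1:]) + [3],
                          pos_targets=[0] * n, dep_targets=[0] * n,
                          ent_targets=[0] * n, condition_ids=list(conds))


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = M.positional_encoding(3, 8)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_position_one_first_column_is_sin_one(self):
        pe = M.positional_encoding(2, 4)
        assert pe[1, 0] == pytest.approx(math.sin(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(math.cos(1.0), abs=1e-12)

    def test_entries_bounded(self):
        pe = M.positional_encoding(50, 12)
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            M.positional_encoding(4, 5)


class TestAttention:
    def test_equal_scores_average_values(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = M.attention(np.zeros((2, 2)), np.zeros((3, 2)), V)
        assert np.allclose(out.data, V.mean(axis=0))

    def test_hand_computed_softmax(self):
        out = M.attention(np.array([[1.0, 0.0]]), np.eye(2), np.eye(2))
        assert out.data[0] == pytest.approx([0.670, 0.330], abs=1e-3)

    def test_causal_mask_zeroes_future_weights(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(4, 3))
        mask = np.tril(np.ones((4, 4), dtype=bool))
        # identity V exposes the weight matrix directly
        out = M.attention(Q, K, np.eye(4), mask=mask)
        assert np.all(np.triu(out.data, k=1) == 0.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = M.attention(rng.normal(size=(5, 4)), rng.normal(size=(6, 4)),
                          np.eye(6))
        assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_fully_masked_row_rejected(self):
        with pytest.raises(ValueError):
            M.attention(np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2),
                        mask=np.array([[True, True], [False, False]]))


class TestMultiHead:
    def test_single_head_identity_mix_reduces_to_attention(self):
        rng = np.random.default_rng(2)
        d = 4
        X = rng.normal(size=(3, d))
        params = {k: Tensor(rng.normal(size=(d, d))) for k in ("wq", "wk", "wv")}
        params["wo"] = Tensor(np.eye(d))
        out = M.multi_head(X, X, params, heads=1)
        direct = M.attention(X @ params["wq"].data, X @ params["wk"].data,
                             X @ params["wv"].data)
        assert np.allclose(out.data, direct.data, atol=1e-12)

    def test_output_rows_follow_queries(self):
        rng = np.random.default_rng(3)
        d = 8
        params = {k: Tensor(rng.normal(size=(d, d)))
                  for k in ("wq", "wk", "wv", "wo")}
        out = M.multi_head(rng.normal(size=(5, d)), rng.normal(size=(9, d)),
                           params, heads=2)
        assert out.shape == (5, d)

    def test_matches_per_head_loop_oracle(self):
        rng = np.random.default_rng(4)
        d, heads = 8, 4
        X = rng.normal(size=(4, d))
        Y = rng.normal(size=(6, d))
        params = {k: Tensor(rng.normal(size=(d, d)))
                  for k in ("wq", "wk", "wv", "wo")}
        out = M.multi_head(X, Y, params, heads=heads)
        dh = d // heads
        hs = []
        for i in range(heads):
            sl = slice(i * dh, (i + 1) * dh)
            q = X @ params["wq"].data[:, sl]
            k = Y @ params["wk"].data[:, sl]
            v = Y @ params["wv"].data[:, sl]
            w = np.exp(q @ k.T / np.sqrt(dh))
            w /= w.sum(axis=-1, keepdims=True)
            hs.append(w @ v)
        oracle = np.concatenate(hs, axis=-1) @ params["wo"].data
        assert np.allclose(out.data, oracle, atol=1e-6)


class TestFeedForward:
    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(5)
        params = {"w1": Tensor(rng.normal(size=(4, 8))),
                  "w2": Tensor(rng.normal(size=(8, 4)))}
        assert np.all(M.feed_forward(np.zeros((3, 4)), params).data == 0.0)

    def test_relu_kills_negative_preactivations(self):
        params = {"w1": Tensor(-np.ones((4, 8))),
                  "w2": Tensor(np.ones((8, 4)))}
        X = np.abs(np.random.default_rng(6).normal(size=(3, 4)))
        assert np.all(M.feed_forward(X, params).data == 0.0)

    def test_matches_two_matmul_oracle(self):
        rng = np.random.default_rng(7)
        params = {"w1": Tensor(rng.normal(size=(4, 8))),
                  "w2": Tensor(rng.normal(size=(8, 4)))}
        X = rng.normal(size=(5, 4))
        oracle = np.maximum(X @ params["w1"].data, 0.0) @ params["w2"].data
        assert np.allclose(M.feed_forward(X, params).data, oracle, atol=1e-12)


class TestBlocks:
    def _layer(self, rng, d=8, ff=16):
        return {"attn": {k: Tensor(rng.normal(size=(d, d)))
                         for k in ("wq", "wk", "wv", "wo")},
                "ln1": {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))},
                "ff": {"w1": Tensor(rng.normal(size=(d, ff))),
                       "w2": Tensor(rng.normal(size=(ff, d)))},
                "ln2": {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))}}

    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(8)
        layer = self._layer(rng)
        X = rng.normal(size=(4, 8))
        a = M.encoder_block(X, layer, heads=2)
        b = M.encoder_block(X, layer, heads=2)
        assert np.array_equal(a.data, b.data)

    def test_output_rows_normalized(self):
        rng = np.random.default_rng(9)
        out = M.encoder_block(rng.normal(size=(4, 8)), self._layer(rng), heads=2)
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-9)
        assert np.allclose(out.data.var(axis=-1), 1.0, atol=1e-3)

    def test_single_condition_row_passes(self):
        rng = np.random.default_rng(10)
        out = M.encoder_block(rng.normal(size=(1, 8)), self._layer(rng), heads=2)
        assert out.shape == (1, 8)

    def test_decoder_causality_and_cross_sensitivity(self):
        rng = np.random.default_rng(11)
        d = 8
        layer = {"self": {k: Tensor(rng.normal(size=(d, d)))
                          for k in ("wq", "wk", "wv", "wo")},
                 "ln1": {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))},
                 "cross": {k: Tensor(rng.normal(size=(d, d)))
                           for k in ("wq", "wk", "wv", "wo")},
                 "ln2": {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))},
                 "ff": {"w1": Tensor(rng.normal(size=(d, 16))),
                        "w2": Tensor(rng.normal(size=(16, d)))},
                 "ln3": {"g": Tensor(np.ones(d)), "b": Tensor(np.zeros(d))}}
        X = rng.normal(size=(5, d))
        Y = rng.normal(size=(3, d))
        mask = np.tril(np.ones((5, 5), dtype=bool))
        base = M.decoder_block(X, Y, layer, heads=2, self_mask=mask)
        X2 = X.copy()
        X2[3] += 1.0
        pert = M.decoder_block(X2, Y, layer, heads=2, self_mask=mask)
        assert np.allclose(base.data[:3], pert.data[:3], atol=1e-12)
        assert not np.allclose(base.data[3:], pert.data[3:])
        Y2 = Y.copy()
        Y2[0] += 1.0
        pert_y = M.decoder_block(X, Y2, layer, heads=2, self_mask=mask)
        assert not np.allclose(base.data[0], pert_y.data[0])


@pytest.fixture(scope="module")
def setup():
    cfg = tiny_config()
    return cfg, M.init_params(cfg, seed=1)


class TestForward:
    def test_condition_permutation_invariance(self, setup):
        cfg, params = setup
        a = M.forward_window(window([2, 5, 6, 7], conds=[5, 2, 3]), params)
        b = M.forward_window(window([2, 5, 6, 7], conds=[3, 5, 2]), params)
        assert np.allclose(a.token_logits.data, b.token_logits.data, atol=1e-12)

    def test_causality_through_full_model(self, setup):
        cfg, params = setup
        a = M.forward_window(window([2, 5, 6, 7, 8]), params)
        b = M.forward_window(window([2, 5, 6, 9, 8]), params)
        assert np.allclose(a.token_logits.data[0, :3],
                           b.token_logits.data[0, :3], atol=1e-9)
        assert not np.allclose(a.token_logits.data[0, 3:],
                               b.token_logits.data[0, 3:])

    def test_four_logit_tracks_with_configured_widths(self, setup):
        cfg, params = setup
        out = M.forward_window(window([2, 5, 6]), params)
        assert out.token_logits.shape == (1, 3, cfg.vocab_size)
        assert out.pos_logits.shape[-1] == cfg.n_pos
        assert out.dep_logits.shape[-1] == cfg.n_dep
        assert out.ent_logits.shape[-1] == cfg.n_ent == 15

    def test_overlong_window_rejected(self, setup):
        cfg, params = setup
        with pytest.raises(ValueError, match="max_seq"):
            M.forward_window(window(list(range(2, 2 + 17))), params)

    def test_train_mode_requires_rng_and_differs(self, setup):
        cfg, params = setup
        w = window([2, 5, 6, 7])
        with pytest.raises(ValueError):
            M.forward_window(w, params, mode="train")
        a = M.forward_window(w, params, mode="train",
                             rng=np.random.default_rng(0))
        b = M.forward_window(w, params)
        assert not np.allclose(a.token_logits.data, b.token_logits.data)


class TestLoss:
    def test_uniform_logits_give_log_vocab(self):
        z = Tensor(np.zeros((1, 3, 4)))
        out = M.ForwardOutput(z, z, z, z)
        batch = M.collate([window([2, 5, 6], conds=[1])])
        batch.pos_targets = batch.dep_targets = batch.ent_targets = \
            np.zeros((1, 3), dtype=np.int64)
        batch.token_targets = np.zeros((1, 3), dtype=np.int64)
        total, comp = M.multitask_loss(out, batch)
        for c in comp.values():
            assert float(c.data) == pytest.approx(math.log(4), abs=1e-12)
        assert float(total.data) == pytest.approx(4 * math.log(4), abs=1e-12)

    def test_confident_correct_logits_drive_loss_to_zero(self):
        z = np.full((1, 2, 4), -1e3)
        z[..., 1] = 1e3
        out = M.ForwardOutput(Tensor(z), Tensor(z), Tensor(z), Tensor(z))
        batch = M.collate([window([2, 5], conds=[1])])
        for name in ("token_targets", "pos_targets", "dep_targets",
                     "ent_targets"):
            setattr(batch, name, np.ones((1, 2), dtype=np.int64))
        total, _ = M.multitask_loss(out, batch)
        assert float(total.data) == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_label_rejected(self):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=0)
        w = window([2, 5, 6])
        batch = M.collate([w])
        batch.ent_targets = np.full((1, 3), 99, dtype=np.int64)
        out = M.forward(batch, params)
        with pytest.raises(ValueError, match="out of range"):
            M.multitask_loss(out, batch)

    def test_gradient_check_on_toy_config(self):
        cfg = tiny_config(decoder_layers=1)
        params = M.init_params(cfg, seed=2)
        batch = M.collate([window([2, 5, 6, 7]), window([2, 8, 9, 10])])

        def loss():
            return M.multitask_loss(M.forward(batch, params), batch)[0]

        total = loss()
        total.backward()
        rnd = random.Random(0)
        for name, t in params.named_tensors():
            if t.grad is None:
                continue
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            for i in rnd.sample(range(flat.size), min(2, flat.size)):
                eps, old = 1e-5, flat[i]
                flat[i] = old + eps
                lp = float(loss().data)
                flat[i] = old - eps
                lm = float(loss().data)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert (abs(num - gflat[i]) < 1e-7
                        or abs(num - gflat[i]) / abs(num) < 1e-3), name


class TestCheckpoint:
    def test_roundtrip_reproduces_logits_exactly(self, tmp_path):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=3)
        w = window([2, 5, 6, 7])
        before = M.forward_window(w, params).token_logits.data
        path = tmp_path / "model.npz"
        M.save_checkpoint(str(path), params, step=7)
        loaded, step, _ = M.load_checkpoint(str(path))
        assert step == 7
        after = M.forward_window(w, loaded).token_logits.data
        assert np.array_equal(before, after)
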