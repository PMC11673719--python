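import numpy as np
import pytest

from chemnmt import autodiff as ad
from chemnmt.model import (Adam, ModelConfig, Transformer, build_transformer,
                           learning_rate, masked_accuracy, masked_loss, train)
from chemnmt.tokens import PAD_ID


def closed_form_lr(step, d_model, warmup):
    return d_model ** -0.5 * min(step ** -0.5, step * warmup ** -1.5)


class TestLearningRate:
    def test_degenerate_point(self):
        assert learning_rate(1, 1, 1) == pytest.approx(1.0)

    def test_crossover_value(self):
        # at step == warmup both branches coincide: 512^-0.5 * 4000^-0.5
        assert learning_rate(4000, 512, 4000) == pytest.approx(
            512 ** -0.5 * 4000 ** -0.5, rel=1e-12)
        assert learning_rate(4000, 512, 4000) == pytest.approx(6.99e-4, rel=1e-3)

    @pytest.mark.parametrize("step", [1, 2, 17, 399, 4000, 4001, 10 ** 5, 10 ** 6])
    def test_matches_closed_form(self, step):
        assert learning_rate(step, 512, 4000) == pytest.approx(
            closed_form_lr(step, 512, 4000), rel=1e-12)

    def test_warmup_linear_then_decay(self):
        warm = [learning_rate(s, 128, 100) for s in range(1, 100)]
        ratios = [b / a for a, b in zip(warm, warm[1:])]
        assert all(r > 1 for r in ratios)  # increasing during warmup
        decay = [learning_rate(s, 128, 100) for s in (200, 800, 3200)]
        # inverse-sqrt decay: quadrupling the step halves the rate
        assert decay[1] == pytest.approx(decay[0] / 2, rel=1e-9)
        assert decay[2] == pytest.approx(decay[1] / 2, rel=1e-9)


class TestMaskedLoss:
    def test_uniform_logits_give_log_v(self):
        V = 7
        labels = np.array([[3, PAD_ID, PAD_ID]])
        logits = np.zeros((1, 3, V))
        assert masked_loss(labels, logits) == pytest.approx(np.log(V), abs=1e-6)

    def test_padding_invariance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 9, size=(4, 6))
        logits = rng.normal(size=(4, 6, 9))
        base = masked_loss(labels, logits)
        padded_labels = np.concatenate(
            [labels, np.full((4, 3), PAD_ID)], axis=1)
        padded_logits = np.concatenate(
            [logits, rng.normal(size=(4, 3, 9))], axis=1)
        assert masked_loss(padded_labels, padded_logits) == pytest.approx(
            base, rel=1e-9)

    def test_perfect_prediction_loss_vanishes(self):
        labels = np.array([[2, 5, PAD_ID]])
        logits = np.full((1, 3, 8), -30.0)
        logits[0, 0, 2] = 30.0
        logits[0, 1, 5] = 30.0
        assert masked_loss(labels, logits) == pytest.approx(0.0, abs=1e-6)

    def test_all_pad_batch_is_zero(self):
        labels = np.full((2, 3), PAD_ID)
        assert masked_loss(labels, np.zeros((2, 3, 5))) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            masked_loss(np.zeros((2, 3), dtype=int), np.zeros((2, 4, 5)))


class TestMaskedAccuracy:
    def test_extremes_and_pad_invariance(self):
        labels = np.array([[1, 2, PAD_ID]])
        logits = np.zeros((1, 3, 4))
        logits[0, 0, 1] = 5
        logits[0, 1, 2] = 5
        assert masked_accuracy(labels, logits) == 1.0
        logits[0, 0, 1] = -5
        logits[0, 1, 2] = -5
        logits[0, 0, 3] = 5
        logits[0, 1, 3] = 5
        assert masked_accuracy(labels, logits) == 0.0
        more_pad = np.array([[1, 2, PAD_ID, PAD_ID, PAD_ID]])
        padded = np.concatenate([logits, np.zeros((1, 2, 4))], axis=1)
        assert masked_accuracy(more_pad, padded) == 0.0


TINY = dict(num_layers=1, num_heads=2, d_model=16, dff=32, dropout_rate=0.0,
            input_vocab=12, target_vocab=12, max_input_len=12,
            max_target_len=12, batch_size=4, warmup_steps=50)


class TestTransformer:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(num_heads=3, d_model=64)
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout_rate=1.0)

    def test_seeded_init_deterministic(self):
        a = build_transformer(ModelConfig(**TINY, seed=9))
        b = build_transformer(ModelConfig(**TINY, seed=9))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
        c = build_transformer(ModelConfig(**TINY, seed=10))
        assert any((a.params[k].data != c.params[k].data).any()
                   for k in a.params)

    def test_causal_mask_blocks_future(self):
        model = build_transformer(ModelConfig(**TINY, seed=1))
        inp = np.array([[1, 4, 5, 2]])
        dec = np.array([[1, 6, 7, 8]])
        base = model.forward(inp, dec).data.copy()
        edited = dec.copy()
        edited[0, 3] = 9  # change the last target token only
        out = model.forward(inp, edited).data
        np.testing.assert_allclose(out[0, :3], base[0, :3], atol=1e-5)

    def test_padding_mask_shields_real_positions(self):
        model = build_transformer(ModelConfig(**TINY, seed=1))
        inp = np.array([[1, 4, 5, 2, PAD_ID, PAD_ID]])
        longer = np.array([[1, 4, 5, 2, PAD_ID, PAD_ID, PAD_ID, PAD_ID]])
        e1 = model.encode(inp).data
        e2 = model.encode(longer).data
        np.testing.assert_allclose(e1[0, :4], e2[0, :4], atol=1e-5)

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(**{**TINY, "d_model": 8, "dff": 16}, seed=3)
        model = Transformer(cfg)
        rng = np.random.default_rng(0)
        inp = rng.integers(1, 12, size=(2, 5))
        tar = rng.integers(1, 12, size=(2, 6))

        def loss():
            logits = model.forward(inp, tar[:, :-1])
            mask = (tar[:, 1:] != PAD_ID).astype(np.float32)
            l, _ = ad.masked_softmax_cross_entropy(logits, tar[:, 1:], mask)
            return l

        l = loss()
        l.backward()
        for key in ["emb_in", "enc0.a0.Wq", "dec0.a1.Wk", "out.W"]:
            grad = model.params[key].grad
            idx = tuple(rng.integers(0, s) for s in grad.shape)
            eps = 1e-2
            p = model.params[key]
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss().data)
            p.data[idx] = orig - eps
            lm = float(loss().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=0.05, abs=1e-4)


def _toy_data(rng, n=32, v=12, li=8, lt=10):
    inp = np.zeros((n, li), dtype=np.int64)
    tar = np.zeros((n, lt), dtype=np.int64)
    for i in range(n):
        k = rng.integers(3, li - 2)
        seq = rng.integers(4, v, size=k)
        inp[i, 0] = 1
        inp[i, 1:k + 1] = seq
        inp[i, k + 1] = 2
        tar[i, 0] = 1
        tar[i, 1:k + 1] = seq[::-1]  # learn to reverse
        tar[i, k + 1] = 2
    return inp, tar


class TestTraining:
    def test_vocab_mismatch_rejected_before_training(self):
        model = build_transformer(ModelConfig(**TINY, seed=0))
        bad = np.full((4, 6), 99)
        with pytest.raises(ValueError, match="vocabulary"):
            train(model, (bad, bad))

    def test_same_seed_same_loss_trace(self):
        rng = np.random.default_rng(1)
        data = _toy_data(rng)
        cfg = ModelConfig(**TINY, seed=5)
        h1 = train(build_transformer(cfg), data, cfg, epochs=3)
        h2 = train(build_transformer(cfg), data, cfg, epochs=3)
        assert [s.train_loss for s in h1] == [s.train_loss for s in h2]

    def test_overfits_fixed_pairs(self):
        """Capacity sanity check: 32 fixed pairs memorised to >=99% accuracy."""
        rng = np.random.default_rng(2)
        data = _toy_data(rng)
        cfg = ModelConfig(num_layers=2, num_heads=4, d_model=64, dff=128,
                          dropout_rate=0.0, input_vocab=12, target_vocab=12,
                          max_input_len=12, max_target_len=12, batch_size=32,
                          warmup_steps=60, seed=4)
        model = build_transformer(cfg)
        history = train(model, data, cfg, epochs=800)
        assert history[-1].step >= 300
        assert history[-1].train_accuracy >= 0.99

    def test_resume_from_checkpoint(self, tmp_path):
        rng = np.random.default_rng(3)
        data = _toy_data(rng)
        cfg = ModelConfig(**TINY, seed=6)
        model = build_transformer(cfg)
        opt = Adam(model.params, cfg)
        train(model, data, cfg, epochs=2, optimizer=opt)
        model.save(tmp_path / "ckpt", extra=opt.state())

        resumed = Transformer.load(tmp_path / "ckpt")
        opt2 = Adam(resumed.params, cfg)
        opt2.load_state(np.load(tmp_path / "ckpt" / "optimizer.npz"))
        assert opt2.step == opt.step
        for k in model.params:
            np.testing.assert_array_equal(model.params[k].data,
                                          resumed.params[k].data)
        h = train(resumed, data, cfg, epochs=1, optimizer=opt2)
        assert np.isfinite(h[-1].train_loss)

    def test_loss_decreases_on_learnable_corpus(self):
        rng = np.random.default_rng(4)
        data = _toy_data(rng)
        cfg = ModelConfig(**TINY, seed=7)
        history = train(build_transformer(cfg), data, cfg, epochs=40)
        assert history[-1].train_loss < history[0].train_loss
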