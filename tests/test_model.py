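"""Encoder architecture, MLM objective, schedule and batch semantics."""

import numpy as np
import pytest

from chemlm import model as M
from chemlm import nn
from chemlm.nn import Tensor
from chemlm.tokenizer import CLS_ID, MASK_ID, PAD_ID, SEP_ID


@pytest.fixture(scope="module")
def small_encoder():
    enc = M.TransformerEncoder(
        M.EncoderConfig(vocab_size=100, n_layers=2, n_heads=4, hidden=64,
                        intermediate=128, max_positions=64), seed=0)
    enc.eval()
    return enc


class TestEncoder:
    def test_output_shape(self, small_encoder):
        ids = np.array([[CLS_ID, 10, 11, 12, SEP_ID]])
        hidden, _ = small_encoder(ids)
        assert hidden.shape == (1, 5, 64)

    def test_attention_rows_sum_to_one(self, small_encoder):
        ids = np.array([[CLS_ID, 10, 11, 12, SEP_ID],
                        [CLS_ID, 20, SEP_ID, PAD_ID, PAD_ID]])
        pad = ids != PAD_ID
        _, attn = small_encoder(ids, pad, collect_attention=True)
        assert len(attn) == 2
        for layer in attn:
            assert layer.shape == (2, 4, 5, 5)
            np.testing.assert_allclose(layer.sum(axis=-1), 1.0, atol=1e-5)

    def test_eval_determinism(self, small_encoder):
        ids = np.array([[CLS_ID, 7, 8, SEP_ID]])
        a, _ = small_encoder(ids)
        b, _ = small_encoder(ids)
        np.testing.assert_array_equal(a.data, b.data)

    def test_over_length_input_errors(self, small_encoder):
        with pytest.raises(ValueError):
            small_encoder(np.zeros((1, 65), dtype=int))

    def test_padding_does_not_change_real_positions(self, small_encoder):
        seqs = [[CLS_ID, 10, 11, SEP_ID]]
        ids_a, pad_a = M.collate(seqs)
        ids_b, pad_b = M.collate(seqs, pad_to=10)
        ha, _ = small_encoder(ids_a, pad_a)
        hb, _ = small_encoder(ids_b, pad_b)
        np.testing.assert_allclose(ha.data[0], hb.data[0, :4], atol=1e-10)


class TestParameterCount:
    def test_zero_layer_closed_form(self):
        cfg = M.EncoderConfig(vocab_size=50, n_layers=0, n_heads=2, hidden=16,
                              intermediate=32, max_positions=10)
        enc = M.TransformerEncoder(cfg)
        # embeddings (word + position) + embedding LayerNorm only
        assert M.count_parameters(enc) == 50 * 16 + 10 * 16 + 2 * 16

    def test_tied_head_marginal_vocab_cost(self):
        def total(v):
            enc = M.TransformerEncoder(
                M.EncoderConfig(vocab_size=v, n_layers=1, n_heads=2, hidden=16,
                                intermediate=32, max_positions=10))
            return M.count_parameters(M.MlmModel(enc))

        # +1 vocab = one embedding row (tied decoder) + one decoder bias entry
        assert total(51) - total(50) == 16 + 1

    def test_closed_form_full_model(self):
        V, H, I, L, P = 60, 16, 32, 2, 12
        enc = M.TransformerEncoder(M.EncoderConfig(
            vocab_size=V, n_layers=L, n_heads=2, hidden=H, intermediate=I,
            max_positions=P))
        per_layer = 4 * (H * H + H) + 2 * 2 * H + (H * I + I) + (I * H + H)
        expect = V * H + P * H + 2 * H + L * per_layer
        assert M.count_parameters(enc) == expect
        head = (H * H + H) + 2 * H + V  # dense + norm + bias; decoder tied
        assert M.count_parameters(M.MlmModel(enc)) == expect + head


class TestMasking:
    def test_mask_prob_zero_is_noop(self):
        ids = np.array([[CLS_ID, 10, 11, SEP_ID]])
        corrupted, labels, sel = M.mask_tokens(ids, M.MlmConfig(mask_prob=0.0),
                                               vocab_size=100)
        np.testing.assert_array_equal(corrupted, ids)
        assert (labels == M.IGNORE_INDEX).all()
        assert not sel.any()

    def test_mask_prob_one_all_content_masked(self):
        ids = np.array([[CLS_ID, 10, 11, 12, SEP_ID, PAD_ID]])
        corrupted, labels, _ = M.mask_tokens(
            ids, M.MlmConfig(mask_prob=1.0, mask_split=(1.0, 0.0, 0.0)),
            vocab_size=100)
        np.testing.assert_array_equal(corrupted[0, 1:4], MASK_ID)
        np.testing.assert_array_equal(labels[0, 1:4], [10, 11, 12])

    def test_specials_never_corrupted(self):
        rng = np.random.default_rng(0)
        ids = np.full((64, 32), 10)
        ids[:, 0] = CLS_ID
        ids[:, -2] = SEP_ID
        ids[:, -1] = PAD_ID
        corrupted, labels, _ = M.mask_tokens(
            ids, M.MlmConfig(mask_prob=1.0, seed=1), vocab_size=100, rng=rng)
        for col in (0, 30, 31):
            np.testing.assert_array_equal(corrupted[:, col], ids[:, col])
            assert (labels[:, col] == M.IGNORE_INDEX).all()

    def test_empirical_fraction(self):
        """~100k content tokens: corrupted fraction within binomial bounds."""
        ids = np.full((500, 202), 10)
        ids[:, 0] = CLS_ID
        ids[:, -1] = SEP_ID
        _, labels, _ = M.mask_tokens(ids, M.MlmConfig(mask_prob=0.15, seed=3),
                                     vocab_size=100)
        frac = (labels != M.IGNORE_INDEX).sum() / (500 * 200)
        assert frac == pytest.approx(0.15, abs=0.005)

    def test_no_content_tokens_is_not_an_error(self):
        ids = np.array([[CLS_ID, SEP_ID, PAD_ID]])
        corrupted, labels, sel = M.mask_tokens(ids, M.MlmConfig(mask_prob=1.0),
                                               vocab_size=100)
        assert not sel.any()


class TestMlmLoss:
    def test_uniform_logits_give_log_vocab(self):
        V = 17
        logits = Tensor(np.zeros((1, 1, V)), requires_grad=True)
        labels = np.array([[3]])
        loss, n = M.mlm_loss(logits, labels)
        assert n == 1
        assert float(loss.data) == pytest.approx(np.log(V))

    def test_confident_correct_logits_near_zero(self):
        logits_arr = np.zeros((1, 1, 10))
        logits_arr[0, 0, 4] = 50.0
        loss, _ = M.mlm_loss(Tensor(logits_arr, requires_grad=True),
                             np.array([[4]]))
        assert float(loss.data) < 1e-6

    def test_matches_direct_softmax_arithmetic(self, rng):
        logits_arr = rng.normal(size=(1, 4, 6))
        labels = np.array([[2, M.IGNORE_INDEX, 0, 5]])
        loss, n = M.mlm_loss(Tensor(logits_arr, requires_grad=True), labels)
        assert n == 3
        expect = 0.0
        for pos, lab in [(0, 2), (2, 0), (3, 5)]:
            z = logits_arr[0, pos]
            expect += -(z[lab] - np.log(np.exp(z).sum()))
        assert float(loss.data) == pytest.approx(expect / 3)

    def test_no_corrupted_positions_defined_zero(self):
        loss, n = M.mlm_loss(Tensor(np.zeros((1, 2, 5))),
                             np.full((1, 2), M.IGNORE_INDEX))
        assert n == 0 and float(loss.data) == 0.0


class TestSchedule:
    def test_endpoints_and_peak(self):
        s = M.Schedule(peak_lr=6e-4, warmup_steps=100, total_steps=1000)
        assert M.lr_at_step(s, 0) == 0.0
        assert M.lr_at_step(s, 100) == pytest.approx(6e-4)
        assert M.lr_at_step(s, 1000) == pytest.approx(s.end_lr)

    def test_continuous_and_piecewise_monotone(self):
        s = M.Schedule(peak_lr=1e-3, warmup_steps=50, total_steps=500,
                       power=2.0, end_lr=1e-5)
        lrs = [M.lr_at_step(s, t) for t in range(501)]
        diffs = np.diff(lrs)
        assert (diffs[:49] > 0).all()          # warmup increases
        assert (diffs[50:] <= 0).all()         # decay never increases
        assert abs(lrs[50] - lrs[49]) < 2.1e-5  # no jump at the seam

    def test_out_of_range_errors(self):
        s = M.Schedule(total_steps=10)
        with pytest.raises(ValueError):
            M.lr_at_step(s, 11)
        with pytest.raises(ValueError):
            M.lr_at_step(s, -1)


class TestBatchPlan:
    @pytest.mark.parametrize("plan,expected", [
        ((8, 32, 16), 4096),
        ((1, 1, 1), 1),
        ((8, 32, 1), 256),
    ])
    def test_effective_batch_size(self, plan, expected):
        assert M.effective_batch_size(M.BatchPlan(*plan)) == expected


class TestGradientAccumulation:
    def test_micro_batches_equal_one_large_batch(self, tiny_corpus,
                                                 tiny_tokenizer):
        """k micro-batches accumulate to the large-batch gradient (<1e-5)."""
        enc = M.TransformerEncoder(M.desk_config(tiny_tokenizer.vocab_size),
                                   seed=0)
        model = M.MlmModel(enc)
        model.eval()  # no dropout: determinism for the comparison
        seqs = [tiny_tokenizer.encode(s).ids for s in tiny_corpus[:32]]
        ids, pad = M.collate(seqs)
        corrupted, labels, _ = M.mask_tokens(ids, M.MlmConfig(seed=7),
                                             tiny_tokenizer.vocab_size)
        total = int((labels != M.IGNORE_INDEX).sum())

        model.zero_grad()
        hidden, _ = model.encoder(corrupted, pad)
        loss, _ = M.mlm_loss(model.head(hidden), labels)
        loss.backward()
        big = {id(p): p.grad.copy() for p in model.parameters()}

        model.zero_grad()
        for lo in range(0, 32, 8):
            sl = slice(lo, lo + 8)
            L = int(pad[sl].sum(axis=1).max())
            hidden, _ = model.encoder(corrupted[sl, :L], pad[sl, :L])
            micro_loss, n = M.mlm_loss(model.head(hidden), labels[sl, :L])
            if n:
                (micro_loss * (n / total)).backward()
        for p in model.parameters():
            a = big[id(p)]
            b = p.grad if p.grad is not None else np.zeros_like(p.data)
            denom = np.abs(a).max() + 1e-12
            assert np.abs(a - b).max() / denom < 1e-5


class TestPretrain:
    def test_loss_decreases_and_is_deterministic(self, tiny_corpus,
                                                 tiny_tokenizer):
        def run():
            enc = M.TransformerEncoder(M.desk_config(tiny_tokenizer.vocab_size),
                                       seed=0)
            _, trace = M.pretrain(tiny_corpus, tiny_tokenizer, enc, epochs=1,
                                  seed=5,
                                  plan=M.BatchPlan(per_device=8, accum_steps=4))
            return trace

        t1, t2 = run(), run()
        assert [e.loss for e in t1] == [e.loss for e in t2]
        losses = [e.loss for e in t1]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_checkpoint_round_trip(self, tmp_path, tiny_corpus, tiny_tokenizer):
        enc = M.TransformerEncoder(M.desk_config(tiny_tokenizer.vocab_size),
                                   seed=0)
        enc, trace = M.pretrain(tiny_corpus[:64], tiny_tokenizer, enc, epochs=1,
                                seed=5, checkpoint_dir=tmp_path / "ckpt")
        loaded = M.load_checkpoint(tmp_path / "ckpt")
        ids = np.array([tiny_tokenizer.encode("CCO").ids])
        a, _ = enc(ids)
        b, _ = loaded(ids)
        np.testing.assert_allclose(a.data, b.data)
        trace_csv = (tmp_path / "ckpt" / "trace.csv").read_text().splitlines()
        assert trace_csv[0] == "step,lr,loss"
        assert len(trace_csv) == len(trace) + 1

    def test_empty_corpus_errors(self, tiny_tokenizer):
        enc = M.TransformerEncoder(M.desk_config(tiny_tokenizer.vocab_size))
        with pytest.raises(ValueError):
            M.pretrain([], tiny_tokenizer, enc)
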