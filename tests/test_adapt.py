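"""Fine-tuning strategies, Siamese contracts, classical heads, splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemlm import adapt as A
from chemlm import fingerprint as FP
from chemlm import model as M
from chemlm.fixtures import gen_labeled_dataset


@pytest.fixture(scope="module")
def small_setup(tiny_tokenizer):
    enc = M.TransformerEncoder(M.desk_config(tiny_tokenizer.vocab_size), seed=0)
    enc.eval()
    ds = gen_labeled_dataset(120, "nitro", 0.0, seed=8)
    return enc, tiny_tokenizer, ds


class TestSiameseFeatures:
    def test_identical_inputs_zero_difference_block(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            A.siamese_features(v, v), np.concatenate([v, v, np.zeros(3)]))

    def test_unit_vectors(self):
        out = A.siamese_features([1.0, 0.0], [0.0, 1.0])
        np.testing.assert_array_equal(out, [1, 0, 0, 1, 1, 1])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_third_block_is_absolute_difference(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=6)
        out = A.siamese_features(a, b)
        np.testing.assert_array_equal(out[:6], a)
        np.testing.assert_array_equal(out[6:12], b)
        np.testing.assert_array_equal(out[12:], np.abs(b - a))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            A.siamese_features([1, 2], [1, 2, 3])


class TestLatentLoss:
    def test_identical_is_zero(self):
        assert A.siamese_latent_loss([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_orthogonal_is_one(self):
        assert A.siamese_latent_loss([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_antiparallel_is_four(self):
        assert A.siamese_latent_loss([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(4.0)

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            A.siamese_latent_loss([0.0, 0.0], [1.0, 0.0])


class TestSplit:
    def test_random_split_fractions(self, small_setup):
        _, _, ds = small_setup
        cfg = A.FineTuneConfig(split=(0.8, 0.1, 0.1), seed=1)
        train, valid, test = A.split_dataset(ds.frame, cfg)
        assert len(train) + len(valid) + len(test) == len(ds.frame)
        assert len(train) == round(0.8 * len(ds.frame))
        # disjoint
        assert not set(train.index) & set(test.index)

    def test_scaffold_split_keeps_chemotypes_disjoint(self, small_setup):
        from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles
        _, _, ds = small_setup
        cfg = A.FineTuneConfig(split=(0.8, 0.1, 0.1), split_strategy="scaffold",
                               seed=1)
        train, valid, test = A.split_dataset(ds.frame, cfg)
        s_train = {MurckoScaffoldSmiles(smiles=s) for s in train["smiles"]}
        s_test = {MurckoScaffoldSmiles(smiles=s) for s in test["smiles"]}
        assert not s_train & s_test

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            A.FineTuneConfig(split=(0.5, 0.2, 0.2))


class TestFinetuneSingle:
    def test_noop_when_dropout_and_lr_zero(self, small_setup, tiny_tokenizer):
        # dropout-free encoder so the loss is a pure function of the weights
        enc = M.TransformerEncoder(
            M.desk_config(tiny_tokenizer.vocab_size, dropout=0.0), seed=0)
        _, tok, ds = small_setup
        cfg = A.FineTuneConfig(dropout=0.0, lr=0.0, epochs=2, seed=0)
        before = {k: v.copy() for k, v in enc.state_dict().items()}
        bundle = A.finetune_single(enc, tok, ds, cfg)
        after = bundle.encoder.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        losses = [m["train_loss"] for m in bundle.metrics if "train_loss" in m]
        assert losses[0] == pytest.approx(losses[1])

    def test_same_seed_identical_traces(self, small_setup):
        enc, tok, ds = small_setup
        cfg = A.FineTuneConfig(epochs=2, seed=4)
        m1 = A.finetune_single(enc, tok, ds, cfg).metrics
        m2 = A.finetune_single(enc, tok, ds, cfg).metrics
        assert m1 == m2

    def test_caller_encoder_untouched(self, small_setup):
        enc, tok, ds = small_setup
        before = {k: v.copy() for k, v in enc.state_dict().items()}
        A.finetune_single(enc, tok, ds, A.FineTuneConfig(epochs=1, seed=0))
        for k, v in enc.state_dict().items():
            np.testing.assert_array_equal(before[k], v)

    def test_single_class_errors(self, small_setup):
        enc, tok, _ = small_setup
        import pandas as pd
        frame = pd.DataFrame({"smiles": ["CCO", "CCN", "CCC", "CO"],
                              "label": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            A.finetune_single(enc, tok, frame,
                              A.FineTuneConfig(epochs=1, split=(1.0, 0.0, 0.0)))

    def test_freeze_encoder_only_trains_head(self, small_setup):
        enc, tok, ds = small_setup
        cfg = A.FineTuneConfig(epochs=1, seed=0, freeze_encoder=True)
        bundle = A.finetune_single(enc, tok, ds, cfg)
        for k, v in enc.state_dict().items():
            np.testing.assert_array_equal(v, bundle.encoder.state_dict()[k])


class TestStripHead:
    def test_strip_yields_working_fingerprint_model(self, small_setup):
        enc, tok, ds = small_setup
        bundle = A.finetune_single(enc, tok, ds, A.FineTuneConfig(epochs=1,
                                                                  seed=0))
        stripped = A.strip_head(bundle)
        batch = FP.fingerprint_batch(stripped, tok, ["CCO"])
        assert batch.matrix.shape == (1, enc.config.hidden)

    def test_idempotent(self, small_setup):
        enc, tok, ds = small_setup
        bundle = A.finetune_single(enc, tok, ds, A.FineTuneConfig(epochs=1,
                                                                  seed=0))
        once = A.strip_head(bundle)
        assert A.strip_head(once) is once

    def test_finetuned_fingerprints_differ_from_pretrained(self, small_setup):
        enc, tok, ds = small_setup
        bundle = A.finetune_single(enc, tok, ds, A.FineTuneConfig(epochs=1,
                                                                  seed=0))
        a = FP.fingerprint_batch(enc, tok, ["CCO"]).matrix
        b = FP.fingerprint_batch(A.strip_head(bundle), tok, ["CCO"]).matrix
        assert not np.allclose(a, b)


class TestSiameseClassify:
    def test_weight_sharing_by_identity(self, small_setup):
        """Both branches run the same parameter set: identical inputs give
        identical fingerprints through either branch."""
        enc, tok, ds = small_setup
        bundle = A.siamese_classify(enc, tok, ds, A.FineTuneConfig(epochs=1,
                                                                   seed=0))
        f1 = FP.fingerprint_batch(bundle.encoder, tok, ["CCO"]).matrix
        f2 = FP.fingerprint_batch(bundle.encoder, tok, ["CCO"]).matrix
        np.testing.assert_array_equal(f1, f2)
        assert bundle.head.weight.shape[0] == 3 * enc.config.hidden

    def test_accuracy_comparable_to_single_branch(self, desk_encoder_pretrained,
                                                  desk_tokenizer, nitro_dataset):
        """On the planted structural task the Siamese classifier performs
        on par with single fine-tuning (held-out accuracy within 0.1)."""
        cfg = A.FineTuneConfig(epochs=5, seed=2)
        single = A.finetune_single(desk_encoder_pretrained, desk_tokenizer,
                                   nitro_dataset, cfg)
        siam = A.siamese_classify(desk_encoder_pretrained, desk_tokenizer,
                                  nitro_dataset, cfg)
        acc_single = single.metrics[-1]["test_metric"]
        acc_siam = siam.metrics[-1]["test_metric"]
        assert acc_single > 0.8 and acc_siam > 0.8
        assert abs(acc_single - acc_siam) <= 0.1

    def test_deterministic_pairing(self, small_setup):
        enc, tok, ds = small_setup
        cfg = A.FineTuneConfig(epochs=1, seed=9)
        b1 = A.siamese_classify(enc, tok, ds, cfg)
        b2 = A.siamese_classify(enc, tok, ds, cfg)
        smiles = list(ds.frame["smiles"][:10])
        assert b1._augmented(smiles) == b2._augmented(smiles)
        assert b1.metrics == b2.metrics


class TestClassicalHeads:
    @pytest.mark.parametrize("head", ["svm", "rf", "ffnn"])
    def test_separable_features_reach_perfect_auc(self, head, rng):
        X = np.vstack([rng.normal(0, 0.3, (40, 5)),
                       rng.normal(5, 0.3, (40, 5))])
        y = np.array([0] * 40 + [1] * 40)
        out = A.classical_head_eval(X, y, head=head, task="clf", seed=0)
        assert out["metric"] == "aucroc"
        assert out["value"] == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(120, 5))
        y = rng.integers(0, 2, size=120)
        out = A.classical_head_eval(X, y, head="svm", task="clf", seed=0)
        assert out["value"] == pytest.approx(0.5, abs=0.25)

    def test_regression_rmse_for_mean_predictor_baseline(self, rng):
        """A constant target is degenerate and must raise; a near-constant
        target's RMSE stays close to its tiny spread."""
        X = rng.normal(size=(60, 4))
        with pytest.raises(ValueError):
            A.classical_head_eval(X, np.ones(60), head="rf", task="reg", seed=0)
        y = rng.normal(0, 1.0, size=60)
        out = A.classical_head_eval(X, y, head="rf", task="reg", seed=0)
        assert out["metric"] == "rmse"
        # features are pure noise: cannot beat ~target std by much, nor blow up
        assert 0.3 < out["value"] < 3.0


class TestSiameseLatent:
    def test_zero_epochs_unchanged(self, small_setup, tiny_corpus):
        enc, tok, _ = small_setup
        tuned, rep = A.siamese_latent_train(
            enc, tok, tiny_corpus[:40],
            A.FineTuneConfig(epochs=0, seed=1))
        for k, v in enc.state_dict().items():
            np.testing.assert_array_equal(v, tuned.state_dict()[k])
        assert rep["holdout_cosine_before"] == rep["holdout_cosine_after"]

    def test_fixed_seed_reproducible(self, small_setup, tiny_corpus):
        enc, tok, _ = small_setup
        cfg = A.FineTuneConfig(epochs=1, seed=2, lr=5e-4)
        _, r1 = A.siamese_latent_train(enc, tok, tiny_corpus[:60], cfg)
        _, r2 = A.siamese_latent_train(enc, tok, tiny_corpus[:60], cfg)
        assert r1 == r2
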