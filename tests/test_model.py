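"""The end-to-end tagger: encoder contract, forward pass, decoding,
training dynamics, and gradient correctness."""

import numpy as np
import pytest

from memtagger.corpus import LabeledSentence
from memtagger.fixtures import FixtureConfig, generate, make_samples
from memtagger.model import (EmbeddingMixEncoder, KVMNTagger, encode, forward,
                             predict_tags, train)


@pytest.fixture(scope="module")
def tiny_data():
    bundle = generate(FixtureConfig(seed=5, n_sentences=30))
    return (make_samples(bundle, "train", syntactic_types=("SC",)),
            make_samples(bundle, "dev", syntactic_types=("SC",)))


def fit_quick(samples, dev=None, **kw):
    kw.setdefault("hidden_dim", 8)
    kw.setdefault("epochs", 3)
    kw.setdefault("seed", 1)
    model = KVMNTagger(**kw)
    model.fit(samples, dev=dev)
    return model


class TestEncoder:
    def test_output_length_matches_tokens(self, rng):
        enc = EmbeddingMixEncoder.init(["a", "b", "c"], 4, rng)
        sent = LabeledSentence.from_words(["a", "c", "b", "a"])
        H = encode(sent, enc)
        assert H.shape == (4, 4)

    def test_single_word_is_its_embedding(self, rng):
        enc = EmbeddingMixEncoder.init(["w"], 4, rng)
        H = encode(LabeledSentence.from_words(["w"]), enc)
        np.testing.assert_allclose(H[0], enc.params["emb"][enc.word_to_id["w"]])

    def test_vocabulary_permutation_equivariance(self, rng):
        # renaming words while permuting embedding rows accordingly leaves
        # the encoder output unchanged
        enc = EmbeddingMixEncoder.init(["a", "b", "c"], 4, rng)
        words = ["a", "b", "c", "b"]
        H = encode(LabeledSentence.from_words(words), enc)
        renamed = {"a": "x", "b": "y", "c": "z"}
        vocab2 = {"<UNK>": 0, "x": enc.word_to_id["a"],
                  "y": enc.word_to_id["b"], "z": enc.word_to_id["c"]}
        enc2 = EmbeddingMixEncoder(vocab2, enc.params)
        H2 = encode(LabeledSentence.from_words([renamed[w] for w in words]), enc2)
        np.testing.assert_allclose(H, H2)


class TestDecoding:
    def test_argmax_tag(self):
        labels = ["O", "B-X", "I-X"]
        assert predict_tags([np.array([2.0, 1.0, 0.0])], labels) == ["O"]

    def test_tie_breaks_to_lowest_id(self):
        labels = ["O", "B-X"]
        assert predict_tags([np.array([1.0, 1.0])], labels) == ["O"]

    def test_softmax_monotone_argmax(self, rng):
        labels = [f"B-{i}" for i in range(5)]
        for _ in range(50):
            u = rng.normal(size=5)
            def softmax(x):
                e = np.exp(x - x.max())
                return e / e.sum()
            assert predict_tags([u], labels)[0] == labels[int(np.argmax(softmax(u)))]

    def test_shift_invariance(self, rng):
        labels = [f"B-{i}" for i in range(4)]
        u = rng.normal(size=4)
        assert predict_tags([u], labels) == predict_tags([u + 17.0], labels)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            predict_tags([], ["O"])


class TestForward:
    def test_none_mode_scores_are_projected_hiddens(self, tiny_data):
        tr, _ = tiny_data
        model = fit_quick(tr, mode="none", epochs=1, lr=0.0)
        sent, ctx = tr[0]
        U = forward(sent, ctx, model)
        H = model.encoder_.encode(sent.words)
        W = model.params_["W"]
        np.testing.assert_allclose(np.stack(U), H @ W.T, atol=1e-10)

    def test_matches_independent_matrix_product(self, tiny_data):
        tr, _ = tiny_data
        model = fit_quick(tr, mode="kvmn", syntactic_types=("SC",),
                          epochs=1, lr=0.0)
        sent, ctx = tr[1]
        U = np.stack(forward(sent, ctx, model))
        # independent evaluation of attention + concat + projection
        from memtagger.memory import attend, augment
        H = model.encoder_.encode(sent.words)
        kids, vids = model.vocabs_["SC"].encode(ctx["SC"])
        rows = []
        for i in range(len(sent)):
            res = attend(H[i], kids[i], vids[i], model._mem("SC"))
            rows.append(augment(H[i], res.o))
        expected = np.stack(rows) @ model.params_["W"].T
        np.testing.assert_allclose(U, expected, atol=1e-8)

    def test_zero_memory_reduces_to_baseline(self, tiny_data):
        tr, _ = tiny_data
        base = fit_quick(tr, mode="none", epochs=2)
        kv = fit_quick(tr, mode="kvmn", syntactic_types=("SC",), epochs=1, lr=0.0)
        # transplant baseline weights; zero the value table; widen W with
        # arbitrary entries over the (now inert) memory block
        d = base.hidden_dim
        for k in ("emb", "U_l", "U_r"):
            kv.params_[k][...] = base.params_[k]
        kv.encoder_.word_to_id = dict(base.encoder_.word_to_id)
        kv.params_["mem_SC_v"][...] = 0.0
        kv.params_["W"][:, :d] = base.params_["W"]
        kv.params_["W"][:, d:] = 123.456
        assert kv.predict(tr) == base.predict(tr)


class TestGradients:
    @pytest.mark.parametrize("mode,types", [
        ("none", ()),
        ("kvmn", ("SC",)),
        ("kvmn", ("SC", "DR")),
        ("dc", ("PL",)),
    ])
    def test_backward_matches_finite_differences(self, mode, types):
        bundle = generate(FixtureConfig(seed=11, n_sentences=8))
        samples = make_samples(bundle)[:4]
        model = KVMNTagger(hidden_dim=5, mode=mode, syntactic_types=types,
                           epochs=1, lr=0.0, seed=2)
        model.fit(samples)
        label_id = {t: i for i, t in enumerate(model.labels_)}
        sent, ctx = samples[0]
        tids = np.array([label_id[t] for t in sent.tags])
        slots = model._encode_slots(ctx, len(sent))

        def loss():
            U = model._forward(sent.words, slots).U
            Z = U - U.max(axis=1, keepdims=True)
            logp = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
            return -logp[np.arange(len(tids)), tids].sum()

        cache = model._forward(sent.words, slots)
        Z = cache.U - cache.U.max(axis=1, keepdims=True)
        P = np.exp(Z) / np.exp(Z).sum(axis=1, keepdims=True)
        dU = P.copy()
        dU[np.arange(len(tids)), tids] -= 1.0
        grads = {k: np.zeros_like(v) for k, v in model.params_.items()}
        model._backward(cache, dU, grads)

        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, arr in model.params_.items():
            flat = arr.reshape(-1)
            for idx in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                ana = grads[name].reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_lr_zero_leaves_parameters_unchanged(self, tiny_data):
        tr, _ = tiny_data
        m1 = fit_quick(tr[:1], epochs=1, lr=0.0, mode="none")
        m2 = KVMNTagger(hidden_dim=8, epochs=1, lr=0.0, mode="none", seed=1)
        m2.fit(tr[:1])
        # same seed, no updates: parameters equal the fresh initialization
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])

    def test_converges_on_separable_corpus(self, tiny_data):
        tr, _ = tiny_data
        model = fit_quick(tr, mode="kvmn", syntactic_types=("SC",),
                          epochs=50, hidden_dim=12)
        assert model.score(tr, [s.tags for s, _ in tr]) == 1.0

    def test_same_seed_same_loss_trace(self, tiny_data):
        tr, dv = tiny_data
        dev = (dv, [s.tags for s, _ in dv])
        h1 = fit_quick(tr, dev=dev, epochs=4, seed=7).history_
        h2 = fit_quick(tr, dev=dev, epochs=4, seed=7).history_
        assert h1 == h2

    def test_dev_selection_keeps_best_epoch(self, tiny_data):
        tr, dv = tiny_data
        dev = (dv, [s.tags for s, _ in dv])
        model = fit_quick(tr, dev=dev, epochs=6)
        best = max(r["dev_f1"] for r in model.history_)
        assert model.history_[model.best_epoch_]["dev_f1"] == best
        assert model._dev_f1(dv, dev[1]) == pytest.approx(best)

    def test_unseen_dev_label_rejected(self, tiny_data):
        tr, dv = tiny_data
        bad = [["B-Novel"] * len(s) for s, _ in dv]
        with pytest.raises(ValueError, match="unseen"):
            fit_quick(tr, dev=(dv, bad))

    def test_train_wrapper(self, tiny_data):
        tr, dv = tiny_data
        model = train(tr, dv, hidden_dim=8, epochs=2, mode="none", seed=0)
        assert hasattr(model, "params_")
        assert all("dev_f1" in r for r in model.history_)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_data, tmp_path):
        tr, _ = tiny_data
        model = fit_quick(tr, mode="kvmn", syntactic_types=("SC",), epochs=2)
        model.save(str(tmp_path / "ckpt"))
        again = KVMNTagger.load(str(tmp_path / "ckpt"))
        assert again.predict(tr) == model.predict(tr)
        assert again.labels_ == model.labels_

    def test_sklearn_params_round_trip(self):
        model = KVMNTagger(hidden_dim=9, mode="dc", epochs=4)
        clone = KVMNTagger(**model.get_params())
        assert clone.get_params() == model.get_params()
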