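"""The sequence labeling model: encoder, memory augmentation, projection,
softmax decoding, and training.

The architecture is encoder → (optional) key-value memory → linear
projection → softmax.  For each token x_i the encoder produces a hidden
vector h_i; the memory module replaces h_i with the augmented vector
o'_i = h_i (+) o_i (or the DC-baseline / ensemble variants); a trainable
matrix W maps o'_i to one score per label, u_i = W o'_i; the predicted
tag is the argmax of softmax(u_i), ties broken by lowest label id.
Training minimizes token-level cross-entropy with Adam, fine-tuning all
parameters including the encoder, and keeps the checkpoint with the best
development-set entity F1.

The shipped encoder is a small trainable one — a token embedding plus a
one-step bidirectional mixing of neighbor embeddings — so the full
pipeline trains on a CPU in seconds.  Any encoder satisfying
:class:`EncoderContract` (a map from tokens to one d-vector per token)
can stand in; pretrained transformer encoders plug in through the same
contract.

All forward/backward passes are explicit numpy; gradients are
hand-derived and verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import LabeledCorpus, LabeledSentence
from .evaluation import entity_prf
from .extract import UNK, KeyValueVocab, SyntacticContext
from .memory import INIT_SCALE, MemoryEmbeddings, attend, dc_combine, ensemble

__all__ = [
    "EncoderContract",
    "EmbeddingMixEncoder",
    "KVMNTagger",
    "encode",
    "forward",
    "predict_tags",
    "train",
]

Sample = tuple[LabeledSentence, Mapping[str, SyntacticContext]]


@runtime_checkable
class EncoderContract(Protocol):
    """A map from a token sequence to one hidden vector per token."""

    hidden_size: int

    def encode(self, words: Sequence[str]) -> np.ndarray:  # (l, hidden_size)
        ...


class EmbeddingMixEncoder:
    """Trainable toy encoder: token embedding + bidirectional neighbor mixing.

    h_i = E[x_i] + U_l E[x_{i-1}] + U_r E[x_{i+1}], with missing neighbors
    treated as zero.  Unknown words map to a reserved UNK row.
    """

    def __init__(self, word_to_id: dict[str, int], params: dict[str, np.ndarray]):
        self.word_to_id = word_to_id
        self.params = params  # shares storage with the owning model

    @property
    def hidden_size(self) -> int:
        return self.params["emb"].shape[1]

    @classmethod
    def init(cls, words: Sequence[str], dim: int, rng: np.random.Generator
             ) -> "EmbeddingMixEncoder":
        vocab = {UNK: 0}
        for w in words:
            if w not in vocab:
                vocab[w] = len(vocab)
        params = {
            "emb": rng.uniform(-INIT_SCALE, INIT_SCALE, (len(vocab), dim)),
            "U_l": rng.uniform(-INIT_SCALE, INIT_SCALE, (dim, dim)),
            "U_r": rng.uniform(-INIT_SCALE, INIT_SCALE, (dim, dim)),
        }
        return cls(vocab, params)

    def word_ids(self, words: Sequence[str]) -> np.ndarray:
        return np.array([self.word_to_id.get(w, 0) for w in words], dtype=np.intp)

    def encode(self, words: Sequence[str]) -> np.ndarray:
        X = self.params["emb"][self.word_ids(words)]
        return self._mix(X)

    def _mix(self, X: np.ndarray) -> np.ndarray:
        H = X.copy()
        if len(X) > 1:
            H[1:] += X[:-1] @ self.params["U_l"].T
            H[:-1] += X[1:] @ self.params["U_r"].T
        return H

    def backward(self, words: Sequence[str], X: np.ndarray, dH: np.ndarray,
                 grads: dict[str, np.ndarray]) -> None:
        """Accumulate gradients of the mixing step and embedding lookup."""
        dX = dH.copy()
        if len(X) > 1:
            grads["U_l"] += dH[1:].T @ X[:-1]
            grads["U_r"] += dH[:-1].T @ X[1:]
            dX[:-1] += dH[1:] @ self.params["U_l"]
            dX[1:] += dH[:-1] @ self.params["U_r"]
        np.add.at(grads["emb"], self.word_ids(words), dX)


def encode(sentence: LabeledSentence, encoder: EncoderContract) -> np.ndarray:
    """Run the encoder contract on one sentence: one d-vector per token."""
    if len(sentence) == 0:
        raise ValueError("cannot encode an empty sentence")
    H = encoder.encode(sentence.words)
    if H.shape[0] != len(sentence):
        raise ValueError("encoder output length does not match token count")
    return H


def predict_tags(scores: Sequence[np.ndarray], labels: Sequence[str]) -> list[str]:
    """Argmax decoding of per-token label scores.

    Softmax is monotone, so the argmax of softmax(u_i) is the argmax of
    u_i itself; exact ties break to the lowest label id.
    """
    if len(scores) == 0:
        raise ValueError("empty score list")
    return [labels[int(np.argmax(u))] for u in scores]


def _softmax_rows(U: np.ndarray) -> np.ndarray:
    Z = U - U.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


@dataclass
class _Cache:
    """Per-sentence forward intermediates needed for the backward pass."""

    words: Sequence[str]
    X: np.ndarray
    H: np.ndarray
    Oprime: np.ndarray
    U: np.ndarray
    slots: dict[str, list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    attn: dict[str, list[np.ndarray]] = field(default_factory=dict)  # weights p per token


class KVMNTagger(BaseEstimator):
    """Sequence labeler with optional key-value memory over syntactic context.

    Parameters
    ----------
    hidden_dim : encoder hidden size d; memory embeddings share it.
    mode : "kvmn" (attention-weighted memory), "dc" (direct concatenation
        of unweighted mean key/value embeddings), or "none" (plain
        encoder + softmax baseline).
    syntactic_types : subset of ("PL", "SC", "DR") consumed from each
        sample's context mapping; ignored for mode "none".
    ensemble_strategy : how pooled vectors of several syntactic types are
        combined — "concat" or "sum".
    combine : how the memory output joins the hidden vector — "concat"
        (o' = h (+) o, the default) or "add" (o' = h + o; requires the sum
        ensemble so dimensions agree).
    epochs, lr, batch_size : Adam training schedule.
    min_freq : key/value strings rarer than this map to UNK.
    seed : seeds parameter initialization and batch shuffling.

    Attributes (after fit)
    ----------------------
    labels_ : label list T in sorted order (argmax tie-break order).
    vocabs_ : per-type :class:`KeyValueVocab` built on the training data.
    encoder_ : the trained :class:`EmbeddingMixEncoder`.
    params_ : dict of trainable arrays (encoder, memories, projection W).
    history_ : per-epoch records (train loss, dev F1 when a dev set given).
    best_epoch_ : epoch whose dev F1 selected the returned weights.
    """

    def __init__(self, hidden_dim: int = 16, mode: str = "kvmn",
                 syntactic_types: Sequence[str] = ("SC",),
                 ensemble_strategy: str = "concat", combine: str = "concat",
                 epochs: int = 30, lr: float = 0.01, batch_size: int = 8,
                 min_freq: int = 1, shuffle: bool = True, seed: int = 0):
        self.hidden_dim = hidden_dim
        self.mode = mode
        self.syntactic_types = syntactic_types
        self.ensemble_strategy = ensemble_strategy
        self.combine = combine
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.min_freq = min_freq
        self.shuffle = shuffle
        self.seed = seed

    # -- configuration ------------------------------------------------------

    def _check_config(self) -> None:
        if self.mode not in ("kvmn", "dc", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "none" and len(self.syntactic_types) == 0:
            raise ValueError(f"mode {self.mode!r} needs at least one syntactic type")
        if self.ensemble_strategy not in ("concat", "sum"):
            raise ValueError(f"unknown ensemble strategy {self.ensemble_strategy!r}")
        if self.combine not in ("concat", "add"):
            raise ValueError(f"unknown combine mode {self.combine!r}")
        if (self.combine == "add" and len(self.syntactic_types) > 1
                and self.ensemble_strategy != "sum"):
            raise ValueError("combine='add' over several types requires the sum ensemble")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def _augmented_dim(self) -> int:
        d, n = self.hidden_dim, len(self.syntactic_types)
        if self.mode == "none":
            return d
        if self.mode == "dc":
            return d * (1 + 2 * n)
        if self.combine == "add":
            return d
        if self.ensemble_strategy == "sum":
            return 2 * d
        return d * (1 + n)

    # -- data preparation ---------------------------------------------------

    def _encode_slots(self, contexts: Mapping[str, SyntacticContext], length: int
                      ) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
        slots: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        if self.mode == "none":
            return slots
        for s in self.syntactic_types:
            if s not in contexts:
                raise ValueError(f"sample lacks a {s} context")
            ctx = contexts[s]
            if len(ctx) != length:
                raise ValueError(f"{s} context covers {len(ctx)} tokens, sentence has {length}")
            kids, vids = self.vocabs_[s].encode(ctx)
            slots[s] = [(np.asarray(k, dtype=np.intp), np.asarray(v, dtype=np.intp))
                        for k, v in zip(kids, vids)]
        return slots

    # -- forward / backward -------------------------------------------------

    def _forward(self, words: Sequence[str],
                 slots: dict[str, list[tuple[np.ndarray, np.ndarray]]]) -> _Cache:
        X = self.params_["emb"][self.encoder_.word_ids(words)]
        H = self.encoder_._mix(X)
        d = self.hidden_dim
        rows = []
        attn: dict[str, list[np.ndarray]] = {s: [] for s in slots}
        for i in range(len(words)):
            h = H[i]
            if self.mode == "none":
                rows.append(h)
                continue
            if self.mode == "dc":
                blocks = [h]
                for s in self.syntactic_types:
                    kid, vid = slots[s][i]
                    combined = dc_combine(h, kid, vid, self._mem(s))
                    blocks.append(combined[d:])
                rows.append(np.concatenate(blocks))
                continue
            pooled = []
            for s in self.syntactic_types:
                kid, vid = slots[s][i]
                res = attend(h, kid, vid, self._mem(s))
                attn[s].append(res.p)
                pooled.append(res.o)
            if self.combine == "add":
                rows.append(h + np.sum(pooled, axis=0))
            else:
                rows.append(ensemble(h, pooled, self.ensemble_strategy))
        Oprime = np.stack(rows)
        U = Oprime @ self.params_["W"].T
        return _Cache(words=words, X=X, H=H, Oprime=Oprime, U=U,
                      slots=slots, attn=attn)

    def _mem(self, stype: str) -> MemoryEmbeddings:
        return MemoryEmbeddings(self.params_[f"mem_{stype}_k"],
                                self.params_[f"mem_{stype}_v"])

    def _backward(self, cache: _Cache, dU: np.ndarray,
                  grads: dict[str, np.ndarray]) -> None:
        d = self.hidden_dim
        grads["W"] += dU.T @ cache.Oprime
        dO = dU @ self.params_["W"]  # (l, D)
        l = len(cache.words)
        dH = np.zeros_like(cache.H)
        for i in range(l):
            h = cache.H[i]
            if self.mode == "none":
                dH[i] += dO[i]
                continue
            dH[i] += dO[i][:d]
            if self.mode == "dc":
                off = d
                for s in self.syntactic_types:
                    kid, vid = cache.slots[s][i]
                    gk, gv = dO[i][off:off + d], dO[i][off + d:off + 2 * d]
                    off += 2 * d
                    m = len(kid)
                    if m:
                        np.add.at(grads[f"mem_{s}_k"], kid, gk / m)
                        np.add.at(grads[f"mem_{s}_v"], vid, gv / m)
                continue
            # kvmn: distribute the gradient of each type's pooled vector
            for t, s in enumerate(self.syntactic_types):
                if self.combine == "add":
                    g_o = dO[i][:d]
                elif self.ensemble_strategy == "sum":
                    g_o = dO[i][d:2 * d]
                else:
                    g_o = dO[i][d * (1 + t):d * (2 + t)]
                kid, vid = cache.slots[s][i]
                m = len(kid)
                if m == 0:
                    continue
                p = cache.attn[s][i]
                ek = self.params_[f"mem_{s}_k"][kid]
                ev = self.params_[f"mem_{s}_v"][vid]
                np.add.at(grads[f"mem_{s}_v"], vid, p[:, None] * g_o[None, :])
                sj = ev @ g_o                      # (m,)
                dlogit = p * (sj - p @ sj)         # softmax Jacobian
                np.add.at(grads[f"mem_{s}_k"], kid, dlogit[:, None] * h[None, :])
                dH[i] += ek.T @ dlogit
        self.encoder_.backward(cache.words, cache.X, dH, grads)

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: Sequence[Sample], y: Sequence[Sequence[str]] | None = None,
            dev: tuple[Sequence[Sample], Sequence[Sequence[str]]] | None = None
            ) -> "KVMNTagger":
        """Train on samples ``(sentence, {syntactic_type: context})``.

        ``y`` is the per-sentence tag lists; when omitted, tags are taken
        from the sentences themselves.  With ``dev`` given, the model is
        scored on it (entity F1) after every epoch and the best-scoring
        weights are kept.
        """
        self._check_config()
        X = list(X)
        if len(X) == 0:
            raise ValueError("empty training set")
        if y is None:
            y = [s.tags for s, _ in X]
        y = [list(t) for t in y]
        for (s, _), tags in zip(X, y):
            if tags is None or len(tags) != len(s):
                raise ValueError("tags missing or misaligned with tokens")
        self.labels_ = sorted({t for tags in y for t in tags})
        label_id = {t: i for i, t in enumerate(self.labels_)}
        if dev is not None:
            Xd, yd = list(dev[0]), [list(t) for t in dev[1]]
            unseen = {t for tags in yd for t in tags} - set(self.labels_)
            if unseen:
                raise ValueError(f"dev labels unseen in training: {sorted(unseen)}")

        rng = np.random.default_rng(self.seed)
        all_words = [w for s, _ in X for w in s.words]
        self.encoder_ = EmbeddingMixEncoder.init(all_words, self.hidden_dim, rng)
        self.params_ = dict(self.encoder_.params)
        self.encoder_.params = self.params_

        from .extract import build_vocab
        self.vocabs_ = {}
        if self.mode != "none":
            for s in self.syntactic_types:
                self.vocabs_[s] = build_vocab(
                    [ctx[s] for _, ctx in X], min_freq=self.min_freq)
                mem = MemoryEmbeddings.init(self.vocabs_[s].n_keys,
                                            self.vocabs_[s].n_values,
                                            self.hidden_dim, rng)
                self.params_[f"mem_{s}_k"] = mem.keys
                self.params_[f"mem_{s}_v"] = mem.values
        D = self._augmented_dim()
        self.params_["W"] = rng.uniform(-INIT_SCALE, INIT_SCALE,
                                        (len(self.labels_), D))

        enc = [(s.words, self._encode_slots(ctx, len(s)),
                np.array([label_id[t] for t in tags], dtype=np.intp))
               for (s, ctx), tags in zip(X, y)]

        # Adam state
        m_t = {k: np.zeros_like(v) for k, v in self.params_.items()}
        v_t = {k: np.zeros_like(v) for k, v in self.params_.items()}
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        self.history_ = []
        best_f1, best_params, best_epoch = -1.0, None, -1
        n = len(enc)
        for epoch in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            total_loss, total_tokens = 0.0, 0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                grads = {k: np.zeros_like(v) for k, v in self.params_.items()}
                batch_tokens = 0
                for idx in batch:
                    words, slots, tids = enc[idx]
                    cache = self._forward(words, slots)
                    P = _softmax_rows(cache.U)
                    total_loss += -np.log(
                        np.clip(P[np.arange(len(tids)), tids], 1e-12, None)).sum()
                    dU = P
                    dU[np.arange(len(tids)), tids] -= 1.0
                    self._backward(cache, dU, grads)
                    batch_tokens += len(tids)
                total_tokens += batch_tokens
                if self.lr == 0.0 or batch_tokens == 0:
                    continue
                step += 1
                for k in self.params_:
                    g = grads[k] / batch_tokens
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
                    mhat = m_t[k] / (1 - beta1 ** step)
                    vhat = v_t[k] / (1 - beta2 ** step)
                    self.params_[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            self.encoder_.params = self.params_
            record = {"epoch": epoch, "train_loss": total_loss / max(total_tokens, 1)}
            if dev is not None:
                f1 = self._dev_f1(Xd, yd)
                record["dev_f1"] = f1
                if f1 > best_f1:
                    best_f1, best_epoch = f1, epoch
                    best_params = {k: v.copy() for k, v in self.params_.items()}
            self.history_.append(record)
        if best_params is not None:
            self.params_ = best_params
            self.encoder_.params = self.params_
        self.best_epoch_ = best_epoch if best_epoch >= 0 else self.epochs - 1
        self.n_iter_ = self.epochs
        return self

    def _dev_f1(self, Xd: Sequence[Sample], yd: Sequence[Sequence[str]]) -> float:
        pred = self.predict(Xd)
        gold = LabeledCorpus([LabeledSentence(s.tokens, list(t))
                              for (s, _), t in zip(Xd, yd)])
        predc = LabeledCorpus([LabeledSentence(s.tokens, p)
                               for (s, _), p in zip(Xd, pred)])
        return entity_prf(gold, predc).f1

    def decision_function(self, X: Sequence[Sample]) -> list[np.ndarray]:
        """Per-sentence (l, |T|) label score matrices u_i = W o'_i."""
        self._check_fitted()
        out = []
        for sent, ctx in X:
            slots = self._encode_slots(ctx, len(sent))
            out.append(self._forward(sent.words, slots).U)
        return out

    def predict(self, X: Sequence[Sample]) -> list[list[str]]:
        """Predicted BIO tag lists, one per sentence."""
        return [predict_tags(list(U), self.labels_)
                for U in self.decision_function(X)]

    def score(self, X: Sequence[Sample], y: Sequence[Sequence[str]]) -> float:
        """Entity-level micro F1 against gold tags."""
        pred = self.predict(X)
        gold = LabeledCorpus([LabeledSentence(s.tokens, list(t))
                              for (s, _), t in zip(X, y)])
        predc = LabeledCorpus([LabeledSentence(s.tokens, p)
                               for (s, _), p in zip(X, pred)])
        return entity_prf(gold, predc).f1

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        """Write weights, vocabularies, label set and config to a directory."""
        self._check_fitted()
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.params_)
        meta = {
            "config": self.get_params(),
            "labels": self.labels_,
            "word_to_id": self.encoder_.word_to_id,
            "vocabs": {s: v.to_dict() for s, v in self.vocabs_.items()},
        }
        meta["config"]["syntactic_types"] = list(meta["config"]["syntactic_types"])
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, directory: str) -> "KVMNTagger":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        cfg = dict(meta["config"])
        cfg["syntactic_types"] = tuple(cfg["syntactic_types"])
        model = cls(**cfg)
        weights = np.load(os.path.join(directory, "weights.npz"))
        model.params_ = {k: weights[k] for k in weights.files}
        model.labels_ = list(meta["labels"])
        model.encoder_ = EmbeddingMixEncoder(dict(meta["word_to_id"]), model.params_)
        model.vocabs_ = {s: KeyValueVocab.from_dict(d)
                         for s, d in meta["vocabs"].items()}
        model.history_ = []
        return model


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator

def forward(sentence: LabeledSentence, contexts: Mapping[str, SyntacticContext],
            model: KVMNTagger) -> list[np.ndarray]:
    """Per-token label score vectors u_i for one sentence."""
    return list(model.decision_function([(sentence, contexts)])[0])


def train(train_data: Sequence[Sample], dev_data: Sequence[Sample] | None = None,
          **config) -> KVMNTagger:
    """Fit a :class:`KVMNTagger` on labeled samples; tags come from the
    sentences.  ``config`` forwards to the estimator constructor."""
    model = KVMNTagger(**config)
    dev = None
    if dev_data is not None:
        dev = (dev_data, [s.tags for s, _ in dev_data])
    return model.fit(train_data, dev=dev)
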