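"""Key/value syntactic-context extraction.

For every token x_i of a sentence, each extractor produces an aligned pair
of lists: *context features* (keys) K_i — words syntactically associated
with x_i — and *syntactic information instances* (values) V_i — each key
word joined with its syntactic label as ``word_LABEL``.  Three extractors
are provided:

PL (POS labels)
    keys = x_i plus its window neighbors; values carry each word's POS tag,
    e.g. ``dehydrogenase_NN``.
SC (syntactic constituents)
    ascend from x_i's leaf to the first ancestor whose label is in a
    configured acceptable set L (NP, VP, ...); keys = the words under that
    node, values carry the node label, e.g. ``deficiency_NP``.  If no
    ancestor label is acceptable, the token gets an empty context.
DR (dependency relations)
    keys = x_i itself, its direct dependents, and its governor; values
    carry each word's own relation to *its* governor (the root carries the
    ROOT pseudo-relation, e.g. ``disease_ROOT``).

Extraction is deterministic and case-preserving (an optional ``lowercase``
flag normalizes).  The memory module attends over these slots; slot order
never affects the attention result, only serialization.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .corpus import LabeledSentence
from .syntax import AlignmentError, ConstituencyTree, DependencyGraph, PosAnnotation

__all__ = [
    "SYNTACTIC_TYPES",
    "DEFAULT_ACCEPTABLE_LABELS",
    "SyntacticContext",
    "KeyValueVocab",
    "extract_pos_context",
    "extract_constituent_context",
    "extract_dependency_context",
    "extract",
    "build_vocab",
    "write_contexts_jsonl",
    "read_contexts_jsonl",
]

SYNTACTIC_TYPES = ("PL", "SC", "DR")

#: Constituent categories accepted by the SC extractor (configurable).
DEFAULT_ACCEPTABLE_LABELS = frozenset(
    {"NP", "VP", "PP", "ADJP", "ADVP", "S", "SBAR", "QP", "PRT", "PRN"})

#: Reserved id 0 in every vocabulary maps unseen strings.
UNK = "<UNK>"


@dataclass
class SyntacticContext:
    """Aligned per-token key and value lists for one sentence."""

    keys: list[list[str]]
    values: list[list[str]]
    syntactic_type: str

    def __post_init__(self) -> None:
        if self.syntactic_type not in SYNTACTIC_TYPES:
            raise ValueError(f"unknown syntactic type {self.syntactic_type!r}")
        if len(self.keys) != len(self.values):
            raise ValueError("keys/values sentence-length mismatch")
        for k, v in zip(self.keys, self.values):
            if len(k) != len(v):
                raise ValueError("per-token key/value length mismatch")

    def __len__(self) -> int:
        return len(self.keys)

    def m(self, i: int) -> int:
        """Number of memory slots for token i."""
        return len(self.keys[i])


def _window_context(words: Sequence[str], labels: Sequence[str], window: int
                    ) -> tuple[list[list[str]], list[list[str]]]:
    keys, values = [], []
    for i in range(len(words)):
        idx = [i]
        idx += [i - d for d in range(1, window + 1) if i - d >= 0]
        idx += [i + d for d in range(1, window + 1) if i + d < len(words)]
        keys.append([words[j] for j in idx])
        values.append([f"{words[j]}_{labels[j]}" for j in idx])
    return keys, values


def extract_pos_context(sentence: LabeledSentence, pos: PosAnnotation,
                        window: int = 1, lowercase: bool = False
                        ) -> SyntacticContext:
    """PL extraction: the token itself plus its ``window`` neighbors on each
    side, each valued with its POS label.

    Key order is self first, then left neighbors nearest-first, then right
    neighbors nearest-first; boundary tokens simply have fewer slots.
    """
    if len(pos) != len(sentence):
        raise AlignmentError(
            f"{len(pos)} POS labels for {len(sentence)} tokens")
    words = _norm(sentence.words, lowercase)
    keys, values = _window_context(words, pos.labels, window)
    return SyntacticContext(keys, values, "PL")


def extract_constituent_context(sentence: LabeledSentence, tree: ConstituencyTree,
                                acceptable: Iterable[str] = DEFAULT_ACCEPTABLE_LABELS,
                                lowercase: bool = False) -> SyntacticContext:
    """SC extraction: words under the token's first acceptable ancestor.

    The focus word is listed first, then the other words of the yield in
    surface order.  A token with no acceptable ancestor gets an empty slot
    list (the memory then contributes a zero vector).
    """
    acceptable = frozenset(acceptable)
    if not acceptable:
        raise ValueError("acceptable label set must be non-empty")
    tree.check_alignment(sentence.words)
    words = _norm(sentence.words, lowercase)
    keys, values = [], []
    for i in range(len(words)):
        node = next((a for a in tree.ancestors(i) if a.label in acceptable), None)
        if node is None:
            keys.append([])
            values.append([])
            continue
        lo, hi = node.span
        idx = [i] + [j for j in range(lo, hi) if j != i]
        keys.append([words[j] for j in idx])
        values.append([f"{words[j]}_{node.label}" for j in idx])
    return SyntacticContext(keys, values, "SC")


def extract_dependency_context(sentence: LabeledSentence, graph: DependencyGraph,
                               lowercase: bool = False) -> SyntacticContext:
    """DR extraction: the token itself, its direct dependents, and its
    governor (omitted for the root token).

    Each word is valued with its *own* relation to its governor; a governor
    that is the sentence root contributes the ROOT pseudo-relation, as in
    ``disease_ROOT``.
    """
    if len(graph) != len(sentence):
        raise AlignmentError(
            f"dependency graph over {len(graph)} tokens for {len(sentence)}-token sentence")
    words = _norm(sentence.words, lowercase)

    def rel_of(j: int) -> str:
        return graph.root_label if graph.head[j] == -1 else graph.rel[j]

    keys, values = [], []
    for i in range(len(words)):
        idx = [i] + graph.dependents(i)
        if graph.head[i] != -1:
            idx.append(graph.head[i])
        keys.append([words[j] for j in idx])
        values.append([f"{words[j]}_{rel_of(j)}" for j in idx])
    return SyntacticContext(keys, values, "DR")


def extract(sentence: LabeledSentence, syntactic_type: str, *,
            pos: PosAnnotation | None = None,
            tree: ConstituencyTree | None = None,
            graph: DependencyGraph | None = None,
            window: int = 1,
            acceptable: Iterable[str] = DEFAULT_ACCEPTABLE_LABELS,
            lowercase: bool = False) -> SyntacticContext:
    """Dispatch to the extractor for ``syntactic_type`` (PL, SC or DR)."""
    if syntactic_type == "PL":
        if pos is None:
            raise ValueError("PL extraction needs a PosAnnotation")
        return extract_pos_context(sentence, pos, window, lowercase)
    if syntactic_type == "SC":
        if tree is None:
            raise ValueError("SC extraction needs a ConstituencyTree")
        return extract_constituent_context(sentence, tree, acceptable, lowercase)
    if syntactic_type == "DR":
        if graph is None:
            raise ValueError("DR extraction needs a DependencyGraph")
        return extract_dependency_context(sentence, graph, lowercase)
    raise ValueError(f"unknown syntactic type {syntactic_type!r}")


def _norm(words: Sequence[str], lowercase: bool) -> list[str]:
    return [w.lower() for w in words] if lowercase else list(words)


@dataclass
class KeyValueVocab:
    """String-to-id maps for keys and values with a reserved UNK id 0.

    Ids are dense, assigned in first-occurrence order over the corpus, so
    identical extraction input yields identical id assignment.
    """

    key_to_id: dict[str, int] = field(default_factory=lambda: {UNK: 0})
    value_to_id: dict[str, int] = field(default_factory=lambda: {UNK: 0})
    syntactic_type: str | None = None
    key_counts: Counter = field(default_factory=Counter)
    value_counts: Counter = field(default_factory=Counter)

    @property
    def n_keys(self) -> int:
        return len(self.key_to_id)

    @property
    def n_values(self) -> int:
        return len(self.value_to_id)

    def key_id(self, key: str) -> int:
        return self.key_to_id.get(key, 0)

    def value_id(self, value: str) -> int:
        return self.value_to_id.get(value, 0)

    def encode(self, context: SyntacticContext
               ) -> tuple[list[list[int]], list[list[int]]]:
        """Map a sentence's key/value strings to id lists (unseen → UNK)."""
        kids = [[self.key_id(k) for k in ks] for ks in context.keys]
        vids = [[self.value_id(v) for v in vs] for vs in context.values]
        return kids, vids

    def to_dict(self) -> dict:
        return {
            "syntactic_type": self.syntactic_type,
            "key_to_id": self.key_to_id,
            "value_to_id": self.value_to_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KeyValueVocab":
        return cls(key_to_id=dict(d["key_to_id"]),
                   value_to_id=dict(d["value_to_id"]),
                   syntactic_type=d.get("syntactic_type"))


def build_vocab(contexts: Iterable[SyntacticContext], min_freq: int = 1
                ) -> KeyValueVocab:
    """Build key/value vocabularies over extracted contexts.

    All contexts must share one syntactic type.  Strings occurring fewer
    than ``min_freq`` times map to UNK.
    """
    contexts = list(contexts)
    stypes = {c.syntactic_type for c in contexts}
    if len(stypes) > 1:
        raise ValueError(f"mixed syntactic types in one vocab: {sorted(stypes)}")
    vocab = KeyValueVocab(syntactic_type=next(iter(stypes)) if stypes else None)
    for c in contexts:
        for ks in c.keys:
            vocab.key_counts.update(ks)
        for vs in c.values:
            vocab.value_counts.update(vs)
    for c in contexts:
        for ks in c.keys:
            for k in ks:
                if k not in vocab.key_to_id and vocab.key_counts[k] >= min_freq:
                    vocab.key_to_id[k] = len(vocab.key_to_id)
        for vs in c.values:
            for v in vs:
                if v not in vocab.value_to_id and vocab.value_counts[v] >= min_freq:
                    vocab.value_to_id[v] = len(vocab.value_to_id)
    return vocab


def write_contexts_jsonl(contexts: Iterable[SyntacticContext], stream: IO[str]) -> None:
    """One JSON record per sentence: syntactic type + per-token slot arrays."""
    for c in contexts:
        rec = {
            "syntactic_type": c.syntactic_type,
            "tokens": [
                [{"key": k, "value": v} for k, v in zip(ks, vs)]
                for ks, vs in zip(c.keys, c.values)
            ],
        }
        stream.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_contexts_jsonl(stream: IO[str] | Iterable[str]) -> list[SyntacticContext]:
    out = []
    for line in stream:
        if not line.strip():
            continue
        rec = json.loads(line)
        keys = [[slot["key"] for slot in tok] for tok in rec["tokens"]]
        values = [[slot["value"] for slot in tok] for tok in rec["tokens"]]
        out.append(SyntacticContext(keys, values, rec["syntactic_type"]))
    return out
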