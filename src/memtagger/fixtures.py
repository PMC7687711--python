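"""Seeded generator of toy parsed, BIO-labeled corpora.

The generator emulates the statistical premise that constituent structure
cues entity status — an object noun phrase is where the named entity
lives — while keeping every parse valid by construction.  Each sentence
follows a fixed template:

    [subject NP of 1-3 filler nouns] [verb] [object NP of 1-3 nouns]
    [optional 1-2 bare-noun adjuncts]

The object NP is always the (single) entity span.  The knob is
``signal_strength`` (rho): with probability rho a sentence draws its
entity words from an *ambiguous* pool whose words also occur, unlabeled,
in adjunct positions elsewhere in the corpus — so token surface form (and
POS, which is NN in both positions) cannot decide entity status, and only
the constituent / dependency context disambiguates.  With probability
1 - rho the entity words come from a dedicated pool that appears nowhere
else, so surface form alone suffices.  At rho = 0 the mutual information
between "token sits in an NP" and "token is an entity", over
ambiguous-pool tokens, is zero; at rho = 1 it is maximal.

Constituency trees and dependency graphs are built by rule from the
template (the subject head attaches to the object head — the sentence
root — by nsubj; NP modifiers by compound; the verb by cop; adjuncts by
nmod), mirroring a copular biomedical sentence pattern.  A ``noise``
knob relabels a fraction of dependency relations at random, default 0.

The generator does not emulate realistic biomedical vocabulary, parse
diversity, or parser errors beyond that single knob.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import LabeledCorpus, LabeledSentence, write_conll
from .extract import (DEFAULT_ACCEPTABLE_LABELS, SyntacticContext, extract)
from .syntax import (ConstituencyTree, DependencyGraph, PosAnnotation, ROOT,
                     TreeNode, write_conllu)

__all__ = ["FixtureConfig", "FixtureBundle", "generate", "write_bundle",
           "make_samples", "syntactic_signal_mi"]

_DEP_LABELS = ("nsubj", "compound", "cop", "nmod", "amod", "det")


@dataclass(frozen=True)
class FixtureConfig:
    """Generation parameters; the bundle is a pure function of these."""

    seed: int = 0
    n_sentences: int = 100
    n_entity_words: int = 10       # dedicated, surface-determined entity nouns
    n_filler_words: int = 15       # subject-NP nouns, never entities
    n_ambiguous_words: int = 12    # occur both as entities and as adjuncts
    n_verbs: int = 5
    np_len: tuple[int, int] = (1, 3)       # subject and object NP lengths
    adjunct_len: tuple[int, int] = (1, 2)
    adjunct_prob: float = 0.7
    signal_strength: float = 1.0   # rho: P(entity words drawn from ambiguous pool)
    entity_types: tuple[str, ...] = ("Disease",)
    noise: float = 0.0             # fraction of dependency relations corrupted

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if self.np_len[0] < 1 or self.np_len[1] < self.np_len[0]:
            raise ValueError("invalid NP length range")
        if not self.entity_types:
            raise ValueError("need at least one entity type")
        per_type = self.n_ambiguous_words // len(self.entity_types)
        if per_type < self.np_len[1] or self.n_entity_words // len(self.entity_types) < self.np_len[1]:
            raise ValueError("word pools too small for the requested NP lengths")
        if self.n_filler_words < self.np_len[1]:
            raise ValueError("filler pool too small for the requested NP lengths")


@dataclass
class FixtureBundle:
    """A labeled corpus with aligned syntax and a train/dev/test split."""

    config: FixtureConfig
    sentences: list[LabeledSentence] = field(default_factory=list)
    pos: list[PosAnnotation] = field(default_factory=list)
    trees: list[ConstituencyTree] = field(default_factory=list)
    graphs: list[DependencyGraph] = field(default_factory=list)
    split: dict[str, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def corpus(self) -> LabeledCorpus:
        return LabeledCorpus(self.sentences)

    def subset(self, name: str) -> list[int]:
        return self.split.get(name, [])


def _pools(config: FixtureConfig) -> dict[str, list[str]]:
    return {
        "entity": [f"entwd{i}" for i in range(config.n_entity_words)],
        "filler": [f"filler{i}" for i in range(config.n_filler_words)],
        "ambiguous": [f"ambwd{i}" for i in range(config.n_ambiguous_words)],
        "verb": [f"links{i}" for i in range(config.n_verbs)],
    }


def _type_slice(pool: list[str], type_index: int, n_types: int) -> list[str]:
    per = len(pool) // n_types
    return pool[type_index * per:(type_index + 1) * per]


def generate(config: FixtureConfig) -> FixtureBundle:
    """Generate a bundle; byte-identical output for identical config."""
    rng = np.random.default_rng([config.seed, 0])
    # separate stream so the noise knob relabels relations without
    # perturbing the rest of the generated corpus
    noise_rng = np.random.default_rng([config.seed, 1])
    pools = _pools(config)
    n_types = len(config.entity_types)
    bundle = FixtureBundle(config=config)

    for si in range(config.n_sentences):
        lo, hi = config.np_len
        subj_len = int(rng.integers(lo, hi + 1))
        obj_len = int(rng.integers(lo, hi + 1))
        type_index = int(rng.integers(n_types))
        etype = config.entity_types[type_index]
        syntax_mode = bool(rng.random() < config.signal_strength)
        entity_pool = _type_slice(
            pools["ambiguous" if syntax_mode else "entity"], type_index, n_types)

        subj = list(rng.choice(pools["filler"], size=subj_len, replace=False))
        verb = str(rng.choice(pools["verb"]))
        obj = list(rng.choice(entity_pool, size=obj_len, replace=False))
        adjunct: list[str] = []
        if rng.random() < config.adjunct_prob:
            alen = int(rng.integers(config.adjunct_len[0], config.adjunct_len[1] + 1))
            adjunct = list(rng.choice(pools["ambiguous"], size=alen, replace=False))

        words = subj + [verb] + obj + adjunct
        tags = (["O"] * subj_len + ["O"]
                + [f"B-{etype}"] + [f"I-{etype}"] * (obj_len - 1)
                + ["O"] * len(adjunct))
        pos = (["NN"] * subj_len + ["VBZ"] + ["NN"] * obj_len + ["NN"] * len(adjunct))

        # constituency: (S (NP subj...) (VP (VBZ v) (NP obj...)) adjuncts...)
        subj_np = TreeNode("NP", [TreeNode("NN", word=w) for w in subj])
        obj_np = TreeNode("NP", [TreeNode("NN", word=w) for w in obj])
        vp = TreeNode("VP", [TreeNode("VBZ", word=verb), obj_np])
        s_children = [subj_np, vp] + [TreeNode("NN", word=a) for a in adjunct]
        tree = ConstituencyTree(TreeNode("S", s_children))

        # dependencies: object head is the root, mirroring a copular pattern
        subj_head = subj_len - 1
        verb_i = subj_len
        obj_start = subj_len + 1
        root_i = obj_start + obj_len - 1
        head = [0] * len(words)
        rel = [""] * len(words)
        for i in range(subj_len - 1):
            head[i], rel[i] = subj_head, "compound"
        head[subj_head], rel[subj_head] = root_i, "nsubj"
        head[verb_i], rel[verb_i] = root_i, "cop"
        for i in range(obj_start, root_i):
            head[i], rel[i] = root_i, "compound"
        head[root_i], rel[root_i] = ROOT, "root"
        for i in range(root_i + 1, len(words)):
            head[i], rel[i] = root_i, "nmod"
        if config.noise > 0:
            for i in range(len(words)):
                if head[i] != ROOT and noise_rng.random() < config.noise:
                    rel[i] = str(noise_rng.choice(_DEP_LABELS))
        graph = DependencyGraph(tuple(head), tuple(rel))

        bundle.sentences.append(LabeledSentence.from_words(words, tags))
        bundle.pos.append(PosAnnotation(tuple(pos)))
        bundle.trees.append(tree)
        bundle.graphs.append(graph)

    # deterministic round-robin 60/20/20 split
    bundle.split = {"train": [], "dev": [], "test": []}
    for i in range(config.n_sentences):
        name = ("train", "train", "train", "dev", "test")[i % 5]
        bundle.split[name].append(i)
    return bundle


def write_bundle(bundle: FixtureBundle, directory: str) -> None:
    """Write the bundle as plain-text files that round-trip through the
    package's readers: ``corpus.conll`` (tokens + BIO tags),
    ``corpus.conllu`` (POS + dependencies), ``trees.txt`` (one bracketed
    tree per line), plus ``split.json`` with the subset indices."""
    import json

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "corpus.conll"), "w") as fh:
        write_conll(bundle.corpus, fh)
    with open(os.path.join(directory, "corpus.conllu"), "w") as fh:
        write_conllu(
            [(s.words, p, g) for s, p, g in
             zip(bundle.sentences, bundle.pos, bundle.graphs)], fh)
    with open(os.path.join(directory, "trees.txt"), "w") as fh:
        for t in bundle.trees:
            fh.write(t.render() + "\n")
    with open(os.path.join(directory, "split.json"), "w") as fh:
        json.dump(bundle.split, fh)


def make_samples(bundle: FixtureBundle, subset: str | None = None,
                 syntactic_types: Sequence[str] = ("PL", "SC", "DR"),
                 acceptable: frozenset = DEFAULT_ACCEPTABLE_LABELS,
                 window: int = 1):
    """Extract per-sentence contexts and pair them with the sentences,
    yielding (sentence, {type: context}) samples ready for the tagger."""
    idx = bundle.subset(subset) if subset else range(len(bundle))
    samples = []
    for i in idx:
        s = bundle.sentences[i]
        ctx: dict[str, SyntacticContext] = {}
        for st in syntactic_types:
            ctx[st] = extract(s, st, pos=bundle.pos[i], tree=bundle.trees[i],
                              graph=bundle.graphs[i], window=window,
                              acceptable=acceptable)
        samples.append((s, ctx))
    return samples


def syntactic_signal_mi(bundle: FixtureBundle) -> float:
    """Mutual information (bits) between NP membership and entity status,
    counted over ambiguous-pool tokens of the generated corpus.

    Zero when entity status never depends on structure (rho = 0) and
    maximal when structure fully determines it (rho = 1).
    """
    counts = np.zeros((2, 2))
    for s, tree, _ in zip(bundle.sentences, bundle.trees, bundle.graphs):
        assert s.tags is not None
        for i, w in enumerate(s.words):
            if not w.startswith("ambwd"):
                continue
            in_np = any(a.label == "NP" for a in tree.ancestors(i))
            is_ent = s.tags[i] != "O"
            counts[int(in_np), int(is_ent)] += 1
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    px, py = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if p[a, b] > 0:
                mi += p[a, b] * math.log2(p[a, b] / (px[a] * py[b]))
    return mi
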