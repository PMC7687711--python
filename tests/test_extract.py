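"""The three syntactic context extractors and the key/value vocabularies."""

import io

import pytest

from memtagger.corpus import LabeledSentence
from memtagger.extract import (DEFAULT_ACCEPTABLE_LABELS, UNK, build_vocab,
                               extract, extract_constituent_context,
                               extract_dependency_context, extract_pos_context,
                               read_contexts_jsonl, write_contexts_jsonl)
from memtagger.syntax import ROOT, AlignmentError, DependencyGraph, PosAnnotation
from memtagger.fixtures import make_samples

FOCUS = 2  # "deficiency" in the worked example


def lower(xs):
    return [x.lower() for x in xs]


class TestWorkedExample:
    """The copular disease sentence reproduces the documented key/value lists."""

    def test_pos_labels(self, worked_example):
        sent, pos, _, _ = worked_example
        ctx = extract_pos_context(sent, pos, window=1)
        assert ctx.keys[FOCUS] == ["deficiency", "dehydrogenase", "is"]
        assert ctx.values[FOCUS] == ["deficiency_NN", "dehydrogenase_NN", "is_VBZ"]

    def test_constituents(self, worked_example):
        sent, _, tree, _ = worked_example
        ctx = extract_constituent_context(sent, tree)
        assert lower(ctx.keys[FOCUS]) == [
            "deficiency", "dihydropyrimidine", "dehydrogenase"]
        assert lower(ctx.values[FOCUS]) == [
            "deficiency_np", "dihydropyrimidine_np", "dehydrogenase_np"]

    def test_dependencies(self, worked_example):
        sent, _, _, graph = worked_example
        ctx = extract_dependency_context(sent, graph)
        assert lower(ctx.values[FOCUS]) == [
            "deficiency_nsubj", "dihydropyrimidine_compound",
            "dehydrogenase_compound", "disease_root"]


class TestPosContext:
    def test_single_word_sentence(self):
        sent = LabeledSentence.from_words(["w"])
        ctx = extract_pos_context(sent, PosAnnotation(("T",)))
        assert ctx.keys == [["w"]]
        assert ctx.values == [["w_T"]]

    def test_against_brute_force_window(self, small_bundle):
        for i in range(10):
            sent, pos = small_bundle.sentences[i], small_bundle.pos[i]
            for window in (1, 2):
                ctx = extract_pos_context(sent, pos, window=window)
                words = sent.words
                for t in range(len(sent)):
                    expected = {words[j] for j in range(len(words))
                                if abs(j - t) <= window}
                    assert set(ctx.keys[t]) == expected
                    assert ctx.keys[t][0] == words[t]  # self listed first

    def test_window_1_slot_bounds(self, small_bundle):
        for i in range(10):
            ctx = extract_pos_context(small_bundle.sentences[i], small_bundle.pos[i])
            assert all(1 <= ctx.m(t) <= 3 for t in range(len(ctx)))

    def test_misaligned_pos_rejected(self):
        sent = LabeledSentence.from_words(["a", "b"])
        with pytest.raises(AlignmentError):
            extract_pos_context(sent, PosAnnotation(("NN",)))


class TestConstituentContext:
    def test_root_only_acceptable(self, worked_example):
        sent, _, tree, _ = worked_example
        ctx = extract_constituent_context(sent, tree, acceptable={"S"})
        for t in range(len(sent)):
            assert set(ctx.keys[t]) == set(sent.words)
            assert ctx.keys[t][0] == sent.words[t]

    def test_no_acceptable_ancestor_gives_empty_context(self, worked_example):
        sent, _, tree, _ = worked_example
        ctx = extract_constituent_context(sent, tree, acceptable={"SBAR"})
        assert all(ctx.m(t) == 0 for t in range(len(sent)))

    def test_against_ancestor_enumeration_oracle(self, small_bundle):
        for i in range(10):
            sent, tree = small_bundle.sentences[i], small_bundle.trees[i]
            ctx = extract_constituent_context(sent, tree)
            for t in range(len(sent)):
                chain = [a for a in tree.ancestors(t)
                         if a.label in DEFAULT_ACCEPTABLE_LABELS]
                if not chain:
                    assert ctx.m(t) == 0
                    continue
                lowest = chain[0]
                lo, hi = lowest.span
                assert set(ctx.keys[t]) == {sent.words[j] for j in range(lo, hi)}
                assert all(v.endswith("_" + lowest.label) for v in ctx.values[t])


class TestDependencyContext:
    def test_single_token_root(self):
        sent = LabeledSentence.from_words(["w"])
        g = DependencyGraph(head=(ROOT,), rel=("root",))
        ctx = extract_dependency_context(sent, g)
        assert ctx.keys == [["w"]]
        assert ctx.values == [["w_ROOT"]]

    def test_against_adjacency_oracle(self, small_bundle):
        for i in range(10):
            sent, g = small_bundle.sentences[i], small_bundle.graphs[i]
            ctx = extract_dependency_context(sent, g)
            for t in range(len(sent)):
                expected = [t] + g.dependents(t)
                if g.head[t] != ROOT:
                    expected.append(g.head[t])
                assert ctx.keys[t] == [sent.words[j] for j in expected]

    def test_edge_contributions_match_tree(self, small_bundle):
        # each edge shows up once as a dependent-slot and once as a
        # governor-slot; plus one self-slot per token
        for i in range(10):
            sent, g = small_bundle.sentences[i], small_bundle.graphs[i]
            ctx = extract_dependency_context(sent, g)
            l = len(sent)
            total_slots = sum(ctx.m(t) for t in range(l))
            assert total_slots == l + 2 * (l - 1)


class TestInvariants:
    def test_value_strips_to_key_for_every_extractor(self, small_bundle):
        for sample, ctx in make_samples(small_bundle)[:10]:
            for st, c in ctx.items():
                for ks, vs in zip(c.keys, c.values):
                    assert len(ks) == len(vs)
                    for k, v in zip(ks, vs):
                        assert v.startswith(k + "_")

    def test_extraction_deterministic(self, small_bundle):
        a = make_samples(small_bundle)[:5]
        b = make_samples(small_bundle)[:5]
        for (_, ca), (_, cb) in zip(a, b):
            for st in ca:
                assert ca[st].keys == cb[st].keys
                assert ca[st].values == cb[st].values


class TestVocab:
    def test_empty_corpus_has_only_unk(self):
        v = build_vocab([])
        assert v.key_to_id == {UNK: 0}
        assert v.value_to_id == {UNK: 0}

    def test_single_slot(self, worked_example):
        sent, pos, _, _ = worked_example
        single = LabeledSentence.from_words(["w"])
        ctx = extract_pos_context(single, PosAnnotation(("T",)))
        v = build_vocab([ctx])
        assert v.n_keys == 2 and v.n_values == 2
        assert v.key_id("w") == 1 and v.key_id("unseen") == 0

    def test_min_freq_maps_rare_to_unk(self):
        common = extract_pos_context(
            LabeledSentence.from_words(["w", "w"]), PosAnnotation(("T", "T")))
        rare = extract_pos_context(
            LabeledSentence.from_words(["q"]), PosAnnotation(("T",)))
        v = build_vocab([common, rare], min_freq=2)
        assert v.key_id("w") != 0
        assert v.key_id("q") == 0  # below min frequency -> UNK

    def test_id_assignment_stable(self, small_bundle):
        ctxs = [c["SC"] for _, c in make_samples(small_bundle)]
        v1, v2 = build_vocab(ctxs), build_vocab(ctxs)
        assert v1.key_to_id == v2.key_to_id
        assert v1.value_to_id == v2.value_to_id

    def test_mixed_types_rejected(self, small_bundle):
        samples = make_samples(small_bundle)[:2]
        with pytest.raises(ValueError, match="mixed"):
            build_vocab([samples[0][1]["SC"], samples[1][1]["DR"]])


def test_jsonl_round_trip(small_bundle):
    ctxs = [c["DR"] for _, c in make_samples(small_bundle)[:5]]
    buf = io.StringIO()
    write_contexts_jsonl(ctxs, buf)
    again = read_contexts_jsonl(io.StringIO(buf.getvalue()))
    assert len(again) == len(ctxs)
    for a, b in zip(ctxs, again):
        assert a.keys == b.keys and a.values == b.values and \
            a.syntactic_type == b.syntactic_type
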