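import numpy as np
import pytest

from memtagger import (FixtureConfig, LabeledSentence, PosAnnotation,
                       generate, parse_bracketed)
from memtagger.syntax import ROOT, DependencyGraph

WORKED_SENTENCE = "Dihydropyrimidine dehydrogenase deficiency is an autosomal recessive disease"
FOCUS = 2  # "deficiency"


@pytest.fixture(scope="session")
def worked_example():
    """The copular disease sentence used throughout the docs, with its
    POS row, constituency tree and dependency tree."""
    sent = LabeledSentence.from_words(WORKED_SENTENCE.split())
    pos = PosAnnotation(("NN", "NN", "NN", "VBZ", "DT", "JJ", "JJ", "NN"))
    tree = parse_bracketed(
        "(S (NP (NN Dihydropyrimidine) (NN dehydrogenase) (NN deficiency))"
        " (VP (VBZ is) (NP (DT an) (JJ autosomal) (JJ recessive) (NN disease))))")
    graph = DependencyGraph(
        head=(2, 2, 7, 7, 7, 7, 7, ROOT),
        rel=("compound", "compound", "nsubj", "cop", "det", "amod", "amod", "root"))
    return sent, pos, tree, graph


@pytest.fixture(scope="session")
def small_bundle():
    return generate(FixtureConfig(seed=7, n_sentences=40))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
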