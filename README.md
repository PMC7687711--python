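# memtagger

Sequence labeling for biomedical named entity recognition (BioNER) with a
key-value memory attention module over auto-extracted syntactic context.

Biomedical text is rich in long, well-structured sentences where syntax is
a strong cue for entity boundaries — the yield of a noun phrase often *is*
the gene, disease, chemical or species mention. Auto-produced parses are
cheap to obtain but noisy, and concatenating syntactic embeddings directly
onto the encoder output lets that noise propagate. This package instead
weighs syntactic evidence per token with a key-value memory: useful
context is amplified, noisy context is attenuated.

## Model

The input sentence `X = {x_1, ..., x_l}` is tagged with BIO labels. For
each token `x_i`, an extractor derives *context features* (keys)
`K_i = [k_{i,1}, ..., k_{i,m_i}]` and *syntactic information instances*
(values) `V_i = [v_{i,1}, ..., v_{i,m_i}]`, where each value is a key word
joined with its syntactic label (e.g. `dehydrogenase_NN`,
`deficiency_NP`, `disease_ROOT`). Three extractors are provided:

* **PL** (POS labels): a 1-word window around `x_i`; values carry each
  word's POS tag.
* **SC** (syntactic constituents): ascend from `x_i`'s leaf in the
  constituency tree to the first node whose label is in an acceptable set
  `L` (NP, VP, PP, ...); keys are the words under that node, values carry
  the node label.
* **DR** (dependency relations): `x_i` itself, its dependents and its
  governor; values carry each word's own relation to its governor.

Given encoder hidden vectors `[h_1, ..., h_l]`, the memory module computes

    p_{i,j} = exp(h_i · e^k_{i,j}) / Σ_{j'} exp(h_i · e^k_{i,j'})
    o_i     = Σ_j p_{i,j} e^v_{i,j}

with `e^k`, `e^v` trainable key/value embedding tables, then concatenates
`o'_i = h_i ⊕ o_i`. A trainable matrix `W` projects `o'_i` to label
scores `u_i = W o'_i`, and the predicted tag is `ŷ_i = argmax softmax(u_i)`.
A direct-concatenation (DC) baseline appends unweighted means of the slot
embeddings instead of attending, and several syntactic types can be
ensembled by summing or concatenating their pooled vectors.

The encoder is a pluggable contract (token sequence → one d-vector per
token). The package ships a small trainable encoder (token embedding plus
one-step bidirectional neighbor mixing) so the full pipeline trains on a
CPU in seconds; the training loop fine-tunes all parameters, including the
encoder, with Adam on token-level cross-entropy and keeps the checkpoint
with the best development-set entity F1. Evaluation is entity-level micro
P/R/F1 with exact span-and-type matching, averaged over five seeds.

## Worked example

```python
from memtagger import (LabeledSentence, PosAnnotation, parse_bracketed,
                       extract_pos_context, extract_constituent_context)

sent = LabeledSentence.from_words(
    "Dihydropyrimidine dehydrogenase deficiency is an autosomal recessive disease".split())
pos = PosAnnotation(("NN", "NN", "NN", "VBZ", "DT", "JJ", "JJ", "NN"))
tree = parse_bracketed(
    "(S (NP (NN Dihydropyrimidine) (NN dehydrogenase) (NN deficiency))"
    " (VP (VBZ is) (NP (DT an) (JJ autosomal) (JJ recessive) (NN disease))))")

print(extract_pos_context(sent, pos).values[2])
# ['deficiency_NN', 'dehydrogenase_NN', 'is_VBZ']
print(extract_constituent_context(sent, tree).values[2])
# ['deficiency_NP', 'Dihydropyrimidine_NP', 'dehydrogenase_NP']
```

For the focus word *deficiency*, the window extractor pairs it with its
two neighbors and their POS tags; the constituent extractor finds the
subject NP as the first acceptable ancestor and pairs every word under it
with the `NP` label. Training end to end on a synthetic corpus whose
entity status is decided purely by constituent structure:

```python
from memtagger import FixtureConfig, generate, make_samples, KVMNTagger

bundle = generate(FixtureConfig(seed=42, n_sentences=300, signal_strength=1.0))
train = make_samples(bundle, "train", syntactic_types=("SC",))
test = make_samples(bundle, "test", syntactic_types=("SC",))
model = KVMNTagger(mode="kvmn", syntactic_types=("SC",), epochs=30, seed=11)
model.fit(train)
print(round(100 * model.score(test, [s.tags for s, _ in test]), 2))  # 100.0
```

The plain baseline (`mode="none"`) reaches only ~50 F1 on the same data,
because the entity words also occur, unlabeled, outside noun phrases —
surface form alone cannot decide them.

A `memtagger` console script exposes the same workflow as subcommands:
`fixtures`, `extract`, `train`, `predict`, `evaluate`, `aggregate`.

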