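# Methods

## Task and model

The package treats biomedical named entity recognition as per-token BIO
sequence labeling. An encoder maps the token sequence to hidden vectors
`h_1..h_l`; an optional key-value memory augments each `h_i` with pooled
syntactic evidence; a linear projection and a softmax produce the tag.
The memory holds, per token, `m_i` slots extracted from an automatic
parse of the sentence: keys are context words, values are the same words
joined with a syntactic label. Attention weights come from dot products
between `h_i` and the key embeddings, normalized by softmax; the pooled
vector is the weight-averaged value embedding, concatenated to `h_i`
before projection. The intent is robustness to parser noise: a slot whose
key does not fit the token's context receives low weight, unlike the
direct-concatenation (DC) baseline, which averages all slot embeddings
with equal weight.

Assumptions: one tag per token (no CRF transition modeling — the decoder
is an independent softmax per position); parses are given as files aligned
positionally with the corpus; keys and values are looked up as whole-token
strings.

## Extraction rules

* **PL**: keys are the token plus up to `window` (default 1) neighbors
  per side, self first, then left neighbors nearest-first, then right.
  Every token therefore has 1–3 slots at window 1.
* **SC**: the first ancestor of the token's leaf whose label is in the
  acceptable set `L` supplies the slot words (its yield, focus word
  first) and the value label. `L` defaults to
  {NP, VP, PP, ADJP, ADVP, S, SBAR, QP, PRT, PRN} and is configurable;
  there is no single canonical set in the literature, so the choice is
  exposed rather than hard-coded. A token with no acceptable ancestor
  gets zero slots, and the memory then contributes a zero vector — the
  neutral element under concatenation.
* **DR**: slots are the token itself, its direct dependents (token
  order), and its governor (omitted for the root). Each slot word is
  valued with its *own* relation to its governor; a root governor
  contributes the ROOT pseudo-relation (`disease_ROOT`). The alternative
  convention — labeling the governor with the focus token's relation —
  was rejected because it cannot produce instances of the `word_ROOT`
  form for non-root focus tokens.

Extraction is case-preserving by default (`lowercase` flag available),
deterministic, and duplicate slots are kept: softmax attention handles
repeated keys naturally. Over a sentence, DR slot counts total
`l + 2(l-1)`: one self slot per token and two slots per tree edge.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `hidden_dim` | 16 | encoder and memory embedding dimension d (dimensionless) |
| `mode` | `kvmn` | `kvmn` attention memory, `dc` unweighted baseline, `none` plain tagger |
| `syntactic_types` | `("SC",)` | which extractors feed the memory |
| `ensemble_strategy` | `concat` | multi-type fusion: concat keeps per-type blocks (dim d(1+n)); sum adds them (dim 2d) |
| `combine` | `concat` | how memory joins the hidden state; `add` (h + o) mirrors the original memory-network formulation and is kept behind this switch |
| `epochs` | 30 | training epochs; benchmark-scale corpora conventionally use 60–150 |
| `lr` | 0.01 | Adam step size |
| `min_freq` | 1 | key/value strings rarer than this map to UNK (id 0) |
| `seed` | 0 | initialization and shuffling |

Embeddings initialize uniformly in [-0.1, 0.1]; the memory tables share
the encoder dimension so the key–hidden dot product is defined.

## Training and numerics

The loss is token-level cross-entropy — the canonical companion of an
independent softmax decoder. All forward/backward passes are explicit
numpy with hand-derived gradients (softmax-attention Jacobian included),
verified against central finite differences in the test suite at relative
tolerance 1e-4. Softmax computations subtract the row maximum before
exponentiation; this is algebraically identical to the plain form.
Argmax ties break to the lowest label id (labels sorted lexicographically)
so decoding is deterministic. When a development set is supplied, entity
F1 is measured after every epoch and the best-scoring parameter snapshot
is returned; with no dev set the final epoch's parameters stand.

The shipped encoder is `h_i = E[x_i] + U_l E[x_{i-1}] + U_r E[x_{i+1}]`
with zero vectors past the sentence boundary. It is deliberately local:
it can learn begin-vs-inside distinctions from the neighboring word but
cannot see global structure, which is exactly the information the memory
supplies. Any object with a `hidden_size` and an `encode(words)` method
satisfies the encoder contract; pretrained contextual encoders plug in
through the same interface and are not bundled.

## Evaluation

Entity-level micro precision/recall/F1 with exact (start, end, type)
matching, the convention under which the standard BioNER benchmarks are
scored. Zero-denominator precision or recall is defined as 0. Predicted
tag sequences are repaired leniently before span extraction: an `I-t`
that does not continue a same-type span starts one, since an unconstrained
softmax decoder can emit such sequences. Multi-seed aggregation reports
the mean and, by default, the population (divide-by-n) standard
deviation; `ddof=1` switches to the sample convention.

## Synthetic corpus

The generator emits template sentences — subject NP of filler nouns, a
linking verb, an object NP (always the single entity span), optional
bare-noun adjuncts — with constituency and dependency structure built by
rule: the object head is the sentence root, the subject head attaches by
`nsubj`, NP modifiers by `compound`, the verb by `cop`, adjuncts by
`nmod`, mirroring the copular pattern common in definitional biomedical
sentences. `signal_strength` (rho) controls whether entity words come
from an ambiguous pool that also appears unlabeled in adjunct position
(structure decides; probability rho) or from a dedicated pool (surface
decides). Adjunct words carry the same NN POS as entity words so the
POS-window extractor cannot resolve the ambiguity — only constituent or
dependency context can. A `noise` knob relabels a fraction of dependency
relations from an independent random stream, leaving the rest of the
corpus untouched. Generation is a pure function of the config, split
round-robin 60/20/20 into train/dev/test.

What passing tests on this corpus show: the full pipeline — extraction,
memory attention, training — can recover a planted structural signal that
a surface-only tagger provably cannot. What they do not show: performance
on real biomedical text, where parses are imperfect, vocabulary is
open-ended, entities are rarer and sentence structure far more varied.

## Problem sizes

The recovery experiment uses 300 generated sentences (180 train / 60 dev
/ 60 test), hidden dimension 16, 30 epochs, five seeds per condition —
sizes at which the contrast between the memory tagger and the baseline is
already decisive (roughly 100 vs 50 F1 at rho = 1, a tie at rho = 0) and
the whole experiment runs in well under a minute on one CPU. Unit suites
use 8–40-sentence bundles.

## Known limitations

* No CRF or transition constraints; illegal BIO sequences are possible
  and handled by lenient repair at evaluation time.
* Subword pooling is out of scope for the bundled whole-token encoder;
  adapters for subword encoders should expose first-subword pooling
  behind the same contract.
* The DC baseline's unweighted mean is one of several defensible
  aggregations for "no attention"; it was chosen as the cleanest contrast
  to the weighted mean the memory computes.
* Hidden vectors and embeddings are not L2-normalized before the dot
  product; the weighting formula is used exactly as stated.
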