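"""BIO-tagged corpora: reading/writing two-column CoNLL files and
converting between tag sequences and typed entity spans.

A corpus is a list of sentences; each sentence is a token sequence
``x_1..x_l`` with an optional aligned list of BIO tags (``O``,
``B-<type>``, ``I-<type>``).  Entity spans are half-open 0-based token
intervals carrying an entity type; all index arithmetic in the package
is 0-based and conversion to 1-based happens only at format boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "Token",
    "LabeledSentence",
    "EntitySpan",
    "LabeledCorpus",
    "CorpusFormatError",
    "TagValidationError",
    "read_conll",
    "write_conll",
    "spans_from_bio",
    "bio_from_spans",
]

_BIO_RE = re.compile(r"^(O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Malformed CoNLL input (missing columns, bad structure)."""


class TagValidationError(ValueError):
    """A tag string does not match the BIO grammar, or tags misalign."""


@dataclass(frozen=True)
class Token:
    text: str
    index: int

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("token text must be non-empty")
        if self.index < 0:
            raise ValueError("token index must be >= 0")


@dataclass
class LabeledSentence:
    """A token sequence with optional aligned BIO tags."""

    tokens: list[Token]
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ValueError(
                    f"token index {tok.index} at position {i}: indices must be "
                    "consecutive from 0"
                )
        if self.tags is not None:
            if len(self.tags) != len(self.tokens):
                raise TagValidationError(
                    f"{len(self.tags)} tags for {len(self.tokens)} tokens"
                )
            for t in self.tags:
                _check_tag(t)

    @classmethod
    def from_words(cls, words: Sequence[str], tags: Sequence[str] | None = None
                   ) -> "LabeledSentence":
        return cls([Token(w, i) for i, w in enumerate(words)],
                   list(tags) if tags is not None else None)

    @property
    def words(self) -> list[str]:
        return [t.text for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledSentence):
            return NotImplemented
        return self.tokens == other.tokens and self.tags == other.tags


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open token interval [start, end) with an entity type."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class LabeledCorpus:
    sentences: list[LabeledSentence] = field(default_factory=list)

    @property
    def label_set(self) -> set[str]:
        out: set[str] = set()
        for s in self.sentences:
            if s.tags is not None:
                out.update(s.tags)
        return out

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledCorpus):
            return NotImplemented
        return self.sentences == other.sentences


def _check_tag(tag: str) -> None:
    if not _BIO_RE.match(tag):
        raise TagValidationError(f"tag {tag!r} does not match O / B-<type> / I-<type>")


def read_conll(stream: IO[str] | Iterable[str], token_col: int = 0,
               tag_col: int | None = 1) -> LabeledCorpus:
    """Read a blank-line-separated CoNLL corpus.

    Parameters
    ----------
    stream : text stream or iterable of lines
    token_col : column index holding the token text
    tag_col : column index holding the BIO tag, or None for unlabeled input

    Raises
    ------
    CorpusFormatError
        A non-blank line has fewer columns than needed (the message names
        the 1-based line number).
    TagValidationError
        A tag does not match the BIO grammar.
    """
    need = token_col + 1 if tag_col is None else max(token_col, tag_col) + 1
    sentences: list[LabeledSentence] = []
    words: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if words:
            sentences.append(
                LabeledSentence.from_words(words, None if tag_col is None else tags))
            words.clear()
            tags.clear()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        cols = line.split()
        if len(cols) < need:
            raise CorpusFormatError(
                f"line {lineno}: expected at least {need} columns, got {len(cols)}")
        words.append(cols[token_col])
        if tag_col is not None:
            _check_tag(cols[tag_col])
            tags.append(cols[tag_col])
    flush()
    return LabeledCorpus(sentences)


def write_conll(corpus: LabeledCorpus, stream: IO[str]) -> None:
    """Write ``token TAB tag`` lines, sentences separated by a blank line.

    Output is bit-stable given the same corpus and round-trips through
    :func:`read_conll`.
    """
    for sent in corpus:
        tags = sent.tags
        if tags is not None and len(tags) != len(sent.tokens):
            raise TagValidationError("sentence tags misaligned with tokens")
        for i, tok in enumerate(sent.tokens):
            if tags is None:
                stream.write(f"{tok.text}\n")
            else:
                stream.write(f"{tok.text}\t{tags[i]}\n")
        stream.write("\n")


def spans_from_bio(tags: Sequence[str]) -> list[EntitySpan]:
    """Decode a BIO tag sequence into typed entity spans.

    ``B-t`` starts a span; ``I-t`` continues a span of the same type.  An
    ``I-t`` that does not continue one (after ``O``, at sentence start, or
    after a different type) leniently starts a new span — an argmax decoder
    can emit such sequences and common CoNLL scorers repair rather than
    reject them.  Returned spans never overlap and are sorted by start.
    """
    for t in tags:
        _check_tag(t)
    spans: list[EntitySpan] = []
    start: int | None = None
    etype: str | None = None
    for i, tag in enumerate(tags):
        if tag == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, etype))  # type: ignore[arg-type]
                start = etype = None
        elif tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, etype))  # type: ignore[arg-type]
            start, etype = i, tag[2:]
        else:  # I-
            t = tag[2:]
            if start is None or t != etype:
                if start is not None:
                    spans.append(EntitySpan(start, i, etype))  # type: ignore[arg-type]
                start, etype = i, t
    if start is not None:
        spans.append(EntitySpan(start, len(tags), etype))  # type: ignore[arg-type]
    return spans


def bio_from_spans(spans: Iterable[EntitySpan], length: int) -> list[str]:
    """Encode non-overlapping spans as a BIO tag sequence of ``length``.

    Inverse of :func:`spans_from_bio` on any valid span set:
    ``spans_from_bio(bio_from_spans(s, l)) == sorted(s)``.
    """
    tags = ["O"] * length
    for sp in sorted(spans):
        if sp.end > length:
            raise ValueError(f"span {sp} exceeds sentence length {length}")
        for i in range(sp.start, sp.end):
            if tags[i] != "O":
                raise ValueError(f"span {sp} overlaps a previous span")
            tags[i] = ("B-" if i == sp.start else "I-") + sp.etype
    return tags
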