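"""Syntactic annotations from standard file formats.

Three annotation types travel with each sentence: POS labels (one per
token), a dependency tree (per-token governor index plus relation label),
and a constituency tree (PTB-style bracketing whose leaves align 1:1 with
the tokens).  Annotations arrive as files — CoNLL-U for POS + dependencies,
one-per-line bracketed trees for constituents — so any parser toolkit can
produce them; nothing here shells out to a parser.

Alignment between a BIO corpus and its parse files is positional: the
i-th parsed sentence annotates the i-th corpus sentence, and token counts
must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "ROOT",
    "PosAnnotation",
    "DependencyGraph",
    "TreeNode",
    "ConstituencyTree",
    "SyntaxFormatError",
    "AlignmentError",
    "read_conllu",
    "write_conllu",
    "read_bracketed_trees",
    "parse_bracketed",
]

#: Sentinel used as the governor index of the root token.
ROOT = -1


class SyntaxFormatError(ValueError):
    """Malformed CoNLL-U or bracketed-tree input."""


class AlignmentError(ValueError):
    """Annotation does not align with its sentence's tokens."""


@dataclass(frozen=True)
class PosAnnotation:
    """Per-token POS labels, aligned to the sentence."""

    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DependencyGraph:
    """A rooted dependency tree over a sentence.

    ``head[i]`` is the 0-based index of token i's governor, or :data:`ROOT`
    for the single root token; ``rel[i]`` is the relation of token i to its
    governor (the root carries ``root_label``, a pseudo-relation such as
    ``ROOT``, matching instance strings like ``disease_ROOT``).
    """

    head: tuple[int, ...]
    rel: tuple[str, ...]
    root_label: str = "ROOT"

    def __post_init__(self) -> None:
        n = len(self.head)
        if len(self.rel) != n:
            raise ValueError("head/rel length mismatch")
        roots = [i for i, h in enumerate(self.head) if h == ROOT]
        if len(roots) != 1:
            raise SyntaxFormatError(f"expected exactly one root, found {len(roots)}")
        for i, h in enumerate(self.head):
            if h != ROOT and not (0 <= h < n):
                raise SyntaxFormatError(f"head {h} of token {i} out of range")
        # Tree check: every token must reach the root without revisiting.
        for i in range(n):
            seen = set()
            j = i
            while self.head[j] != ROOT:
                if j in seen:
                    raise SyntaxFormatError(f"cycle through token {i}")
                seen.add(j)
                j = self.head[j]

    def __len__(self) -> int:
        return len(self.head)

    @property
    def root(self) -> int:
        return self.head.index(ROOT)

    def dependents(self, i: int) -> list[int]:
        """Direct dependents of token i, in token order."""
        return [j for j, h in enumerate(self.head) if h == i]


@dataclass
class TreeNode:
    """An internal constituency node; leaves are (label, word) preterminals.

    ``span`` is the node's yield as a half-open token interval, filled in
    when the tree is built.
    """

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    word: str | None = None  # set iff this is a leaf (preterminal)
    span: tuple[int, int] = (0, 0)

    @property
    def is_leaf(self) -> bool:
        return self.word is not None


@dataclass
class ConstituencyTree:
    root: TreeNode

    def __post_init__(self) -> None:
        self._leaves: list[TreeNode] = []
        self._parent: dict[int, TreeNode] = {}
        self._index(self.root, None)

    def _index(self, node: TreeNode, parent: TreeNode | None) -> None:
        if parent is not None:
            self._parent[id(node)] = parent
        if node.is_leaf:
            i = len(self._leaves)
            node.span = (i, i + 1)
            self._leaves.append(node)
            return
        if not node.children:
            raise SyntaxFormatError(f"internal node {node.label!r} has no children")
        start = len(self._leaves)
        for child in node.children:
            self._index(child, node)
        node.span = (start, len(self._leaves))

    @property
    def leaves(self) -> list[TreeNode]:
        return self._leaves

    @property
    def words(self) -> list[str]:
        return [lf.word for lf in self._leaves]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self._leaves)

    def ancestors(self, token_index: int) -> Iterator[TreeNode]:
        """Ancestors of a token's leaf, lowest first, ending at the root."""
        node: TreeNode | None = self._leaves[token_index]
        node = self._parent.get(id(node))
        while node is not None:
            yield node
            node = self._parent.get(id(node))

    def render(self) -> str:
        """One-line PTB bracketing; inverse of :func:`parse_bracketed`."""
        def rec(n: TreeNode) -> str:
            if n.is_leaf:
                return f"({n.label} {n.word})"
            return "(" + n.label + " " + " ".join(rec(c) for c in n.children) + ")"
        return rec(self.root)

    def check_alignment(self, words: list[str]) -> None:
        if self.words != words:
            raise AlignmentError(
                f"tree yield {self.words!r} does not match tokens {words!r}")


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(stream: IO[str] | Iterable[str], use_xpos: bool = False
                ) -> list[tuple[list[str], PosAnnotation, DependencyGraph]]:
    """Read sentences from 10-column CoNLL-U.

    Multi-word-token ranges (``1-2``) and empty nodes (``1.1``) are
    skipped; ``#`` comment lines are ignored.  HEAD 0 becomes the
    :data:`ROOT` sentinel and 1-based heads become 0-based indices.  UPOS
    fills the POS annotation unless ``use_xpos`` is set.
    """
    out: list[tuple[list[str], PosAnnotation, DependencyGraph]] = []
    words: list[str] = []
    pos: list[str] = []
    heads: list[int] = []
    rels: list[str] = []

    def flush(lineno: int) -> None:
        if not words:
            return
        for i, h in enumerate(heads):
            if h != ROOT and not (0 <= h < len(words)):
                raise SyntaxFormatError(
                    f"near line {lineno}: HEAD {h + 1} of token {i + 1} out of range")
        out.append((list(words), PosAnnotation(tuple(pos)),
                    DependencyGraph(tuple(heads), tuple(rels))))
        words.clear(); pos.clear(); heads.clear(); rels.clear()

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise SyntaxFormatError(f"line {lineno}: expected 10 columns, got {len(cols)}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue  # multi-word token range / empty node
        words.append(cols[1])
        pos.append(cols[4] if use_xpos else cols[3])
        try:
            h = int(cols[6])
        except ValueError as exc:
            raise SyntaxFormatError(f"line {lineno}: non-integer HEAD {cols[6]!r}") from exc
        heads.append(ROOT if h == 0 else h - 1)
        rels.append(cols[7])
    flush(lineno + 1)
    return out


def write_conllu(sentences: Iterable[tuple[list[str], PosAnnotation, DependencyGraph]],
                 stream: IO[str]) -> None:
    """Write 10-column CoNLL-U (UPOS and XPOS both set to the POS label)."""
    for words, pos, graph in sentences:
        if len(pos) != len(words) or len(graph) != len(words):
            raise AlignmentError("POS/dependency annotation misaligned with tokens")
        for i, w in enumerate(words):
            head = 0 if graph.head[i] == ROOT else graph.head[i] + 1
            stream.write("\t".join([
                str(i + 1), w, w, pos.labels[i], pos.labels[i], "_",
                str(head), graph.rel[i], "_", "_",
            ]) + "\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Bracketed trees

def parse_bracketed(text: str) -> ConstituencyTree:
    """Parse one PTB-style bracketed tree, e.g. ``(S (NP (NN a)) (VP (VBZ b)))``."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise SyntaxFormatError("empty tree")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise SyntaxFormatError(f"expected '(' at item {pos}, got {tokens[pos]!r}")
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise SyntaxFormatError(f"missing node label at item {pos}")
        label = tokens[pos]
        pos += 1
        node = TreeNode(label)
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                node.children.append(parse_node())
            else:
                if node.word is not None or node.children:
                    raise SyntaxFormatError(
                        f"preterminal {label!r} mixes words and children")
                node.word = tokens[pos]
                pos += 1
        if pos >= len(tokens):
            raise SyntaxFormatError("unbalanced parentheses: missing ')'")
        pos += 1  # consume ')'
        if node.word is None and not node.children:
            raise SyntaxFormatError(f"empty node {label!r}")
        return node

    root = parse_node()
    if pos != len(tokens):
        raise SyntaxFormatError(f"trailing material after tree at item {pos}")
    return ConstituencyTree(root)


def read_bracketed_trees(stream: IO[str] | Iterable[str]) -> list[ConstituencyTree]:
    """Read one bracketed tree per non-blank line."""
    trees = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            trees.append(parse_bracketed(line))
        except SyntaxFormatError as exc:
            raise SyntaxFormatError(f"line {lineno}: {exc}") from exc
    return trees
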