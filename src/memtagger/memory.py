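"""Key-value memory attention.

Each token carries m_i memory slots — key ids pointing into a key
embedding table e^k and value ids into a value table e^v, both of the
encoder's hidden dimension d and randomly initialized.  The module scores
each key against the token's hidden vector h_i by dot product, softmaxes
the scores into weights

    p_{i,j} = exp(h_i . e^k_{i,j}) / sum_j' exp(h_i . e^k_{i,j'}),

pools the value embeddings o_i = sum_j p_{i,j} e^v_{i,j}, and concatenates
the result with the hidden vector: o'_i = h_i (+) o_i.  The softmax is
computed with max-subtraction, which is mathematically identical to the
plain form.  A token with no slots contributes a zero vector.

Also here: the direct-concatenation (DC) baseline, which appends the
*unweighted* means of the slot key and value embeddings (no attention),
and the multi-type ensemble (sum or concat of the per-type pooled
vectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MemoryEmbeddings",
    "AttentionResult",
    "attend",
    "augment",
    "ensemble",
    "dc_combine",
]

#: Half-width of the uniform interval used for embedding initialization.
INIT_SCALE = 0.1


@dataclass
class MemoryEmbeddings:
    """Trainable key and value embedding tables of equal dimension d."""

    keys: np.ndarray    # (n_keys, d)
    values: np.ndarray  # (n_values, d)

    def __post_init__(self) -> None:
        if self.keys.ndim != 2 or self.values.ndim != 2:
            raise ValueError("embedding tables must be 2-D")
        if self.keys.shape[1] != self.values.shape[1]:
            raise ValueError("key/value embedding dimensions differ")

    @property
    def dim(self) -> int:
        return self.keys.shape[1]

    @classmethod
    def init(cls, n_keys: int, n_values: int, dim: int,
             rng: np.random.Generator) -> "MemoryEmbeddings":
        """Seeded uniform initialization in [-0.1, 0.1]."""
        return cls(
            keys=rng.uniform(-INIT_SCALE, INIT_SCALE, (n_keys, dim)),
            values=rng.uniform(-INIT_SCALE, INIT_SCALE, (n_values, dim)),
        )


@dataclass
class AttentionResult:
    """Attention weights p (length m_i) and pooled value vector o (dim d)."""

    p: np.ndarray
    o: np.ndarray


def attend(h: np.ndarray, key_ids: Sequence[int], value_ids: Sequence[int],
           mem: MemoryEmbeddings) -> AttentionResult:
    """Score keys against h, softmax into weights, pool the values.

    With no slots (m_i = 0) the weights are empty and o is the zero
    vector, so an empty memory contributes nothing after concatenation.
    """
    if len(key_ids) != len(value_ids):
        raise ValueError("key/value slot count mismatch")
    d = mem.dim
    if h.shape != (d,):
        raise ValueError(f"hidden vector shape {h.shape} does not match dim {d}")
    if len(key_ids) == 0:
        return AttentionResult(p=np.empty(0), o=np.zeros(d))
    ek = mem.keys[np.asarray(key_ids, dtype=np.intp)]      # (m, d)
    ev = mem.values[np.asarray(value_ids, dtype=np.intp)]  # (m, d)
    logits = ek @ h
    logits = logits - logits.max()  # stabilized; softmax is shift-invariant
    w = np.exp(logits)
    p = w / w.sum()
    return AttentionResult(p=p, o=p @ ev)


def augment(h: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Concatenate the hidden vector with the pooled memory: o' = h (+) o."""
    if h.shape != o.shape:
        raise ValueError(f"dimension mismatch: h {h.shape}, o {o.shape}")
    return np.concatenate([h, o])


def ensemble(h: np.ndarray, pooled: Sequence[np.ndarray], strategy: str = "concat"
             ) -> np.ndarray:
    """Combine pooled vectors from several syntactic types with h.

    ``sum`` adds the per-type pooled vectors before concatenation (output
    dim 2d); ``concat`` appends each in turn (dim d(1+n)).
    """
    if not pooled:
        raise ValueError("ensemble needs at least one pooled vector")
    for o in pooled:
        if o.shape != h.shape:
            raise ValueError("pooled vector dimension mismatch")
    if strategy == "sum":
        return np.concatenate([h, np.sum(pooled, axis=0)])
    if strategy == "concat":
        return np.concatenate([h, *pooled])
    raise ValueError(f"unknown ensemble strategy {strategy!r}")


def dc_combine(h: np.ndarray, key_ids: Sequence[int], value_ids: Sequence[int],
               mem: MemoryEmbeddings) -> np.ndarray:
    """Direct-concatenation baseline: no attention weighting.

    The unweighted mean of the slot key embeddings and the unweighted mean
    of the slot value embeddings are each appended to h (output dim 3d);
    with no slots both blocks are zero.
    """
    if len(key_ids) != len(value_ids):
        raise ValueError("key/value slot count mismatch")
    d = mem.dim
    if h.shape != (d,):
        raise ValueError(f"hidden vector shape {h.shape} does not match dim {d}")
    if len(key_ids) == 0:
        return np.concatenate([h, np.zeros(d), np.zeros(d)])
    ek = mem.keys[np.asarray(key_ids, dtype=np.intp)]
    ev = mem.values[np.asarray(value_ids, dtype=np.intp)]
    return np.concatenate([h, ek.mean(axis=0), ev.mean(axis=0)])
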