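"""Post-decoding operations: interleaving, compression, priors, readout.

After the decoder recovers a K*M-bit message, the model (i) interleaves the
bits into importance-ranked feature groups, (ii) compresses repeated viewings
into a short memory representation keyed on the most important feature,
(iii) estimates transition priors from the stored bit stream for feedback to
the decoder, and (iv) declares an object category by a linear readout.
"""

from __future__ import annotations

import json
from collections import Counter, OrderedDict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decoder import DEFAULT_PRIOR_FLOOR, PriorModel
from .encoder import BitSequence, GeneratorSpec, as_bits, build_trellis

__all__ = [
    "InterleaverSpec",
    "CompressedMemory",
    "interleave",
    "deinterleave",
    "compress",
    "estimate_priors",
    "stream_states",
    "categorize",
]


@dataclass(frozen=True)
class InterleaverSpec:
    """Ordered partition of the K*M bit indices into F feature groups.

    ``groups[g]`` lists the 1-based message-bit indices belonging to feature
    ``g``; position in ``groups`` is the importance rank (rank 1 first).  The
    groups must form an exact partition of {1..KM}.
    """

    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        groups = tuple(tuple(int(i) for i in g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        flat = [i for g in groups for i in g]
        km = len(flat)
        if sorted(flat) != list(range(1, km + 1)):
            raise ValueError(
                "interleaver groups must form an exact partition of 1..KM"
            )

    @property
    def n_features(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    @property
    def total_bits(self) -> int:
        return sum(self.sizes)

    def to_json(self) -> str:
        """Nested 1-based index lists, e.g. ``[[1, 3], [2, 4]]``."""
        return json.dumps([list(g) for g in self.groups])

    @classmethod
    def from_json(cls, text: str) -> "InterleaverSpec":
        return cls(tuple(tuple(g) for g in json.loads(text)))

    @classmethod
    def identity(cls, km: int) -> "InterleaverSpec":
        return cls((tuple(range(1, km + 1)),))


def interleave(
    message: Sequence[int] | BitSequence, spec: InterleaverSpec
) -> list[BitSequence]:
    """Split a message into importance-ranked feature groups.

    Group ``g`` holds the message bits at the spec's 1-based indices, in
    index order; the concatenation of all groups is a permutation of the
    message.
    """
    bits = as_bits(message)
    if bits.size != spec.total_bits:
        raise ValueError(
            f"message length {bits.size} != interleaver size {spec.total_bits}"
        )
    return [bits[np.asarray(g) - 1] for g in spec.groups]


def deinterleave(
    groups: Sequence[Sequence[int]], spec: InterleaverSpec
) -> BitSequence:
    """Invert :func:`interleave`, restoring original bit positions."""
    out = np.zeros(spec.total_bits, dtype=np.uint8)
    if len(groups) != spec.n_features:
        raise ValueError("group count does not match interleaver spec")
    for g, idx in zip(groups, spec.groups):
        g = as_bits(g)
        if g.size != len(idx):
            raise ValueError("group size does not match interleaver spec")
        out[np.asarray(idx) - 1] = g
    return out


@dataclass(frozen=True)
class CompressedMemory:
    """Memory representation of repeated viewings after compression.

    One representative K*M-bit block is stored per distinct value of the
    most-important feature, in first-appearance order of those values.
    """

    blocks: tuple[tuple[int, ...], ...]

    @property
    def total_bits(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def stream(self) -> BitSequence:
        """All stored blocks concatenated into one bit stream."""
        return as_bits([b for blk in self.blocks for b in blk])


def compress(
    blocks: Sequence[Sequence[int]], spec: InterleaverSpec
) -> CompressedMemory:
    """Compress a stream of decoded blocks into memory representatives.

    Blocks are grouped by the value of their rank-1 (most important)
    feature; each group is replaced by its most frequent full block (earliest
    occurrence wins frequency ties) and representatives are concatenated in
    first-appearance order of the important-feature values.  Less important
    features are thereby summarised implicitly by the majority rule.
    """
    block_arrays = [as_bits(b) for b in blocks]
    if not block_arrays:
        return CompressedMemory(blocks=())
    km = spec.total_bits
    if any(b.size != km for b in block_arrays):
        raise ValueError("all blocks must have the interleaver's KM bits")

    key_idx = np.asarray(spec.groups[0]) - 1
    groups: "OrderedDict[tuple[int, ...], list[tuple[int, ...]]]" = OrderedDict()
    for b in block_arrays:
        key = tuple(int(x) for x in b[key_idx])
        groups.setdefault(key, []).append(tuple(int(x) for x in b))

    reps = []
    for members in groups.values():
        counts = Counter(members)
        best = max(counts, key=lambda blk: (counts[blk], -members.index(blk)))
        reps.append(best)
    return CompressedMemory(blocks=tuple(reps))


def stream_states(stream: BitSequence, L: int) -> np.ndarray:
    """Register-order state labels of the overlapping L-bit stream windows.

    The stream is read left to right (older bit first); a window
    ``(older, ..., newer)`` corresponds to register contents written
    most-recent-bit-first, so the label reverses the window's bit order.
    This is the same convention as the encoder's state labels.
    """
    bits = as_bits(stream)
    if bits.size < L:
        raise ValueError(f"stream of {bits.size} bits has no L={L} window")
    if L == 0:
        return np.zeros(bits.size + 1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(bits, L)
    weights = 1 << np.arange(L)  # newest (last) window bit -> high label bit
    return (windows.astype(np.int64) * weights[None, :]).sum(axis=1)


def estimate_priors(
    stream: Sequence[int] | BitSequence,
    L: int,
    floor: float = DEFAULT_PRIOR_FLOOR,
    spec: GeneratorSpec | None = None,
) -> PriorModel:
    """Estimate transition priors P[b_{k+1} | b_k] from a stored bit stream.

    States are the overlapping L-bit windows of the stream (stride 1).  The
    prior of an ordered state pair is its count divided by the count of the
    current state among non-terminal window positions; rows are floored at
    ``floor`` over the valid trellis transitions and renormalised, and states
    never observed fall back to a uniform row.
    """
    bits = as_bits(stream)
    if bits.size < L + 1:
        raise ValueError(
            f"stream of {bits.size} bits too short to estimate L={L} priors"
        )
    labels = stream_states(bits, L)
    n = 1 << L
    counts = np.zeros((n, n))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    # any feedforward generator with memory L induces the same state graph
    trellis = build_trellis(spec if spec is not None else GeneratorSpec(((1,) * (L + 1),)))
    return PriorModel.from_counts(counts, trellis, floor=floor)


def categorize(
    message: Sequence[int] | BitSequence, weights: Sequence[float] | np.ndarray
) -> float:
    """Linear category readout f(b) = w^T b.

    With all-ones weights the score is the Hamming weight of the message;
    the score is invariant to any coordinated permutation of message and
    weights.
    """
    bits = as_bits(message).astype(float)
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != bits.size:
        raise ValueError(f"weights length {w.size} != message length {bits.size}")
    return float(w @ bits)
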