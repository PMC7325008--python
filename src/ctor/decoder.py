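"""Viterbi MAP/MLE untangling of the object representation.

The decoder receives the channel-perturbed codeword and recovers the most
probable message by minimum-length path search through the encoder trellis.
Each trellis transition is scored by the branch metric

    lambda = -ln P[next state | state] - sum_j ln P[r_j | output bit j],

the negative log prior plus the negative log likelihood of the received
N-symbol block.  With uniform priors the prior term is a constant and MAP
decoding reduces to maximum-likelihood (MLE) decoding; non-uniform priors
(estimated from memory, see :mod:`ctor.downstream`) bias the search toward
previously decoded transitions.  An exhaustive search over all 2^K messages
is provided as an independent oracle for small K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelModel, SymbolSequence
from .encoder import BitSequence, GeneratorSpec, Trellis, build_trellis, encode

__all__ = [
    "PriorModel",
    "DecodedResult",
    "branch_metric",
    "viterbi_decode",
    "viterbi_decode_batch",
    "exhaustive_map_decode",
]

#: Default floor applied to valid-transition priors so that a transition never
#: becomes hard-forbidden by one bad estimate.
DEFAULT_PRIOR_FLOOR = 1e-6


def _neg_log(p: np.ndarray) -> np.ndarray:
    """Elementwise -ln p with -ln 0 = +inf (saturating, no warnings)."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, -np.inf)
    np.log(arr, out=out, where=arr > 0)
    return -out if out.ndim else float(-out)


@dataclass(frozen=True)
class PriorModel:
    """Transition priors P[b_{k+1} | b_k] over the trellis states.

    ``matrix[s, s']`` holds the prior of moving to state ``s'`` from ``s``;
    entries on invalid transitions are zero and each row sums to 1 over the
    two valid successors.  Rows are floored at ``floor`` and renormalised so
    an unobserved but valid transition keeps a small positive prior.
    """

    matrix: np.ndarray
    floor: float = DEFAULT_PRIOR_FLOOR

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("prior matrix must be square (n_states x n_states)")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def uniform(cls, n_states: int, trellis: Trellis | None = None) -> "PriorModel":
        """Uniform prior: 1/2 on each of the two valid successors."""
        m = np.zeros((n_states, n_states))
        if trellis is None:
            L = int(np.log2(n_states))
            for s in range(n_states):
                for u in (0, 1):
                    nxt = (u << (L - 1)) | (s >> 1) if L > 0 else 0
                    m[s, nxt] += 0.5
        else:
            for s in range(n_states):
                for u in (0, 1):
                    m[s, trellis.next_state[s, u]] += 0.5
        return cls(matrix=m)

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        trellis: Trellis,
        floor: float = DEFAULT_PRIOR_FLOOR,
    ) -> "PriorModel":
        """Normalise raw transition counts into floored per-state priors.

        Each row is normalised over the state's two valid successors; rows
        with no observations fall back to uniform.  Valid-successor entries
        are floored at ``floor`` and renormalised.
        """
        counts = np.asarray(counts, dtype=float)
        n = trellis.n_states
        m = np.zeros((n, n))
        for s in range(n):
            succ = np.unique(trellis.next_state[s])
            row = counts[s, succ]
            total = row.sum()
            probs = row / total if total > 0 else np.full(len(succ), 1.0 / len(succ))
            probs = np.maximum(probs, floor)
            m[s, succ] = probs / probs.sum()
        return cls(matrix=m, floor=floor)

    def transition_neg_log(self, trellis: Trellis) -> np.ndarray:
        """-ln prior arranged per (state, input bit) for metric computation."""
        nll = np.empty((trellis.n_states, 2))
        for u in (0, 1):
            nll[:, u] = _neg_log(
                self.matrix[np.arange(trellis.n_states), trellis.next_state[:, u]]
            )
        return nll


@dataclass
class DecodedResult:
    """Outcome of one Viterbi decode.

    ``message`` is the K-bit estimate b-hat, ``codeword_estimate`` its
    re-encoding s-hat, ``final_metric`` the accumulated path length Gamma of
    the winning path, and ``survivor_states[k, s]`` the winning predecessor
    of state s at stage k (for trellis-diagram rendering).
    """

    message: BitSequence
    codeword_estimate: BitSequence
    final_metric: float
    survivor_states: np.ndarray = field(repr=False)
    state_sequence: np.ndarray = field(repr=False)


def _block_metrics(
    received: np.ndarray, trellis: Trellis, channel: ChannelModel
) -> np.ndarray:
    """Likelihood part of the branch metric for every stage and transition.

    Returns an array of shape (T, K, n_states, 2): the total -ln likelihood
    of each stage's received N-symbol block given each transition's output
    block.  ``received`` has shape (T, K*N) in alphabet indices.
    """
    T = received.shape[0]
    K = received.shape[1] // trellis.N
    nll = _neg_log(channel.pmf)  # (2, n_symbols)
    blocks = received.reshape(T, K, trellis.N)
    # nll_sym[t, k, j, s, u] = -ln P[r | output bit of (s, u) at position j]
    out = trellis.output_bits  # (S, 2, N)
    per_symbol = nll[out[None, None, :, :, :], blocks[:, :, None, None, :]]
    # axes: (T, K, S, 2, N) after broadcasting; sum the N symbol positions
    return per_symbol.sum(axis=-1)


def branch_metric(
    received_block: SymbolSequence,
    transition: tuple[int, int],
    trellis: Trellis,
    channel: ChannelModel,
    priors: PriorModel | None = None,
) -> float:
    """Length of one trellis transition given a received N-symbol block.

    With ``priors=None`` (MLE mode) the constant uniform-prior term is
    omitted and the metric is the pure negative log likelihood.  A zero
    channel probability yields +inf (the transition cannot survive unless
    every alternative is also impossible).
    """
    state, nxt = transition
    block = np.asarray(received_block, dtype=np.int64)
    if block.size != trellis.N:
        raise ValueError(f"received block must have {trellis.N} symbols")
    out = trellis.transition_output(state, nxt)
    nll = _neg_log(channel.pmf)
    metric = float(nll[out, block].sum())
    if priors is not None:
        metric += float(_neg_log(priors.matrix[state, nxt]))
    return metric


def viterbi_decode_batch(
    received: np.ndarray,
    trellis: Trellis,
    channel: ChannelModel,
    priors: PriorModel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Viterbi-decode T received sequences at once.

    Parameters
    ----------
    received
        (T, K*N) array of alphabet indices.

    Returns
    -------
    messages : (T, K) uint8 array of decoded bits.
    final_metrics : (T,) array of winning path lengths Gamma.
    survivors : (T, K, n_states) int8 array; entry k, s is the index (0/1)
        into the state's ordered predecessor list chosen at stage k.

    The decoder starts from b_0 = S0 (Gamma(S0) = 0, all other states
    excluded) and runs exactly K stages with no trellis termination;
    traceback begins at the terminal state of smallest Gamma.  Ties — among
    predecessors and among terminal states — are broken toward the smaller
    state label.
    """
    received = np.asarray(received, dtype=np.int64)
    if received.ndim != 2:
        raise ValueError("received must be a (T, K*N) array")
    if received.shape[1] % trellis.N != 0:
        raise ValueError(
            f"received length {received.shape[1]} not divisible by N={trellis.N}"
        )
    T = received.shape[0]
    K = received.shape[1] // trellis.N
    S = trellis.n_states

    bm = _block_metrics(received, trellis, channel)  # (T, K, S, 2)
    if priors is not None:
        bm = bm + priors.transition_neg_log(trellis)[None, None, :, :]

    preds = trellis.predecessors  # (S, 2) ascending labels
    pred_inputs = trellis.predecessor_inputs  # (S, 2)

    pm = np.full((T, S), np.inf)
    pm[:, 0] = 0.0
    survivors = np.zeros((T, K, S), dtype=np.int8)
    for k in range(K):
        # candidate[t, s', c] = Gamma(pred_c) + lambda(pred_c -> s')
        cand = pm[:, preds] + bm[:, k, preds, pred_inputs]
        choice = np.argmin(cand, axis=2)  # ties -> first = smaller pred label
        survivors[:, k, :] = choice
        pm = np.take_along_axis(cand, choice[:, :, None], axis=2)[:, :, 0]

    end_state = np.argmin(pm, axis=1)  # ties -> smaller label
    final_metrics = pm[np.arange(T), end_state]

    states = np.empty((T, K + 1), dtype=np.int64)
    messages = np.empty((T, K), dtype=np.uint8)
    states[:, K] = end_state
    cur = end_state
    for k in range(K - 1, -1, -1):
        c = survivors[np.arange(T), k, cur]
        messages[:, k] = pred_inputs[cur, c]
        cur = preds[cur, c]
        states[:, k] = cur
    return messages, final_metrics, survivors


def viterbi_decode(
    received: SymbolSequence,
    trellis: Trellis,
    channel: ChannelModel,
    priors: PriorModel | None = None,
) -> DecodedResult:
    """Decode one received sequence; see :func:`viterbi_decode_batch`."""
    r = np.asarray(received, dtype=np.int64).ravel()
    messages, metrics, survivors = viterbi_decode_batch(
        r[None, :], trellis, channel, priors
    )
    message = messages[0]
    # reconstruct the winning state sequence for reporting
    K = message.size
    states = np.zeros(K + 1, dtype=np.int64)
    for k, u in enumerate(message):
        states[k + 1] = trellis.next_state[states[k], u]
    return DecodedResult(
        message=message,
        codeword_estimate=encode(message, trellis.spec),
        final_metric=float(metrics[0]),
        survivor_states=survivors[0],
        state_sequence=states,
    )


def exhaustive_map_decode(
    received: SymbolSequence,
    spec: GeneratorSpec,
    channel: ChannelModel,
    priors: PriorModel | None = None,
    max_bits: int = 16,
) -> BitSequence:
    """Brute-force MAP decoding by scoring every candidate message.

    Enumerates all 2^K messages, encodes each, accumulates the full path
    length (priors included when given) and returns the argmin; ties are
    broken toward the smallest message read as an MSB-first integer.  Guarded
    to K <= ``max_bits`` for tractability.
    """
    r = np.asarray(received, dtype=np.int64).ravel()
    trellis = build_trellis(spec)
    if r.size % trellis.N != 0:
        raise ValueError(f"received length {r.size} not divisible by N={trellis.N}")
    K = r.size // trellis.N
    if K > max_bits:
        raise ValueError(f"exhaustive search refused for K={K} > {max_bits}")

    n_msgs = 1 << K
    msg_ints = np.arange(n_msgs)
    # MSB-first bits so enumeration order equals integer order for tie-breaks
    bits = (msg_ints[:, None] >> np.arange(K - 1, -1, -1)[None, :]) & 1

    nll = _neg_log(channel.pmf)
    prior_nll = priors.transition_neg_log(trellis) if priors is not None else None
    blocks = r.reshape(K, trellis.N)
    scores = np.zeros(n_msgs)
    states = np.zeros(n_msgs, dtype=np.int64)
    for k in range(K):
        u = bits[:, k]
        out = trellis.output_bits[states, u]  # (n_msgs, N)
        scores += nll[out, blocks[k][None, :]].sum(axis=1)
        if prior_nll is not None:
            scores += prior_nll[states, u]
        states = trellis.next_state[states, u]
    best = int(np.argmin(scores))  # first occurrence = smallest message int
    return bits[best].astype(np.uint8)
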