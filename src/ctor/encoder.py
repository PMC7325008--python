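"""Front-end rate coding and convolutional tangling of object representations.

The early visual stages (retina, LGN, V1) are modelled as a rate-coding front
end followed by a rate-1/N feedforward convolutional encoder.  Attention
multiplies resting firing rates (gain modulation), an integrate-and-threshold
rule turns each unit's rate trace into a binary symbol, and a shift-register
state machine "tangles" the resulting K-bit object representation ``b`` into a
K*N-bit codeword ``s`` that downstream circuitry must untangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BitSequence",
    "GeneratorSpec",
    "Trellis",
    "RateCodeConfig",
    "SIMPLE_GENERATOR",
    "COMPLEX_GENERATOR",
    "get_generator",
    "bits_from_str",
    "bits_to_str",
    "attention_modulate",
    "rate_code",
    "build_trellis",
    "encode",
    "state_path",
]

#: A binary message/codeword is held as a 1-D uint8 numpy array over {0, 1}.
BitSequence = np.ndarray


def as_bits(bits: Sequence[int] | np.ndarray) -> BitSequence:
    """Coerce a bit container to a validated uint8 array over {0, 1}."""
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    if arr.size and arr.max(initial=0) > 1:
        raise ValueError("bit sequences may contain only 0 and 1")
    return arr


def bits_from_str(text: str) -> BitSequence:
    """Parse a bit string such as ``"111 010 110 011"`` (whitespace ignored)."""
    return as_bits([int(c) for c in text if c in "01"])


def bits_to_str(bits: BitSequence, group: int = 0) -> str:
    """Render bits as a string, optionally space-grouped every ``group`` bits."""
    s = "".join(str(int(b)) for b in bits)
    if group > 0:
        s = " ".join(s[i : i + group] for i in range(0, len(s), group))
    return s


@dataclass(frozen=True)
class GeneratorSpec:
    """A rate-1/N feedforward convolutional encoder G(D).

    Parameters
    ----------
    taps
        N coefficient vectors over GF(2), each of length L+1; position ``j``
        holds the coefficient of D^j (D^0 first, i.e. the current input).

    The constraint length L is the maximal shift-register memory order; the
    encoder accepts M = 1 input bit per step and emits N output bits.
    """

    taps: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        taps = tuple(tuple(int(t) for t in g) for g in self.taps)
        object.__setattr__(self, "taps", taps)
        if len(taps) < 1:
            raise ValueError("need at least one tap vector (N >= 1)")
        width = len(taps[0])
        if width < 1 or any(len(g) != width for g in taps):
            raise ValueError("all tap vectors must have equal length L+1 >= 1")
        if any(t not in (0, 1) for g in taps for t in g):
            raise ValueError("tap coefficients must be 0 or 1")

    @property
    def N(self) -> int:
        """Output bits per input bit."""
        return len(self.taps)

    @property
    def L(self) -> int:
        """Maximal memory order of the shift register."""
        return len(self.taps[0]) - 1

    @property
    def M(self) -> int:
        """Input bits per step (fixed at 1)."""
        return 1

    @property
    def n_states(self) -> int:
        return 1 << self.L

    def to_text(self) -> str:
        """Serialise as one tap vector per line, D^0 coefficient first."""
        return "\n".join(" ".join(str(t) for t in g) for g in self.taps)

    @classmethod
    def from_text(cls, text: str) -> "GeneratorSpec":
        rows = [ln.split() for ln in text.strip().splitlines() if ln.strip()]
        return cls(tuple(tuple(int(t) for t in row) for row in rows))


#: G(D) = [1+D, 1+D^2, 1+D+D^2]; L = 2, four states.
SIMPLE_GENERATOR = GeneratorSpec(((1, 1, 0), (1, 0, 1), (1, 1, 1)))

#: G(D) = [1+D^2+D^3+D^5+D^6+D^7+D^8, 1+D+D^3+D^4+D^7+D^8, 1+D+D^2+D^5+D^8];
#: L = 8, 256 states.
COMPLEX_GENERATOR = GeneratorSpec(
    (
        (1, 0, 1, 1, 0, 1, 1, 1, 1),
        (1, 1, 0, 1, 1, 0, 0, 1, 1),
        (1, 1, 1, 0, 0, 1, 0, 0, 1),
    )
)

_GENERATORS = {"simple": SIMPLE_GENERATOR, "complex": COMPLEX_GENERATOR}


def get_generator(name: str) -> GeneratorSpec:
    """Look up a named built-in encoder (``"simple"`` or ``"complex"``)."""
    try:
        return _GENERATORS[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; choose from {sorted(_GENERATORS)}")


@dataclass(frozen=True)
class RateCodeConfig:
    """Integrate-and-threshold rate-coding rule for one population.

    ``thresholds[i]`` is the spike-count threshold alpha_i > 0 of unit i and
    ``epoch_duration`` the integration window T in seconds (a per-symbol
    window, e.g. 50 ms; unrelated to the Monte-Carlo trial count).
    """

    thresholds: tuple[float, ...]
    epoch_duration: float

    def __post_init__(self) -> None:
        thr = tuple(float(a) for a in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if any(a <= 0 for a in thr):
            raise ValueError("all thresholds alpha_i must be > 0")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be > 0")


def attention_modulate(rest_rates: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Apply multiplicative attentional gain to resting firing rates.

    ``out[i](t) = gains[i](t) * rest_rates[i](t)`` elementwise; gains must be
    strictly positive and shaped like the rate traces.
    """
    rest = np.asarray(rest_rates, dtype=float)
    g = np.asarray(gains, dtype=float)
    if rest.shape != g.shape:
        raise ValueError(f"shape mismatch: rates {rest.shape} vs gains {g.shape}")
    if g.size and g.min() <= 0:
        raise ValueError("attentional gains must be strictly positive")
    return g * rest


def rate_code(
    rate_trace: np.ndarray, config: RateCodeConfig, unit_index: int = 0
) -> int:
    """Binary rate-coding of one unit: 1 iff the integrated rate exceeds alpha.

    The trace is taken as uniformly sampled over ``config.epoch_duration``
    seconds and integrated with the trapezoidal rule.
    """
    trace = np.asarray(rate_trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("empty rate trace")
    alpha = config.thresholds[unit_index]
    if trace.size == 1:
        integral = float(trace[0]) * config.epoch_duration
    else:
        dt = config.epoch_duration / (trace.size - 1)
        integral = float(np.trapezoid(trace, dx=dt))
    return int(integral > alpha)


@dataclass(frozen=True)
class Trellis:
    """State machine of a convolutional encoder.

    States are labelled by the integer value of the register contents written
    most-recent-bit-first (S0 = 00, S1 = 01, S2 = 10, S3 = 11 for L = 2), so
    the most recent input occupies the high bit of the label.

    ``next_state[s, u]`` is the successor of state ``s`` on input bit ``u``
    and ``output_bits[s, u]`` the N-bit block emitted on that transition.
    ``predecessors[s']`` lists the two predecessor states of ``s'`` in
    ascending label order, with ``predecessor_inputs`` the matching input
    bits — the fixed ordering gives deterministic tie-breaking downstream.
    """

    spec: GeneratorSpec
    next_state: np.ndarray = field(repr=False)
    output_bits: np.ndarray = field(repr=False)
    predecessors: np.ndarray = field(repr=False)
    predecessor_inputs: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return self.spec.n_states

    @property
    def L(self) -> int:
        return self.spec.L

    @property
    def N(self) -> int:
        return self.spec.N

    def transition_output(self, state: int, next_state: int) -> np.ndarray:
        """Output block of the transition ``state -> next_state``."""
        for u in (0, 1):
            if self.next_state[state, u] == next_state:
                return self.output_bits[state, u]
        raise ValueError(f"no trellis transition S{state} -> S{next_state}")

    def successors(self, state: int) -> tuple[int, int]:
        """Successor labels of ``state`` on input 0 and 1, in that order."""
        return int(self.next_state[state, 0]), int(self.next_state[state, 1])


def build_trellis(spec: GeneratorSpec) -> Trellis:
    """Expand a generator into its 2^L-state trellis.

    Each transition's output block applies every tap vector g to the current
    input (D^0) and the L register bits (D^1..D^L) with mod-2 accumulation;
    the register then shifts the new input in at the most-recent position.
    """
    L, N, n_states = spec.L, spec.N, spec.n_states
    states = np.arange(n_states)
    # reg_bits[s, j-1] = input delayed by j steps when the register reads s
    if L > 0:
        shifts = L - 1 - np.arange(L)
        reg_bits = (states[:, None] >> shifts[None, :]) & 1
    else:
        reg_bits = np.zeros((n_states, 0), dtype=int)

    next_state = np.zeros((n_states, 2), dtype=np.int64)
    output_bits = np.zeros((n_states, 2, N), dtype=np.uint8)
    for u in (0, 1):
        if L > 0:
            next_state[:, u] = (u << (L - 1)) | (states >> 1)
        for i, g in enumerate(spec.taps):
            acc = g[0] * u + reg_bits @ np.asarray(g[1:], dtype=int)
            output_bits[:, u, i] = acc % 2

    predecessors = np.zeros((n_states, 2), dtype=np.int64)
    predecessor_inputs = np.zeros((n_states, 2), dtype=np.int64)
    incoming: list[list[tuple[int, int]]] = [[] for _ in range(n_states)]
    for s in range(n_states):
        for u in (0, 1):
            incoming[next_state[s, u]].append((s, u))
    for s2, pairs in enumerate(incoming):
        if len(pairs) != 2:
            raise AssertionError("each state must have exactly two predecessors")
        pairs.sort()  # ascending predecessor label
        predecessors[s2] = [p for p, _ in pairs]
        predecessor_inputs[s2] = [u for _, u in pairs]

    return Trellis(
        spec=spec,
        next_state=next_state,
        output_bits=output_bits,
        predecessors=predecessors,
        predecessor_inputs=predecessor_inputs,
    )


def encode(message: Sequence[int] | BitSequence, spec: GeneratorSpec) -> BitSequence:
    """Convolutionally encode a message from the all-zero state S0.

    Returns the K*N-bit codeword; no tail bits are appended (exactly K trellis
    stages, the register is not driven back to S0).
    """
    bits = as_bits(message)
    trellis = build_trellis(spec)
    out = np.empty((bits.size, spec.N), dtype=np.uint8)
    state = 0
    for k, u in enumerate(bits):
        out[k] = trellis.output_bits[state, u]
        state = int(trellis.next_state[state, u])
    return out.ravel()


def state_path(message: Sequence[int] | BitSequence, spec: GeneratorSpec) -> np.ndarray:
    """State labels S_0..S_K visited while encoding ``message`` from S0."""
    bits = as_bits(message)
    trellis = build_trellis(spec)
    path = np.zeros(bits.size + 1, dtype=np.int64)
    for k, u in enumerate(bits):
        path[k + 1] = trellis.next_state[path[k], u]
    return path
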