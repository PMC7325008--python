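"""Stochastic channels separating the encoding and decoding stages.

The codeword leaving the early visual stages is perturbed before it reaches
the decoder.  Two channel families are provided: a binary-input discrete
memoryless channel (DMC) with a finite output alphabet, and an additive-noise
continuous channel ``r = s + n``.  Channel quality metrics are the conditional
output entropy (discrete) and the SNR (continuous).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoder import BitSequence, as_bits

__all__ = [
    "ChannelModel",
    "AdditiveNoiseModel",
    "SymbolSequence",
    "validate_channel",
    "get_channel",
    "DISPERSIVE",
    "UNIFORM",
    "LESS_DISPERSIVE",
    "transmit",
    "conditional_entropy",
    "additive_transmit",
    "snr",
    "symbols_from_str",
    "symbols_to_str",
]

#: Channel outputs are held as 1-D int64 arrays of alphabet indices.
SymbolSequence = np.ndarray

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class ChannelModel:
    """Binary-input discrete memoryless channel.

    ``pmf[n, m]`` is P[r = alphabet[m] | s = n] for input bit n; each row is a
    probability vector.  The channel acts independently on every codeword
    symbol (memoryless, time-invariant within a run).
    """

    alphabet: tuple[str, ...]
    pmf: np.ndarray

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if pmf.shape != (2, len(self.alphabet)):
            raise ValueError("pmf must be 2 x |alphabet|")

    @property
    def n_symbols(self) -> int:
        return len(self.alphabet)

    def symbol_index(self, symbol: str) -> int:
        return self.alphabet.index(symbol)

    def to_csv(self) -> str:
        """Rows = input bit 0/1, columns = output symbols."""
        buf = io.StringIO()
        buf.write("input," + ",".join(self.alphabet) + "\n")
        for n in (0, 1):
            buf.write(f"{n}," + ",".join(repr(float(p)) for p in self.pmf[n]) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "ChannelModel":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        alphabet = tuple(lines[0].split(",")[1:])
        rows = [[float(x) for x in ln.split(",")[1:]] for ln in lines[1:3]]
        return validate_channel(rows, alphabet)


def validate_channel(
    pmf: Sequence[Sequence[float]] | np.ndarray,
    alphabet: Sequence[str] | None = None,
) -> ChannelModel:
    """Validate a raw conditional pmf table and build a :class:`ChannelModel`.

    Requires two rows (input bit 0 and 1) of at least two non-negative
    entries, each summing to 1 within 1e-12.
    """
    table = np.asarray(pmf, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("channel pmf must have 2 rows and at least 2 columns")
    if np.any(table < 0):
        raise ValueError("invalid pmf: negative probability entry")
    sums = table.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _ROW_TOL):
        raise ValueError(f"invalid pmf: row sums {sums} differ from 1")
    if alphabet is None:
        alphabet = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[: table.shape[1]])
    return ChannelModel(alphabet=tuple(alphabet), pmf=table)


#: Dispersive 4-ary DMC (conditional entropy 1.846 bits).
DISPERSIVE = validate_channel([[0.4, 0.3, 0.2, 0.1], [0.1, 0.2, 0.3, 0.4]])

#: Maximally dispersive channel: uniform rows (conditional entropy 2 bits).
UNIFORM = validate_channel([[0.25, 0.25, 0.25, 0.25], [0.25, 0.25, 0.25, 0.25]])

#: Less dispersive 4-ary DMC (conditional entropy 1.416 bits).
LESS_DISPERSIVE = validate_channel(
    [[0.65, 0.2, 0.1, 0.05], [0.05, 0.1, 0.2, 0.65]]
)

_CHANNELS = {
    "dispersive": DISPERSIVE,
    "uniform": UNIFORM,
    "less_dispersive": LESS_DISPERSIVE,
}


def get_channel(name: str) -> ChannelModel:
    """Look up a named built-in channel."""
    try:
        return _CHANNELS[name]
    except KeyError:
        raise KeyError(f"unknown channel {name!r}; choose from {sorted(_CHANNELS)}")


def transmit(
    codeword: Sequence[int] | BitSequence,
    channel: ChannelModel,
    rng: np.random.Generator | int,
) -> SymbolSequence:
    """Pass a codeword through the DMC, drawing each output independently.

    Sampling inverts the row CDF on a uniform draw per symbol, so matched
    random streams yield coupled outputs across channels of the same
    alphabet (useful for paired channel comparisons).
    """
    bits = as_bits(codeword)
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return transmit_batch(bits[None, :], channel, gen)[0]


def transmit_batch(
    codewords: np.ndarray, channel: ChannelModel, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`transmit` for a (T, KN) array of codewords."""
    cdf = np.cumsum(channel.pmf, axis=1)
    u = rng.random(codewords.shape)
    out = np.empty(codewords.shape, dtype=np.int64)
    for n in (0, 1):
        mask = codewords == n
        out[mask] = np.searchsorted(cdf[n], u[mask], side="right")
    return np.minimum(out, channel.n_symbols - 1)


def conditional_entropy(channel: ChannelModel, input_bit: int) -> float:
    """Conditional output entropy H(r | s = input_bit) in bits.

    This is the equivocation of the channel row: -sum_m p log2 p with the
    convention 0 * log 0 = 0.  It is maximal (log2 |r|) for a uniform row.
    """
    row = channel.pmf[int(input_bit)]
    nz = row[row > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class AdditiveNoiseModel:
    """Zero-location additive noise with prescribed power E[n^2].

    Only the second moment is pinned down by the model; the law itself is
    configurable (``"gaussian"`` or ``"uniform"``, both zero-mean with the
    requested second moment).
    """

    noise_power: float
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.noise_power <= 0:
            raise ValueError("noise_power must be > 0")
        if self.distribution not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise law {self.distribution!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "gaussian":
            return rng.normal(0.0, math.sqrt(self.noise_power), size)
        half = math.sqrt(3.0 * self.noise_power)  # Var(U[-a,a]) = a^2/3
        return rng.uniform(-half, half, size)


def additive_transmit(
    codeword: Sequence[int] | BitSequence,
    noise: AdditiveNoiseModel,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Continuous channel r = s + n with i.i.d. noise draws."""
    bits = as_bits(codeword).astype(float)
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return bits + noise.sample(bits.size, gen)


def snr(noise: AdditiveNoiseModel) -> float:
    """SNR of binary 0/1 signalling over the additive channel: 1 / E[n^2]."""
    if noise.noise_power == 0:
        return math.inf
    return 1.0 / noise.noise_power


def symbols_from_str(text: str, channel: ChannelModel) -> SymbolSequence:
    """Parse a symbol string such as ``"DCA DDB DDA DDD"`` to indices."""
    return np.array(
        [channel.symbol_index(c) for c in text if not c.isspace()], dtype=np.int64
    )


def symbols_to_str(symbols: SymbolSequence, channel: ChannelModel, group: int = 0) -> str:
    s = "".join(channel.alphabet[i] for i in symbols)
    if group > 0:
        s = " ".join(s[i : i + group] for i in range(0, len(s), group))
    return s
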