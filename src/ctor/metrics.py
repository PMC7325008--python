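"""Recognition-performance metrics.

Recognition fidelity is graded at three levels: per-bit (BCR), whole-message
(SCR), and category (CCR and its tolerant variant ACCR).  All four are
Monte-Carlo averages over trial records pairing the true object
representation with the decoded one; a single simulation pass therefore
feeds every metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .downstream import categorize
from .encoder import BitSequence, as_bits

__all__ = [
    "TrialRecord",
    "MetricsReport",
    "hamming_distance",
    "make_trial",
    "bcr",
    "scr",
    "ccr",
    "accr",
    "chance_bcr",
    "chance_scr",
    "nominal_chance_ccr",
    "summarize",
]


def hamming_distance(a: Sequence[int] | BitSequence, b: Sequence[int] | BitSequence) -> int:
    """Number of positions where two equal-length bit sequences disagree."""
    x, y = as_bits(a), as_bits(b)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return int(np.count_nonzero(x ^ y))


@dataclass(frozen=True)
class TrialRecord:
    """One Monte-Carlo viewing: truth, decode, deviation, and readouts."""

    truth: BitSequence
    decoded: BitSequence
    deviation: int
    truth_score: float
    decoded_score: float


def make_trial(
    truth: Sequence[int] | BitSequence,
    decoded: Sequence[int] | BitSequence,
    weights: Sequence[float] | np.ndarray | None = None,
) -> TrialRecord:
    """Build a :class:`TrialRecord`; weights default to all-ones."""
    t, d = as_bits(truth), as_bits(decoded)
    w = np.ones(t.size) if weights is None else np.asarray(weights, dtype=float)
    return TrialRecord(
        truth=t,
        decoded=d,
        deviation=hamming_distance(t, d),
        truth_score=categorize(t, w),
        decoded_score=categorize(d, w),
    )


def _require(trials: Sequence[TrialRecord]) -> None:
    if len(trials) == 0:
        raise ValueError("metric undefined on an empty trial set")


def bcr(trials: Sequence[TrialRecord], km: int) -> float:
    """Bit correct rate: 1 - mean(deviation / KM).  Chance level 1/2."""
    _require(trials)
    return 1.0 - float(np.mean([t.deviation for t in trials])) / km


def scr(trials: Sequence[TrialRecord]) -> float:
    """Symbol correct rate: fraction of trials decoded with zero deviation."""
    _require(trials)
    return float(np.mean([t.deviation == 0 for t in trials]))


def ccr(trials: Sequence[TrialRecord]) -> float:
    """Category correct rate: fraction with matching readout scores."""
    _require(trials)
    return float(np.mean([t.decoded_score == t.truth_score for t in trials]))


def accr(trials: Sequence[TrialRecord], c1: float) -> float:
    """Approximate category correct rate: |score difference| <= c1.

    Non-decreasing in c1, with accr(trials, 0) == ccr(trials).
    """
    if c1 < 0:
        raise ValueError("c1 must be non-negative")
    _require(trials)
    return float(
        np.mean([abs(t.decoded_score - t.truth_score) <= c1 for t in trials])
    )


def chance_bcr() -> float:
    """BCR of decoding by fair coin flips."""
    return 0.5


def chance_scr(km: int) -> float:
    """SCR of guessing the whole KM-bit message uniformly."""
    return 1.0 / (1 << km)


def nominal_chance_ccr(km: int) -> float:
    """Nominal chance CCR, 1/KM.

    This is the conventional reciprocal-of-category-count figure; with an
    all-ones readout there are actually KM + 1 attainable score values, so
    the constant is reported as a label, not enforced as an invariant.
    """
    return 1.0 / km


@dataclass(frozen=True)
class MetricsReport:
    """Aggregated metrics for one experimental cell."""

    encoder: str
    channel: str
    K: int
    n_trials: int
    seed: int
    bcr: float
    scr: float
    ccr: float
    accr: float
    c1: float

    def __post_init__(self) -> None:
        for name in ("bcr", "scr", "ccr", "accr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def summarize(
    trials: Sequence[TrialRecord],
    km: int,
    c1: float,
    *,
    encoder: str,
    channel: str,
    K: int,
    seed: int,
) -> MetricsReport:
    """Compute all four metrics from one pass of trial records."""
    return MetricsReport(
        encoder=encoder,
        channel=channel,
        K=K,
        n_trials=len(trials),
        seed=seed,
        bcr=bcr(trials, km),
        scr=scr(trials),
        ccr=ccr(trials),
        accr=accr(trials, c1),
        c1=c1,
    )
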