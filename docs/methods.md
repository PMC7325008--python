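# Methods

## The model

`ctor` simulates object recognition in the primate ventral visual stream
(VVS) as a communication system.  A viewed object is identified with a
binary representation **b** of K·M bits (M = 1 throughout: one bit enters
the encoder per time step).  The early visual stages (retina, LGN, V1) are
modelled as a rate-1/N feedforward convolutional encoder that "tangles"
**b** into a K·N-bit codeword **s**; neural and environmental noise between
those stages and inferior temporal (IT) cortex is a memoryless stochastic
channel producing **r**; and the IT's "untangling" is Viterbi maximum a
posteriori (MAP) sequence estimation of **b** from **r**.  Downstream of
the decoder, an interleaver ranks the decoded bits into feature groups, a
compression rule stores repeated viewings in memory, and the stored stream
is used to re-estimate the transition priors that feed back into the
decoder — the model's account of memory guiding perception.

### Encoder

A generator G(D) is N coefficient vectors of length L+1 over GF(2)
(`GeneratorSpec`); L is the constraint length, giving a 2^L-state trellis.
Two encoders are built in:

* `simple` — G(D) = [1+D, 1+D², 1+D+D²], L = 2, 4 states;
* `complex` — G(D) = [1+D²+D³+D⁵+D⁶+D⁷+D⁸, 1+D+D³+D⁴+D⁷+D⁸, 1+D+D²+D⁵+D⁸],
  L = 8, 256 states.

Conventions that pin the arithmetic down (the unique pair consistent with
all the worked numbers):

* **Tap convention.**  Coefficient j of a tap vector multiplies the input
  delayed by j steps; the register holds the L most recent inputs.
* **State labels.**  A state is the integer value of the register written
  most-recent-bit-first (S0 = 00, S1 = 01, S2 = 10, S3 = 11).  When a state
  is read off a bit *stream* left-to-right (older bit first), the window is
  reversed before labelling; this is why the stream window "10" is S1.
* **No termination.**  Exactly K stages are encoded and decoded; no tail
  bits drive the register back to S0, and traceback starts from the
  terminal state of smallest accumulated metric.

A rate-coding front end (attention gain `attention_modulate`, threshold
rule `rate_code`) shows how codeword bits arise from firing-rate traces:
unit i emits 1 iff its rate integrates above a threshold α_i > 0 over an
epoch of T seconds (default use: ~50 ms epochs).  The Monte-Carlo
experiments feed bits to the encoder directly; the front end is a
standalone demonstration, which is also how the source material treats it.

### Channel

`ChannelModel` is a binary-input discrete memoryless channel: a 2 × |r|
conditional pmf over a symbol alphabet (default A–D), validated to row-sum
1 within 1e-12.  Built-ins: `dispersive` (rows 0.4/0.3/0.2/0.1 and its
mirror), `uniform` (all 0.25), `less_dispersive` (0.65/0.2/0.1/0.05 and
mirror).  The channel quality metric is the conditional entropy
H(r|s=n) = −Σ p log₂ p: 1.846, 2.0 and 1.416 bits respectively, so the
dispersiveness ordering is less_dispersive < dispersive < uniform.
Sampling inverts the row CDF on one uniform draw per symbol; because the
uniform stream depends on the seed but not on the channel, comparisons
between channels at matched seeds are coupled.

An additive continuous channel r = s + n is provided with configurable
zero-location law (gaussian or uniform) and prescribed power E[n²]; only
the second moment is specified by the model, and the SNR for 0/1
signalling is 1/E[n²].  No decoding is performed over this channel — the
decoder operates on discrete channels only.

### Decoder

The branch metric of a trellis transition is
λ = −ln P[b_{k+1}|b_k] − Σ_j ln P[r_j | output bit j].  With uniform
priors the first term is the constant ln 2 per stage and is omitted (MLE
mode); decisions are unchanged.  −ln 0 is represented as +inf with
saturating addition, so a transition with an impossible symbol never
survives unless every alternative is impossible too.  Ties — between a
state's two predecessors and between terminal states — are broken toward
the smaller state label, which makes runs bit-reproducible; on the
`uniform` channel (all metrics equal) this deterministically yields the
all-zero message, the enumeration oracle's tie-break representative as
well.

The 4-symbol channel likelihoods are used directly as soft metrics; no
separate quantiser exists (the alphabet *is* the 4-level soft decision).
Decoding is vectorised across Monte-Carlo trials (`viterbi_decode_batch`);
the single-sequence `viterbi_decode` wraps a batch of one and additionally
reports the survivor table and winning state sequence for trellis-diagram
rendering.

`exhaustive_map_decode` is an independent oracle: it scores all 2^K
candidate messages and returns the argmin, refusing K > 16.  Ties break
toward the smallest message read as an MSB-first integer.  Note that under
count-derived priors exact metric ties between distinct messages do occur,
and the two tie-break rules may then pick different (equally optimal)
representatives; the equivalence tests therefore require message agreement
only when the optimum is unique, and metric optimality always.

### Priors from memory

`estimate_priors` counts overlapping L-bit windows (stride 1) of a stored
bit stream, maps each window to its register-order state label, and
normalises each state's transition counts by the state's occurrences among
non-terminal positions.  Rows are floored at ε = 1e−6 over the two valid
successors and renormalised, so one bad iteration can never hard-forbid a
transition; states never observed fall back to a uniform row.  Overlapping
(not disjoint) windows are essential: they are what reproduces
P[S1|S3] = 2/3 on the stream 1100 1110.

### Interleaver, compression, readout

`InterleaverSpec` is an ordered partition of the 1-based bit indices into
F importance-ranked groups (serialised as a nested JSON list, e.g.
`[[1, 3], [2, 4]]`).  `compress` groups viewed blocks by their rank-1
feature value, keeps each group's most frequent full block (earliest
occurrence wins ties) and concatenates representatives in first-appearance
order of the feature values — less important features are summarised
implicitly by the majority rule.  `categorize` is the linear readout
f(b) = wᵀb; weight fitting is out of scope and w defaults to all-ones, in
which case the score is the Hamming weight of the message.

### Metrics

Recognition is graded at four levels over T Monte-Carlo trials: BCR
(1 − mean Hamming deviation / KM; chance 1/2), SCR (fraction of perfect
recoveries; chance 2^−KM), CCR (readout score equality) and ACCR (score
difference within tolerance c1, default 1; ACCR ≥ CCR with equality at
c1 = 0).  The conventional chance CCR of 1/KM is reported as a labelled
nominal constant only — an all-ones readout actually has KM + 1 attainable
scores, so it is not enforced as an invariant.

## Experiments and problem sizes

* `worked_example()` runs the whole pipeline at K = 4 with the simple
  encoder and dispersive channel on fixed inputs and reports every
  intermediate quantity; it is bit-exact and runs in milliseconds.
* `run_recognition_experiment` sweeps K ∈ {6, 12, 24, 36, 48, 60} with an
  alternating truth (1010…, starting at 1), MLE decoding, and c1 = 1.  The
  default budget is T = 10⁴ trials per cell, chosen so the full two-channel
  sweep completes in seconds with binomial standard errors around 0.005;
  larger T is a config field away and changes only the variance.
* `run_map_vs_mle` runs the iterative feedback study at K = 60, T = 10³:
  both decoders see the identical received sequence each iteration; the MAP
  branch re-estimates priors from the previous iteration's decoded stream
  (protocol choice: the immediately preceding iteration only, not an
  accumulation over all past iterations — accumulation and a
  compressed-stream source are exposed as config switches).  Iteration 1
  uses uniform priors, so it coincides with MLE by construction.

One master seed spawns a substream per (encoder, K) cell; the channel is
deliberately excluded from the derivation so that channel comparisons are
matched-seed.  All randomness flows through `numpy.random.Generator`.

## What the synthetic data does and does not show

The generator produces exactly the study conditions of the model: fixed
alternating truth sequences, i.i.d. channel draws, a time-invariant pmf
within a run.  Real neural data would add features the simulator does not
emulate — correlated noise across units and time, attentional drift of the
channel within a trial, stimulus-dependent encoders, and genuinely unknown
generators.  Passing tests therefore validate the algorithmic claims
(optimality of the decoder, metric behaviour, the value of memory priors
under these conditions), not biological fidelity.

## Known limitations and open choices

* The iterative MAP protocol saturates under these study conditions: once
  decoding is mostly correct, the estimated priors concentrate (≈ 0.999)
  on the alternating transitions S1→S2 and S2→S1 and the decoder locks
  onto the truth, driving BCR near 1.  Mean rates from this study are
  therefore sensitive to the prior-feedback protocol.
* For an alternating truth the most frequent transitions of the decoded
  stream are S1→S2 and S2→S1; the prior trace is maximal there.
* BCR on the dispersive channel is nearly flat in K beyond K ≈ 24
  (differences of order 0.003), so its downward trend is assessed by rank
  correlation rather than strict elementwise monotonicity.
* Encoders with M > 1, recursive (feedback) encoders, erasure outputs,
  channel re-estimation (Baum–Welch) and decoding over the additive
  channel are out of scope.
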