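import math

import numpy as np
import pytest

from ctor import (
    COMPLEX_GENERATOR,
    DISPERSIVE,
    PriorModel,
    SIMPLE_GENERATOR,
    UNIFORM,
    bits_to_str,
    branch_metric,
    build_trellis,
    encode,
    exhaustive_map_decode,
    symbols_from_str,
    transmit,
    viterbi_decode,
)
from ctor.decoder import viterbi_decode_batch

RECEIVED = "DCA DDB DDA DDD"


def path_scores_by_enumeration(received, spec, channel, priors=None):
    """Independent oracle: total path length of every candidate message."""
    trellis = build_trellis(spec)
    K = len(received) // trellis.N
    scores = {}
    for m in range(1 << K):
        bits = [(m >> (K - 1 - k)) & 1 for k in range(K)]
        codeword = encode(bits, spec)
        total = 0.0
        for j, bit in enumerate(codeword):
            p = channel.pmf[bit, received[j]]
            total += -math.log(p) if p > 0 else math.inf
        if priors is not None:
            state = 0
            for u in bits:
                nxt = int(trellis.next_state[state, u])
                total += -math.log(priors.matrix[state, nxt])
                state = nxt
        scores[m] = total
    return scores


class TestBranchMetric:
    def test_first_stage_metrics_of_worked_example(self, simple_trellis):
        r1 = symbols_from_str("DCA", DISPERSIVE)
        lam00 = branch_metric(r1, (0, 0), simple_trellis, DISPERSIVE)
        lam02 = branch_metric(r1, (0, 2), simple_trellis, DISPERSIVE)
        # -ln(0.1) - ln(0.2) - ln(0.4) and -ln(0.4) - ln(0.3) - ln(0.1)
        assert lam00 == pytest.approx(4.8283, abs=1e-4)
        assert lam02 == pytest.approx(4.4228, abs=1e-4)

    def test_uniform_channel_gives_equal_metrics(self, simple_trellis):
        r1 = symbols_from_str("ABD", UNIFORM)
        expected = 3 * math.log(4)
        for s in range(4):
            for nxt in simple_trellis.successors(s):
                assert branch_metric(
                    r1, (s, nxt), simple_trellis, UNIFORM
                ) == pytest.approx(expected)

    def test_map_mode_adds_negative_log_prior(self, simple_trellis):
        r1 = symbols_from_str("DCA", DISPERSIVE)
        priors = PriorModel.uniform(4, simple_trellis)
        mle = branch_metric(r1, (0, 2), simple_trellis, DISPERSIVE)
        mapm = branch_metric(r1, (0, 2), simple_trellis, DISPERSIVE, priors)
        assert mapm == pytest.approx(mle + math.log(2))

    def test_zero_probability_saturates_to_inf(self, simple_trellis, identity_channel):
        received = np.array([1, 1, 1])
        assert branch_metric(received, (0, 0), simple_trellis, identity_channel) == math.inf

    def test_invalid_transition_rejected(self, simple_trellis):
        r1 = symbols_from_str("DCA", DISPERSIVE)
        with pytest.raises(ValueError, match="transition"):
            branch_metric(r1, (0, 1), simple_trellis, DISPERSIVE)


class TestViterbiDecode:
    def test_worked_example_decodes_to_1100(self, simple_trellis):
        received = symbols_from_str(RECEIVED, DISPERSIVE)
        result = viterbi_decode(received, simple_trellis, DISPERSIVE)
        assert bits_to_str(result.message) == "1100"
        assert bits_to_str(result.codeword_estimate, group=3) == "111 010 110 011"
        np.testing.assert_array_equal(result.state_sequence, [0, 2, 3, 1, 0])

    def test_first_stage_path_metrics(self, simple_trellis):
        # Gamma after stage 1 is 0 + lambda for the two reachable states
        received = symbols_from_str("DCA", DISPERSIVE)
        _, metrics, _ = viterbi_decode_batch(
            received[None, :], simple_trellis, DISPERSIVE
        )
        # a single stage: terminal metric is min(4.82, 4.42) reached at S2
        assert metrics[0] == pytest.approx(4.4228, abs=1e-4)

    def test_framing_error_on_partial_block(self, simple_trellis):
        with pytest.raises(ValueError, match="divisible"):
            viterbi_decode(np.array([0, 1]), simple_trellis, DISPERSIVE)

    def test_reencoding_message_gives_codeword_estimate(self, simple_trellis, rng):
        codeword = encode(rng.integers(0, 2, 30), SIMPLE_GENERATOR)
        received = transmit(codeword, DISPERSIVE, rng)
        result = viterbi_decode(received, simple_trellis, DISPERSIVE)
        np.testing.assert_array_equal(
            result.codeword_estimate, encode(result.message, SIMPLE_GENERATOR)
        )

    @pytest.mark.parametrize("spec", [SIMPLE_GENERATOR, COMPLEX_GENERATOR])
    def test_noiseless_round_trip_all_8bit_messages(self, spec, identity_channel):
        trellis = build_trellis(spec)
        K = 8
        messages = np.array(
            [[(m >> (K - 1 - k)) & 1 for k in range(K)] for m in range(1 << K)],
            dtype=np.uint8,
        )
        codewords = np.array([encode(m, spec) for m in messages])
        decoded, _, _ = viterbi_decode_batch(
            codewords.astype(np.int64), trellis, identity_channel
        )
        np.testing.assert_array_equal(decoded, messages)

    def test_uniform_channel_forces_tiebreak_representative(self, simple_trellis):
        received = symbols_from_str("ABCD CBAD", UNIFORM)[: 2 * 3]
        result = viterbi_decode(received, simple_trellis, UNIFORM)
        oracle = exhaustive_map_decode(received, SIMPLE_GENERATOR, UNIFORM)
        np.testing.assert_array_equal(result.message, oracle)
        np.testing.assert_array_equal(result.message, 0)

    def test_mle_equals_uniform_prior_map(self, simple_trellis, rng):
        # adding a constant to every branch cannot change the decision
        priors = PriorModel.uniform(4, simple_trellis)
        codeword = encode(rng.integers(0, 2, 40), SIMPLE_GENERATOR)
        received = transmit(codeword, DISPERSIVE, rng)
        mle = viterbi_decode(received, simple_trellis, DISPERSIVE)
        mapu = viterbi_decode(received, simple_trellis, DISPERSIVE, priors)
        np.testing.assert_array_equal(mle.message, mapu.message)


class TestExhaustiveOracle:
    def test_worked_example_agrees_with_viterbi(self):
        received = symbols_from_str(RECEIVED, DISPERSIVE)
        oracle = exhaustive_map_decode(received, SIMPLE_GENERATOR, DISPERSIVE)
        assert bits_to_str(oracle) == "1100"

    def test_refuses_large_k(self):
        with pytest.raises(ValueError, match="refused"):
            exhaustive_map_decode(
                np.zeros(3 * 20, dtype=np.int64), SIMPLE_GENERATOR, DISPERSIVE
            )

    def test_dp_optimality_against_enumeration(self, simple_trellis, dmc, rng):
        """Viterbi's final metric equals the global minimum path length and,
        when that optimum is unique, the decoded sequence matches it."""
        for _ in range(25):
            K = int(rng.integers(2, 9))
            msg = rng.integers(0, 2, K)
            received = transmit(encode(msg, SIMPLE_GENERATOR), dmc, rng)
            priors = (
                None
                if rng.random() < 0.5
                else PriorModel.from_counts(
                    rng.integers(0, 10, (4, 4)).astype(float), simple_trellis
                )
            )
            scores = path_scores_by_enumeration(
                received, SIMPLE_GENERATOR, dmc, priors
            )
            best = min(scores.values())
            result = viterbi_decode(received, simple_trellis, dmc, priors)
            assert result.final_metric == pytest.approx(best, rel=1e-12)
            if sum(abs(v - best) < 1e-9 for v in scores.values()) == 1:
                decoded_int = int("".join(map(str, result.message)), 2)
                assert scores[decoded_int] == pytest.approx(best)


class TestPriorModel:
    def test_rows_sum_to_one_over_valid_successors(self, simple_trellis, rng):
        counts = rng.integers(0, 20, (4, 4)).astype(float)
        model = PriorModel.from_counts(counts, simple_trellis)
        for s in range(4):
            succ = np.unique(simple_trellis.next_state[s])
            assert model.matrix[s, succ].sum() == pytest.approx(1.0, abs=1e-12)
            invalid = np.setdiff1d(np.arange(4), succ)
            assert np.all(model.matrix[s, invalid] == 0)

    def test_flooring_keeps_unobserved_transitions_possible(self, simple_trellis):
        counts = np.zeros((4, 4))
        counts[0, 2] = 100  # only S0 -> S2 ever observed
        model = PriorModel.from_counts(counts, simple_trellis, floor=1e-6)
        assert model.matrix[0, 0] > 0
        assert model.matrix[0, 2] == pytest.approx(1.0, abs=1e-5)

    def test_unobserved_state_falls_back_to_uniform(self, simple_trellis):
        model = PriorModel.from_counts(np.zeros((4, 4)), simple_trellis)
        np.testing.assert_allclose(
            model.matrix[1, np.unique(simple_trellis.next_state[1])], 0.5
        )
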