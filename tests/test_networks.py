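import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalnet import (
    EventTable,
    binarize,
    build_cc_network,
    caller_sequence,
    cross_correlation,
    estimate_transition_matrix,
    max_transition_edges,
)
from vocalnet.networks import BinarySignal

from conftest import make_table

BIRDS4 = ("1", "2", "3", "4")


def sig(bits):
    return BinarySignal("x", np.array(bits))


class TestBinarize:
    def test_event_within_one_bin(self):
        s = binarize(make_table([("a", 0.10, 0.20)]), "a", 2.0)
        assert s.bits.tolist() == [1, 0, 0, 0]

    def test_event_straddling_bin_edge_sets_both(self):
        s = binarize(make_table([("a", 0.40, 0.60)]), "a", 2.0)
        assert s.bits.tolist() == [1, 1, 0, 0]

    def test_halfopen_end_does_not_spill(self):
        # event ending exactly at a bin boundary stays out of the next bin
        s = binarize(make_table([("a", 0.10, 0.50)]), "a", 2.0)
        assert s.bits.tolist() == [1, 0, 0, 0]

    def test_onset_only_semantics(self):
        s = binarize(make_table([("a", 0.40, 1.80)]), "a", 2.0, onset_only=True)
        assert s.bits.tolist() == [1, 0, 0, 0]

    def test_empty_table_all_zero(self):
        s = binarize(EventTable.empty(), "a", 3.0)
        assert s.n_bins == 6 and not s.bits.any()


def pearson_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std()))


class TestCrossCorrelation:
    def test_self_correlation_is_one(self):
        assert cross_correlation(sig([1, 0, 1, 0, 0]), sig([1, 0, 1, 0, 0])) == pytest.approx(1.0)

    def test_complement_is_minus_one(self):
        assert cross_correlation(sig([1, 0, 1, 0]), sig([0, 1, 0, 1])) == pytest.approx(-1.0)

    def test_worked_orthogonal_example(self):
        assert cross_correlation(sig([1, 1, 0, 0]), sig([1, 0, 1, 0])) == pytest.approx(0.0)

    def test_zero_variance_is_undefined_not_error(self):
        assert math.isnan(cross_correlation(sig([0, 0, 0]), sig([1, 0, 1])))
        assert math.isnan(cross_correlation(sig([1, 0, 1]), sig([1, 1, 1])))

    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_pearson_oracle_and_is_symmetric(self, xa, xb):
        a = [(xa >> i) & 1 for i in range(20)]
        b = [(xb >> i) & 1 for i in range(20)]
        if len(set(a)) < 2 or len(set(b)) < 2:
            return
        cc = cross_correlation(sig(a), sig(b))
        assert cc == pytest.approx(pearson_oracle(a, b), abs=1e-12)
        assert cc == pytest.approx(cross_correlation(sig(b), sig(a)), abs=1e-15)
        assert -1.0 - 1e-12 <= cc <= 1.0 + 1e-12

    def test_invariant_under_session_duplication(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        cc1 = cross_correlation(sig(a), sig(b))
        cc2 = cross_correlation(sig(np.tile(a, 2)), sig(np.tile(b, 2)))
        assert cc2 == pytest.approx(cc1, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cross_correlation(sig([1, 0]), sig([1, 0, 1]))


class TestCallerSequence:
    def test_onset_order(self):
        table = make_table([("B", 0.0, 0.1), ("A", 1.0, 1.1), ("B", 2.0, 2.1)])
        assert caller_sequence(table) == ["B", "A", "B"]

    def test_empty(self):
        assert caller_sequence(EventTable.empty()) == []

    def test_simultaneous_onsets_deterministic(self):
        rows = [("B", 1.0, 1.3), ("A", 1.0, 1.2), ("C", 0.5, 0.6)]
        assert caller_sequence(make_table(rows)) == ["C", "A", "B"]
        assert caller_sequence(make_table(reversed(rows))) == ["C", "A", "B"]


class TestTransitionMatrix:
    def test_worked_ten_call_sequence(self, worked_sequence_table):
        seq = caller_sequence(worked_sequence_table)
        assert seq == list("1123113134")
        m = estimate_transition_matrix(seq, BIRDS4)
        np.testing.assert_allclose(m.probs[0], [0.4, 0.2, 0.4, 0.0])
        np.testing.assert_allclose(m.probs[1], [0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(m.probs[2], [2 / 3, 0.0, 0.0, 1 / 3])
        assert np.isnan(m.probs[3]).all()
        assert m.undefined_rows == ("4",)
        assert m.counts.sum() == len(seq) - 1

    def test_alternating_pair_sequence(self):
        seq = ["A", "B"] * 50
        m = estimate_transition_matrix(seq, ("A", "B"))
        assert m.prob("A", "B") == 1.0 and m.prob("B", "A") == 1.0

    def test_short_sequence_warns_all_undefined(self):
        with pytest.warns(UserWarning, match="shorter than 2"):
            m = estimate_transition_matrix(["A"], ("A", "B"))
        assert np.isnan(m.probs).all()

    def test_marginals_recoverable_from_counts(self):
        rng = np.random.default_rng(1)
        seq = [BIRDS4[i] for i in rng.integers(0, 4, 500)]
        m = estimate_transition_matrix(seq, BIRDS4)
        # every caller except the last appears as a "from"; except the first as a "to"
        from_counts = m.counts.sum(axis=1)
        for i, b in enumerate(BIRDS4):
            assert from_counts[i] == sum(1 for s in seq[:-1] if s == b)

    def test_defined_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        seq = [BIRDS4[i] for i in rng.integers(0, 3, 200)]
        m = estimate_transition_matrix(seq, BIRDS4)
        sums = np.nansum(m.probs, axis=1)
        assert np.allclose(sums[:3], 1.0, atol=1e-12)

    def test_recovery_of_known_chain(self):
        # 20k-step simulated chain: estimates within 0.02 of the truth
        P = np.array([[0.1, 0.6, 0.2, 0.1],
                      [0.3, 0.3, 0.2, 0.2],
                      [0.25, 0.25, 0.25, 0.25],
                      [0.4, 0.1, 0.1, 0.4]])
        rng = np.random.default_rng(5)
        states = [0]
        for _ in range(20_000):
            states.append(rng.choice(4, p=P[states[-1]]))
        m = estimate_transition_matrix([BIRDS4[s] for s in states], BIRDS4)
        assert np.abs(m.probs - P).max() < 0.02


class TestMaxTransitionEdges:
    def test_worked_example_dyad(self, worked_sequence_table):
        m = estimate_transition_matrix(caller_sequence(worked_sequence_table), BIRDS4)
        net = max_transition_edges(m)
        assert net.weight("1", "3") == pytest.approx(2 / 3)
        assert net.weight_type == "max_transition"

    def test_undefined_direction_treated_as_absent(self, worked_sequence_table):
        m = estimate_transition_matrix(caller_sequence(worked_sequence_table), BIRDS4)
        net = max_transition_edges(m)
        # row 4 is undefined; p(3->4) = 1/3 still defines the dyad
        assert net.weight("3", "4") == pytest.approx(1 / 3)

    def test_both_directions_undefined_gives_nan(self):
        m = estimate_transition_matrix(["1", "2", "1", "2"], BIRDS4)
        net = max_transition_edges(m)
        assert math.isnan(net.weight("3", "4"))

    def test_symmetric_matrix_weight_is_shared_value(self):
        seq = ["A", "B", "A", "B", "A"]
        net = max_transition_edges(estimate_transition_matrix(seq, ("A", "B")))
        assert net.weight("A", "B") == pytest.approx(1.0)


class TestBuildCcNetwork:
    def test_four_birds_six_edges(self):
        table = make_table((b, float(i), i + 0.1) for i, b in enumerate(BIRDS4))
        net = build_cc_network(table, BIRDS4, 10.0)
        assert len(net.weights) == 6

    def test_identical_timing_perfect_edge_silent_birds_undefined(self):
        table = make_table([("1", 0.1, 0.2), ("2", 0.1, 0.2), ("1", 3.1, 3.2), ("2", 3.1, 3.2)])
        net = build_cc_network(table, BIRDS4, 6.0)
        assert net.weight("1", "2") == pytest.approx(1.0)
        assert math.isnan(net.weight("1", "3"))
        assert math.isnan(net.weight("3", "4"))

    def test_synchronized_pair_outranks_independent_birds(self):
        # birds 1,2 call in shared bouts; 3,4 independently: cc(1,2) must top
        # every mixed dyad (Monte-Carlo with a known generator)
        rng = np.random.default_rng(12)
        rows = []
        t = 0.0
        while t < 1800.0:
            t += rng.exponential(20.0)
            for b, off in (("1", 0.0), ("2", rng.uniform(0, 0.4))):
                rows.append((b, t + off, t + off + 0.1))
        for b in ("3", "4"):
            t = 0.0
            while t < 1800.0:
                t += rng.exponential(15.0)
                rows.append((b, t, t + 0.1))
        net = build_cc_network(make_table(rows), BIRDS4, 1800.0)
        cc12 = net.weight("1", "2")
        for dyad in (("1", "3"), ("1", "4"), ("2", "3"), ("2", "4")):
            assert cc12 > net.weight(*dyad)
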