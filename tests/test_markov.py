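"""Markov estimation, stationary distributions, SMR distances, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movesyll.errors import ValidationError
from movesyll.markov import (
    SMR,
    TransitionCounts,
    TransitionMatrix,
    count_transitions,
    dissimilarity_matrix,
    estimate_transition_matrix,
    smr_distance,
    smr_from_sequences,
    smr_stability_curve,
    stationary_distribution,
    stationary_power_iteration,
)
from movesyll.simulate import make_base_grammar, sample_path
from movesyll.tokenize import SyllableSequence


def seq(symbols, k, sid="s", adl=None):
    symbols = np.asarray(symbols)
    return SyllableSequence(
        session_id=sid, symbols=symbols,
        start_times=np.arange(symbols.size) * 0.24, k=k, adl_label=adl,
    )


def random_smoothed_matrix(k, rng):
    counts = rng.integers(0, 50, size=(k, k))
    counts[rng.random(size=(k, k)) < 0.4] = 0
    # ensure one off-diagonal observation per row: a chain that is only
    # eps away from reducible has an ill-conditioned stationary problem and
    # stalls power iteration, which is outside what this oracle check covers
    for a in range(k):
        b = (a + 1 + int(rng.integers(k - 1))) % k
        counts[a, b] += 1
    return estimate_transition_matrix(TransitionCounts(counts=counts))


class TestCounting:
    def test_hand_counted_single_sequence(self):
        c = count_transitions(seq([0, 1, 0, 1], k=2), k=2)
        assert c.counts[0, 1] == 2
        assert c.counts[1, 0] == 1
        assert c.total == 3

    def test_no_pair_spans_sequence_boundary(self):
        c = count_transitions([seq([0, 1], 2), seq([1, 0], 2)], k=2)
        assert c.counts[0, 1] == 1
        assert c.counts[1, 0] == 1
        assert c.counts[1, 1] == 0

    def test_total_is_sum_of_lengths_minus_one(self):
        seqs = [seq(np.zeros(5, int), 3), seq(np.zeros(8, int), 3)]
        assert count_transitions(seqs, k=3).total == (5 - 1) + (8 - 1)

    def test_out_of_vocabulary_symbol_errors(self):
        with pytest.raises(ValidationError, match="out of vocabulary"):
            count_transitions(seq([0, 5], k=6), k=3)


class TestEstimate:
    def test_mle_rows(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 0], counts[0, 1] = 1, 3
        counts[1, 0] = 1
        tm = estimate_transition_matrix(TransitionCounts(counts=counts))
        assert np.allclose(tm.P[0], [0.25, 0.75], atol=1e-9)

    def test_all_zero_counts_gives_uniform(self):
        tm = estimate_transition_matrix(
            TransitionCounts(counts=np.zeros((24, 24), dtype=int))
        )
        assert np.allclose(tm.P, 1.0 / 24)

    def test_rows_sum_to_one_and_strictly_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tm = random_smoothed_matrix(5, rng)
            assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-12)
            assert tm.P.min() > 0

    def test_smoothing_perturbation_bounded(self):
        # all rows observed: smoothing moves no entry by more than k * eps
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, size=(6, 6))
        counts[2, 3] = 0
        c = TransitionCounts(counts=counts)
        mle = counts / counts.sum(axis=1, keepdims=True)
        tm = estimate_transition_matrix(c, eps=1e-10)
        assert np.max(np.abs(tm.P - mle)) <= 6 * 1e-10


class TestStationary:
    def test_uniform_matrix_gives_uniform(self):
        tm = TransitionMatrix(P=np.full((4, 4), 0.25))
        assert np.allclose(stationary_distribution(tm).pi, 0.25, atol=1e-12)

    def test_two_state_closed_form(self):
        tm = TransitionMatrix(P=np.array([[0.7, 0.3], [0.1, 0.9]]))
        pi = stationary_distribution(tm).pi
        # closed form (b/(a+b), a/(a+b)) with a = 0.3, b = 0.1
        assert np.allclose(pi, [0.25, 0.75], atol=1e-12)

    def test_agrees_with_power_iteration(self):
        rng = np.random.default_rng(7)
        for k in (2, 5, 24):
            for _ in range(10):
                tm = random_smoothed_matrix(k, rng)
                pi = stationary_distribution(tm).pi
                oracle = stationary_power_iteration(tm, tol=1e-13)
                assert np.abs(pi - oracle).sum() < 1e-8

    def test_residual_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tm = random_smoothed_matrix(8, rng)
            pi = stationary_distribution(tm).pi
            assert np.abs(pi - pi @ tm.P).sum() < 1e-10

    def test_non_stochastic_rejected(self):
        tm = TransitionMatrix(P=np.array([[0.5, 0.2], [0.3, 0.7]]))
        with pytest.raises(ValidationError, match="invalid transition matrix"):
            stationary_distribution(tm)


class TestDistance:
    def test_identity_and_disjoint_support(self):
        p = SMR(pi=np.array([1.0, 0.0]))
        q = SMR(pi=np.array([0.0, 1.0]))
        assert smr_distance(p, p) == 0.0
        assert smr_distance(p, q) == 2.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = rng.dirichlet(np.ones(6), size=3)
        dpq, dqp = smr_distance(p, q), smr_distance(q, p)
        assert dpq == dqp
        assert 0.0 <= dpq <= 2.0
        assert smr_distance(p, r) <= dpq + smr_distance(q, r) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            smr_distance(np.array([0.5, 0.5]), np.array([1.0]))


class TestDissimilarityMatrix:
    def test_single_smr_zero_matrix(self):
        D = dissimilarity_matrix([SMR(pi=np.array([0.5, 0.5]), session_id="a")])
        assert D.D.shape == (1, 1)
        assert D.D[0, 0] == 0.0

    def test_duplicates_give_zero_offdiagonal(self):
        s = SMR(pi=np.array([0.3, 0.7]), session_id="a")
        t = SMR(pi=np.array([0.3, 0.7]), session_id="b")
        D = dissimilarity_matrix([s, t])
        assert D.D[0, 1] == 0.0

    def test_entries_bounded_and_symmetric(self):
        rng = np.random.default_rng(2)
        smrs = [
            SMR(pi=rng.dirichlet(np.ones(10)), session_id=str(i))
            for i in range(8)
        ]
        D = dissimilarity_matrix(smrs)
        assert (D.D >= 0).all() and (D.D <= 2).all()
        assert np.array_equal(D.D, D.D.T)

    def test_reference_ordering_sorts_by_distance(self):
        rng = np.random.default_rng(4)
        smrs = [
            SMR(pi=rng.dirichlet(np.ones(6)), session_id=f"s{i}")
            for i in range(6)
        ]
        ref = [SMR(pi=np.full(6, 1 / 6), session_id="ref")]
        D = dissimilarity_matrix(smrs, order_by_reference=ref)
        d_from_ref = [
            smr_distance(next(s for s in smrs if s.session_id == sid), ref[0])
            for sid in D.session_ids
        ]
        assert d_from_ref == sorted(d_from_ref)

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            dissimilarity_matrix([])


class TestStabilityCurve:
    @staticmethod
    def _adls_from_chain(grammar, n_adls, length, seed):
        rng = np.random.default_rng(seed)
        return [
            seq(sample_path(grammar, length, rng), grammar.k, adl=f"a{i}")
            for i in range(n_adls)
        ]

    def test_identical_chain_gives_near_zero_curve(self):
        g = make_base_grammar(4, seed=0)
        adls = self._adls_from_chain(g, 6, 2000, seed=1)
        curve = smr_stability_curve(adls, k=4, n_shuffles=20, seed=0)
        assert curve.max() < 0.01

    def test_variance_shrinks_with_concatenation(self):
        # heterogeneous ADLs: different chains per ADL
        adls = []
        for i in range(10):
            g = make_base_grammar(6, seed=i)
            adls.extend(self._adls_from_chain(g, 1, 300, seed=100 + i))
        curve = smr_stability_curve(adls, k=6, n_shuffles=30, seed=0)
        assert curve[-1] <= curve[0]
        assert curve[-1] < 1e-20  # all shuffles pool the same full set

    def test_seeded_determinism(self):
        g = make_base_grammar(5, seed=2)
        adls = self._adls_from_chain(g, 5, 200, seed=3)
        a = smr_stability_curve(adls, k=5, n_shuffles=10, seed=9)
        b = smr_stability_curve(adls, k=5, n_shuffles=10, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_inputs(self):
        g = make_base_grammar(3, seed=0)
        adls = self._adls_from_chain(g, 3, 50, seed=0)
        with pytest.raises(ValidationError):
            smr_stability_curve(adls[:1], k=3)
        with pytest.raises(ValidationError):
            smr_stability_curve(adls, k=3, n_shuffles=0)


def test_smr_from_sequences_contract():
    g = make_base_grammar(5, seed=1)
    rng = np.random.default_rng(0)
    s = seq(sample_path(g, 500, rng), 5, sid="sess")
    smr = smr_from_sequences(s, k=5)
    assert smr.session_id == "sess"
    assert abs(smr.pi.sum() - 1.0) < 1e-12
    assert (smr.pi >= 0).all()
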