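"""Contract and reversibility tests of the six proposal types."""

import math

import numpy as np
import pytest
from scipy import stats

from argmc import Parameters, simulate_arg
from argmc.ats import ATS
from argmc.density import event_sequence, log_prior_ats
from argmc.moves import (MOVES, apply_move, inverse_move, log_q, propose)

PRIOR = Parameters(mu=0.0, r=2e-7, N=1e4)


def prior_state(seed=42, n=4, L=100):
    return simulate_arg(n, L, PRIOR, seed)


def mh_prior_step(state, move, params, rng):
    """One prior-targeting MH step; returns (state, outcome, accepted)."""
    out = propose(state, move, params, rng)
    if not out.available or out.proposal_invalid:
        return state, out, False
    la = (log_prior_ats(out.proposal, params) - log_prior_ats(state, params)
          + out.log_q_reverse - out.log_q_forward)
    if la >= 0 or math.log(rng.random()) < la:
        return out.proposal, out, True
    return state, out, False


class TestSpr:
    def test_n2_single_tree_prune_and_reattach(self):
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        rng = np.random.default_rng(0)
        out = propose(ats, "spr", PRIOR, rng)
        assert out.available and not out.proposal_invalid
        assert np.isfinite(out.log_q_forward) and np.isfinite(out.log_q_reverse)
        assert out.proposal.validate() == []

    def test_recombination_count_always_fixed(self):
        rng = np.random.default_rng(1)
        state = prior_state()
        for _ in range(300):
            state, out, acc = mh_prior_step(state, "spr", PRIOR, rng)
            if out.available and not out.proposal_invalid:
                assert out.proposal.num_recombinations == \
                    (state if acc else state).num_recombinations


class TestRemoveAdd:
    def test_remove_unavailable_without_recombinations(self):
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        out = propose(ats, "remove_recomb", PRIOR, np.random.default_rng(0))
        assert not out.available

    def test_remove_one_recombination_ats_reaches_zero(self):
        # a bubble: its removal must empty the recombination table
        ats = ATS(10, 2)
        rec = ats.add_rec(100.0, 0, 4)
        ats.add_ca(200.0, rec.left_parent, rec.right_parent)
        ats.add_ca(900.0, ats.next_id - 1, 1)
        assert ats.validate() == []
        out = propose(ats, "remove_recomb", PRIOR, np.random.default_rng(3))
        assert out.available
        assert out.proposal.num_recombinations == 0

    def test_add_unavailable_on_single_site_genome(self):
        ats = ATS(1, 2)
        ats.add_ca(500.0, 0, 1)
        out = propose(ats, "add_recomb", PRIOR, np.random.default_rng(0))
        assert not out.available

    def test_add_increments_count_and_pairs_with_remove(self):
        rng = np.random.default_rng(2)
        state = prior_state()
        checked = 0
        for _ in range(300):
            out = propose(state, "add_recomb", PRIOR, rng)
            if not out.available or out.proposal_invalid:
                continue
            assert out.proposal.num_recombinations == \
                state.num_recombinations + 1
            # forward probability of the add equals the reverse probability
            # quoted by the paired remove on the proposed state
            back = propose_remove_with(out.proposal, out.reverse_choices)
            assert back == state
            lq = log_q(out.proposal, "remove_recomb", out.reverse_choices, PRIOR)
            assert math.isclose(lq, out.log_q_reverse, abs_tol=1e-9)
            checked += 1
            state, _, _ = mh_prior_step(state, "add_recomb", PRIOR, rng)
        assert checked > 50


def propose_remove_with(state, choices):
    return apply_move(state, "remove_recomb", choices)


class TestBreakpoint:
    def test_unavailable_without_recombinations(self):
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        out = propose(ats, "resample_breakpoint", PRIOR,
                      np.random.default_rng(0))
        assert not out.available

    def test_single_link_span_is_identity(self):
        ats = ATS(2, 2)  # one link only
        rec = ats.add_rec(100.0, 0, 0)
        ats.add_ca(200.0, rec.left_parent, rec.right_parent)
        ats.add_ca(900.0, ats.next_id - 1, 1)
        out = propose(ats, "resample_breakpoint", PRIOR,
                      np.random.default_rng(1))
        assert out.available and out.proposal == ats

    def test_trees_outside_moved_interval_unchanged(self):
        rng = np.random.default_rng(3)
        state = prior_state(seed=7)
        assert state.num_recombinations >= 1
        for _ in range(100):
            out = propose(state, "resample_breakpoint", PRIOR, rng)
            if not out.available or out.proposal_invalid:
                continue
            old_b = out.reverse_choices["breakpoint"]
            new_b = out.choices["breakpoint"]
            lo, hi = min(old_b, new_b), max(old_b, new_b)
            for site in range(state.L):
                if site <= lo or site > hi:
                    assert state.marginal_tree(site).key() == \
                        out.proposal.marginal_tree(site).key()


class TestKuhner:
    def test_r0_resimulation_never_adds_recombinations(self):
        p0 = Parameters(mu=0, r=0, N=1e4)
        state = simulate_arg(4, 100, p0, 5)
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = propose(state, "kuhner", p0, rng)
            assert out.proposal.num_recombinations == 0

    def test_prior_sampling_with_kuhner_alone(self):
        # chain driven solely by the Kuhner move matches direct simulation
        from argmc import prior_reference_summaries
        rng = np.random.default_rng(8)
        state = prior_state(seed=1)
        n_rec, tbl = [], []
        for it in range(30_000):
            state, _, _ = mh_prior_step(state, "kuhner", PRIOR, rng)
            if it % 10 == 0:
                n_rec.append(state.num_recombinations)
                tbl.append(state.total_branch_length_sum())
        ref = prior_reference_summaries(4, 100, PRIOR, 8000, 99)
        for vals, refvals in ((n_rec, ref["n_recombinations"]),
                              (tbl, ref["total_branch_length"])):
            vals = np.asarray(vals, dtype=float)
            bm = vals[:len(vals) // 50 * 50].reshape(-1, 50).mean(axis=1)
            se = np.hypot(bm.std(ddof=1) / np.sqrt(len(bm)),
                          refvals.std(ddof=1) / np.sqrt(len(refvals)))
            assert abs(vals.mean() - refvals.mean()) < 3 * se


class TestResampleTimes:
    def test_event_type_sequence_preserved(self):
        rng = np.random.default_rng(2)
        state = prior_state(seed=3)
        for _ in range(50):
            out = propose(state, "resample_times", PRIOR, rng)
            es0 = event_sequence(state)
            es1 = event_sequence(out.proposal)
            assert np.array_equal(es0.ic, es1.ic)
            assert np.array_equal(es0.k, es1.k)
            assert np.array_equal(es0.kp, es1.kp)
            state = out.proposal

    def test_times_increase_along_rootward_paths(self):
        rng = np.random.default_rng(4)
        state = prior_state(seed=5)
        for _ in range(100):
            out = propose(state, "resample_times", PRIOR, rng)
            assert out.proposal.validate() == []
            state = out.proposal

    def test_n2_tmrca_resampled_exponentially(self):
        # r = 0: the single CA waiting time is Exp with rate 1/(2N)
        p0 = Parameters(mu=0, r=0, N=1e4)
        ats = ATS(5, 2)
        ats.add_ca(500.0, 0, 1)
        rng = np.random.default_rng(6)
        draws = []
        for _ in range(10_000):
            out = propose(ats, "resample_times", p0, rng)
            draws.append(out.choices["times"][0])
        res = stats.kstest(draws, "expon", args=(0, 2 * p0.N))
        assert res.pvalue > 0.01


class TestReversibility:
    @pytest.mark.parametrize("move", MOVES)
    def test_accepted_moves_are_reversible(self, move):
        # the state evolves under the full prior-targeting mixture so every
        # move type is exercised from typical states
        rng = np.random.default_rng(abs(hash(move)) % 2 ** 31)
        state = prior_state(seed=11)
        accepted = 0
        attempts = 0
        while accepted < 150 and attempts < 8000:
            attempts += 1
            out = propose(state, move, PRIOR, rng)
            if out.available and not out.proposal_invalid:
                back = apply_move(out.proposal, inverse_move(move),
                                  out.reverse_choices)
                assert back == state
                lq_r = log_q(out.proposal, inverse_move(move),
                             out.reverse_choices, PRIOR)
                assert math.isclose(lq_r, out.log_q_reverse, abs_tol=1e-9)
                lq_f = log_q(state, move, out.choices, PRIOR)
                assert math.isclose(lq_f, out.log_q_forward, abs_tol=1e-9)
                _, _, acc = mh_prior_step(state, move, PRIOR, rng)
                accepted += acc
            mix = MOVES[rng.integers(len(MOVES))]
            state, _, _ = mh_prior_step(state, mix, PRIOR, rng)
        assert accepted >= 100
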