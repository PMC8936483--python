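"""Tests of posterior summaries."""

import numpy as np
import pytest

from argmc import (Parameters, allele_age, equal_tailed_interval,
                   posterior_summary, recomb_rate_estimate, simulate_arg,
                   simulate_dataset, tmrca_by_site)
from argmc.ats import ATS


def test_tmrca_constant_for_single_tree():
    ats = ATS(20, 2)
    ats.add_ca(1234.0, 0, 1)
    assert np.all(tmrca_by_site(ats) == 1234.0)


def test_tmrca_changes_only_at_breakpoints(oracle):
    p = Parameters(mu=0, r=2e-6, N=1e4)
    for seed in range(10):
        ats = simulate_arg(4, 40, p, seed)
        got = tmrca_by_site(ats)
        want = np.array([ats.node_time[oracle.site_tree(ats, s)[1]]
                         for s in range(ats.L)])
        assert np.array_equal(got, want)
        breakpoints = {r.breakpoint for r in ats.recs}
        for s in range(1, ats.L):
            if got[s] != got[s - 1]:
                assert s - 1 in breakpoints


def test_tmrca_n2_mean_is_2N():
    p = Parameters(mu=0, r=0, N=1e4)
    rng = np.random.default_rng(3)
    vals = [tmrca_by_site(simulate_arg(2, 3, p, rng))[0] for _ in range(5000)]
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 2e4) < 3 * se


class TestAlleleAge:
    def test_midpoint_of_branch(self):
        from argmc.dataset import Dataset
        ats = ATS(10, 3)
        a = ats.add_ca(300.0, 0, 1)
        ats.add_ca(1000.0, a, 2)
        data = Dataset(n=3, L=10, seg={4: frozenset({0, 1})})
        ats.mutations = ats.assign_mutations(data)
        # mutation on branch a: child time 300, parent 1000 -> midpoint 650
        assert allele_age(ats, 4) == 650.0

    def test_leaf_branch_half_parent_time(self):
        from argmc.dataset import Dataset
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        data = Dataset(n=2, L=10, seg={0: frozenset({1})})
        ats.mutations = ats.assign_mutations(data)
        assert allele_age(ats, 0) == 250.0

    def test_non_segregating_site_errors(self):
        from argmc.dataset import Dataset
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        ats.mutations = []
        with pytest.raises(ValueError):
            allele_age(ats, 3)

    def test_age_below_tmrca(self):
        p = Parameters(mu=2e-6, r=1e-6, N=1e4)
        for seed in range(20):
            ats, data, _ = simulate_dataset(5, 50, p, seed)
            tm = tmrca_by_site(ats)
            for m in ats.mutations:
                age = allele_age(ats, m.site)
                assert 0 < age < tm[m.site]


class TestRecombRate:
    def test_zero_recombinations_gives_zero(self):
        ats = ATS(10, 2)
        ats.add_ca(500.0, 0, 1)
        assert recomb_rate_estimate([ats]) == 0.0

    def test_ratio_arithmetic(self):
        # 1 ancestral recombination over total branch length l*g
        ats = ATS(10, 2)
        rec = ats.add_rec(100.0, 0, 4)
        ats.add_ca(200.0, rec.left_parent, rec.right_parent)
        ats.add_ca(1000.0, ats.next_id - 1, 1)
        n_anc, _ = ats.classify_recombinations()
        _, total = ats.total_branch_length()
        assert recomb_rate_estimate([ats]) == n_anc / total

    def test_truth_args_estimate_r_within_10pct(self):
        p = Parameters(mu=1e-8, r=1e-8, N=1e4)  # R = 1
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(200):
            ats = simulate_arg(10, 10_000, p, rng)
            vals.append(recomb_rate_estimate([ats]))
        assert abs(np.mean(vals) - p.r) / p.r < 0.10

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            recomb_rate_estimate([])


class TestEqualTailed:
    def test_hand_quantiles(self):
        lo, hi = equal_tailed_interval(np.arange(1, 101), 0.5)
        assert (lo, hi) == (25.75, 75.25)

    def test_constant_samples_zero_width(self):
        lo, hi = equal_tailed_interval([5.0, 5.0, 5.0], 0.5)
        assert lo == hi == 5.0

    def test_wider_level_wider_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        lo50, hi50 = equal_tailed_interval(x, 0.5)
        lo95, hi95 = equal_tailed_interval(x, 0.95)
        assert lo95 < lo50 and hi95 > hi50

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            equal_tailed_interval([1.0], 0.5)
        with pytest.raises(ValueError):
            equal_tailed_interval([1.0, 2.0], 1.5)


class TestPosteriorSummary:
    def _samples(self, k=5):
        p = Parameters(mu=2e-6, r=1e-6, N=1e4)
        out = []
        for seed in range(k):
            ats, data, _ = simulate_dataset(4, 50, p, seed)
            out.append(ats)
        return out

    def test_single_sample_zero_width(self):
        s = self._samples(1)
        table = posterior_summary(s)
        assert np.allclose(table["lower"], table["mean"])
        assert np.allclose(table["upper"], table["mean"])

    def test_permutation_invariance(self):
        s = self._samples(6)
        t1 = posterior_summary(s)
        t2 = posterior_summary(list(reversed(s)))
        assert np.allclose(t1["mean"], t2["mean"])
        assert np.allclose(t1["lower"], t2["lower"])

    def test_matches_direct_recomputation(self):
        s = self._samples(6)
        table = posterior_summary(s)
        tbls = [a.total_branch_length_sum() / a.L for a in s]
        assert np.isclose(table.loc["total_branch_length_per_site", "mean"],
                          np.mean(tbls))
        n_anc = [a.classify_recombinations()[0] for a in s]
        assert np.isclose(table.loc["n_ancestral_recombinations", "mean"],
                          np.mean(n_anc))
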