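"""Convergence diagnostics and the calibration harness.

Autocorrelation uses the biased (divide-by-T) normalization, giving a
well-behaved spectral estimate.  ``T'`` is the first lag at which the
empirical autocorrelation drops to or below zero, and the effective sample
size is ``ESS = T / (1 + 2 sum_{h<=T'} rho(h))``.  The Gelman-Rubin
diagnostic is the classic multi-chain potential scale reduction factor,
without chain splitting.

The calibration harness repeats simulate -> infer -> summarize, recording
how often the truth falls inside posterior equal-tailed intervals, the RMSE
of posterior means, and interval lengths; the binomial uncertainty of a
coverage estimate from ``m`` trials is the normal-approximation band
``p +- 1.96 sqrt(p(1-p)/m)`` around the target level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import Parameters
from .mcmc import ChainConfig, run_chain
from .simulate import simulate_dataset
from .summaries import equal_tailed_interval, posterior_summary, tmrca_by_site

__all__ = ["autocorrelation", "t_prime", "ess", "gelman_rhat",
           "coverage_binomial_interval", "coverage_experiment"]


def autocorrelation(chain, max_lag: int) -> np.ndarray:
    """Empirical autocorrelations ``rho(1..max_lag)`` of a scalar chain."""
    x = np.asarray(chain, dtype=float)
    T = len(x)
    if T < 2:
        raise ValueError("chain must have length >= 2")
    if max_lag < 1 or max_lag > T - 1:
        raise ValueError("max_lag must be in 1..T-1")
    x = x - x.mean()
    c0 = np.dot(x, x) / T
    if c0 == 0:
        raise ValueError("autocorrelation undefined for a constant chain")
    return np.array([np.dot(x[:-h], x[h:]) / T / c0 for h in range(1, max_lag + 1)])


def t_prime(chain) -> int:
    """First lag ``h >= 1`` with ``rho(h) <= 0``.

    If no lag up to ``T-1`` qualifies (rare: the biased autocorrelations of
    any finite chain sum to -1/2, so a non-positive lag almost always
    exists), the maximum lag ``T-1`` is returned with a warning.
    """
    x = np.asarray(chain, dtype=float)
    rho = autocorrelation(x, len(x) - 1)
    idx = np.flatnonzero(rho <= 0)
    if idx.size == 0:
        import warnings
        warnings.warn("autocorrelation never reaches zero; T' set to T-1")
        return len(x) - 1
    return int(idx[0] + 1)


def ess(chain) -> float:
    """Effective sample size ``T / (1 + 2 sum_h rho(h))``.

    The sum runs over the initial run of strictly positive autocorrelations
    (all lags below ``T'``); when ``rho(1) <= 0`` the sum is empty and the
    estimate equals ``T``.  The truncation keeps the estimate positive and
    at most ``T`` for positively correlated chains.
    """
    x = np.asarray(chain, dtype=float)
    T = len(x)
    tp = t_prime(x)
    if tp <= 1:
        return float(T)
    rho = autocorrelation(x, tp - 1)
    return float(T / (1.0 + 2.0 * rho.sum()))


def gelman_rhat(chains) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is a sequence of >= 2 equal-length scalar chains from
    independent runs; values near 1 indicate agreement.
    """
    arr = [np.asarray(c, dtype=float) for c in chains]
    if len(arr) < 2:
        raise ValueError("need at least two chains")
    T = len(arr[0])
    if any(len(c) != T for c in arr):
        raise ValueError("chains must have equal length")
    m = len(arr)
    means = np.array([c.mean() for c in arr])
    variances = np.array([c.var(ddof=1) for c in arr])
    W = variances.mean()
    B = T * means.var(ddof=1)
    var_hat = (T - 1) / T * W + B / T
    return float(np.sqrt(var_hat / W))


def coverage_binomial_interval(m: int, level: float = 0.5):
    """Normal-approximation 95% band for a coverage estimate from m trials.

    Centred at the target ``level``: ``level +- 1.96 sqrt(level(1-level)/m)``.
    """
    half = 1.96 * np.sqrt(level * (1.0 - level) / m)
    return level - half, level + half


@dataclass
class CoverageResult:
    table: pd.DataFrame
    binomial_interval: tuple
    truths: pd.DataFrame
    estimates: pd.DataFrame


def coverage_experiment(replicates: int, n: int, L: int, params: Parameters,
                        chain_config: ChainConfig, level: float = 0.5,
                        seed=None) -> CoverageResult:
    """Simulate/infer/summarize calibration loop.

    For each replicate a dataset is simulated from the CwR, the sampler is
    run, and equal-tailed intervals at ``level`` are formed for the total
    branch length per site and the ancestral/non-ancestral recombination
    counts.  Reports, per quantity: coverage (fraction of replicates with
    the truth inside the interval), RMSE of the posterior mean against the
    truth, and mean interval length, plus the ``m``-trial binomial 95% band
    for the coverage.  Fully reproducible from the master seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    quantities = ["total_branch_length_per_site", "n_ancestral_recombinations",
                  "n_nonancestral_recombinations"]
    truth_rows, est_rows = [], []
    hits = {q: 0 for q in quantities}
    sqerr = {q: [] for q in quantities}
    lengths = {q: [] for q in quantities}
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        truth, data, _ = simulate_dataset(n, L, params, rng)
        cfg = ChainConfig(iterations=chain_config.iterations,
                          burn_in=chain_config.burn_in, thin=chain_config.thin,
                          weights=chain_config.weights,
                          seed=int(rng.integers(2 ** 31)))
        trace = run_chain(data, params, cfg)
        summ = posterior_summary(trace.samples, level=level)
        n_anc, n_non = truth.classify_recombinations()
        truths = {"total_branch_length_per_site":
                      truth.total_branch_length_sum() / L,
                  "n_ancestral_recombinations": n_anc,
                  "n_nonancestral_recombinations": n_non}
        truth_rows.append({"replicate": rep, **truths})
        est_rows.append({"replicate": rep,
                         **{q: summ.loc[q, "mean"] for q in quantities}})
        for q in quantities:
            lo, hi = summ.loc[q, "lower"], summ.loc[q, "upper"]
            if lo <= truths[q] <= hi:
                hits[q] += 1
            sqerr[q].append((summ.loc[q, "mean"] - truths[q]) ** 2)
            lengths[q].append(hi - lo)
    rows = []
    for q in quantities:
        rows.append({"quantity": q,
                     "coverage": hits[q] / replicates,
                     "rmse": float(np.sqrt(np.mean(sqerr[q]))),
                     "mean_interval_length": float(np.mean(lengths[q]))})
    return CoverageResult(table=pd.DataFrame(rows).set_index("quantity"),
                          binomial_interval=coverage_binomial_interval(
                              replicates, level),
                          truths=pd.DataFrame(truth_rows).set_index("replicate"),
                          estimates=pd.DataFrame(est_rows).set_index("replicate"))
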