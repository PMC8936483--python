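"""Model / Results interface for posterior ARG inference.

:class:`ArgInferenceModel` couples a binary haplotype dataset with the CwR
parameters (mu, r, N); :meth:`ArgInferenceModel.fit` runs the
Metropolis-Hastings sampler and returns an :class:`ArgInferenceResults`
carrying the trace, the retained ARG samples, posterior summaries with
equal-tailed intervals, and convergence diagnostics.

    >>> model = ArgInferenceModel(data, Parameters(mu=1e-8, r=1e-8, N=1e4))
    >>> res = model.fit(iterations=100_000, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ats import ATS
from .dataset import Dataset
from .density import Parameters
from .diagnostics import ess, t_prime
from .mcmc import ChainConfig, Trace, run_chain
from .moves import DEFAULT_WEIGHTS
from .summaries import (allele_age, equal_tailed_interval, posterior_summary,
                        recomb_rate_estimate, tmrca_by_site)

__all__ = ["ArgInferenceModel", "ArgInferenceResults"]


class ArgInferenceModel:
    """Bayesian ARG inference under the coalescent with recombination.

    Parameters
    ----------
    data : Dataset
        ``n`` binary haplotypes over ``L`` sites, ancestral allele coded 0.
    params : Parameters
        Fixed model parameters (mu, r, N); the ARG is the inferred object.
    """

    def __init__(self, data: Dataset, params: Parameters):
        self.data = data
        self.params = params

    @classmethod
    def from_tsv(cls, path, params: Parameters) -> "ArgInferenceModel":
        from .io import read_dataset
        return cls(read_dataset(path, fmt="matrix-tsv"), params)

    @classmethod
    def from_vcf(cls, path, params: Parameters, L=None) -> "ArgInferenceModel":
        from .io import read_dataset
        return cls(read_dataset(path, fmt="vcf", L=L), params)

    def fit(self, iterations: int = 2_000_000, burn_in: float = 0.20,
            thin: int = 400, weights=DEFAULT_WEIGHTS, seed=None,
            initial: "ATS | None" = None) -> "ArgInferenceResults":
        """Run the sampler; returns the results object."""
        cfg = ChainConfig(iterations=iterations, burn_in=burn_in, thin=thin,
                          weights=tuple(weights), seed=seed)
        trace = run_chain(self.data, self.params, cfg, initial=initial)
        return ArgInferenceResults(self, trace)


class ArgInferenceResults:
    """Posterior sample of ARGs with summaries and diagnostics."""

    def __init__(self, model: ArgInferenceModel, trace: Trace):
        self.model = model
        self.trace = trace
        self.samples = trace.samples

    # -- point summaries ---------------------------------------------------

    def summary(self, level: float = 0.5) -> pd.DataFrame:
        """Posterior means and equal-tailed intervals of ARG properties,
        with per-property effective sample sizes of the retained chain."""
        table = posterior_summary(self.samples, level=level)
        cols = {"total_branch_length_per_site": "total_branch_length",
                "n_ancestral_recombinations": "n_ancestral",
                "n_nonancestral_recombinations": "n_nonancestral"}
        ess_col, tp_col = [], []
        for q in table.index:
            col = cols.get(q)
            if col is None:
                ess_col.append(np.nan)
                tp_col.append(np.nan)
                continue
            vals = self.trace.retained(col)
            if np.ptp(vals) == 0:
                ess_col.append(np.nan)
                tp_col.append(np.nan)
            else:
                ess_col.append(ess(vals))
                tp_col.append(t_prime(vals))
        table["ess"] = ess_col
        table["t_prime"] = tp_col
        table.attrs["acceptance_rate"] = self.trace.acceptance_rate
        return table

    def tmrca(self, level: float = 0.5):
        """Posterior mean per-site TMRCA and equal-tailed band.

        Returns a DataFrame with columns mean/lower/upper, one row per site.
        """
        stack = np.vstack([tmrca_by_site(s) for s in self.samples])
        alpha = (1 - level) / 2
        lo, hi = np.quantile(stack, [alpha, 1 - alpha], axis=0)
        return pd.DataFrame({"mean": stack.mean(axis=0), "lower": lo, "upper": hi})

    def allele_ages(self, level: float = 0.5) -> pd.DataFrame:
        """Posterior mean age (branch midpoint) per segregating site."""
        sites = self.model.data.positions
        rows = []
        for site in sites:
            vals = [allele_age(s, site) for s in self.samples
                    if s.mutations is not None]
            lo, hi = equal_tailed_interval(vals, level) if len(vals) > 1 \
                else (vals[0], vals[0])
            rows.append({"site": site, "mean": float(np.mean(vals)),
                         "lower": lo, "upper": hi})
        return pd.DataFrame(rows).set_index("site")

    def recomb_rate(self) -> float:
        """Ratio estimator of r: posterior mean of (#ancestral
        recombinations / total branch length)."""
        return recomb_rate_estimate(self.samples)

    @property
    def acceptance_rate(self) -> float:
        return self.trace.acceptance_rate

    # -- plotting ----------------------------------------------------------

    def plot_trace(self, ax=None):
        """Trace plots of log posterior, total branch length and
        recombination counts."""
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(4, 1, figsize=(8, 9), sharex=True)
        t = self.trace
        for a, (name, vals) in zip(axes, [
                ("log posterior", t.log_posterior),
                ("total branch length / site", t.total_branch_length / t.L),
                ("# ancestral recombinations", t.n_ancestral),
                ("# non-ancestral recombinations", t.n_nonancestral)]):
            a.plot(vals, lw=0.5)
            a.set_ylabel(name)
        axes[-1].set_xlabel("iteration")
        fig.tight_layout()
        return fig

    def plot_tmrca(self, truth=None, level: float = 0.5):
        """Per-site posterior TMRCA band, optionally against the truth."""
        import matplotlib.pyplot as plt
        df = self.tmrca(level=level)
        fig, ax = plt.subplots(figsize=(9, 4))
        x = np.arange(len(df))
        ax.fill_between(x, df["lower"], df["upper"], alpha=0.3,
                        label=f"{int(level * 100)}% interval")
        ax.plot(x, df["mean"], label="posterior mean")
        if truth is not None:
            ax.plot(x, truth, "k--", label="truth")
        ax.set_xlabel("site")
        ax.set_ylabel("TMRCA (generations)")
        ax.legend()
        fig.tight_layout()
        return fig
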