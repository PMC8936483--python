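"""Posterior summaries of sampled ARGs.

All functions here are pure functions of retained samples: per-site TMRCA,
allele ages (the midpoint of the branch carrying a site's mutation),
recombination counts, the ratio estimator of the recombination rate, and
equal-tailed credible intervals with linear-interpolation quantiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ats import ATS, _contains

__all__ = [
    "tmrca_by_site",
    "allele_age",
    "recomb_rate_estimate",
    "equal_tailed_interval",
    "posterior_summary",
]


def tmrca_by_site(ats: ATS) -> np.ndarray:
    """Root time of the marginal tree at every site, in generations.

    The TMRCA is piecewise constant between recombination breakpoints, so
    one tree traversal per breakpoint interval suffices.
    """
    an = ats._require_valid()
    cuts = sorted({0} | {rec.breakpoint + 1 for rec in ats.recs
                         if rec.breakpoint + 1 < ats.L})
    out = np.empty(ats.L)
    for i, left in enumerate(cuts):
        right = cuts[i + 1] if i + 1 < len(cuts) else ats.L
        out[left:right] = ats.marginal_tree(left).tmrca
    return out


def allele_age(ats: ATS, site: int) -> float:
    """Age of the derived allele at ``site``: the midpoint of the branch
    carrying its mutation, ``(t_child + t_parent) / 2`` in generations."""
    if ats.mutations is None:
        raise ValueError("ATS has no mutation table; run assign_mutations first")
    for m in ats.mutations:
        if m.site == site:
            an = ats._require_valid()
            u = m.branch
            return 0.5 * (ats.node_time[u] + an.death[u])
    raise ValueError(f"site {site} is not segregating in the mutation table")


def recomb_rate_estimate(samples) -> float:
    """Ratio estimator of the per-site per-generation recombination rate.

    The posterior mean over retained ARGs of the number of *ancestral*
    recombinations divided by the site-summed total branch length
    ``sum_v l_v g_v``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty trace")
    vals = []
    for ats in samples:
        n_anc, _ = ats.classify_recombinations()
        _, total = ats.total_branch_length()
        vals.append(n_anc / total)
    return float(np.mean(vals))


def equal_tailed_interval(samples, level: float):
    """Equal-tailed interval of ``samples`` at coverage ``level``.

    Empirical quantiles at ``(1-level)/2`` and ``1-(1-level)/2`` with linear
    interpolation between order statistics.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def posterior_summary(samples, level: float = 0.5, data=None) -> pd.DataFrame:
    """Posterior means and equal-tailed intervals over retained ARGs.

    One row per summarized quantity: total branch length per site, numbers
    of ancestral and non-ancestral recombinations, mean per-site TMRCA, and
    (when the samples carry mutation tables) the mean allele age.  With a
    single retained sample the intervals are zero-width.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty retained sample")
    cols = {"total_branch_length_per_site": [], "n_ancestral_recombinations": [],
            "n_nonancestral_recombinations": [], "mean_tmrca": [],
            "mean_allele_age": []}
    for ats in samples:
        per_site, total = ats.total_branch_length()
        cols["total_branch_length_per_site"].append(total / ats.L)
        n_anc, n_tnam = ats.classify_recombinations()
        cols["n_ancestral_recombinations"].append(n_anc)
        cols["n_nonancestral_recombinations"].append(n_tnam)
        cols["mean_tmrca"].append(tmrca_by_site(ats).mean())
        if ats.mutations:
            ages = [allele_age(ats, m.site) for m in ats.mutations]
            cols["mean_allele_age"].append(float(np.mean(ages)))
    rows = []
    single = len(samples) < 2
    for name, vals in cols.items():
        if not vals:
            continue
        mean = float(np.mean(vals))
        if single:
            lo = hi = mean
        else:
            lo, hi = equal_tailed_interval(vals, level)
        rows.append({"quantity": name, "mean": mean, "lower": lo, "upper": hi})
    return pd.DataFrame(rows).set_index("quantity")
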