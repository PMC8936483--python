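"""Exact densities under the coalescent with recombination (CwR).

The prior density of an ARG with events at times ``t_1 < ... < t_E`` is a
product over events of competing-exponential terms.  Writing ``k_i`` for the
number of lineages and ``k'_i`` for the number of recombination links (gaps
between carried sites, spanning ancestral and trapped material alike) just
before event ``i``, the total event rate is

    lambda_i = k_i (k_i - 1) / (4N) + r k'_i ,

and each event contributes ``exp(-lambda_i * w_i) / (2N)`` for a
common-ancestor event or ``r * exp(-lambda_i * w_i)`` for a recombination,
``w_i`` being the waiting time since the previous event.

The likelihood uses the discretized infinite-sites model.  With ``T`` the
set of distinct branches, ``l_v`` a branch's length in generations, ``g_v``
the number of ancestral sites it spans and ``|m_v|`` its mutation count,

    P(D | G) = (1/M!) * prod_v exp(-l_v g_v mu) (l_v mu)^{|m_v|} ,

which equals the site-by-site Poisson-thinning probability of the observed
binary patterns.  ``M`` is the total mutation count (the number of
segregating sites); the ``1/M!`` factor is constant given the data and
cancels from all Metropolis-Hastings ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ats import ATS
from .dataset import Dataset

__all__ = [
    "Parameters",
    "EventSequence",
    "event_sequence",
    "log_prior",
    "log_likelihood",
    "log_posterior",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Parameters:
    """Model parameters: per-site per-generation mutation and recombination
    rates and the haploid effective population size."""

    mu: float
    r: float
    N: float

    def __post_init__(self):
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")
        if self.N <= 0:
            raise ValueError("N must be positive")


@dataclass(frozen=True)
class EventSequence:
    """Time-ordered event bookkeeping for the CwR prior.

    Arrays are aligned per event: waiting time since the previous event,
    lineage count ``k`` and link count ``k'`` just before the event, and the
    indicator ``ic`` (1 = common ancestor, 0 = recombination).
    """

    waits: np.ndarray
    k: np.ndarray
    kp: np.ndarray
    ic: np.ndarray

    def __post_init__(self):
        for name in ("waits", "k", "kp", "ic"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.waits) == len(self.k) == len(self.kp) == len(self.ic)):
            raise ValueError("event arrays must have equal length")
        if np.any(self.waits <= 0):
            raise ValueError("waiting times must be strictly positive")

    def __len__(self):
        return len(self.waits)


def event_sequence(ats: ATS) -> EventSequence:
    """Extract the event sequence of a valid ATS, sorted by time."""
    an = ats.analysis
    if not an.ok:
        raise ValueError("invalid ATS: " + "; ".join(an.violations[:3]))
    return EventSequence(waits=an.waits, k=an.k, kp=an.kp, ic=an.ic)


def _event_terms(events: EventSequence, params: Parameters) -> np.ndarray:
    lam = events.k * (events.k - 1.0) / (4.0 * params.N) + params.r * events.kp
    with np.errstate(divide="ignore"):
        log_r = math.log(params.r) if params.r > 0 else NEG_INF
    type_term = np.where(events.ic == 1.0, -math.log(2.0 * params.N), log_r)
    return -lam * events.waits + type_term


def log_prior(events: EventSequence, params: Parameters) -> float:
    """Log CwR prior density of an event sequence (``-inf`` allowed).

    A recombination event under ``r = 0`` has zero density.
    """
    terms = _event_terms(events, params)
    if np.any(np.isneginf(terms)):
        return NEG_INF
    return float(np.sum(terms))


def log_prior_ats(ats: ATS, params: Parameters) -> float:
    return log_prior(event_sequence(ats), params)


def log_likelihood(ats: ATS, data: Dataset, params: Parameters) -> float:
    """Discretized infinite-sites log likelihood of ``data`` given the ARG.

    Requires a mutation assignment consistent with the data: uses the ATS's
    cached mutation table when present, otherwise computes one.  Raises
    ``ValueError`` if the ARG is incompatible (callers that want a zero
    likelihood instead should use :func:`log_posterior`).
    """
    muts = ats.mutations
    if muts is None:
        muts = ats.assign_mutations(data)
        if muts is None:
            raise ValueError("ARG is incompatible with the dataset")
        ats.mutations = muts
    an = ats._require_valid()
    mu = params.mu
    total = -math.lgamma(data.M + 1)
    for u, m in an.mat.items():
        l = an.death[u] - ats.node_time[u]
        g = sum(r - a for a, r, _ in m)
        total -= l * g * mu
    for rec in muts:
        l = an.death[rec.branch] - ats.node_time[rec.branch]
        if l * mu <= 0:
            return NEG_INF
        total += math.log(l * mu)
    return total


def log_posterior(ats: ATS, data: Dataset, params: Parameters) -> float:
    """Log unnormalized posterior; ``-inf`` for invalid or incompatible ARGs."""
    if not ats.is_valid:
        return NEG_INF
    if ats.mutations is None:
        muts = ats.assign_mutations(data)
        if muts is None:
            return NEG_INF
        ats.mutations = muts
    lp = log_prior_ats(ats, params)
    if lp == NEG_INF:
        return NEG_INF
    return lp + log_likelihood(ats, data, params)
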