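"""Backwards-in-time simulation of the coalescent with recombination.

Implements Hudson's algorithm on a discrete genome of ``L`` sites in
"little ARG" form: common-ancestor events occur at rate ``1/(2N)`` per
lineage pair, recombination at rate ``r`` per link per lineage (a lineage's
links being the gaps inside its carried span, so lineages spanning a single
site cannot recombine), breakpoints uniform on the lineage's links.  Genomic
segments are dropped as soon as they reach their sample-wide MRCA and
lineages of pure non-ancestral material are never created; the process stops
when every site has found its MRCA.

Mutations are dropped on the resulting ARG as a Poisson process with rate
``mu`` per ancestral site per generation along branches; datasets in which
any site receives more than one mutation violate the discretized
infinite-sites model and are rejected and resimulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ats import ATS, _clip, _first_last, _gsize, _merge, _span_links
from .dataset import Dataset
from .density import EventSequence, Parameters

__all__ = [
    "simulate_arg",
    "simulate_arg_with_log",
    "drop_mutations",
    "simulate_dataset",
    "prior_reference_summaries",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_arg_with_log(n: int, L: int, params: Parameters, seed=None):
    """Simulate a little ARG; returns ``(ats, event_sequence)``.

    The event sequence is the simulator's own bookkeeping (waiting times,
    lineage counts, link counts, event types), recorded as the events are
    generated; it must agree field-by-field with the sequence re-derived
    from the returned ATS.
    """
    rng = _as_rng(seed)
    if n < 1 or L < 1:
        raise ValueError("need n >= 1 and L >= 1")
    ats = ATS(L, n)
    r, N = params.r, params.N
    alive = {}
    for i in range(n):
        if n > 1:
            alive[i] = ((0, L, 1),)
    t = 0.0
    waits, ks, kps, ics = [], [], [], []
    while len(alive) >= 2:
        k = len(alive)
        links = {u: _span_links(m) for u, m in alive.items()}
        total_links = sum(links.values())
        ca_rate = k * (k - 1) / (4.0 * N)
        rec_rate = r * total_links
        lam = ca_rate + rec_rate
        w = rng.exponential(1.0 / lam)
        t += w
        waits.append(w)
        ks.append(k)
        kps.append(total_links)
        if rng.random() < ca_rate / lam:
            ics.append(1)
            ids = list(alive)
            ia, ib = rng.choice(len(ids), size=2, replace=False)
            a, b = ids[ia], ids[ib]
            p = ats.add_ca(t, a, b)
            merged, _ = _merge(alive.pop(a), alive.pop(b), n)
            if merged:
                alive[p] = merged
        else:
            ics.append(0)
            ids = list(alive)
            weights = np.array([links[u] for u in ids], dtype=float)
            u = ids[rng.choice(len(ids), p=weights / weights.sum())]
            m = alive.pop(u)
            f, last = _first_last(m)
            b = int(f + rng.integers(last - f))  # link in [f, last-1]
            rec = ats.add_rec(t, u, b)
            alive[rec.left_parent] = _clip(m, 0, b + 1)
            alive[rec.right_parent] = _clip(m, b + 1, L)
    log = EventSequence(waits=waits, k=ks, kp=kps, ic=ics) if waits else None
    return ats, log


def simulate_arg(n: int, L: int, params: Parameters, seed=None) -> ATS:
    """Simulate a little ARG under the CwR (see module docstring)."""
    ats, _ = simulate_arg_with_log(n, L, params, seed)
    return ats


def drop_mutations(ats: ATS, mu: float, seed=None, return_count: bool = False):
    """Drop mutations on an ARG; returns a :class:`Dataset` or ``None``.

    ``None`` signals rejection: some site received more than one mutation,
    violating the discretized infinite-sites model.  With ``return_count``
    the result is a ``(dataset-or-None, number of mutation events)`` pair;
    the count is recorded whether or not the draw is rejected (the
    *unconditional* mutation count is what coalescent expectations such as
    Watterson's refer to).
    """
    def _ret(dataset, count):
        return (dataset, count) if return_count else dataset

    rng = _as_rng(seed)
    an = ats._require_valid()
    lineages = list(an.mat)
    if not lineages:
        return _ret(Dataset(n=ats.n, L=ats.L, seg={}) if ats.n >= 2 else None, 0)
    weights = np.array(
        [(an.death[u] - ats.node_time[u]) * _gsize(an.mat[u]) for u in lineages])
    total = weights.sum() * mu
    n_mut = rng.poisson(total) if total > 0 else 0
    if n_mut == 0:
        return _ret(Dataset(n=ats.n, L=ats.L, seg={}), 0)
    picks = rng.choice(len(lineages), size=n_mut, p=weights / weights.sum())
    sites = {}
    collided = False
    for idx in picks:
        u = lineages[idx]
        m = an.mat[u]
        seg_lens = np.array([r - l for l, r, _ in m], dtype=float)
        si = rng.choice(len(m), p=seg_lens / seg_lens.sum()) if len(m) > 1 else 0
        site = int(m[si][0] + rng.integers(m[si][1] - m[si][0]))
        if site in sites:
            collided = True  # > 1 mutation at a site
        sites[site] = u
    if collided:
        return _ret(None, int(n_mut))
    seg = {}
    for site, u in sites.items():
        ls = ats._leaf_sets_at_site(site)
        carriers = ls[u]
        if carriers and len(carriers) < ats.n:
            seg[site] = carriers
        else:  # pragma: no cover - cannot happen: lineages carry proper subsets
            raise AssertionError("mutation on a non-proper carrier set")
    return _ret(Dataset(n=ats.n, L=ats.L, seg=seg), int(n_mut))


def simulate_dataset(n: int, L: int, params: Parameters, seed=None):
    """Simulate ``(truth ATS, dataset, rejection count)``.

    Re-runs ARG simulation and mutation dropping until a dataset satisfying
    the one-mutation-per-site rule is produced, counting rejected draws.
    """
    rng = _as_rng(seed)
    rejections = 0
    while True:
        ats = simulate_arg(n, L, params, rng)
        data = drop_mutations(ats, params.mu, rng)
        if data is not None:
            ats.mutations = ats.assign_mutations(data)
            return ats, data, rejections
        rejections += 1


def prior_reference_summaries(n: int, L: int, params: Parameters, reps: int,
                              seed=None) -> dict:
    """Empirical prior distributions of ARG summaries from direct simulation.

    Returns per-replicate arrays of the number of recombination events, the
    site-summed total branch length, and the mean per-site TMRCA — the
    reference against which prior-targeting MCMC output is compared.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _as_rng(seed)
    n_rec = np.empty(reps)
    total_bl = np.empty(reps)
    mean_tmrca = np.empty(reps)
    for i in range(reps):
        ats = simulate_arg(n, L, params, rng)
        n_rec[i] = ats.num_recombinations
        per_site, total = ats.total_branch_length()
        total_bl[i] = total
        roots = _tmrca_array(ats)
        mean_tmrca[i] = roots.mean()
    return {"n_recombinations": n_rec, "total_branch_length": total_bl,
            "mean_tmrca": mean_tmrca}


def _tmrca_array(ats: ATS) -> np.ndarray:
    # local import to avoid a cycle
    from .summaries import tmrca_by_site
    return tmrca_by_site(ats)
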