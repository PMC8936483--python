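"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's derived-state machinery: they
work directly off the raw node/CA/recombination tables by following each
sample's ancestry path site by site, so they provide an independent check
of marginal trees, branch lengths, materials and likelihoods.
"""

import math

import numpy as np
import pytest

from argmc import Parameters
from argmc.ats import ATS


@pytest.fixture
def paper_params():
    """The reference simulation parameters (R = mu/r = 1)."""
    return Parameters(mu=1e-8, r=1e-8, N=1e4)


# ---------------------------------------------------------------------------
# oracle: per-site tree by path following
# ---------------------------------------------------------------------------

def oracle_parent_at(ats: ATS, u: int, site: int):
    """Parent of node u at a site, read straight from the tables."""
    for P, (a, b) in ats.ca_children.items():
        if u in (a, b):
            return P
    for rec in ats.recs:
        if rec.child == u:
            return rec.left_parent if site <= rec.breakpoint else rec.right_parent
    return None


def oracle_site_tree(ats: ATS, site: int):
    """(edges, mrca) of the marginal tree at ``site``.

    Edges are (child, parent) pairs on the paths from each sample up to the
    site's MRCA (the lowest node common to all paths).
    """
    paths = {}
    for i in range(ats.n):
        path = [i]
        u = i
        while True:
            p = oracle_parent_at(ats, u, site)
            if p is None:
                break
            path.append(p)
            u = p
        paths[i] = path
    common = set(paths[0])
    for i in range(1, ats.n):
        common &= set(paths[i])
    mrca = min(common, key=lambda u: ats.node_time[u])
    edges = set()
    for path in paths.values():
        idx = path.index(mrca)
        for c, p in zip(path[:idx], path[1:idx + 1]):
            edges.add((c, p))
    return edges, mrca


def oracle_site_branch_length(ats: ATS, site: int) -> float:
    edges, _ = oracle_site_tree(ats, site)
    return sum(ats.node_time[p] - ats.node_time[c] for c, p in edges)


def oracle_material(ats: ATS, u: int):
    """Sites for which lineage ``u`` is ancestral (below the site's MRCA)."""
    out = set()
    for site in range(ats.L):
        edges, _ = oracle_site_tree(ats, site)
        if any(c == u for c, _ in edges):
            out.add(site)
    return out


def oracle_leafset(ats: ATS, u: int, site: int):
    edges, _ = oracle_site_tree(ats, site)
    children = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)
    out = set()
    stack = [u]
    while stack:
        v = stack.pop()
        if v < ats.n:
            out.add(v)
        stack.extend(children.get(v, []))
    return frozenset(out)


def oracle_log_likelihood(ats: ATS, data, mu: float) -> float:
    """Site-by-site Poisson-thinning log likelihood (brute force)."""
    mut_branch = {m.site: m.branch for m in ats.mutations}
    total = -math.lgamma(data.M + 1)
    for site in range(ats.L):
        edges, _ = oracle_site_tree(ats, site)
        for c, p in edges:
            total -= (ats.node_time[p] - ats.node_time[c]) * mu
        if site in data.seg:
            u = mut_branch[site]
            p = next(p for c, p in edges if c == u)
            total += math.log((ats.node_time[p] - ats.node_time[u]) * mu)
    return total


# ---------------------------------------------------------------------------
# oracle: Hudson-Kaplan minimum recombination bound
# ---------------------------------------------------------------------------

def hk_bound(data) -> int:
    """Hudson-Kaplan lower bound R_m by interval dynamic programming.

    Incompatible site pairs define open intervals that must each contain a
    breakpoint; R_m is the maximum number of pairwise disjoint intervals.
    """
    from argmc import incompatible_pairs
    intervals = sorted(incompatible_pairs(data), key=lambda ab: ab[1])
    best = 0
    last_end = -1
    for a, b in intervals:
        if a >= last_end:  # disjoint as open intervals (a, b)
            best += 1
            last_end = b
    return best


@pytest.fixture
def oracle():
    class Oracle:
        parent_at = staticmethod(oracle_parent_at)
        site_tree = staticmethod(oracle_site_tree)
        site_branch_length = staticmethod(oracle_site_branch_length)
        material = staticmethod(oracle_material)
        leafset = staticmethod(oracle_leafset)
        log_likelihood = staticmethod(oracle_log_likelihood)
        hk_bound = staticmethod(hk_bound)
    return Oracle
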