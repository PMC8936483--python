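"""Construction of an initial ARG compatible with the data.

The Markov chain needs a starting ARG with positive posterior density,
which requires every segregating site's derived-carrier set to be a clade
of the marginal tree at that site.  Most ARGs are incompatible with a given
dataset, so the initial state is built constructively:

1. scan the genome left to right, greedily splitting it into maximal
   intervals ("blocks") whose carrier sets are pairwise nested or disjoint
   (a laminar family), which is exactly the condition for a rooted perfect
   phylogeny with a known ancestral allele;
2. build one tree per block: the containment order of the distinct carrier
   sets fixes its clades, remaining joins are resolved at random, and event
   times are drawn from pure-coalescent waiting times assigned along a
   random linear extension of the tree's ranking;
3. split every sample lineage at every block boundary by a recombination at
   a recent time, so each block's material coalesces independently along
   its own tree.

The result always validates and always admits a mutation assignment, and
its recombination count ``n*(B-1)`` (for ``B`` blocks) is at least the
Hudson-Kaplan lower bound ``R_m <= B-1``.  The chain's stationary
distribution does not depend on this choice of initializer.
"""

from __future__ import annotations

import itertools

import numpy as np

from .ats import ATS
from .dataset import Dataset
from .density import Parameters

__all__ = ["incompatible_pairs", "build_initial_arg"]


def incompatible_pairs(data: Dataset) -> set:
    """Site pairs failing the four-gamete test.

    A pair ``(a, b)`` (with ``a < b``) is returned iff all four gamete
    patterns 00, 01, 10, 11 occur across the two sites — impossible on a
    single tree under the infinite-sites model, hence evidence of a
    recombination between them.
    """
    out = set()
    full = frozenset(range(data.n))
    sites = data.positions
    for a, b in itertools.combinations(sites, 2):
        ca, cb = data.seg[a], data.seg[b]
        has11 = bool(ca & cb)
        has10 = bool(ca - cb)
        has01 = bool(cb - ca)
        has00 = (ca | cb) != full
        if has00 and has01 and has10 and has11:
            out.add((a, b))
    return out


def _laminar_conflict(ca, cb) -> bool:
    """Crossing carrier sets: no rooted tree holds both as clades."""
    return bool(ca & cb) and bool(ca - cb) and bool(cb - ca)


def _blocks(data: Dataset) -> list:
    """Greedy maximal laminar blocks, as lists of sites; covers [0, L)."""
    sites = data.positions
    if not sites:
        return [[]]
    blocks = [[sites[0]]]
    block_sets = [{data.seg[sites[0]]}]
    for s in sites[1:]:
        cs = data.seg[s]
        if any(_laminar_conflict(cs, t) for t in block_sets[-1]):
            blocks.append([s])
            block_sets.append({cs})
        else:
            blocks[-1].append(s)
            block_sets[-1].add(cs)
    return blocks


def _block_tree_joins(carrier_sets, n, rng):
    """Join order (pairs of clades) for one block's perfect phylogeny.

    Returns a list of (left frozenset, right frozenset) merges ending in the
    full sample set; every carrier set appears as a clade.
    """
    clades = [frozenset((i,)) for i in range(n)]
    ordered = sorted({c for c in carrier_sets if len(c) > 1}, key=len)
    for target in ordered + [frozenset(range(n))]:
        if target in clades:
            continue
        merges = []
        parts = [c for c in clades if c <= target]
        rest = [c for c in clades if not c <= target]
        if frozenset().union(*parts) != target:  # pragma: no cover
            raise AssertionError("carrier sets are not laminar")
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(j)
            a = parts.pop(i)
            merges.append((a, b))
            parts.append(a | b)
        clades = rest + parts
        yield from merges
    if len(clades) > 1:  # pragma: no cover
        raise AssertionError("tree construction did not finish")


def _coalescent_times(n, N, rng):
    """Times of the n-1 coalescences of a pure coalescent, ascending."""
    t = 0.0
    out = []
    for k in range(n, 1, -1):
        t += rng.exponential(4.0 * N / (k * (k - 1)))
        out.append(t)
    return out


def build_initial_arg(data: Dataset, params: Parameters, seed=None) -> ATS:
    """Build a valid ARG compatible with ``data`` (positive likelihood).

    Seed-controlled; raises ``ValueError`` if the dataset cannot be
    represented (which for binary data with a known ancestral allele does
    not happen).
    """
    rng = np.random.default_rng(seed)
    n, L = data.n, data.L
    blocks = _blocks(data)
    # boundary x_j = first site of block j+1; breakpoint at link x_j - 1
    boundaries = [blk[0] for blk in blocks[1:]]

    # draw per-block join orders and event times, ensuring distinct times
    joins_per_block = []
    times_per_block = []
    taken = {0.0}
    for blk in blocks:
        carrier_sets = [data.seg[s] for s in blk]
        joins = list(_block_tree_joins(carrier_sets, n, rng))
        while True:
            times = _coalescent_times(n, params.N, rng)
            if all(t not in taken for t in times):
                break
        taken.update(times)
        joins_per_block.append(joins)
        times_per_block.append(times)

    ats = ATS(L, n)
    # recombination chains: split every sample at every boundary,
    # at recent times below every coalescence
    t_floor = min(min(t) for t in times_per_block)
    piece = {}  # (sample, block index) -> node id carrying that block's material
    n_bound = len(boundaries)
    for i in range(n):
        while True:
            t_recs = sorted(0.9 * t_floor * rng.random(n_bound))
            if (len(set(t_recs)) == n_bound
                    and all(t not in taken for t in t_recs)):
                break
        taken.update(t_recs)
        current = i
        for j, x in enumerate(boundaries):
            rec = ats.add_rec(t_recs[j], current, x - 1)
            piece[(i, j)] = rec.left_parent
            current = rec.right_parent
        piece[(i, len(boundaries))] = current

    # per-block coalescent trees over the piece lineages
    for j, (joins, times) in enumerate(zip(joins_per_block, times_per_block)):
        node_of = {frozenset((i,)): piece[(i, j)] for i in range(n)}
        # joins were generated in a valid order but interleave by clade;
        # assign ascending coalescent times along that order
        for (a, b), t in zip(joins, sorted(times)):
            p = ats.add_ca(t, node_of[a], node_of[b])
            node_of[a | b] = p

    violations = ats.validate()
    if violations:  # pragma: no cover
        raise AssertionError("initial ARG invalid: " + "; ".join(violations[:3]))
    muts = ats.assign_mutations(data)
    if muts is None:  # pragma: no cover
        raise AssertionError("initial ARG incompatible with the data")
    ats.mutations = muts
    return ats
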