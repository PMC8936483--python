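"""The augmented tree sequence (ATS).

An ATS is a table-based representation of an ancestral recombination graph
(ARG) realized under the coalescent with recombination.  Like a succinct tree
sequence it stores each branch shared by neighbouring marginal trees only
once; on top of that it records every event of the underlying process —
common-ancestor (CA) events, including non-coalescing ones, and recombination
events with their breakpoints and times — plus the assignment of each
segregating site's mutation to a branch.  It is the state of the Markov chain
in posterior sampling.

Coordinates are 0-based; genomic intervals are half-open ``[left, right)``;
recombination breakpoints are *links*, link ``b`` being the gap between sites
``b`` and ``b+1`` (``b`` in ``0..L-2``).

The graph is encoded by three primitives:

* a node table (id, time, kind in {sample, common_ancestor, recombination}),
* for each CA node, its two child nodes,
* a recombination record per recombination event: the child node, the
  breakpoint link, and the two parent nodes created by the event (both carry
  the event time).  The left parent receives the child's material strictly
  left of the breakpoint, the right parent the rest.

Everything else — the ancestral-material segments carried by each branch,
trapped non-ancestral material (TNAM), event ordering, lineage and link
counts, marginal trees, and validity — is *derived* deterministically from
these tables by a single bottom-up replay (:meth:`ATS.analysis`).  A lineage
(equivalently a distinct branch) is identified by its child node: it extends
from the child's birth time to the time of the event that consumes it.

This module only represents ARGs in "little ARG" form: lineages carrying no
ancestral material are never created, and genomic segments are dropped from
a lineage as soon as they reach their sample-wide MRCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .dataset import Dataset

__all__ = [
    "ANCESTRAL",
    "TRAPPED",
    "Segment",
    "Node",
    "RecombinationRecord",
    "MutationRecord",
    "MarginalTree",
    "ATS",
]

ANCESTRAL = "ancestral"
TRAPPED = "trapped"

SAMPLE = "sample"
COMMON_ANCESTOR = "common_ancestor"
RECOMBINATION = "recombination"


class Segment(NamedTuple):
    """A half-open genomic interval ``[left, right)`` of one material kind."""

    left: int
    right: int
    material: str = ANCESTRAL


@dataclass(frozen=True)
class Node:
    id: int
    time: float
    kind: str


@dataclass(frozen=True)
class RecombinationRecord:
    """One recombination event.

    The child lineage is cut at link ``breakpoint``; ``left_parent`` receives
    the child's material in ``[0, breakpoint+1)`` and ``right_parent`` the
    material in ``[breakpoint+1, L)``.  Both parent nodes carry the event
    time.
    """

    child: int
    breakpoint: int
    left_parent: int
    right_parent: int


@dataclass(frozen=True)
class MutationRecord:
    """A mutation at ``site`` on the branch whose child node is ``branch``."""

    site: int
    branch: int
    carriers: frozenset


# ---------------------------------------------------------------------------
# segment arithmetic: material is a tuple of (left, right, count) triples,
# disjoint, sorted; count = number of samples the interval is ancestral to.
# ---------------------------------------------------------------------------

def _clip(mat, lo, hi):
    """Intersect material with [lo, hi)."""
    out = []
    for l, r, c in mat:
        if r <= lo or l >= hi:
            continue
        out.append((max(l, lo), min(r, hi), c))
    return tuple(out)


def _merge(mat_a, mat_b, n):
    """Merge two lineages' material, adding counts where they overlap.

    Segments whose count reaches ``n`` have found their sample-wide MRCA and
    are dropped.  Returns ``(merged, coalesced)`` where ``coalesced`` is True
    if any site was shared by both inputs (a coalescence, as opposed to a
    plain common-ancestor event).
    """
    # sweep over breakpoints of both inputs
    events = []
    for l, r, c in mat_a:
        events.append((l, c))
        events.append((r, -c))
    for l, r, c in mat_b:
        events.append((l, c))
        events.append((r, -c))
    events.sort()
    out = []
    coalesced = False
    depth = 0
    # walk distinct positions, tracking current total count
    i = 0
    m = len(events)
    prev_pos = None
    while i < m:
        pos = events[i][0]
        if prev_pos is not None and depth > 0 and pos > prev_pos:
            if depth < n:
                if out and out[-1][1] == prev_pos and out[-1][2] == depth:
                    out[-1] = (out[-1][0], pos, depth)
                else:
                    out.append((prev_pos, pos, depth))
        while i < m and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        prev_pos = pos
    # coalescence detection: any overlap between inputs
    ai = bi = 0
    while ai < len(mat_a) and bi < len(mat_b):
        al, ar, _ = mat_a[ai]
        bl, br, _ = mat_b[bi]
        if al < br and bl < ar:
            coalesced = True
            break
        if ar <= br:
            ai += 1
        else:
            bi += 1
    return tuple(out), coalesced


def _first_last(mat):
    """(first site, last site) carried, both inclusive."""
    return mat[0][0], mat[-1][1] - 1


def _span_links(mat):
    """Number of links in the lineage's span (ancestral + trapped)."""
    f, last = _first_last(mat)
    return last - f


def _gsize(mat):
    """Number of ancestral sites carried."""
    return sum(r - l for l, r, _ in mat)


def _contains(mat, site):
    for l, r, _ in mat:
        if l <= site < r:
            return True
    return False


# ---------------------------------------------------------------------------


@dataclass
class _Analysis:
    """Everything derived from the tables by one bottom-up replay."""

    ok: bool
    violations: list
    parent_slot: dict            # node id -> ("ca", P) | ("rec", rec_index) | None
    events: list                 # [(time, kind 'ca'|'rec', payload)], time-sorted
    mat: dict                    # lineage child id -> material (consumed nodes only)
    death: dict                  # lineage child id -> time of consuming event
    waits: list                  # per event: waiting time since previous event
    k: list                      # lineage count just before each event
    kp: list                     # link count just before each event
    ic: list                     # 1 = CA, 0 = recombination
    rec_class: list              # per recombination record: classification string
    coalescing: dict             # CA node id -> bool (did material coalesce)
    dead: set                    # nodes born carrying no onward material (roots)


class MarginalTree:
    """The genealogical tree embedded at a single site.

    Retains the full chain of nodes through which the site's ancestry passes
    (including nodes that are unary at this site); ``parent`` maps each
    non-root node in the chain to the next node rootward.
    """

    def __init__(self, site, parent, times, samples):
        self.site = site
        self.parent = dict(parent)
        self.times = dict(times)
        self.samples = list(samples)
        children = {}
        for c, p in self.parent.items():
            children.setdefault(p, []).append(c)
        self.children = children
        roots = [u for u in self.times if u not in self.parent]
        if len(roots) != 1:
            raise AssertionError(f"marginal tree at site {site} has roots {roots}")
        self.root = roots[0]

    @property
    def tmrca(self):
        return self.times[self.root]

    def leaf_set(self, u):
        """Samples at or below ``u``."""
        out = set()
        stack = [u]
        while stack:
            v = stack.pop()
            kids = self.children.get(v)
            if kids:
                stack.extend(kids)
            else:
                out.add(v)
        return frozenset(out)

    @property
    def total_branch_length(self):
        return sum(self.times[self.parent[c]] - self.times[c] for c in self.parent)

    def key(self):
        """Canonical form ignoring unary pass-through nodes.

        The frozenset of ``(leaf clade, node time)`` over the root and every
        node with >= 2 children in this tree; two marginal trees are equal as
        genealogies iff their keys are equal.
        """
        items = set()
        for u in self.times:
            kids = self.children.get(u, [])
            if len(kids) >= 2 or u == self.root:
                items.add((self.leaf_set(u), self.times[u]))
        return frozenset(items)

    def newick(self) -> str:
        def rec(u):
            kids = self.children.get(u, [])
            kids = [k for k in kids]
            if not kids:
                return f"{u}"
            if len(kids) == 1:  # contract unary chain
                return rec(kids[0])
            parts = []
            for k in kids:
                sub = rec(k)
                # branch length from the nearest retained descendant
                v = k
                while len(self.children.get(v, [])) == 1:
                    v = self.children[v][0]
                parts.append(f"{sub}:{self.times[u] - self.times[v]:.8g}")
            return "(" + ",".join(parts) + ")"
        return rec(self.root) + ";"


class ATS:
    """Augmented tree sequence over ``n`` samples and ``L`` sites.

    Samples are nodes ``0..n-1`` at time 0.  The object is cheap to copy;
    Monte-Carlo moves operate on copies and derived state is (re)computed
    lazily.
    """

    __slots__ = ("L", "n", "node_time", "node_kind", "ca_children", "recs",
                 "next_id", "mutations", "_an")

    def __init__(self, L: int, n: int):
        if n < 1:
            raise ValueError("an ATS needs at least one sample")
        if L < 1:
            raise ValueError("L must be positive")
        self.L = L
        self.n = n
        self.node_time = {i: 0.0 for i in range(n)}
        self.node_kind = {i: SAMPLE for i in range(n)}
        self.ca_children: dict = {}
        self.recs: list = []
        self.next_id = n
        self.mutations: Optional[list] = None
        self._an: Optional[_Analysis] = None

    # -- construction -----------------------------------------------------

    def new_node(self, time: float, kind: str) -> int:
        u = self.next_id
        self.next_id += 1
        self.node_time[u] = float(time)
        self.node_kind[u] = kind
        self._an = None
        return u

    def add_ca(self, time: float, u: int, v: int, node_id: "int | None" = None) -> int:
        """Add a common-ancestor event merging lineages ``u`` and ``v``."""
        if node_id is None:
            p = self.new_node(time, COMMON_ANCESTOR)
        else:
            p = self._new_node_with_id(node_id, time, COMMON_ANCESTOR)
        self.ca_children[p] = (u, v)
        self._an = None
        return p

    def add_rec(self, time: float, child: int, breakpoint: int,
                ids: "tuple[int, int] | None" = None) -> RecombinationRecord:
        """Add a recombination event splitting ``child`` at link ``breakpoint``."""
        if not 0 <= breakpoint <= self.L - 2:
            raise ValueError(f"breakpoint link {breakpoint} outside 0..L-2")
        if ids is None:
            lp = self.new_node(time, RECOMBINATION)
            rp = self.new_node(time, RECOMBINATION)
        else:
            lp = self._new_node_with_id(ids[0], time, RECOMBINATION)
            rp = self._new_node_with_id(ids[1], time, RECOMBINATION)
        rec = RecombinationRecord(child, breakpoint, lp, rp)
        self.recs.append(rec)
        self._an = None
        return rec

    def _new_node_with_id(self, u: int, time: float, kind: str) -> int:
        if u in self.node_time:
            raise ValueError(f"node id {u} already in use")
        self.node_time[u] = float(time)
        self.node_kind[u] = kind
        self.next_id = max(self.next_id, u + 1)
        self._an = None
        return u

    def remove_node(self, u: int) -> None:
        del self.node_time[u]
        del self.node_kind[u]
        self.ca_children.pop(u, None)
        self._an = None

    def copy(self) -> "ATS":
        new = ATS.__new__(ATS)
        new.L = self.L
        new.n = self.n
        new.node_time = dict(self.node_time)
        new.node_kind = dict(self.node_kind)
        new.ca_children = dict(self.ca_children)
        new.recs = list(self.recs)
        new.next_id = self.next_id
        new.mutations = None
        new._an = None
        return new

    def __eq__(self, other):
        if not isinstance(other, ATS):
            return NotImplemented
        return (self.L == other.L and self.n == other.n
                and self.node_time == other.node_time
                and self.node_kind == other.node_kind
                and {p: tuple(sorted(cs)) for p, cs in self.ca_children.items()}
                == {p: tuple(sorted(cs)) for p, cs in other.ca_children.items()}
                and sorted(self.recs, key=lambda r: r.left_parent)
                == sorted(other.recs, key=lambda r: r.left_parent))

    def __hash__(self):  # identity hashing; equality is structural
        return id(self)

    # -- derived state -----------------------------------------------------

    @property
    def analysis(self) -> _Analysis:
        if self._an is None:
            self._an = self._analyze()
        return self._an

    def _analyze(self) -> _Analysis:
        violations: list = []
        parent_slot = {u: None for u in self.node_time}
        for p, (a, b) in self.ca_children.items():
            for c in (a, b):
                if c not in parent_slot:
                    violations.append(f"CA {p} references unknown child {c}")
                elif parent_slot[c] is not None:
                    violations.append(f"node {c} has more than one parent event")
                else:
                    parent_slot[c] = ("ca", p)
        for i, rec in enumerate(self.recs):
            c = rec.child
            if c not in parent_slot:
                violations.append(f"recombination {i} references unknown child {c}")
            elif parent_slot[c] is not None:
                violations.append(f"node {c} has more than one parent event")
            else:
                parent_slot[c] = ("rec", i)

        events = []
        for p in self.ca_children:
            events.append((self.node_time[p], "ca", p))
        for i, rec in enumerate(self.recs):
            tl = self.node_time.get(rec.left_parent)
            tr = self.node_time.get(rec.right_parent)
            if tl is None or tr is None or tl != tr:
                violations.append(f"recombination {i}: malformed parent nodes")
                tl = tl if tl is not None else (tr or 0.0)
            events.append((tl, "rec", i))
        events.sort(key=lambda e: e[0])

        for u, t in self.node_time.items():
            kind = self.node_kind[u]
            if kind == SAMPLE:
                if t != 0.0:
                    violations.append(f"sample {u} has nonzero time")
                if u >= self.n:
                    violations.append(f"non-sample id {u} marked as sample")
            elif t <= 0.0:
                violations.append(f"event node {u} has non-positive time {t}")
        times = [t for t, _, _ in events]
        for a, b in zip(times, times[1:]):
            if a == b:
                violations.append(f"two events share time {a}")

        an = _Analysis(ok=not violations, violations=violations,
                       parent_slot=parent_slot, events=events,
                       mat={}, death={}, waits=[], k=[], kp=[], ic=[],
                       rec_class=[None] * len(self.recs), coalescing={},
                       dead=set())
        if violations:
            an.ok = False
            return an

        alive = {}
        full = ((0, self.L, 1),)
        for i in range(self.n):
            if self.n == 1:
                an.dead.add(i)
            else:
                alive[i] = full
        prev_t = 0.0
        for (t, kind, payload) in events:
            an.waits.append(t - prev_t)
            an.k.append(len(alive))
            an.kp.append(sum(_span_links(m) for m in alive.values()))
            prev_t = t
            if kind == "ca":
                p = payload
                a, b = self.ca_children[p]
                if a not in alive or b not in alive or a == b:
                    violations.append(f"CA {p} consumes unavailable lineage")
                    break
                if not (self.node_time[a] < t and self.node_time[b] < t):
                    violations.append(f"CA {p} not older than its children")
                    break
                an.ic.append(1)
                for c in (a, b):
                    an.mat[c] = alive[c]
                    an.death[c] = t
                merged, coal = _merge(alive.pop(a), alive.pop(b), self.n)
                an.coalescing[p] = coal
                if merged:
                    alive[p] = merged
                else:
                    an.dead.add(p)
            else:
                i = payload
                rec = self.recs[i]
                c = rec.child
                if c not in alive:
                    violations.append(f"recombination {i} consumes unavailable lineage")
                    break
                if not self.node_time[c] < t:
                    violations.append(f"recombination {i} not older than its child")
                    break
                m = alive.pop(c)
                an.mat[c] = m
                an.death[c] = t
                an.ic.append(0)
                f, last = _first_last(m)
                b = rec.breakpoint
                if not f <= b < last:
                    violations.append(
                        f"recombination {i}: breakpoint {b} outside lineage span")
                    an.rec_class[i] = "other"
                    break
                # ancestral iff both flanking sites are ancestral material
                # (stored segments may split at coalescence-count changes)
                inside = _contains(m, b) and _contains(m, b + 1)
                an.rec_class[i] = ANCESTRAL if inside else TRAPPED
                alive[rec.left_parent] = _clip(m, 0, b + 1)
                alive[rec.right_parent] = _clip(m, b + 1, self.L)

        if not violations:
            if alive:
                violations.append(
                    f"lineages {sorted(alive)} never reach a most recent common ancestor")
            for u, slot in parent_slot.items():
                if u in an.dead and slot is not None:
                    violations.append(f"node {u} carries no material but has a parent")
                if (u not in an.dead and slot is None and u not in an.mat
                        and not (self.n == 1 and u < self.n)):
                    violations.append(f"node {u} is disconnected")
        an.ok = not violations
        an.violations = violations
        return an

    def validate(self) -> list:
        """Check every structural invariant; returns a list of violations.

        An empty list means the ATS is a valid little-ARG realization.  Pure:
        does not modify the object.
        """
        return list(self.analysis.violations)

    @property
    def is_valid(self) -> bool:
        return self.analysis.ok

    def _require_valid(self):
        an = self.analysis
        if not an.ok:
            raise ValueError("invalid ATS: " + "; ".join(an.violations[:3]))
        return an

    @property
    def num_recombinations(self) -> int:
        return len(self.recs)

    @property
    def num_events(self) -> int:
        return len(self.ca_children) + len(self.recs)

    # -- queries -----------------------------------------------------------

    def branch_segments(self, u: int) -> list:
        """Ancestral and trapped segments carried by lineage ``u``."""
        an = self._require_valid()
        if u not in an.mat:
            raise KeyError(f"no lineage with child node {u}")
        runs = []  # coalesce stored segments (they may split at count changes)
        for l, r, _ in an.mat[u]:
            if runs and runs[-1][1] == l:
                runs[-1][1] = r
            else:
                runs.append([l, r])
        segs = [Segment(l, r, ANCESTRAL) for l, r in runs]
        out = []
        for a, b in zip(segs, segs[1:]):
            out.append(a)
            if a.right < b.left:
                out.append(Segment(a.right, b.left, TRAPPED))
        out.append(segs[-1])
        return out

    def tnam_intervals(self, lineage: int) -> list:
        """Trapped-non-ancestral-material gaps of one lineage.

        Exactly the maximal intervals strictly between the lineage's first
        and last ancestral sites that carry no ancestral material.
        """
        return [s for s in self.branch_segments(lineage) if s.material == TRAPPED]

    def marginal_tree(self, site: int) -> MarginalTree:
        """The genealogical tree at ``site`` (times in generations)."""
        if not 0 <= site < self.L:
            raise ValueError(f"site {site} outside [0, {self.L})")
        an = self._require_valid()
        parent = {}
        times = {}
        for i in range(self.n):
            u = i
            times[u] = self.node_time[u]
            while u in an.mat and _contains(an.mat[u], site) and u not in parent:
                slot = an.parent_slot[u]
                if slot is None:
                    break
                if slot[0] == "ca":
                    p = slot[1]
                else:
                    rec = self.recs[slot[1]]
                    p = rec.left_parent if site <= rec.breakpoint else rec.right_parent
                parent[u] = p
                times[p] = self.node_time[p]
                u = p
        return MarginalTree(site, parent, times, range(self.n))

    def _leaf_sets_at_site(self, site: int) -> dict:
        """Leaf set below each lineage covering ``site`` (child-node keyed)."""
        an = self._require_valid()
        covering = [u for u, m in an.mat.items() if _contains(m, site)]
        covering.sort(key=lambda u: self.node_time[u])
        ls = {}
        for u in covering:
            kind = self.node_kind[u]
            if kind == SAMPLE:
                ls[u] = frozenset((u,))
            elif kind == COMMON_ANCESTOR:
                acc = frozenset()
                for c in self.ca_children[u]:
                    if c in ls and _contains(an.mat[c], site):
                        acc |= ls[c]
                ls[u] = acc
            else:  # recombination parent: inherits from the record's child
                for rec in self.recs:
                    if u in (rec.left_parent, rec.right_parent):
                        ls[u] = ls[rec.child]
                        break
        return ls

    def distinct_branches(self) -> list:
        """Per-branch ``(length, genomic span, mutation count)`` triples.

        Each physical branch (lineage) appears exactly once even when it
        spans many sites or is bracketed by events on other lineages.  The
        mutation counts come from :attr:`mutations` when assigned, else 0.
        """
        an = self._require_valid()
        if not an.mat:
            raise ValueError("ATS has no branches")
        mcount = {}
        if self.mutations:
            for m in self.mutations:
                mcount[m.branch] = mcount.get(m.branch, 0) + 1
        out = []
        for u, m in an.mat.items():
            l = an.death[u] - self.node_time[u]
            out.append((l, _gsize(m), mcount.get(u, 0)))
        return sorted(out)

    def total_branch_length(self):
        """Per-site total branch length and its site-summed total.

        Returns ``(per_site, total)`` where ``per_site[s]`` is the total
        branch length of the marginal tree at site ``s`` and
        ``total = sum_v l_v * g_v`` over distinct branches.
        """
        an = self._require_valid()
        diff = np.zeros(self.L + 1)
        total = 0.0
        for u, m in an.mat.items():
            l = an.death[u] - self.node_time[u]
            for a, b, _ in m:
                diff[a] += l
                diff[b] -= l
                total += l * (b - a)
        return np.cumsum(diff[:-1]), total

    def total_branch_length_sum(self) -> float:
        """Site-summed total branch length ``sum_v l_v g_v`` alone."""
        an = self._require_valid()
        return sum((an.death[u] - self.node_time[u]) * _gsize(m)
                   for u, m in an.mat.items())

    def classify_recombinations(self):
        """Counts of (ancestral, trapped/non-ancestral) recombinations."""
        an = self._require_valid()
        n_anc = sum(1 for c in an.rec_class if c == ANCESTRAL)
        n_tnam = sum(1 for c in an.rec_class if c == TRAPPED)
        return n_anc, n_tnam

    def assign_mutations(self, data: Dataset):
        """Place each segregating site's mutation on the lowest fitting branch.

        For every segregating site the branch must cover the site and have
        leaf set equal to the derived-carrier set; among candidates the one
        with the smallest child-node time (ties: smallest id) is chosen.
        Returns the mutation table, or ``None`` if some site admits no such
        branch (the ARG is incompatible with the data).
        """
        an = self._require_valid()
        if data.n != self.n or data.L != self.L:
            raise ValueError("dataset dimensions do not match the ATS")
        table = []
        for site in sorted(data.seg):
            carriers = data.seg[site]
            ls = self._leaf_sets_at_site(site)
            best = None
            for u, s in ls.items():
                if s == carriers:
                    key = (self.node_time[u], u)
                    if best is None or key < best:
                        best = key
            if best is None:
                return None
            table.append(MutationRecord(site=site, branch=best[1], carriers=carriers))
        return table
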