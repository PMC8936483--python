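"""The six ARG proposal types and their transition densities.

Every move is factored into three pieces sharing one code path:

* ``propose(ats, move, params, rng)`` samples a concrete set of *choices*
  and returns a :class:`ProposalOutcome`;
* ``apply_move(ats, move, choices)`` deterministically applies recorded
  choices (used both by ``propose`` and by reversibility checks — applying
  an outcome's ``reverse_choices`` to the proposal reconstructs the original
  state exactly, including node ids);
* ``log_q(ats, move, choices)`` evaluates the log transition density of
  those choices from that state.

The moves:

``spr``
    Subtree pruning and regrafting.  A branch whose parent event is a
    common-ancestor node is detached (its parent CA dissolves, the sibling
    splices through) and reattached at an older time: a target edge or open
    root lineage is chosen uniformly in the detached graph, the attachment
    time is uniform on the target edge's time interval (exponential with
    mean 2N above a root).  The pruned lineage carries no recombination and
    the recombination count is unchanged.

``remove_recomb`` / ``add_recomb``
    A reversible pair changing the recombination count by one.  Removal
    picks a (recombination, survivor-parent) pair — the discarded parent
    must be the child of a CA node — transfers the child's full span to the
    survivor's parent slot and splices the discarded parent's sibling
    through.  Addition is the exact reverse: an edge with at least one link
    is split by a new recombination at a uniform breakpoint and time, one
    side keeps the old parent slot, the other regrafts like an SPR (which
    may rejoin the survivor's own upper half, creating a "bubble").

``resample_breakpoint``
    Moves one recombination's breakpoint uniformly over its child lineage's
    links.  The child's material does not depend on the breakpoint, so the
    proposal is symmetric.

``kuhner``
    Erases the ARG above the time of one of its most recent events and
    re-simulates that region from the coalescent-with-recombination prior
    started from the lineages alive at the cut.  The cut is uniform over
    the top ``KUHNER_WINDOW`` events (plus "cut nothing"); states small
    enough fit entirely inside the window, so the move can also rebuild
    the whole graph.  Proposals whose re-simulated region exceeds the
    window have zero reverse density and are rejected, keeping the kernel
    exactly reversible; the Hastings ratio is the ratio of window sizes
    times the prior ratio of the replaced region's event terms, computed
    here as honest forward/reverse densities.

``resample_times``
    Keeps the event order, participants and breakpoints, redrawing every
    inter-event waiting time from its conditional exponential
    ``Exp(lambda_i)``.  The proposal density cancels the prior's waiting
    time terms exactly.

Proposals that would produce a structurally invalid ARG (material failing
to coalesce, a breakpoint leaving a lineage's span, ...) are returned with
``proposal_invalid`` set and are rejected by the acceptance step without a
likelihood evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ats import ATS, RecombinationRecord, _clip, _first_last, _merge, _span_links
from .density import Parameters

__all__ = ["MOVES", "DEFAULT_WEIGHTS", "ProposalOutcome", "propose",
           "apply_move", "log_q", "inverse_move"]

MOVES = ("spr", "remove_recomb", "add_recomb", "resample_breakpoint",
         "kuhner", "resample_times")

DEFAULT_WEIGHTS = (1 / 14, 1 / 14, 1 / 14, 1 / 14, 5 / 14, 5 / 14)

# The Kuhner move erases at most this many of the topmost events.  Small
# enough to keep the rearrangement local (and acceptably often compatible
# with the data), large enough to cover entire small ARGs; ARGs with more
# events are rebuilt bottom-up over successive accepted moves.
KUHNER_WINDOW = 6

_INVERSE = {"spr": "spr", "remove_recomb": "add_recomb",
            "add_recomb": "remove_recomb",
            "resample_breakpoint": "resample_breakpoint",
            "kuhner": "kuhner", "resample_times": "resample_times"}


def inverse_move(move: str) -> str:
    return _INVERSE[move]


@dataclass
class ProposalOutcome:
    """A proposed state with its forward/reverse transition densities."""

    move: str
    available: bool
    proposal: Optional[ATS] = None
    log_q_forward: float = float("nan")
    log_q_reverse: float = float("nan")
    choices: dict = field(default_factory=dict)
    reverse_choices: dict = field(default_factory=dict)
    proposal_invalid: bool = False


# ---------------------------------------------------------------------------
# structural helpers (no material replay; usable on intermediate graphs)
# ---------------------------------------------------------------------------

def _slots(ats: ATS) -> dict:
    slot = {u: None for u in ats.node_time}
    for p, (a, b) in ats.ca_children.items():
        slot[a] = ("ca", p)
        slot[b] = ("ca", p)
    for i, rec in enumerate(ats.recs):
        slot[rec.child] = ("rec", i)
    return slot


def _slot_time(ats: ATS, slot) -> float:
    if slot[0] == "ca":
        return ats.node_time[slot[1]]
    return ats.node_time[ats.recs[slot[1]].left_parent]


def _replace_in_slot(ats: ATS, slot, old: int, new: int) -> None:
    if slot[0] == "ca":
        a, b = ats.ca_children[slot[1]]
        ats.ca_children[slot[1]] = (new if a == old else a, new if b == old else b)
    else:
        i = slot[1]
        r = ats.recs[i]
        ats.recs[i] = RecombinationRecord(new, r.breakpoint, r.left_parent,
                                          r.right_parent)
    ats._an = None


def _detach(work: ATS, u: int):
    """Dissolve u's parent CA; returns (sibling, removed CA id, its slot, its time)."""
    slots = _slots(work)
    s = slots[u]
    if s is None or s[0] != "ca":
        raise ValueError(f"node {u} is not prunable")
    P = s[1]
    a, b = work.ca_children[P]
    x = b if a == u else a
    pslot = slots[P]
    tP = work.node_time[P]
    work.remove_node(P)
    if pslot is not None:
        _replace_in_slot(work, pslot, P, x)
    return x, P, pslot, tP


def _attach(work: ATS, u: int, target, tau: float, ca_id: int) -> int:
    """Create a CA at time tau joining u with the target edge or root."""
    kind, w = target
    if kind == "edge":
        wslot = _slots(work)[w]
        if wslot is None:
            raise ValueError(f"target {w} is not an edge")
        A = work.add_ca(tau, u, w, node_id=ca_id)
        _replace_in_slot(work, wslot, w, A)
        # the new CA must not appear as its own parent
        if work.ca_children[A].count(A):  # pragma: no cover
            raise AssertionError("self-attachment")
    else:
        A = work.add_ca(tau, u, w, node_id=ca_id)
    return A


def _targets(inter: ATS, t_min: float, exclude) -> list:
    """Attachment targets in a (possibly detached) graph.

    Edges whose top event is older than ``t_min`` plus every parentless
    node, deterministic order.  Validity of the resulting state is checked
    after the fact, not here, so forward and reverse counting agree.
    """
    slots = _slots(inter)
    out = []
    for u in sorted(slots):
        if u in exclude:
            continue
        s = slots[u]
        if s is None:
            out.append(("root", u))
        elif _slot_time(inter, s) > t_min:
            out.append(("edge", u))
    return out


def _attach_interval(inter: ATS, target, t_min: float):
    kind, w = target
    lo = max(t_min, inter.node_time[w])
    if kind == "edge":
        return lo, _slot_time(inter, _slots(inter)[w])
    return lo, None


def _log_attach_density(lo, hi, tau, N):
    if hi is None:
        if tau <= lo:
            return float("-inf")
        return -math.log(2.0 * N) - (tau - lo) / (2.0 * N)
    if not lo < tau < hi:
        return float("-inf")
    return -math.log(hi - lo)


def _sample_attach_time(rng, lo, hi, N, taken):
    while True:
        if hi is None:
            tau = lo + rng.exponential(2.0 * N)
        else:
            tau = lo + (hi - lo) * rng.random()
        if tau not in taken:
            return tau


def _prunable(ats: ATS) -> list:
    slots = _slots(ats)
    return sorted(u for u, s in slots.items() if s is not None and s[0] == "ca")


def _removable_pairs(ats: ATS) -> list:
    slots = _slots(ats)
    out = []
    for rec in ats.recs:
        for side in ("l", "r"):
            other = rec.right_parent if side == "l" else rec.left_parent
            s = slots.get(other)
            if s is not None and s[0] == "ca":
                out.append((rec.left_parent, side))
    return sorted(out)


def _rec_by_lp(ats: ATS, lp: int) -> RecombinationRecord:
    for rec in ats.recs:
        if rec.left_parent == lp:
            return rec
    raise KeyError(f"no recombination with left parent {lp}")


def _addable(ats: ATS) -> list:
    an = ats._require_valid()
    return sorted(u for u, m in an.mat.items() if _span_links(m) >= 1)


def _alive_at_cut(ats: ATS, cut: int):
    """Lineages alive just after the ``cut``-th event (materials included)."""
    an = ats._require_valid()
    t_cut = 0.0 if cut == 0 else an.events[cut - 1][0]
    alive = {}
    for u, m in an.mat.items():
        if ats.node_time[u] <= t_cut < an.death[u]:
            alive[u] = m
    return t_cut, alive


# ---------------------------------------------------------------------------
# apply
# ---------------------------------------------------------------------------

def apply_move(ats: ATS, move: str, choices: dict) -> ATS:
    """Apply recorded proposal choices to a state; deterministic."""
    work = ats.copy()
    if move == "spr":
        u = choices["u"]
        _detach(work, u)
        _attach(work, u, choices["target"], choices["tau"], choices["ca_id"])
    elif move == "remove_recomb":
        rec = _rec_by_lp(work, choices["rec_lp"])
        side = choices["survivor"]
        Rs = rec.left_parent if side == "l" else rec.right_parent
        Ro = rec.right_parent if side == "l" else rec.left_parent
        slots = _slots(work)
        so = slots[Ro]
        if so is None or so[0] != "ca":
            raise ValueError("discarded parent is not the child of a CA event")
        P2 = so[1]
        a, b = work.ca_children[P2]
        x2 = b if a == Ro else a
        pslot2 = slots[P2]
        c = rec.child
        if x2 == Rs:  # bubble: both parents re-coalesce at P2
            if pslot2 is not None:
                _replace_in_slot(work, pslot2, P2, c)
        else:
            ss = slots[Rs]
            if ss is not None:
                _replace_in_slot(work, ss, Rs, c)
            if pslot2 is not None:
                _replace_in_slot(work, pslot2, P2, x2)
        work.recs.remove(_rec_by_lp(work, choices["rec_lp"]))
        for v in (Rs, Ro, P2):
            work.remove_node(v)
        work._an = None
    elif move == "add_recomb":
        u = choices["u"]
        s_u = _slots(work)[u]
        if s_u is None:
            raise ValueError(f"node {u} has no parent event")
        rec = work.add_rec(choices["t_rec"], u, choices["breakpoint"],
                           ids=(choices["lp_id"], choices["rp_id"]))
        side = choices["side"]
        Rs = rec.left_parent if side == "l" else rec.right_parent
        Ro = rec.right_parent if side == "l" else rec.left_parent
        _replace_in_slot(work, s_u, u, Rs)
        _attach(work, Ro, choices["target"], choices["tau"], choices["ca_id"])
    elif move == "resample_breakpoint":
        rec = _rec_by_lp(work, choices["rec_lp"])
        i = work.recs.index(rec)
        work.recs[i] = RecombinationRecord(rec.child, choices["breakpoint"],
                                           rec.left_parent, rec.right_parent)
        work._an = None
    elif move == "kuhner":
        an = ats._require_valid()
        cut = choices["cut"]
        for (t, kind, payload) in an.events[cut:]:
            if kind == "ca":
                work.remove_node(payload)
            else:
                rec = ats.recs[payload]
                work.recs.remove(rec)
                work.remove_node(rec.left_parent)
                work.remove_node(rec.right_parent)
        for ev in choices["upper"]:
            if ev[0] == "ca":
                _, t, a, b, nid = ev
                work.add_ca(t, a, b, node_id=nid)
            else:
                _, t, c, bp, lp, rp = ev
                work.add_rec(t, c, bp, ids=(lp, rp))
        work._an = None
    elif move == "resample_times":
        an = ats._require_valid()
        times = choices["times"]
        if len(times) != len(an.events):
            raise ValueError("times length mismatch")
        for (old_t, kind, payload), t in zip(an.events, times):
            if kind == "ca":
                work.node_time[payload] = t
            else:
                rec = ats.recs[payload]
                work.node_time[rec.left_parent] = t
                work.node_time[rec.right_parent] = t
        work._an = None
    else:
        raise ValueError(f"unknown move {move!r}")
    return work


# ---------------------------------------------------------------------------
# log transition densities
# ---------------------------------------------------------------------------

def log_q(ats: ATS, move: str, choices: dict, params: Parameters) -> float:
    """Log density of proposing ``choices`` via ``move`` from state ``ats``."""
    if move == "spr":
        u = choices["u"]
        prunable = _prunable(ats)
        if u not in prunable:
            return float("-inf")
        inter = ats.copy()
        _detach(inter, u)
        t_u = ats.node_time[u]
        targets = _targets(inter, t_u, {u})
        if choices["target"] not in targets:
            return float("-inf")
        lo, hi = _attach_interval(inter, choices["target"], t_u)
        return (-math.log(len(prunable)) - math.log(len(targets))
                + _log_attach_density(lo, hi, choices["tau"], params.N))
    if move == "remove_recomb":
        pairs = _removable_pairs(ats)
        if (choices["rec_lp"], choices["survivor"]) not in pairs:
            return float("-inf")
        return -math.log(len(pairs))
    if move == "add_recomb":
        u = choices["u"]
        cand = _addable(ats)
        if u not in cand:
            return float("-inf")
        an = ats.analysis
        links = _span_links(an.mat[u])
        f, last = _first_last(an.mat[u])
        if not f <= choices["breakpoint"] < last:
            return float("-inf")
        s_u = _slots(ats)[u]
        t_u, t_top = ats.node_time[u], _slot_time(ats, s_u)
        t_rec = choices["t_rec"]
        if not t_u < t_rec < t_top:
            return float("-inf")
        # intermediate: edge split, floating side not yet attached
        inter = ats.copy()
        s_u_i = _slots(inter)[u]
        rec = inter.add_rec(t_rec, u, choices["breakpoint"],
                            ids=(choices["lp_id"], choices["rp_id"]))
        side = choices["side"]
        Rs = rec.left_parent if side == "l" else rec.right_parent
        Ro = rec.right_parent if side == "l" else rec.left_parent
        _replace_in_slot(inter, s_u_i, u, Rs)
        targets = _targets(inter, t_rec, {Ro})
        if choices["target"] not in targets:
            return float("-inf")
        lo, hi = _attach_interval(inter, choices["target"], t_rec)
        return (-math.log(len(cand)) - math.log(links) - math.log(t_top - t_u)
                - math.log(2.0) - math.log(len(targets))
                + _log_attach_density(lo, hi, choices["tau"], params.N))
    if move == "resample_breakpoint":
        if not ats.recs:
            return float("-inf")
        rec = _rec_by_lp(ats, choices["rec_lp"])
        an = ats._require_valid()
        m = an.mat[rec.child]
        f, last = _first_last(m)
        if not f <= choices["breakpoint"] < last:
            return float("-inf")
        return -math.log(len(ats.recs)) - math.log(last - f)
    if move == "kuhner":
        E = ats.num_events
        cut = choices["cut"]
        lo = max(0, E - KUHNER_WINDOW)
        if not lo <= cut <= E:
            return float("-inf")
        t_prev, alive = _alive_at_cut(ats, cut)
        alive = dict(alive)
        total = -math.log(E - lo + 1)
        N, r = params.N, params.r
        for ev in choices["upper"]:
            k = len(alive)
            kp = sum(_span_links(m) for m in alive.values())
            lam = k * (k - 1) / (4.0 * N) + r * kp
            t = ev[1]
            if t <= t_prev:
                return float("-inf")
            total += -lam * (t - t_prev)
            if ev[0] == "ca":
                _, _, a, b, nid = ev
                if a not in alive or b not in alive:
                    return float("-inf")
                total += -math.log(2.0 * N)
                merged, _ = _merge(alive.pop(a), alive.pop(b), ats.n)
                if merged:
                    alive[nid] = merged
            else:
                _, _, c, bp, lp, rp = ev
                if c not in alive or r <= 0:
                    return float("-inf")
                m = alive.pop(c)
                f, last = _first_last(m)
                if not f <= bp < last:
                    return float("-inf")
                total += math.log(r)
                alive[lp] = _clip(m, 0, bp + 1)
                alive[rp] = _clip(m, bp + 1, ats.L)
            t_prev = t
        if alive:
            return float("-inf")  # described upper part does not finish the ARG
        return total
    if move == "resample_times":
        an = ats._require_valid()
        k = np.asarray(an.k, dtype=float)
        kp = np.asarray(an.kp, dtype=float)
        lam = k * (k - 1) / (4.0 * params.N) + params.r * kp
        times = np.asarray(choices["times"], dtype=float)
        if len(times) != len(lam):
            return float("-inf")
        waits = np.diff(times, prepend=0.0)
        if np.any(waits <= 0):
            return float("-inf")
        return float(np.sum(np.log(lam) - lam * waits))
    raise ValueError(f"unknown move {move!r}")


# ---------------------------------------------------------------------------
# propose
# ---------------------------------------------------------------------------

def propose(ats: ATS, move: str, params: Parameters,
            rng: np.random.Generator) -> ProposalOutcome:
    """Draw one proposal of the given type from the current state."""
    sampler = _SAMPLERS[move]
    choices = sampler(ats, params, rng)
    if choices is None:
        return ProposalOutcome(move=move, available=False)
    proposal = apply_move(ats, move, choices)
    lqf = log_q(ats, move, choices, params)
    out = ProposalOutcome(move=move, available=True, proposal=proposal,
                          choices=choices, log_q_forward=lqf)
    if not proposal.is_valid:
        out.proposal_invalid = True
        return out
    rev = _reverse_choices(ats, move, choices, proposal)
    out.reverse_choices = rev
    out.log_q_reverse = log_q(proposal, inverse_move(move), rev, params)
    return out


def _taken_times(ats: ATS):
    return set(ats.node_time.values())


def _sample_spr(ats, params, rng):
    prunable = _prunable(ats)
    if not prunable:
        return None
    u = prunable[rng.integers(len(prunable))]
    inter = ats.copy()
    _detach(inter, u)
    t_u = ats.node_time[u]
    targets = _targets(inter, t_u, {u})
    if not targets:
        return None
    target = targets[rng.integers(len(targets))]
    lo, hi = _attach_interval(inter, target, t_u)
    tau = _sample_attach_time(rng, lo, hi, params.N, _taken_times(inter))
    return {"u": u, "target": target, "tau": tau, "ca_id": ats.next_id}


def _sample_remove(ats, params, rng):
    pairs = _removable_pairs(ats)
    if not pairs:
        return None
    lp, side = pairs[rng.integers(len(pairs))]
    return {"rec_lp": lp, "survivor": side}


def _sample_add(ats, params, rng):
    cand = _addable(ats)
    if not cand:
        return None
    u = cand[rng.integers(len(cand))]
    an = ats.analysis
    m = an.mat[u]
    f, last = _first_last(m)
    bp = int(f + rng.integers(last - f))
    s_u = _slots(ats)[u]
    t_u, t_top = ats.node_time[u], _slot_time(ats, s_u)
    taken = _taken_times(ats)
    while True:
        t_rec = t_u + (t_top - t_u) * rng.random()
        if t_rec not in taken:
            break
    side = "l" if rng.random() < 0.5 else "r"
    lp_id, rp_id, ca_id = ats.next_id, ats.next_id + 1, ats.next_id + 2
    inter = ats.copy()
    s_u_i = _slots(inter)[u]
    rec = inter.add_rec(t_rec, u, bp, ids=(lp_id, rp_id))
    Rs = rec.left_parent if side == "l" else rec.right_parent
    Ro = rec.right_parent if side == "l" else rec.left_parent
    _replace_in_slot(inter, s_u_i, u, Rs)
    targets = _targets(inter, t_rec, {Ro})
    if not targets:
        return None
    target = targets[rng.integers(len(targets))]
    lo, hi = _attach_interval(inter, target, t_rec)
    tau = _sample_attach_time(rng, lo, hi, params.N, _taken_times(inter))
    return {"u": u, "breakpoint": bp, "t_rec": t_rec, "side": side,
            "target": target, "tau": tau,
            "lp_id": lp_id, "rp_id": rp_id, "ca_id": ca_id}


def _sample_breakpoint(ats, params, rng):
    if not ats.recs:
        return None
    rec = ats.recs[rng.integers(len(ats.recs))]
    an = ats._require_valid()
    f, last = _first_last(an.mat[rec.child])
    bp = int(f + rng.integers(last - f))
    return {"rec_lp": rec.left_parent, "breakpoint": bp}


def _sample_kuhner(ats, params, rng):
    E = ats.num_events
    lo = max(0, E - KUHNER_WINDOW)
    cut = int(lo + rng.integers(E - lo + 1))
    t, alive = _alive_at_cut(ats, cut)
    alive = dict(alive)
    N, r = params.N, params.r
    taken = _taken_times(ats)
    upper = []
    next_id = ats.next_id
    while len(alive) >= 2:
        k = len(alive)
        links = {u: _span_links(m) for u, m in alive.items()}
        ca_rate = k * (k - 1) / (4.0 * N)
        rec_rate = r * sum(links.values())
        lam = ca_rate + rec_rate
        while True:
            t_new = t + rng.exponential(1.0 / lam)
            if t_new not in taken:
                break
        t = t_new
        taken.add(t)
        ids = sorted(alive)
        if rng.random() < ca_rate / lam:
            ia, ib = rng.choice(len(ids), size=2, replace=False)
            a, b = ids[ia], ids[ib]
            nid = next_id
            next_id += 1
            upper.append(("ca", t, a, b, nid))
            merged, _ = _merge(alive.pop(a), alive.pop(b), ats.n)
            if merged:
                alive[nid] = merged
        else:
            weights = np.array([links[u] for u in ids], dtype=float)
            u = ids[rng.choice(len(ids), p=weights / weights.sum())]
            m = alive.pop(u)
            f, last = _first_last(m)
            bp = int(f + rng.integers(last - f))
            lp, rp = next_id, next_id + 1
            next_id += 2
            upper.append(("rec", t, u, bp, lp, rp))
            alive[lp] = _clip(m, 0, bp + 1)
            alive[rp] = _clip(m, bp + 1, ats.L)
    return {"cut": cut, "upper": tuple(upper)}


def _sample_times(ats, params, rng):
    an = ats._require_valid()
    if not an.events:
        return None
    k = np.asarray(an.k, dtype=float)
    kp = np.asarray(an.kp, dtype=float)
    lam = k * (k - 1) / (4.0 * params.N) + params.r * kp
    waits = rng.exponential(1.0 / lam)
    times = np.cumsum(waits)
    return {"times": tuple(float(t) for t in times)}


_SAMPLERS = {"spr": _sample_spr, "remove_recomb": _sample_remove,
             "add_recomb": _sample_add, "resample_breakpoint": _sample_breakpoint,
             "kuhner": _sample_kuhner, "resample_times": _sample_times}


# ---------------------------------------------------------------------------
# reverse choices
# ---------------------------------------------------------------------------

def _reverse_choices(ats: ATS, move: str, choices: dict, proposal: ATS) -> dict:
    if move == "spr":
        u = choices["u"]
        slots = _slots(ats)
        P = slots[u][1]
        a, b = ats.ca_children[P]
        x = b if a == u else a
        pslot = slots[P]
        target = ("edge", x) if pslot is not None else ("root", x)
        return {"u": u, "target": target, "tau": ats.node_time[P], "ca_id": P}
    if move == "remove_recomb":
        rec = _rec_by_lp(ats, choices["rec_lp"])
        side = choices["survivor"]
        Rs = rec.left_parent if side == "l" else rec.right_parent
        Ro = rec.right_parent if side == "l" else rec.left_parent
        slots = _slots(ats)
        P2 = slots[Ro][1]
        a, b = ats.ca_children[P2]
        x2 = b if a == Ro else a
        if x2 == Rs:  # bubble: regraft onto the survivor's own upper half
            target = ("edge", Rs)
        else:
            pslot2 = slots[P2]
            target = ("edge", x2) if pslot2 is not None else ("root", x2)
        return {"u": rec.child, "breakpoint": rec.breakpoint,
                "t_rec": ats.node_time[rec.left_parent], "side": side,
                "target": target, "tau": ats.node_time[P2],
                "lp_id": rec.left_parent, "rp_id": rec.right_parent,
                "ca_id": P2}
    if move == "add_recomb":
        return {"rec_lp": choices["lp_id"], "survivor": choices["side"]}
    if move == "resample_breakpoint":
        rec = _rec_by_lp(ats, choices["rec_lp"])
        return {"rec_lp": choices["rec_lp"], "breakpoint": rec.breakpoint}
    if move == "kuhner":
        an = ats._require_valid()
        cut = choices["cut"]
        upper = []
        for (t, kind, payload) in an.events[cut:]:
            if kind == "ca":
                a, b = ats.ca_children[payload]
                upper.append(("ca", t, a, b, payload))
            else:
                rec = ats.recs[payload]
                upper.append(("rec", t, rec.child, rec.breakpoint,
                              rec.left_parent, rec.right_parent))
        return {"cut": cut, "upper": tuple(upper)}
    if move == "resample_times":
        an = ats._require_valid()
        return {"times": tuple(t for t, _, _ in an.events)}
    raise ValueError(f"unknown move {move!r}")
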