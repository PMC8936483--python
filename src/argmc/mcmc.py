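"""Metropolis-Hastings sampling over ARG space.

The chain state is an :class:`~argmc.ats.ATS`.  Each iteration draws one of
the six proposal types (default mixture weights 1/14 for SPR, recombination
removal, recombination addition and breakpoint resampling, 5/14 for the
Kuhner move and for event-time resampling), and accepts with probability

    A = min{1, [P(D|G')P(G')/P(D|G)P(G)] * [Q(G|G')/Q(G'|G)]} .

Proposals that are unavailable in the current state count as an automatic
rejection (the state is repeated).  Structurally invalid proposals and
proposals whose ARG is incompatible with the data are rejected before any
likelihood evaluation (``lik_evaluated`` stays False on that path).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ats import ATS
from .dataset import Dataset
from .density import Parameters, log_likelihood, log_prior_ats
from .moves import DEFAULT_WEIGHTS, MOVES, ProposalOutcome, propose

__all__ = ["ChainConfig", "Trace", "accept_reject", "run_chain"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    Defaults follow the reference analysis: 2e6 iterations, 20% burn-in,
    thinning interval 400 — i.e. 4000 retained samples.
    """

    iterations: int = 2_000_000
    burn_in: float = 0.20
    thin: int = 400
    weights: tuple = DEFAULT_WEIGHTS
    seed: "int | None" = None
    store_samples: bool = True

    def __post_init__(self):
        if self.iterations < 1 or self.thin < 1:
            raise ValueError("iterations and thin must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")
        if len(self.weights) != len(MOVES):
            raise ValueError(f"need {len(MOVES)} proposal weights")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("proposal weights must sum to 1")

    @property
    def n_burn(self) -> int:
        return int(self.burn_in * self.iterations)

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.n_burn) // self.thin


@dataclass
class Trace:
    """Per-iteration scalar summaries plus the retained ATS samples."""

    log_posterior: np.ndarray
    total_branch_length: np.ndarray      # site-summed, sum_v l_v g_v
    n_ancestral: np.ndarray
    n_nonancestral: np.ndarray
    accepted: np.ndarray
    move: np.ndarray                     # index into MOVES
    lik_evaluated: np.ndarray
    samples: list = field(default_factory=list)
    sample_iterations: np.ndarray = None
    config: ChainConfig = None
    L: int = 0

    @property
    def acceptance_rate(self) -> float:
        """Fraction of iterations whose proposal was accepted."""
        return float(np.mean(self.accepted))

    @property
    def n_retained(self) -> int:
        return len(self.samples)

    def retained(self, column: str) -> np.ndarray:
        """A per-iteration column restricted to the retained iterations."""
        return getattr(self, column)[self.sample_iterations]

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        idx = self.sample_iterations if retained_only else np.arange(
            len(self.log_posterior))
        return pd.DataFrame({
            "iteration": idx,
            "log_posterior": self.log_posterior[idx],
            "total_branch_length": self.total_branch_length[idx],
            "n_ancestral": self.n_ancestral[idx],
            "n_nonancestral": self.n_nonancestral[idx],
            "accepted": self.accepted[idx],
            "move": [MOVES[i] for i in self.move[idx]],
            "lik_evaluated": self.lik_evaluated[idx],
        })


def _log_target(ats: ATS, data, params) -> float:
    """Log posterior (or log prior when data is None); -inf when invalid."""
    if not ats.is_valid:
        return float("-inf")
    lp = log_prior_ats(ats, params)
    if data is None or lp == float("-inf"):
        return lp
    if ats.mutations is None:
        muts = ats.assign_mutations(data)
        if muts is None:
            return float("-inf")
        ats.mutations = muts
    return lp + log_likelihood(ats, data, params)


def accept_reject(current: ATS, outcome: ProposalOutcome, data, params: Parameters,
                  rng: np.random.Generator, current_log_post: float):
    """One MH accept/reject decision.

    Returns ``(next state, accepted, lik_evaluated, next log posterior)``.
    Incompatible or invalid proposals are rejected without evaluating the
    likelihood.  ``data=None`` targets the prior (likelihood == 1).
    """
    if not outcome.available or outcome.proposal_invalid:
        return current, False, False, current_log_post
    if outcome.log_q_reverse == float("-inf"):
        # the reverse move has zero density (e.g. a Kuhner re-simulation
        # exceeding its window): reject without evaluating the likelihood
        return current, False, False, current_log_post
    prop = outcome.proposal
    lp = log_prior_ats(prop, params)
    if lp == float("-inf"):
        return current, False, False, current_log_post
    lik_evaluated = False
    log_post = lp
    if data is not None:
        if outcome.move == "resample_times" and current.mutations is not None:
            # topology, breakpoints and leaf sets unchanged: reuse assignment
            prop.mutations = current.mutations
        else:
            muts = prop.assign_mutations(data)
            if muts is None:
                return current, False, False, current_log_post
            prop.mutations = muts
        lik_evaluated = True
        log_post = lp + log_likelihood(prop, data, params)
    log_alpha = (log_post - current_log_post
                 + outcome.log_q_reverse - outcome.log_q_forward)
    if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
        return prop, True, lik_evaluated, log_post
    return current, False, lik_evaluated, current_log_post


def run_chain(data, params: Parameters, config: ChainConfig,
              initial: "ATS | None" = None) -> Trace:
    """Run the Metropolis-Hastings chain and return its :class:`Trace`.

    With ``data=None`` the chain targets the CwR prior.  When no initial
    state is given, one is built from the data (or simulated from the prior
    in the prior-only case).  Same seed, same trace, bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    if initial is None:
        if data is not None:
            from .initial import build_initial_arg
            initial = build_initial_arg(data, params,
                                        seed=int(rng.integers(2 ** 31)))
        else:
            raise ValueError("prior-only chains need an explicit initial ATS")
    current = initial.copy()
    if data is not None and current.mutations is None:
        muts = current.assign_mutations(data)
        if muts is None:
            raise ValueError("initial ARG is incompatible with the data")
        current.mutations = muts
    current_lp = _log_target(current, data, params)
    if current_lp == float("-inf"):
        raise ValueError("initial ARG has zero posterior density")

    it = config.iterations
    lp_arr = np.empty(it)
    tbl_arr = np.empty(it)
    anc_arr = np.empty(it, dtype=np.int64)
    non_arr = np.empty(it, dtype=np.int64)
    acc_arr = np.zeros(it, dtype=bool)
    mv_arr = np.empty(it, dtype=np.int8)
    le_arr = np.zeros(it, dtype=bool)
    samples = []
    sample_its = []
    weights = np.asarray(config.weights, dtype=float)
    n_burn = config.n_burn
    log_every = max(1, it // 10)

    for j in range(it):
        mi = int(rng.choice(len(MOVES), p=weights))
        outcome = propose(current, MOVES[mi], params, rng)
        current, accepted, lik_eval, current_lp = accept_reject(
            current, outcome, data, params, rng, current_lp)
        lp_arr[j] = current_lp
        tbl_arr[j] = current.total_branch_length_sum()
        n_anc, n_non = current.classify_recombinations()
        anc_arr[j] = n_anc
        non_arr[j] = n_non
        acc_arr[j] = accepted
        mv_arr[j] = mi
        le_arr[j] = lik_eval
        if j >= n_burn and (j - n_burn + 1) % config.thin == 0:
            if config.store_samples:
                kept = current.copy()
                kept.mutations = current.mutations
                samples.append(kept)
            sample_its.append(j)
        if (j + 1) % log_every == 0:
            logger.info("iteration %d/%d  log-posterior %.2f  acc %.3f",
                        j + 1, it, current_lp, acc_arr[:j + 1].mean())

    return Trace(log_posterior=lp_arr, total_branch_length=tbl_arr,
                 n_ancestral=anc_arr, n_nonancestral=non_arr,
                 accepted=acc_arr, move=mv_arr, lik_evaluated=le_arr,
                 samples=samples, sample_iterations=np.asarray(sample_its),
                 config=config, L=current.L)
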