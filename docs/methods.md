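# Methods

`argmc` performs Bayesian inference of the ancestral recombination graph
(ARG) of a sample of `n` binary haplotypes over `L` discrete genome sites,
under the exact coalescent with recombination (CwR) — not the sequentially
Markov approximation.  This note records the model, the data structure, the
sampler design, the numerical conventions, and what the synthetic-data
experiments do and do not establish.

## Model

**State space.** The latent variable is a realization of the CwR in
"little ARG" form: a time-embedded graph over the sample in which, going
backwards in time, a *common-ancestor* (CA) event merges two lineages and a
*recombination* event splits one lineage at a breakpoint link (the gap
between two adjacent sites).  Lineages carrying no ancestral material are
never tracked, and a genomic segment is dropped from tracking the moment it
reaches its sample-wide most recent common ancestor.  Non-ancestral
material *trapped* between two ancestral segments of the same lineage
(TNAM) is part of the state: recombination within TNAM changes the joint
law of the data across sites, and modelling it is what distinguishes the
CwR from SMC-type approximations.

**Prior.** For an ARG with events at times `t_1 < ... < t_E`, with `k_i`
lineages and `k'_i` recombination links (span links, ancestral plus
trapped) alive just before event `i`, and waiting times `w_i`, the CwR
density is a product of competing-exponential terms

    P(G) = prod_i [ exp(-lambda_i w_i) / (2N) ]           (CA event)
                  [ r exp(-lambda_i w_i) ]                (recombination)
    lambda_i = k_i (k_i - 1) / (4N) + r k'_i .

`N` is the haploid effective population size; time is in generations; `r`
is the recombination rate per link per generation.  Pairwise coalescence
occurs at rate `1/(2N)` per pair, so `E[TMRCA] = 2N` for `n = 2`.

**Likelihood.** Mutation follows a discretized infinite-sites model:
mutations fall as a Poisson process with rate `mu` per ancestral site per
generation on branches; simulated datasets in which a site receives more
than one mutation are rejected and redrawn.  With `T` the set of distinct
branches (each branch stored once however many sites it spans), `l_v` the
branch length, `g_v` its number of ancestral sites and `|m_v|` its
mutation count,

    P(D | G) = (1/M!) prod_{v in T} exp(-l_v g_v mu) (l_v mu)^{|m_v|} ,

which equals the site-by-site Poisson-thinning probability; `M` is the
total mutation count (= number of segregating sites), so `1/M!` is
constant in `G` and cancels from every Metropolis–Hastings ratio.  A
mutation consistent with several branches (a unary chain at its site) is
assigned to the lowest branch, ties broken by smaller child time then
smaller node id.

## The augmented tree sequence

The chain state is held in a table-based *augmented tree sequence*: a node
table (time, kind), the two children of every CA node, and one record per
recombination event (child, breakpoint link, the two parent nodes created
by the event).  Everything else — the ancestral-material segments of every
branch, TNAM gaps, event ordering, the `(k, k')` bookkeeping, marginal
trees, and validity — is recomputed deterministically from those tables by
a single bottom-up replay and cached.  This makes proposal code purely
structural (local edits to small tables) with correctness delegated to one
audited replay; states are cheap to copy, and every derived quantity is
consistent by construction.  Stored segments may split where the
coalescence count changes; span, TNAM and breakpoint classification treat
contiguous ancestral runs as single segments.

Coordinates are 0-based with half-open intervals; links are indexed
`0..L-2`, link `b` lying between sites `b` and `b+1`.  A breakpoint is
classified *ancestral* iff both flanking sites are ancestral material of
the child lineage, else (inside the span) *trapped*.  Event times are
continuous; exact ties are invalid and resampled times are redrawn if they
would tie.

## Simulator

`simulate_arg` is a Hudson-style backwards-in-time simulation of the exact
process above (Gillespie over the competing exponentials; breakpoints
uniform on the chosen lineage's span links).  It produces the truth ARGs
for all experiments and doubles as the *reference distribution* for
validating the sampler: a chain run with likelihood ≡ 1 must reproduce
simulator summaries.  `drop_mutations` implements the discretized ISM with
rejection.  The fraction of rejected datasets at the reference settings
(`n=10`, `L=1e5`, `mu=1e-8`, `N=1e4`) is about 5–7%: with ~113 expected
mutations over 1e5 sites the birthday-collision rate is
`1 - exp(-E[S]^2 / 2L) ≈ 6%`.  Watterson-type expectations refer to the
*unconditional* mutation count; conditioning on accepted datasets biases
the mean segregating-site count low by a few percent, which is why the
closed-form checks count mutation events before rejection.

## Initial ARG

The chain needs a starting ARG whose marginal trees contain every
segregating site's derived-carrier set as a clade.  The genome is scanned
left to right and split greedily into maximal blocks whose carrier sets
are pairwise nested or disjoint — the laminar condition, which with a
known ancestral allele is exactly what a rooted perfect phylogeny
requires (the four-gamete test coincides with it on data generated under
the ISM, but laminarity is the property the construction needs).  Each
block gets a tree whose forced clades are the carrier sets, free joins
resolved at random, with coalescent waiting times assigned along a random
linear extension.  Every sample lineage is then split by one recombination
per block boundary at recent times, so each block coalesces independently
along its own tree.  This uses `n` recombinations per boundary rather than
the minimum; the construction is guaranteed valid and compatible, its
recombination count dominates the Hudson–Kaplan bound, and the excess is
pruned by the sampler during burn-in.  The stationary distribution does
not depend on the initializer.

## Sampler

Six proposal types are mixed with weights `(1/14, 1/14, 1/14, 1/14, 5/14,
5/14)`: SPR, recombination removal, recombination addition, breakpoint
resampling, the Kuhner move, and event-time resampling.  The fine
mechanics (documented in `argmc/moves.py`) were fixed here subject to
three requirements: exact reversibility with computable forward/reverse
densities, availability flags for degenerate states, and the stated count
contracts (SPR preserves the recombination count; removal/addition change
it by exactly one and are mutual inverses).  Unavailable proposals count
as automatic rejections.  All arithmetic is in the log domain.

Design choices worth recording:

* **Attachment machinery.**  SPR and the floating side of a recombination
  addition regraft onto a uniformly chosen target edge of the detached
  graph — or above a root — with attachment time uniform on the target
  edge's interval and exponential with mean `2N` above a root.  Forward
  and reverse moves share the same detached intermediate graph, so the
  target-count factors are computed identically in both directions.
* **Removal survivor.**  Removing a recombination picks a (record,
  surviving parent) pair; the discarded parent must be the child of a CA
  node, which is spliced out like an SPR detach.  Addition is the exact
  mirror (including the "bubble" case where the floating side rejoins the
  survivor's own upper half).
* **Kuhner move.**  Erases the ARG above the time of one of its
  `KUHNER_WINDOW = 6` most recent events (or above time 0 when the graph
  is small enough) and re-simulates the region from the CwR prior.
  Proposals whose re-simulated region exceeds the window have zero reverse
  density and are rejected, which keeps the kernel reversible.  The window
  keeps the rearrangement local: whole-graph re-simulation is almost never
  compatible with informative data, and the bounded version operates in
  the moderate-acceptance regime this family of samplers is designed for
  while small ARGs are still rebuilt wholesale.
* **Times move.**  Redraws every inter-event waiting time from its
  conditional exponential `Exp(lambda_i)` given the event-type sequence;
  its proposal density cancels the prior's waiting-time terms exactly.
  Because it is a *global* joint redraw, its acceptance drops as the
  number of segregating sites grows; it is kept global because that is the
  stated contract for this move.
* **Early rejection.**  Structurally invalid proposals, proposals with
  zero reverse density, and proposals incompatible with the data
  (mutation assignment fails) are rejected before any likelihood
  evaluation.

Correctness of the Hastings factors is enforced empirically by two
harnesses rather than by trusting the derivations: (i) for every proposal
type, accepted moves must round-trip — applying the encoded reverse move
reconstructs the previous state exactly, node ids included, and the quoted
densities match independent re-evaluation to 1e-9; (ii) a chain with
likelihood ≡ 1 using the full mixture must reproduce Hudson-simulator
means of the recombination count, total branch length and TMRCA within
Monte-Carlo error.

## Summaries and diagnostics

Per-site TMRCA is the marginal root time (piecewise constant between
breakpoints); allele age is the midpoint of the mutation's branch,
averaged over retained samples; the recombination-rate estimator is the
posterior mean of (#ancestral recombinations / site-summed total branch
length).  Intervals are equal-tailed with linear-interpolation quantiles.
Autocorrelations use the biased divide-by-`T` normalization; `T'` is the
first lag with non-positive autocorrelation; the effective sample size
truncates the autocorrelation sum at the initial strictly-positive run, so
`rho(1) <= 0` gives ESS = `T`.  The Gelman–Rubin factor is the classic
between/within-variance diagnostic without chain splitting.  The coverage
harness repeats simulate → infer → summarize and reports coverage, RMSE
and interval length per ARG property, with the binomial 95% band
`0.5 ± 1.96 sqrt(0.25/m)` for an `m`-replicate coverage estimate.

## Problem sizes used in the test suite

The full-scale study (150 datasets per scenario at `L = 1e5` with 2e6
iterations each) is a cluster-scale computation.  The package's own
experiments use sizes chosen so each check retains statistical power:
likelihood oracle equivalence on 200 random ARGs (`n <= 5`, `L <= 50`);
prior-sampling correctness at `n=4`, `L=100` with 1e5 iterations against
2e4 direct simulations; 1000 accepted moves per proposal type for
reversibility; the dataset-rejection rate over the full 450 draws at
`L = 1e5`; the mean acceptance rate on one dataset at `n=10`, `L=1e4`,
`R=2` over 1e5 iterations; interval calibration over 40 datasets at
`n=5`, `L=5e3` with 2e4-iteration chains (retained-chain ESS ≈ 400);
and ten 2e4-iteration chains for the multi-chain diagnostic.

## Limitations

* The likelihood is the discretized ISM: sites with more than two alleles
  or back-mutation are outside the model, and the ancestral allele must be
  known.
* Mixing degrades with sample size and mutation density: the global times
  move and the windowed Kuhner move make small steps relative to a sharp
  posterior, so output chains need to be long (the defaults follow the
  reference analysis: 2e6 iterations, 20% burn-in, thinning 400).
* The initializer starts from more recombinations than necessary; short
  chains on recombination-dense data may retain some of that excess.
* The synthetic-data generator *is* the model, so calibration experiments
  validate internal consistency (posterior computation and sampling), not
  robustness to model misspecification — real data violate the constant
  population size, neutrality, complete phasing and known-ancestral-allele
  assumptions in ways these tests cannot detect.
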