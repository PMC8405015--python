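# Methods

## Model

A species phylogeny is a rooted, binary, time-consistent network: nodes
carry ages in coalescent units of 2N generations (leaves at age 0), each
reticulation node has two parent edges whose inheritance probabilities γ sum
to one, and a network with no reticulations is an ultrametric species tree.
Genealogies of sampled individuals evolve inside the phylogeny under the
multispecies (network) coalescent: within every population (edge) each pair
of lineages coalesces at rate 1 per coalescent unit; a lineage reaching a
reticulation node picks a parent edge independently with probability γ; and
lineages that reach the network root keep coalescing in the root population
until a single ancestor remains.  A network can equivalently be viewed as a
mixture of its 2^r displayed trees with weights given by products of the
retained γ values; this equivalence is exact for the trait likelihood only
when at most one lineage can traverse each reticulation (see "Exact
evaluation" below), and is used in that regime as the quadrature oracle.

The binary trait follows a two-state Markov chain along genealogy branches
with instantaneous rates θu (0→1) and θv (1→0), where θ = 2Nμ is the
population mutation rate per coalescent unit.  By default (u, v) are
normalized so that π₀u + π₁v = 1 with (π₀, π₁) = (v, u)/(u+v) — the standard
bi-allelic-marker convention — so θ alone is the expected substitution rate
and a forward/backward ratio plus θ pins down (u, v).  The root state is
drawn from the stationary distribution; conditioning on a known ancestral
state (Dollo-style traits) is not implemented.  θ is a single global dial
for the trait chain: per-edge θ values are parsed, stored and round-tripped
(as `[&theta=...]` comments) for use in sequence-scale bookkeeping, but the
trait chain does not switch rates mid-branch.

Observed state counts give, per species, the number of sampled individuals
in each state.  Missing species are rejected.  Polymorphic counts are
evaluated by summing the pruning likelihood over all assignments of states
to that species' exchangeable leaves (∏ C(n₀+n₁, n₁) terms, capped at
2·10⁵).  At the sample sizes this package targets (≤ 10 per species) the
direct sum is exact and cheap; a count-indexed partial-likelihood recursion
would be the upgrade path for larger samples.

## Estimators

**Monte Carlo.**  f(A|Ψ) is estimated as the mean of the pruning likelihood
over genealogies sampled from f(G|Ψ); the standard error is the sample
standard deviation over √n.  Pruning is evaluated in linear space,
vectorized across genealogies (and count assignments) with closed-form
2×2 transition matrices; at ≤ 12 leaves partial likelihoods cannot
underflow double precision, which is why no log-space accumulation is used.
G-XRF uses independent genealogy streams for Ψ and T (spawned substreams of
one seed), so the combined standard error is the root-sum-square of the two
delta-method log-scale errors.  Common random numbers would shrink the
variance of the difference but invalidate that error formula; independence
was chosen deliberately.

**Exact evaluation.**  For ≤ 3 species, one sample per species, and every
reticulation on a pendant path (exactly one sampled lineage below it), the
network likelihood is the γ-weighted mixture of displayed-tree likelihoods,
and each tree term is integrated over coalescent histories: for a three-leaf
tree, (i) cherry coalescence on the internal branch (density e^(−s), s
truncated at 60 units, error < e^(−60)) followed by an Exp(1) root
coalescence, and (ii) the no-coalescence history with three lineages above
the root (first of three pairs at rate 3, uniform pair choice, then rate 1).
Integrals use Gauss–Legendre (finite intervals) and Gauss–Laguerre
(exponential tails) rules of order 96; agreement with fixed-grid Riemann
oracles is ~10⁻¹² and the reported standard error is 0.  Instances outside
this regime raise rather than silently approximating: with two or more
lineages able to traverse a reticulation, per-lineage parent choice breaks
the displayed-tree mixture.

**G-XRF.**  gxrf = ln L(Ψ) − ln L(T) + log prior odds, with log prior odds
defaulting to 0 (equal priors); the backbone T defaults to the major tree
(keep the higher-γ edge at each reticulation; at a tie the secondary,
#H-referenced edge is removed — deterministic and independent of float
noise).  The grid studies instead fix T to the "primary" displayed tree (the
underlying species tree with every transfer edge removed), because the major
tree would switch topology as γ crosses 0.5 mid-grid.  A zero likelihood
estimate yields ±∞ with a diagnostic note rather than an exception.

**HRF.**  For one internal branch of a species tree, the branch is reduced
to a rooted triplet: its two child clades and its sister clade, each
collapsed to a single lineage at its clade's MRCA age.  Triplet genealogies
are sampled under the MSC; on each, the probability that the incongruent
pattern (one child clade and the sister sharing the derived state) arises
from **exactly one** mutation on a branch whose descendants are exactly the
derived pair (hemiplasy; only discordant genealogies have such a branch) and
from **exactly two** mutations (homoplasy) are computed with per-branch
Poisson factors: 1 − e^(−θu·ℓ) for a gain, e^(−θu·ℓ) for no gain on a
0-background, e^(−θv·ℓ) for no loss below a gain.  Gain-then-loss pairs are
counted in the homoplasy term; on a three-lineage genealogy the enumeration
shows no such pair can produce the pattern, so in practice homoplasy is two
independent gains.  HRF is the ratio of the two Monte-Carlo means with a
delta-method standard error.  Note the θ-dependence: hemiplasy needs one
mutation (∝ θ) and homoplasy two (∝ θ²), so HRF scales like 1/θ at small θ
and *decreases* with θ for u = v — the quadrature oracle confirms this, and
the test suite reports (rather than asserts) that direction.

## Fixtures and what they do (not) emulate

`three_taxon_network(t1, t2, t_r, gamma)` builds the canonical scenario: a
species tree (A,(B,C)) with the (B,C) divergence at t1 (default 1, the
baseline internode interval), root at t2, and a horizontal transfer edge
from A's lineage into B's pendant at t_r.  Grids vary the internal branch
t2 − t1 over 0.001–10, γ over [0, 1], t_r over [0, 1] (clamped to 10⁻⁶,
since a reticulation at the leaves is degenerate), θ over 0.001–0.01, the
forward/backward ratio over {0.1, 1, 10}, and B's derived frequency as
counts (10−k, k) out of ten samples.

`six_taxon_network()` is a six-taxon, two-reticulation benchmark whose
topology follows a published anopheline phylogeny: divergences at 0.5, 0.75,
1.0, 2.0 and 2.5, and two introgression events at 0.25 in which Q's lineage
traces through A's ancestral population with probability 0.7 (retention 0.3)
and A's lineage through C's with probability 0.2 (retention 0.8).  The ages
are carried verbatim from the generating coalescent-simulation recipe;
Hudson-style simulators count time in 4N generations where this package uses
2N, so rescaling to that convention would halve or double the printed ages —
the fixture preserves the printed numbers and leaves the factor to the user.

These generators produce idealized data: a single panmictic population per
edge, no recombination within loci, free recombination between loci,
pulse-like (instantaneous) introgression, i.i.d. GTR sites with no rate
variation or indels, and exactly binary traits with stationary roots.
Passing tests therefore demonstrate internal correctness of the estimators
under the multispecies network coalescent — not robustness to continuous
migration, selection, rate heterogeneity or model misspecification in real
data.

## Numerical choices

- Quadrature order 96 (abs. accuracy well below the 10⁻¹⁰ contract);
  probability assertions use a 10⁻¹² tolerance.
- Newick floats are written with 17 significant digits; round-trips preserve
  topology, lengths, γ and per-edge θ to 10⁻¹⁰.
- Age consistency of parsed networks is enforced to 10⁻⁸ (relative);
  networks whose branch lengths are not time-consistent are rejected.
- Degree-2 nodes created by edge deletion are suppressed with lengths summed
  and θ merged length-weighted.
- All samplers draw from one seeded generator per call; per-locus, per-pair
  and per-cell substreams are spawned deterministically, so every table and
  simulation is reproducible from its seed.

## Problem sizes

Monte-Carlo marginal likelihoods use 10⁵ genealogies for headline numbers
and oracle comparisons, 2·10⁴ for identities and normalization checks, and
4–5·10³ per cell in parameter grids (11-point γ sweeps, 5×5 heat-map grids)
— sizes at which the trends of interest exceed three combined standard
errors while a full grid stays in the minutes range on one core.  HRF uses
2–6·10⁴ triplet genealogies.

## Limitations

- Exact evaluation is restricted to the pendant-reticulation, three-species,
  one-sample regime; everything larger is Monte Carlo.
- The HRF definition is an operational Monte-Carlo formulation of the
  hemiplasy-vs-homoplasy dichotomy on MSC triplets; branches of larger trees
  are collapsed to single lineages at clade MRCA ages, a minimal extension
  that ignores within-clade coalescent variance.
- No inference: networks, trees and their parameters are inputs (e.g.
  posterior samples from external Bayesian tools); the package evaluates
  trait-side quantities conditional on them.
- Binary traits only; no gene duplication/loss, no multistate or continuous
  traits, no ancestral-state conditioning.
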