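# Methods

This note records the models coalseq implements, the conventions and
numerical choices behind them, and the places where a design was genuinely
open and a choice had to be made. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Time and rate conventions

All rates are per generation. A population of size `N(t)` with ploidy `p`
gives a pairwise coalescence rate `1/(p N(t))`, so one "coalescent unit"
is `p N` generations; with the default `p = 2` this reproduces the
standard diploid `2N` scaling while allowing arbitrary ploidy. Sizes may
grow exponentially backwards in time, `N(t) = N0 e^{-g t}`; coalescence
waiting times within a growth epoch are drawn by closed-form inversion of
the integrated hazard, so no time discretization is involved.

Migration rates are *backwards in time*: `m[i][j]` is the per-generation
probability that a lineage now in population `i` traces back to `j`. This
is the classical `ms` convention. Because confusing the two directions is
the single most common demography error, `validate_demography` exists and
is deliberately strict (name uniqueness, matrix shape and signs, event
ordering, sampling from inactive populations, mutually unreachable
populations).

Genome coordinates are 0-based half-open `[left, right)`. Discrete
genomes restrict breakpoints and site positions to integers; continuous
genomes use reals. The recombination mass of a lineage uses the open-left
convention: no breakpoint at or before the first ancestral position, and
on discrete genomes the mass is summed over the internal integer
breakpoints only (`mass(left, right-1)`). Trapped gaps — non-ancestral
intervals between ancestral segments — contribute recombination and
gene-conversion initiation mass, as they must for the ancestral process
to be correct; the same convention is applied to gene conversion, where
the alternative (excluding gaps) would be defensible but is not used.

## The Hudson engine

The simulator holds a multiset of lineages indexed by (population,
label), a piecewise-constant *overlap count* map `S` (how many extant
segments cover each position), the growing tables, and one seeded
`numpy` generator. Each iteration draws competing-risk waiting times — a
single exponential for the combined constant-rate classes (recombination,
gene conversion, migration) and one growth-aware inversion per
(population, label) for coalescence — in a fixed documented order, so a
given (parameters, seed) pair yields byte-identical output. Scheduled
demographic events, model switches and the end time pre-empt stochastic
events; events at equal times execute in list order, with census after
lineage moves.

Merging is one generic k-way operation: elementary intervals covered by
two or more of the merging segments record a node (one per event, also
for multiple mergers — no binary refinement) and one edge per covering
segment; the overlap map decides which sub-intervals have reached their
MRCA (count equals cover) and are retired. Sub-intervals covered once
pass through unchanged. The same machinery serves Hudson common-ancestor
events, DTWF generation merges, bottleneck bursts and Λ-coalescent
multiple mergers.

Full-ARG recording adds two flagged nodes per recombination (left and
right parent) and one node per common-ancestor event (flagged as a
pass-through if nothing coalesced), with unary edges, leaving the random
stream untouched — so simplifying a full-ARG run reproduces the plain run
of the same seed exactly, which the tests assert byte-for-byte. Full-ARG
recording is not defined through a sweep phase and raises there.

Continuation from existing tables ("recapitation") creates one lineage
per root node per maximal interval over which it is a root; intervals
already below a single root everywhere are complete and take no further
part. New nodes only ever appear above the input's maximum node time.

## Alternative models

*SMC / SMC′* use naive rejection sampling: candidate pairs are drawn at
Hudson rates and rejected unless their material overlaps (SMC) or
overlaps-or-abuts (SMC′); rejections advance time. These models are for
studying the approximations themselves, not for speed.

*DTWF* steps generation by generation; every lineage picks a uniform
diploid parent in its population (so the model requires ploidy 2), its
material is split between the parent's two haploid genomes by a
Poisson-distributed crossover count (mean = recombination-map mass,
positions i.i.d. map-weighted, strictly alternating copies), and lineages
landing on one genome merge at the next integer time. When the
configuration is homogeneous (no recombination, migration or growth,
single population) generations are i.i.d., and the engine draws whole
blocks of genome assignments at once, jumping directly to the first
collision generation; this is an exact acceleration, not an
approximation. Hybrid runs switch models at scheduled times; a
DTWF-then-Hudson run has integer node times up to the switch and real
times above it.

*Instantaneous bottlenecks* of strength `B` run a single-locus Kingman
process for imaginary duration `B` (pair rate 1 on that clock) over the
lineages of one population and merge each resulting block in one k-way
merge at the event time, so a pair entering the bottleneck coalesces
there with probability `1 - e^{-B}` and strong bottlenecks produce
multifurcating nodes.

*Λ-coalescents.* Merger rates follow
`λ_{b,k} = ∫ x^{k-2} (1-x)^{b-k} Λ(dx)`, normalized so `λ_{2,2} = 1`.
BETA(α), `1 < α < 2`, uses the Beta(2-α, α) measure, giving
`λ_{b,k} = B(k-α, b-k+α) / B(2-α, α)` evaluated via log-gamma; the
quadrature oracle in the tests integrates the density independently with
algebraic endpoint weighting. DIRAC(ψ, c) is a unit Kingman atom plus
mass `c` at `ψ`. Rates are on the coalescent timescale and divided by
`p N` for generations; the exact timescale constants of specific
derivations in the literature differ by model-dependent factors, so the
normalization here (`λ_{2,2}=1`) is documented rather than asserted as
anyone else's constant. Under growth the current epoch-start size is
used; combine Λ-models with piecewise-constant sizes.

## Selective sweeps

A hard sweep is a frequency trajectory plus a structured coalescent
conditioned on it. The fixation-conditioned Wright–Fisher drift is
`D(x, α) = α x (1-x) / (1 - e^{-α x})` with `α = p N s`; its limits
(`x→0` gives 1, `α→0` gives `1-x`) are checked to 1e-6. The trajectory is
simulated *forward* from the allele's origin `1/(pN)` by an Euler scheme
with step `dt` in units of `pN` generations (default 1/400; halving it
changes mean durations by under 5%, which the tests verify), and the
sampled path is read in reverse. Reversal-by-reading is used because a
naive backward Euler step with the negated drift mishandles the entrance
behaviour at fixation; the resulting pair-coalescence-time law was
checked against an independent reference coalescent simulator's sweep
model by two-sample Kolmogorov–Smirnov.

During the phase every lineage is on the beneficial background (pair
rate `1/(pN x)`) or the wild background (`1/(pN (1-x))`); merges never
cross backgrounds. A lineage's phase links extend from the swept site to
the far end of its material: a breakpoint inside the material splits it,
the site-side piece keeping its background and the detached piece drawing
a fresh one (beneficial with probability `x`); a breakpoint between the
site and the material switches the whole lineage's background. Rates are
piecewise constant within each trajectory step. When the trajectory is
absorbed, the surviving beneficial-background lineages merge into the
single originating genome — a fixed allele has exactly one origin — and
the base model resumes. Gene conversion and migration are not modelled
within the phase (single population).

## Mutations

Transition matrices have zero diagonal: every recorded mutation changes
state, which keeps genotype and VCF semantics unambiguous and makes the
expected recorded-mutation count exactly the map mass times total edge
area, independent of model. The cost is that the stationary allele
distribution is that of the mutation *jump chain* (available as
`MutationModel.equilibrium()`), not the continuous-time chain's π; the
stationarity checks use the jump-chain equilibrium. Named nucleotide
models are built as exchangeabilities × equilibrium frequencies with rows
renormalized. The PAM and BLOSUM62 20-allele matrices shipped as TSV data
are derived from the published log-odds score matrices by inverting the
log-odds relation (`q_ij ∝ π_i π_j b^{s_ij}`, with the target frequencies
solved by fixed point, then conditioned and zero-diagonalized); they are
labelled synthetic derivations in their files, not copies of any other
package's data.

Positions on discrete genomes may collide: a new mutation at an existing
position reuses the site, and per-site mutation chains are threaded
oldest-to-youngest by walking node-to-root paths (each mutation's input
allele is its parent's derived allele, or the site's ancestral allele
drawn from the root distribution). The same path-walk re-threads parent
pointers after `simplify`, which the source tables do not determine once
nodes are removed. Time windows (`start_time`, `end_time`) clip edge
durations so layered epochs and multi-model overlays compose by
superposition.

## Likelihoods

ARG likelihoods require full-ARG tables in a single constant-size
population. Times are converted to coalescent units by `p·Ne`; with `k`
lineages of total span `ℓ` (genome units, trapped gaps included), each
inter-event interval contributes `-(k(k-1)/2 + ρ ℓ / 2) Δt`, a
common-ancestor event contributes rate 1 per pair, and a recombination
event contributes `log(ρ/2)` with the breakpoint uniform over links —
this per-unit-link normalization is a documented choice, validated
against hand-computed densities to 1e-10. Coincident event times are
rejected. The infinite-sites mutation likelihood is the Poisson-process
density `S log(θ/2) - (θ/2) A` over the tree area `A` (node times taken
in coalescent units); a site with more than one mutation raises.

## Demography numerics

The pair coalescence rate solves the Markov chain on unordered pair
locations plus an absorbing coalesced state: migration moves one lineage
at matrix rates, co-located pairs coalesce at `1/(p N_i(t))`. Epochs with
constant rates use the matrix exponential; growth epochs use adaptive
Runge–Kutta with relative tolerance 1e-8. `c(t)` is flux into absorption
divided by survival, and `IICR(t) = 1/(p c(t))` with an infinity sentinel
at zero rate. Lineage-moving events (splits, pulses) are not represented
in the chain — the numerics cover sizes, growth and migration changes;
more-than-two-lineage rates are out of scope.

## Validation design and problem sizes

Monte-Carlo checks use three standard errors with the replicate counts
fixed in the code; distribution tests use α = 0.01. The main sizes: 10^4
replicates for Kingman means, Watterson/SFS, DTWF geometric mean, and the
BETA(1.99) spectrum; 2×10^4 for the bottleneck probability; 200 per grid
point for the trapped-recombination bound; 10^5 for the two-island
pair-density histogram; 100 random table fixtures for the tree-iteration
oracle. The acceptance script re-derives every sub-seed from its single
`--seed` argument.

The synthetic data produced here is exactly what the models describe —
exchangeable samples from idealized randomly mating populations, neutral
apart from the single swept site, with homogeneous or piecewise rates.
Passing tests therefore demonstrate internal correctness of the
implemented stochastic processes and their analytic limits, not that any
real dataset follows these models: real genomes have selection at many
sites, non-exchangeable sampling, gene conversion/recombination
heterogeneity beyond piecewise maps, and sequencing error, none of which
are emulated.

## Known limitations

Pure-Python event loop: practical for sample sizes in the tens to
hundreds and scaled recombination rates up to a few tens, not for
chromosome-scale human simulations. Circular genomes, bacterial gene
transfer and multiple chromosomes per replicate are out of scope
(simulate chromosomes independently). The SMC variants are rejection
samplers, intentionally not an efficiency device. DTWF is diploid-only,
and Λ-models assume piecewise-constant sizes. Newick export requires a
single root; uncoalesced trees (from `end_time` truncation) must be
completed or exported as tables.
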