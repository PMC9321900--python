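# Methods

## Model and units

All times are expected substitutions per site.  A species phylogeny is
a rooted binary tree, optionally with horizontal introgression edges:
an introgression event is a hybrid node `H` at age `τ_H` on a
recipient branch plus a contemporaneous donor node at the same age on
another branch, with inheritance probability `φ` of taking the donor
side (backward in time).  Every branch, including tip branches and the
(unbounded) root population, carries its own `θ = 4Neμ`.  Populations
are identified with branches; a degree-2 donor node splits its branch
into two populations, so the five-species MSci networks carry 6 free
divergence/introgression times (hybrid and donor ages are tied), 13
`θ`s and 2 `φ`s — 21 parameters.

The two bundled five-species MSci networks place the introgression
pairs as follows.  Balanced network `A00-B` (`((A,(B)X)T,(C)Y)S` with
`((D)Z,(E)W)U` as sister group): hybrid `Y` sits on C's branch and
receives `φ_Y = 0.3` from donor `X` on B's branch below `T`; hybrid `W`
on E's branch receives `φ_W = 0.2` from donor `Z` on D's branch below
`U`.  Caterpillar network `A00-U` keeps `Y` on C (donor `X` on B below
`U`) and `W` on E (donor `Z` on D below `S`).  Both have all
introgression times equal to `θ`, give the 21-parameter count above,
and reproduce the recombination-count benchmarks for these models
within Monte-Carlo error, which is the available check on the
reconstruction.

Unit conversions: one unit of `4N_base` generations equals `θ_base`
mutation units.  A pair of lineages in a population of size `θ`
coalesces at rate `2/θ`; a lineage whose ancestral material spans `ℓ`
links recombines at rate `(ρ/1000)·ℓ/θ_base`, with `ρ = 4Ne·r` per kb
per generation.  Because all model grids set `τ ∝ θ`, the distribution
of recombination events per locus depends on `ρ` (and the number of
sampled sequences) but not on `θ`; this invariance is tested.

## ARG simulation

The simulator implements Hudson's exact coalescent-with-recombination
(no sequentially-Markov approximation), structured by the network's
backward-time event schedule (population merges at divergence times;
Bernoulli(φ) routing at hybrid ages, with MERGE processed before ROUTE
at ties).  Ancestral material is tracked as half-open integer site
intervals; recombination acts on the links strictly between a
lineage's leftmost and rightmost carried sites (Hudson's convention,
including "trapped" non-ancestral material), with the breakpoint drawn
uniformly over those links; repeat hits of a link are allowed.
Coalescing lineages merge material; intervals that reach the sample-wide
most recent common ancestor are dropped, and simulation ends when no
ancestral material remains.  Coalescence records `(interval, time,
parent, children)` reconstruct the marginal tree of any site.

Two per-locus recombination statistics are exposed, and they differ at
high `ρ`:

* `num_events` — executed breadth-splitting crossovers.  This matches
  the full-ARG recombination-event count of an independent simulator
  (msprime) on identical demographies.
* `num_tree_transitions` — distinct *effective* breakpoints, where an
  event's effective position is the first ancestral site of its right
  half (splits inside trapped material snap to the next material edge,
  and repeat positions collapse).  This is the number of per-segment
  trees an ms-style `-T` output would print, minus one, and it is the
  statistic the benchmark per-locus "recombination events" tables
  summarize — the two definitions agree below `ρ ≈ 0.5`/kb and diverge
  by ~15% at `ρ = 5`/kb.  Benchmark reproduction uses this statistic.

One RNG stream per locus (`locus_rng`) derives from
`base_seed + replicate·L + locus` for reproducibility under any
execution order.

## Sequence simulation

JC69 by direct transition-probability sampling per branch per site:
root states uniform on {T,C,A,G}; along a branch of length `t` a site
is retained with probability `1/4 + (3/4)e^{-4t/3}` and otherwise jumps
uniformly to one of the other three states.  Sites are i.i.d. within a
segment given that segment's tree; segments are concatenated in
breakpoint order.  No rate heterogeneity, indels or ambiguity codes.

## Inference

The likelihood is Felsenstein pruning under JC69 over
`numpy.unique`-compressed site patterns.  The MSC/MSci density is
computed by sweeping each gene tree through the demographic schedule,
collecting per-population sufficient statistics `(k, c)` (number of
coalescences; `Σ C(j,2)·dt`), giving `Π_p (2/θ_p)^k e^{-2c/θ_p}` times
`φ`/`1−φ` per hybrid passage.  With conjugate `invGamma(α, β)` priors,
`θ` is either Gibbs-sampled from `invGamma(α+k, β+2c)` (A00, which
reports `θ` estimates) or integrated analytically, population by
population, as `2^k β^α Γ(α+k) / (Γ(α)(β+2c)^{α+k})` (A01).  The prior
on node ages is `invGamma` on the root age with the non-root ages
jointly uniform over the order polytope given the root — a
scaling-homogeneous region, so the prior contributes `−d·log τ0` for
`d` free non-root ages.

Moves, all JIT-compiled: per-locus gene-node age slides (a multiplier
for the gene-tree root), Wilson–Balding subtree regrafts (attachment
above the pruned root uses an exponential tail with fixed scale
`τ̄_prior/2`), symmetric flips of hybrid path indicators, a
sliding-window update of each `τ` with a rubber-band remap of gene-node
ages between the neighbouring `τ` bounds (piecewise-linear, with the
product of segment ratios as Jacobian), a whole-model rescaling move
(all `τ`, all gene ages, and in A00 all `θ`, with `x^{dim}` Jacobian),
and — for A01 — nearest-neighbour interchanges of the species tree with
the gene trees held fixed (proposals that strand a coalescence outside
its population are rejected through the density).  Hybrid path
indicators needed by a proposal but absent from the current state are
drawn `Bernoulli(φ)` inside the proposal with the matching Hastings
terms; `φ` itself is updated by an exact Beta Gibbs step (uniform prior
plus Bernoulli indicator counts), chosen over a reflected random walk
because it is tuning-free and mixes at least as well.  Step sizes are
autotuned toward ~30% acceptance during burn-in, then frozen.

Chains initialize at the prior means (node ages rescaled
proportionally, `φ = 1/2`) with gene trees drawn from the MSC at those
parameters, so initialization never uses the generating values beyond
the relative node order of the supplied topology.  Convergence checking
across independent chains is available via `convergence_flag`
(clade/tree probability discrepancy > 0.05).

Posterior summaries: means; 95% HPD as the shortest contiguous window
of sorted samples; ESS by the initial positive-sequence autocorrelation
estimator; tree and clade probabilities as sample frequencies; MAP tree
with lexicographic Newick tie-break.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions exactly: species models
with `τ ∝ θ`, `θ ∈ {0.0025, 0.01}`, `ρ ∈ {0.05, 0.5, 5}`/kb,
`S ∈ {2, 8}` sequences per species, 500-bp loci, `L ∈ {40, 160}`,
`R = 100` replicates, and `φ_Y = 0.3, φ_W = 0.2` for the introgression
networks.  It does not emulate recombination hot spots or variable
recombination along the locus, gene conversion, rate heterogeneity
among sites, sequencing error, or misassignment of samples to species —
so passing tests demonstrate robustness of the inference machinery to
uniform-rate intralocus recombination, not to every failure mode of
real reduced-representation data.

## Numerical choices

Pruning skips per-node rescaling (partials stay far above the
double-precision floor for the ≤40-tip alignments used here) and
returns `-1e300` on underflow.  Tied demographic event times are
processed MERGE-before-ROUTE; a coalescence exactly at a boundary age
belongs to the ancestral population.  The collapsed divergence times of
the species-delimitation trees are `1e-50·θ`, far below any floating
point resolution issue at the scales involved.  HPD is computed on the
sample, not on a density fit.  MAP-tree ties break lexicographically.
Breakpoints are discrete links; `compare_segment_trees` classifies
neighbouring segment trees as identical ("invisible" recombination),
lengths-only, or topology changes with a `1e-12` age tolerance.

## Desk-scale problem sizes

The full experiments (4800 MCMC analyses per experiment, chains of
32,000 burn-in plus 100,000×5 iterations) are available as presets.
The test suite exercises the same machinery at desk scale, as the
package's own choice of problem size: recombination-count benchmarks at
250–4000 loci per setting (Monte-Carlo error well below the printed
precision), HPD calibration of the root divergence time at `L = 50`
loci and 20 replicates with 4,000-iteration chains, and the
directional-bias experiment at `ρ = 5` with `L = 50`, `R = 20` and
2,800-iteration chains.  The acceptance script runs the count
benchmarks at the full 100 × 160-locus scale.

## Known limitations

The A01 topology move holds gene trees fixed, which mixes slowly for
many species with strong signal; it is adequate for the small species
numbers exercised here, whereas full-scale five-species tree estimation
would benefit from a coordinated species-tree/gene-tree SPR.  ESS of
deep `τ` parameters is the practical chain-length bottleneck in the
MSci model.  The benchmark per-locus recombination counts are matched
through the segment-transition statistic described above; raw executed
crossover counts run ~15% higher at `ρ = 5`/kb, a definitional rather
than dynamical difference (the executed counts themselves match
msprime's full-ARG event counts).
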