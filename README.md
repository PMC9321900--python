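# mscrecomb

Phylogenomic inference under the multispecies coalescent (MSC) assumes
that every site of a locus shares one genealogy — that there is no
recombination within loci.  Real loci recombine.  `mscrecomb` is a
simulation laboratory for measuring what that misspecification costs:
it simulates multilocus sequence data under MSC and
MSC-with-introgression (MSci) models **with** Hudson-style intralocus
recombination, re-infers species trees and population parameters by
Bayesian MCMC under the recombination-free model, and scores the damage
(tree recovery, bias, credible-interval coverage, relative RMSE) across
replicates.  It is aimed at statistical phylogeneticists who want a
fully scriptable, fully testable version of this robustness experiment.

## The model in brief

A species phylogeny is a rooted tree or network with node ages `τ`
(expected substitutions/site) and one mutation-scaled population size
`θ = 4Neμ` per branch.  Backward in time, lineages within a population
of size `θ` coalesce at rate `2/θ` per pair; an introgression
(hybridization) node sends each passing lineage to its donor parent
with probability `φ` and to its main parent with probability `1−φ`.
Intralocus recombination follows Hudson's exact ancestral recombination
graph: a lineage spanning `ℓ` links recombines at rate `(ρ/1000)·ℓ/θ_base`
per unit of mutation-scaled time, where `ρ = 4Ne r` per kb per
generation, so that recombination-event counts depend on `ρ` but not on
`θ` when all `τ ∝ θ`.  Sequences evolve along each recombination
segment's gene tree under JC69.

Inference ignores recombination: per-locus gene trees are latent
variables of a Metropolis-within-Gibbs sampler with priors
`τ0 ~ invGamma(3, 10θ)`, `θ ~ invGamma(3, 2θ)` (optionally integrated
out analytically through conjugacy) and `φ ~ U(0,1)`.  Two analyses are
implemented: **A00** (topology fixed, estimate `τ, θ, φ`) and **A01**
(species-tree topology estimation).

## Worked example

Simulate a small multilocus data set under the balanced five-species
tree with a human-like recombination rate, then estimate the MSci
parameters of an introgression data set:

```
$ mscrecomb simulate --model A01-B --theta 0.0025 --rho 0.5 \
      --n-seqs 2 --loci 8 --seed 3 --out run1
simulated 8 loci; mean events/locus 7.125, zero fraction 0.000
```

Eight loci of 500 bp were produced (`run1/alignments.phy`,
`run1/segment_trees.txt`, `run1/events.tsv`); at `ρ = 0.5`/kb a 500-bp
locus accumulates about seven recombination events, and essentially no
locus is recombination-free — the mean printed above matches the
generating process, not an estimate.

The same machinery runs from Python:

```python
import numpy as np
from mscrecomb import (build_study_model, make_sample_map,
                       SimulationDesign, simulate_locus, evolve_jc,
                       run_a00, summarize_posterior, MCMCSettings)
from mscrecomb.harness import prior_for_theta

theta = 0.01
net = build_study_model("A00-B", theta)       # MSci network, phiY=0.3
smap = make_sample_map(net, 2)                # 2 sequences per species
design = SimulationDesign(S=2, L=50, n=500, rho=0.0, theta_base=theta)
rng = np.random.default_rng(100)
loci = [evolve_jc(simulate_locus(net, smap, design, rng), rng)
        for _ in range(50)]
chain = run_a00(loci, net, smap, prior_for_theta(theta),
                MCMCSettings(burnin=3000, nsamples=4000,
                             sample_interval=3, seed=7))
s = summarize_posterior(chain)
print(round(s.means["tau_R"], 4), [round(x, 4) for x in s.hpd["tau_R"]])
```

prints `0.0485 [0.0464, 0.0506]`: the posterior mean of the root age is
within 3% of the generating value `5θ = 0.05` and the 95% HPD interval
covers it, as it should for recombination-free data under a correctly
specified model.

Experiment presets (`mscrecomb reproduce counts|a01|a00 --scale 0.05`)
run the three factorial experiment grids — at full scale, 4800 replicate
data sets each — with resumable per-job manifests.

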