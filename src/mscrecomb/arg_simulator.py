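"""Coalescent-with-recombination simulation inside a species network.

Implements the exact (non-Markovian-approximation-free) Hudson ancestral
recombination graph, constrained by the demographic history of a
:class:`~mscrecomb.species_model.SpeciesNetwork`: within a population of
size ``theta`` each lineage pair coalesces at rate ``2/theta`` per unit of
mutation-scaled time; each lineage recombines at rate
``(rho/1000)/theta_base`` per link spanned by its ancestral breadth
(Hudson's convention, which includes links through trapped non-ancestral
material but nothing outside the leftmost/rightmost carried sites);
breakpoints are discrete links chosen uniformly over the spanned links.
At a hybrid node's age every lineage in the hybrid population moves to the
donor parent with probability ``phi``; at a merge age lineages transfer to
the ancestral population.  Simulation runs until every link's ancestral
material has reached its most recent common ancestor.

One unit of ``4*N_base`` generations equals ``theta_base`` units of
mutation-scaled time, which makes the distribution of recombination-event
counts depend on ``rho`` but not on ``theta`` for designs in which all
``tau`` are proportional to ``theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .species_model import (NetworkError, SampleMap, SpeciesNetwork,
                            event_schedule)

__all__ = [
    "SimulationDesign",
    "LocusGenealogy",
    "MarginalTree",
    "simulate_locus",
    "count_recombination_events",
    "marginal_tree_at",
    "write_segment_trees",
    "locus_rng",
]


@dataclass
class SimulationDesign:
    """The per-locus simulation conditions of one experimental setting.

    ``rho`` is the population recombination rate ``4*N_e*r`` per kb per
    generation; ``theta_base`` anchors the conversion between coalescent
    and mutation time units (the design-wide theta of the tau-proportional
    model grids).
    """

    S: int = 2          # sequences per species
    L: int = 160        # loci per replicate
    n: int = 500        # sites per locus
    rho: float = 0.0    # 4*Ne*r per kb per generation
    theta_base: float = 0.0025
    R: int = 100        # replicates
    seed: int = 0

    def validate(self) -> "SimulationDesign":
        if self.n < 2:
            raise NetworkError("need at least 2 sites per locus")
        if self.rho < 0:
            raise NetworkError("rho must be nonnegative")
        if self.theta_base <= 0:
            raise NetworkError("theta_base must be positive")
        if self.S < 1 or self.L < 1 or self.R < 1:
            raise NetworkError("S, L and R must be positive")
        return self


def locus_rng(design: SimulationDesign, replicate: int, locus: int) -> np.random.Generator:
    """One independent RNG stream per locus: seed = base + rep*L + locus."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed,
                               spawn_key=(replicate * design.L + locus,)))


@dataclass
class MarginalTree:
    """A rooted, dated gene tree for one segment of a locus."""

    parent: dict[int, int]        # node -> parent (root absent)
    children: dict[int, list[int]]
    age: dict[int, float]         # node -> age, substitutions/site
    root: int
    labels: dict[int, str]        # tip node -> sequence label

    def newick(self, precision: int = 10) -> str:
        def render(v: int) -> str:
            kids = self.children.get(v, [])
            if not kids:
                name = self.labels[v]
            else:
                name = ""
            body = f"({','.join(render(c) for c in kids)})" if kids else ""
            if v == self.root:
                return f"{body}{name}"
            blen = self.age[self.parent[v]] - self.age[v]
            return f"{body}{name}:{blen:.{precision}g}"

        return render(self.root) + ";"

    def tip_set(self) -> frozenset[str]:
        return frozenset(self.labels.values())


@dataclass
class LocusGenealogy:
    """Segment decomposition of one locus' genealogical history."""

    n: int
    sample_labels: list[str]
    # coalescence records (left, right, time, parent_id, child1, child2)
    records: list[tuple[int, int, float, int, int, int]]
    # executed recombination events (time, breakpoint link, lineage node ids)
    events: list[tuple[float, int, tuple[int, ...]]]
    # hybrid routing records (hybrid label, lineage node ids, took donor path)
    routing: list[tuple[str, tuple[int, ...], bool]] = field(default_factory=list)
    # per-event effective breakpoint: the first ancestral site carried by
    # the right half (equals the link for splits inside ancestral
    # material; snaps to the next material edge for splits in trapped
    # material) — the position at which ms-style segment output changes
    effective_breakpoints: list[int] = field(default_factory=list)

    @property
    def num_events(self) -> int:
        return len(self.events)

    @property
    def num_tree_transitions(self) -> int:
        """Distinct effective breakpoints: the number of segment-tree
        changes an ms-style per-segment output records (repeat hits of
        one link and events inside the same trapped gap collapse)."""
        return len(set(self.effective_breakpoints))

    @property
    def breakpoints(self) -> list[int]:
        inner = sorted({link for _, link, _ in self.events})
        return [0] + inner + [self.n]

    @property
    def num_segments(self) -> int:
        return len(self.breakpoints) - 1

    def segments(self) -> list[tuple[int, int]]:
        b = self.breakpoints
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def tree_at(self, site: int) -> MarginalTree:
        return marginal_tree_at(self, site)

    def segment_trees(self) -> list[tuple[int, int, MarginalTree]]:
        return [(l, r, self.tree_at(l)) for l, r in self.segments()]


def count_recombination_events(g: LocusGenealogy) -> int:
    """Number of executed breadth-splitting recombination events."""
    return len(g.events)


def marginal_tree_at(g: LocusGenealogy, site: int) -> MarginalTree:
    """The rooted dated gene tree of the segment containing ``site``."""
    if not (0 <= site < g.n):
        raise IndexError(f"site {site} outside locus of {g.n} sites")
    nsamp = len(g.sample_labels)
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    age: dict[int, float] = {i: 0.0 for i in range(nsamp)}
    recs = [r for r in g.records if r[0] <= site < r[1]]
    recs.sort(key=lambda r: r[2])
    for _, _, t, u, c1, c2 in recs:
        parent[c1] = u
        parent[c2] = u
        children[u] = [c1, c2]
        age[u] = t
    roots = [v for v in age if v not in parent]
    if len(roots) != 1:
        raise NetworkError(f"site {site}: malformed genealogy ({len(roots)} roots)")
    return MarginalTree(parent=parent, children=children, age=age,
                        root=roots[0],
                        labels=dict(enumerate(g.sample_labels)))


# ---------------------------------------------------------------------------
# The simulator


def _links(segs: list[tuple[int, int, int, int]]) -> int:
    # segments sorted, half-open [left, right); spanned links are those
    # strictly between the leftmost and rightmost carried sites
    return segs[-1][1] - 1 - segs[0][0]


def simulate_locus(network: SpeciesNetwork, samples: SampleMap,
                   design: SimulationDesign,
                   rng: np.random.Generator) -> LocusGenealogy:
    """Simulate the ARG of one locus backward in time.

    Returns the full segment-tree decomposition together with the executed
    recombination events and hybrid-routing outcomes.
    """
    design.validate()
    samples.validate(network)
    schedule = event_schedule(network)
    n = design.n

    pop_index = {lab: i for i, lab in enumerate(sorted(network.age))}
    theta = [0.0] * len(pop_index)
    for lab, i in pop_index.items():
        theta[i] = network.theta[lab]

    sample_labels = sorted(samples.assignment)
    total = len(sample_labels)
    if total < 2:
        raise NetworkError("need at least two sampled sequences in total")

    # lineage = [segments, population]; segment = (left, right, node, count)
    lineages: list[list] = []
    for i, seq in enumerate(sample_labels):
        lineages.append([[(0, n, i, 1)], pop_index[samples.assignment[seq]]])

    rec_coef = (design.rho / 1000.0) / design.theta_base
    next_node = total
    records: list[tuple[int, int, float, int, int, int]] = []
    events: list[tuple[float, int, tuple[int, ...]]] = []
    routing: list[tuple[str, tuple[int, ...], bool]] = []
    effective: list[int] = []
    pending = list(schedule.events)
    ev_i = 0
    t = 0.0

    def coalesce(a: list, b: list, time: float) -> list | None:
        nonlocal next_node
        u = next_node
        next_node += 1
        out: list[tuple[int, int, int, int]] = []
        ia = ib = 0
        sa, sb = a[0], b[0]
        while ia < len(sa) and ib < len(sb):
            la, ra, na, ca = sa[ia]
            lb, rb, nb, cb = sb[ib]
            if ra <= lb:
                out.append(sa[ia]); ia += 1; continue
            if rb <= la:
                out.append(sb[ib]); ib += 1; continue
            # overlap
            lo = max(la, lb)
            if la < lo:
                out.append((la, lo, na, ca))
            if lb < lo:
                out.append((lb, lo, nb, cb))
            hi = min(ra, rb)
            records.append((lo, hi, time, u, na, nb))
            cnt = ca + cb
            if cnt < total:
                out.append((lo, hi, u, cnt))
            if ra > hi:
                sa = sa[:ia] + [(hi, ra, na, ca)] + sa[ia + 1:]
                a[0] = sa
                ib += 1
            elif rb > hi:
                sb = sb[:ib] + [(hi, rb, nb, cb)] + sb[ib + 1:]
                b[0] = sb
                ia += 1
            else:
                ia += 1
                ib += 1
        out.extend(sa[ia:])
        out.extend(sb[ib:])
        if not out:
            return None
        out.sort()
        # merge adjacent pieces carried by the same ancestor node
        merged = [out[0]]
        for seg in out[1:]:
            last = merged[-1]
            if seg[0] == last[1] and seg[2] == last[2] and seg[3] == last[3]:
                merged[-1] = (last[0], seg[1], last[2], last[3])
            else:
                merged.append(seg)
        return merged

    while lineages:
        # per-population lineage counts
        kpop: dict[int, int] = {}
        for lin in lineages:
            kpop[lin[1]] = kpop.get(lin[1], 0) + 1
        coal_rate = 0.0
        for p, k in kpop.items():
            if k >= 2:
                coal_rate += k * (k - 1) / theta[p]
        links_tot = 0
        if rec_coef > 0.0:
            for lin in lineages:
                links_tot += _links(lin[0])
        rec_rate = rec_coef * links_tot
        rate = coal_rate + rec_rate
        t_next = pending[ev_i].time if ev_i < len(pending) else math.inf
        if rate <= 0.0:
            if math.isinf(t_next):
                raise NetworkError("simulation stalled: no events possible")
            dt = math.inf
        else:
            dt = rng.exponential(1.0 / rate)
        if t + dt >= t_next:
            # apply the scheduled demographic event
            ev = pending[ev_i]
            ev_i += 1
            t = ev.time
            srcs = {pop_index[s] for s in ev.sources}
            if ev.kind == "MERGE":
                dest = pop_index[ev.dest]
                for lin in lineages:
                    if lin[1] in srcs:
                        lin[1] = dest
            else:  # ROUTE
                dest = pop_index[ev.dest]          # donor side, prob phi
                alt = pop_index[ev.alt_dest]       # primary side
                hlabel = ev.alt_dest
                for lin in lineages:
                    if lin[1] in srcs:
                        take_donor = rng.random() < ev.prob
                        lin[1] = dest if take_donor else alt
                        routing.append(
                            (hlabel, tuple(s[2] for s in lin[0]), take_donor))
            continue
        t += dt
        u = rng.random() * rate
        if u < rec_rate:
            # recombination: pick a lineage weighted by its spanned links
            target = u / rec_coef
            acc = 0.0
            lin = lineages[-1]
            for cand in lineages:
                acc += _links(cand[0])
                if target < acc:
                    lin = cand
                    break
            segs = lin[0]
            lo = segs[0][0]
            hi = segs[-1][1] - 1
            link = int(rng.integers(lo + 1, hi + 1))  # link in {lo+1..hi}
            left: list = []
            right: list = []
            for seg in segs:
                sl, sr, nd, ct = seg
                if sr <= link:
                    left.append(seg)
                elif sl >= link:
                    right.append(seg)
                else:
                    left.append((sl, link, nd, ct))
                    right.append((link, sr, nd, ct))
            events.append((t, link, tuple(s[2] for s in segs)))
            effective.append(right[0][0])
            lin[0] = left
            lineages.append([right, lin[1]])
        else:
            # coalescence: pick the population, then a uniform pair
            target = u - rec_rate
            acc = 0.0
            pop = -1
            for p, k in kpop.items():
                if k >= 2:
                    acc += k * (k - 1) / theta[p]
                    if target < acc:
                        pop = p
                        break
            members = [i for i, lin in enumerate(lineages) if lin[1] == pop]
            i1, i2 = rng.choice(len(members), size=2, replace=False)
            a = lineages[members[i1]]
            b = lineages[members[i2]]
            merged = coalesce(a, b, t)
            for idx in sorted((members[i1], members[i2]), reverse=True):
                lineages.pop(idx)
            if merged is not None:
                lineages.append([merged, a[1]])

    return LocusGenealogy(n=n, sample_labels=sample_labels,
                          records=records, events=events, routing=routing,
                          effective_breakpoints=effective)


# ---------------------------------------------------------------------------
# Output


def write_segment_trees(g: LocusGenealogy, sink: TextIO,
                        precision: int = 10) -> None:
    """ms ``-T``-style output: one Newick line per segment, prefixed with
    the segment length in sites, e.g. ``[500](a:0.1,b:0.1);``."""
    for left, right, tree in g.segment_trees():
        sink.write(f"[{right - left}]{tree.newick(precision=precision)}\n")
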