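"""Species trees and introgression (MSci) networks.

A species phylogeny is represented by node ages and child->parent edges.
Times (``tau``) are measured in expected substitutions per site, and every
branch (population) carries a mutation-scaled population size
``theta = 4*Ne*mu`` per site, so that a pair of lineages inside a population
of size ``theta`` coalesces at rate ``2/theta`` per unit of mutation-scaled
time.

Populations are identified with edges and keyed by the label of the node at
the *bottom* of the edge; the root label names the (unbounded) population
above the root.  An introgression event is a hybrid node with two parents:
one positive-length "primary" edge carrying the hybrid's own theta, and one
zero-length "donor" edge to a contemporaneous node on another branch.  A
lineage reaching the hybrid node moves to the donor side with the
inheritance probability ``phi`` attached to that parent edge.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SpeciesNetwork",
    "SampleMap",
    "EventSchedule",
    "ScheduledEvent",
    "NetworkError",
    "parse_species_network",
    "write_species_network",
    "build_study_model",
    "event_schedule",
    "make_sample_map",
    "read_sample_map",
    "write_sample_map",
]

AGE_TOL = 1e-12

STUDY_MODELS = ("A01-B", "A01-U", "A11-shallow", "A11-deep", "A00-B", "A00-U")


class NetworkError(ValueError):
    """Raised for syntactically or semantically invalid species networks."""


@dataclass
class SpeciesNetwork:
    """A dated species tree or network with per-branch population sizes.

    Parameters
    ----------
    age
        Node label -> node age (tips must be 0).
    parents
        Node label -> tuple of parent labels (1 entry, or 2 for hybrids);
        the root is absent from this mapping.
    theta
        Node label -> population size of the edge above the node; the root
        label keys the root population.  Zero-length donor edges of hybrid
        nodes carry no population and take no theta.
    phi
        Hybrid node label -> {parent label: inheritance probability}.
    """

    age: dict[str, float]
    parents: dict[str, tuple[str, ...]]
    theta: dict[str, float]
    phi: dict[str, dict[str, float]] = field(default_factory=dict)

    # -- derived structure -------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return sorted(self.age)

    @property
    def root(self) -> str:
        roots = [v for v in self.age if v not in self.parents]
        if len(roots) != 1:
            raise NetworkError(f"network must have exactly one root, found {roots}")
        return roots[0]

    @property
    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {v: [] for v in self.age}
        for c, ps in self.parents.items():
            for p in ps:
                ch[p].append(c)
        for v in ch:
            ch[v].sort()
        return ch

    @property
    def tips(self) -> list[str]:
        ch = self.children
        return sorted(v for v in self.age if not ch[v])

    @property
    def hybrid_nodes(self) -> list[str]:
        return sorted(v for v, ps in self.parents.items() if len(ps) == 2)

    def primary_parent(self, hybrid: str) -> str:
        """The parent reached through the positive-length edge."""
        ps = self.parents[hybrid]
        older = [p for p in ps if self.age[p] > self.age[hybrid] + AGE_TOL]
        return older[0]

    def donor_parent(self, hybrid: str) -> str:
        """The contemporaneous parent of the zero-length introgression edge."""
        ps = self.parents[hybrid]
        same = [p for p in ps if abs(self.age[p] - self.age[hybrid]) <= AGE_TOL]
        return same[0]

    # -- validation --------------------------------------------------------

    def validate(self) -> "SpeciesNetwork":
        _ = self.root
        ch = self.children
        for c, ps in self.parents.items():
            if len(ps) not in (1, 2):
                raise NetworkError(f"node {c!r} has {len(ps)} parents")
            for p in ps:
                if p not in self.age:
                    raise NetworkError(f"unknown parent {p!r} of {c!r}")
                if self.age[p] < self.age[c] - AGE_TOL:
                    raise NetworkError(
                        f"parent {p!r} (age {self.age[p]}) younger than child "
                        f"{c!r} (age {self.age[c]})")
        for t in self.tips:
            if abs(self.age[t]) > AGE_TOL:
                raise NetworkError(f"tip {t!r} must have age 0, has {self.age[t]}")
        for h in self.hybrid_nodes:
            ps = self.parents[h]
            if h not in self.phi:
                raise NetworkError(f"hybrid node {h!r} lacks phi")
            probs = self.phi[h]
            if set(probs) != set(ps):
                raise NetworkError(f"phi keys of {h!r} do not match its parents")
            for p, f in probs.items():
                if not (0.0 <= f <= 1.0):
                    raise NetworkError(f"phi={f} of {h!r}->{p!r} outside [0,1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise NetworkError(f"phi of {h!r} does not sum to 1")
            same = [p for p in ps if abs(self.age[p] - self.age[h]) <= AGE_TOL]
            if len(same) != 1:
                raise NetworkError(
                    f"hybrid {h!r} needs exactly one contemporaneous (donor) "
                    f"parent; found {len(same)}")
        # every positive-length edge needs a finite positive theta
        for v in self.age:
            if self._has_population(v):
                th = self.theta.get(v)
                if th is None or not math.isfinite(th) or th <= 0:
                    raise NetworkError(f"population above {v!r} needs theta > 0")
        # the graph restricted to primary edges must be a tree (acyclicity)
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise NetworkError("cycle in primary-edge tree")
            seen.add(v)
            for c in ch[v]:
                if len(self.parents[c]) == 1 or self.primary_parent(c) == v:
                    stack.append(c)
        if seen != set(self.age):
            raise NetworkError("primary-edge graph is not a spanning tree")
        return self

    def _has_population(self, v: str) -> bool:
        """Does node v key a population (the edge above it / root pop)?"""
        if v not in self.parents:  # root population
            return True
        return True  # hybrid nodes key their positive-length primary edge

    def population_interval(self, v: str) -> tuple[float, float]:
        """Existence interval [start, end) of the population keyed by v."""
        lo = self.age[v]
        if v not in self.parents:
            return lo, math.inf
        if len(self.parents[v]) == 2:
            return lo, self.age[self.primary_parent(v)]
        return lo, self.age[self.parents[v][0]]

    def scaled(self, factor: float) -> "SpeciesNetwork":
        return SpeciesNetwork(
            age={v: a * factor for v, a in self.age.items()},
            parents=dict(self.parents),
            theta=dict(self.theta),
            phi={h: dict(d) for h, d in self.phi.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesNetwork):
            return NotImplemented

        def close(a: Mapping[str, float], b: Mapping[str, float]) -> bool:
            return set(a) == set(b) and all(
                math.isclose(a[k], b[k], rel_tol=1e-9, abs_tol=1e-300) for k in a)

        return (
            close(self.age, other.age)
            and {k: tuple(sorted(v)) for k, v in self.parents.items()}
            == {k: tuple(sorted(v)) for k, v in other.parents.items()}
            and close(self.theta, other.theta)
            and set(self.phi) == set(other.phi)
            and all(close(self.phi[h], other.phi[h]) for h in self.phi)
        )


# ---------------------------------------------------------------------------
# Sample maps


@dataclass
class SampleMap:
    """Assignment of sequence labels to species (bpp Imap semantics)."""

    assignment: dict[str, str]

    def species(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def sequences_of(self, species: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == species)

    def validate(self, network: SpeciesNetwork) -> "SampleMap":
        tips = set(network.tips)
        for seq, sp in self.assignment.items():
            if sp not in tips:
                raise NetworkError(f"sequence {seq!r} maps to non-tip {sp!r}")
        if not self.assignment:
            raise NetworkError("empty sample map")
        return self

    def __len__(self) -> int:
        return len(self.assignment)


def make_sample_map(network: SpeciesNetwork, n_per_species: int,
                    species: Iterable[str] | None = None) -> SampleMap:
    if n_per_species < 1:
        raise NetworkError("need at least one sequence per sampled species")
    sel = list(species) if species is not None else network.tips
    return SampleMap({f"{sp}{i}": sp for sp in sel
                      for i in range(1, n_per_species + 1)}).validate(network)


def write_sample_map(smap: SampleMap, path) -> None:
    with open(path, "w") as fh:
        for seq in sorted(smap.assignment):
            fh.write(f"{seq}\t{smap.assignment[seq]}\n")


def read_sample_map(path) -> SampleMap:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            seq, sp = line.split()
            out[seq] = sp
    return SampleMap(out)


# ---------------------------------------------------------------------------
# Extended-Newick (de)serialization

_TOKEN = re.compile(r"\s*([(),;]|\[&[^\]]*\]|[^\s(),;\[\]]+)")


def _parse_attrs(text: str) -> dict[str, float]:
    body = text[2:-1]  # strip "[&" and "]"
    out: dict[str, float] = {}
    for item in body.split(","):
        if not item:
            continue
        k, _, v = item.partition("=")
        out[k.strip()] = float(v)
    return out


def parse_species_network(text: str) -> SpeciesNetwork:
    """Parse an extended-Newick string with ``#H`` hybrid tags.

    Node attributes ride in ``[&age=...,theta=...,phi=...]`` comments; a
    hybrid node appears twice (once with its subtree, once as a bare
    reference) and each occurrence's ``phi`` belongs to the parent edge at
    that occurrence.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise NetworkError("empty network string")
    pos = 0
    age: dict[str, float] = {}
    parents: dict[str, list[str]] = {}
    theta: dict[str, float] = {}
    phi: dict[str, dict[str, float]] = {}
    hybrid_edges: list[tuple[str, str, float | None]] = []  # (hybrid, parent, phi)
    counter = [0]

    def fresh_label() -> str:
        counter[0] += 1
        return f"_n{counter[0]}"

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_node(parent: str | None) -> str:
        nonlocal pos
        children_here: list[str] = []
        if peek() == "(":
            pos += 1
            while True:
                children_here.append(parse_node(None))
                tok = peek()
                if tok == ",":
                    pos += 1
                    continue
                if tok == ")":
                    pos += 1
                    break
                raise NetworkError("unbalanced parentheses in network string")
        label = None
        tok = peek()
        if tok is not None and tok not in "(),;" and not tok.startswith("[&"):
            label = tok
            pos += 1
        attrs: dict[str, float] = {}
        tok = peek()
        if tok is not None and tok.startswith("[&"):
            attrs = _parse_attrs(tok)
            pos += 1
        is_hybrid_ref = label is not None and "#" in label
        if is_hybrid_ref:
            name = label.split("#")[0]
            if not name:
                raise NetworkError(f"hybrid tag without a name near {label!r}")
            hybrid_edges.append((name, "PENDING", attrs.get("phi")))
            idx = len(hybrid_edges) - 1
            if children_here or "age" in attrs:  # defining occurrence
                for c in children_here:
                    parents.setdefault(c, []).append(name)
                age[name] = attrs.get("age", 0.0)
                if "theta" in attrs:
                    theta[name] = attrs["theta"]
            hybrid_edges[idx] = (name, "PENDING", attrs.get("phi"))
            return f"#{idx}"  # placeholder resolved by caller
        if label is None:
            label = fresh_label()
        if label in age:
            raise NetworkError(f"duplicate node label {label!r}")
        age[label] = attrs.get("age", 0.0)
        if "theta" in attrs:
            theta[label] = attrs["theta"]
        for c in children_here:
            if c.startswith("#"):
                idx = int(c[1:])
                h, _, f = hybrid_edges[idx]
                hybrid_edges[idx] = (h, label, f)
            else:
                parents.setdefault(c, []).append(label)
        return label

    root = parse_node(None)
    if root.startswith("#"):
        raise NetworkError("root cannot be a hybrid reference")
    if peek() == ";":
        pos += 1
    if pos != len(tokens):
        raise NetworkError("trailing tokens after network string")
    for h, p, f in hybrid_edges:
        if p == "PENDING":
            raise NetworkError(f"dangling hybrid reference {h!r}")
        if h not in age:
            raise NetworkError(f"hybrid {h!r} never defined with a subtree")
        parents.setdefault(h, []).append(p)
        if f is None:
            raise NetworkError(f"hybrid edge {h!r}->{p!r} lacks phi")
        phi.setdefault(h, {})[p] = f
    net = SpeciesNetwork(
        age=age,
        parents={c: tuple(ps) for c, ps in parents.items()},
        theta=theta,
        phi=phi,
    )
    return net.validate()


def write_species_network(net: SpeciesNetwork, precision: int = 12) -> str:
    """Serialize a network to the extended-Newick dialect of the parser."""
    net.validate()
    ch = net.children
    hybrids = set(net.hybrid_nodes)

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def attrs(v: str, phi_val: float | None) -> str:
        parts = []
        if v not in (set(net.tips)):
            parts.append(f"age={fmt(net.age[v])}")
        if v in net.theta:
            parts.append(f"theta={fmt(net.theta[v])}")
        if phi_val is not None:
            parts.append(f"phi={fmt(phi_val)}")
        return f"[&{','.join(parts)}]" if parts else ""

    tagno = {h: i + 1 for i, h in enumerate(sorted(hybrids))}

    def render(v: str, via_parent: str | None) -> str:
        if v in hybrids:
            primary = net.primary_parent(v)
            tag = f"{v}#H{tagno[v]}"
            if via_parent is not None and via_parent != primary:
                return f"{tag}[&phi={fmt(net.phi[v][via_parent])}]"
            inner = ",".join(render(c, v) for c in ch[v])
            body = f"({inner})" if inner else ""
            return f"{body}{tag}{attrs(v, net.phi[v][primary])}"
        inner = ",".join(render(c, v) for c in ch[v])
        body = f"({inner})" if inner else ""
        return f"{body}{v}{attrs(v, None)}"

    return render(net.root, None) + ";"


# ---------------------------------------------------------------------------
# Named models of the study


def _tree(edges: dict[str, str], ages: dict[str, float], theta: float,
          phi: dict[str, dict[str, float]] | None = None,
          extra_parents: dict[str, str] | None = None) -> SpeciesNetwork:
    parents: dict[str, tuple[str, ...]] = {c: (p,) for c, p in edges.items()}
    if extra_parents:
        for c, p in extra_parents.items():
            parents[c] = parents[c] + (p,)
    labels = set(ages) | set(edges)
    age = {v: ages.get(v, 0.0) for v in labels}
    th = {v: theta for v in labels}
    return SpeciesNetwork(age=age, parents=parents, theta=th,
                          phi=phi or {}).validate()


def build_study_model(name: str, theta: float) -> SpeciesNetwork:
    """Construct one of the study's six species models, scaled by theta.

    ``A01-B``/``A01-U`` are the five-species balanced/unbalanced trees used
    for species-tree estimation; ``A11-shallow``/``A11-deep`` the
    five-population, three-species delimitation trees (with two divergence
    times collapsed to ``1e-50*theta``); ``A00-B``/``A00-U`` the MSci
    networks with two introgression events (``phi_Y=0.3``, ``phi_W=0.2``).
    All divergence/introgression times are proportional to theta, and every
    branch carries the same theta.
    """
    if theta <= 0:
        raise NetworkError("theta must be positive")
    t = theta
    if name == "A01-B":
        return _tree(
            {"A": "T", "B": "T", "C": "S", "T": "S", "D": "U", "E": "U",
             "S": "R", "U": "R"},
            {"T": 4.7 * t, "S": 4.8 * t, "U": 4.8 * t, "R": 5 * t}, t)
    if name == "A01-U":
        return _tree(
            {"A": "U", "B": "U", "C": "T", "U": "T", "D": "S", "T": "S",
             "E": "R", "S": "R"},
            {"U": 4.4 * t, "T": 4.6 * t, "S": 4.8 * t, "R": 5 * t}, t)
    if name in ("A11-shallow", "A11-deep"):
        tau_R, tau_S = (t, 0.5 * t) if name.endswith("shallow") else (5 * t, 4.8 * t)
        eps = 1e-50 * t
        return _tree(
            {"A": "T", "B": "T", "C": "S", "T": "S", "D": "U", "E": "U",
             "S": "R", "U": "R"},
            {"T": eps, "U": eps, "S": tau_S, "R": tau_R}, t)
    if name == "A00-B":
        # Y (on C's branch) receives phi_Y=0.3 from X (on B's branch, below T);
        # W (on E's branch) receives phi_W=0.2 from Z (on D's branch, below U).
        return _tree(
            {"A": "T", "B": "X", "X": "T", "C": "Y", "Y": "S", "T": "S",
             "D": "Z", "Z": "U", "E": "W", "W": "U", "S": "R", "U": "R"},
            {"X": t, "Y": t, "Z": t, "W": t, "T": 3 * t, "S": 4 * t,
             "U": 4.5 * t, "R": 5 * t}, t,
            phi={"Y": {"S": 0.7, "X": 0.3}, "W": {"U": 0.8, "Z": 0.2}},
            extra_parents={"Y": "X", "W": "Z"})
    if name == "A00-U":
        return _tree(
            {"A": "U", "B": "X", "X": "U", "C": "Y", "Y": "T", "U": "T",
             "D": "Z", "Z": "S", "T": "S", "E": "W", "W": "R", "S": "R"},
            {"X": t, "Y": t, "Z": t, "W": t, "U": 2.5 * t, "T": 3 * t,
             "S": 4 * t, "R": 5 * t}, t,
            phi={"Y": {"T": 0.7, "X": 0.3}, "W": {"R": 0.8, "Z": 0.2}},
            extra_parents={"Y": "X", "W": "Z"})
    raise NetworkError(f"unknown model name {name!r}; choose from {STUDY_MODELS}")


# ---------------------------------------------------------------------------
# Backward-time event schedules


@dataclass(frozen=True)
class ScheduledEvent:
    """One backward-time demographic event.

    ``MERGE`` moves every lineage of the source populations into ``dest``.
    ``ROUTE`` moves each lineage of the sources independently to ``dest``
    with probability ``prob`` and to ``alt_dest`` otherwise.
    """

    kind: str  # "MERGE" | "ROUTE"
    time: float
    sources: tuple[str, ...]
    dest: str
    alt_dest: str | None = None
    prob: float | None = None


@dataclass
class EventSchedule:
    events: list[ScheduledEvent]
    root_population: str

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def event_schedule(network: SpeciesNetwork) -> EventSchedule:
    """Compile a network into a time-ordered backward-time event schedule.

    Non-hybrid internal nodes (including unary donor-attachment nodes)
    become MERGE events at their ages; each hybrid node becomes a ROUTE
    event carrying its inheritance probabilities.
    """
    network.validate()
    ch = network.children
    hybrids = set(network.hybrid_nodes)
    events: list[ScheduledEvent] = []
    for v in network.age:
        kids = ch[v]
        if not kids:
            continue
        if v in hybrids:
            primary = network.primary_parent(v)
            donor = network.donor_parent(v)
            events.append(ScheduledEvent(
                kind="ROUTE", time=network.age[v], sources=tuple(sorted(kids)),
                dest=donor, alt_dest=v, prob=network.phi[v][donor]))
            continue
        sources = []
        for c in kids:
            if c in hybrids and network.donor_parent(c) == v:
                continue  # routed lineages arrive via the ROUTE event
            sources.append(c)
        if sources:
            events.append(ScheduledEvent(
                kind="MERGE", time=network.age[v], sources=tuple(sorted(sources)),
                dest=v))
    events.sort(key=lambda e: (e.time, 0 if e.kind == "MERGE" else 1, e.dest))
    return EventSchedule(events=events, root_population=network.root)
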