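"""Replicate-level evaluation statistics of the simulation study.

Collects, across replicate data sets, the quantities the study reports:
the probability that the MAP species tree equals the truth, per-clade
recovery and mean posterior probabilities, bias / CI width / coverage /
relative RMSE of parameter estimates, recombination-event summaries, and
segment-tree comparisons that classify recombination events as invisible,
branch-length-only, or topology-changing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arg_simulator import LocusGenealogy, MarginalTree
from .msc_inference import PosteriorSummary, _clades_of, canonical_topology
from .species_model import SpeciesNetwork

__all__ = [
    "ReplicateResult",
    "EvaluationReport",
    "rrmse",
    "ci_coverage",
    "recovery_stats",
    "recombination_summary",
    "compare_segment_trees",
    "parameter_table",
]


@dataclass
class ReplicateResult:
    """One replicate's inference output plus the generating truth."""

    replicate: int
    summary: PosteriorSummary
    truth_params: dict[str, float]
    truth_network: SpeciesNetwork | None = None
    recombination_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key, val in self.truth_params.items():
            if val <= 0 and not key.startswith("phi"):
                raise ValueError(f"truth for {key!r} must be positive")


@dataclass
class EvaluationReport:
    """Aggregated per-setting evaluation quantities."""

    recovery_probability: float | None = None
    clade_recovery: dict[str, float] = field(default_factory=dict)
    clade_mean_posterior: dict[str, float] = field(default_factory=dict)
    # same average restricted to replicates whose MAP tree has the clade
    clade_mean_posterior_recovered: dict[str, float] = field(
        default_factory=dict)
    parameters: pd.DataFrame | None = None
    mean_events_per_locus: float | None = None
    fraction_zero_recombination: float | None = None

    def to_json(self) -> str:
        out = {
            "recovery_probability": self.recovery_probability,
            "clade_recovery": self.clade_recovery,
            "clade_mean_posterior": self.clade_mean_posterior,
            "clade_mean_posterior_recovered":
                self.clade_mean_posterior_recovered,
            "mean_events_per_locus": self.mean_events_per_locus,
            "fraction_zero_recombination": self.fraction_zero_recombination,
        }
        if self.parameters is not None:
            out["parameters"] = self.parameters.to_dict(orient="index")
        return json.dumps(out, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Point-estimate accuracy


def rrmse(estimates, truth: float) -> float:
    """Relative root mean square error of an estimator.

    ``(1/truth) * sqrt(mean((estimate_i - truth)^2))`` over replicates: a
    value of 0.1 means the root mean square error is 10% of the true
    value.  The truth must be positive.
    """
    if truth <= 0:
        raise ValueError("true parameter value must be positive")
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((est - truth) ** 2)) / truth)


def ci_coverage(results: list[ReplicateResult], parameter: str) -> float:
    """Fraction of replicates whose 95% HPD interval contains the truth."""
    hits = 0
    total = 0
    for r in results:
        if parameter not in r.summary.hpd:
            raise KeyError(f"unknown parameter {parameter!r}")
        lo, hi = r.summary.hpd[parameter]
        truth = r.truth_params[parameter]
        hits += int(lo <= truth <= hi)
        total += 1
    if total == 0:
        raise ValueError("no replicates")
    return hits / total


def parameter_table(results: list[ReplicateResult]) -> pd.DataFrame:
    """Per-parameter mean estimate, bias (absolute and relative), mean CI
    width, CI coverage, and relative RMSE across replicates."""
    if not results:
        raise ValueError("no replicates")
    params = sorted(results[0].truth_params)
    rows = []
    for p in params:
        truth = results[0].truth_params[p]
        est = np.array([r.summary.means[p] for r in results])
        widths = np.array([r.summary.hpd[p][1] - r.summary.hpd[p][0]
                           for r in results])
        rows.append({
            "parameter": p,
            "truth": truth,
            "mean_estimate": est.mean(),
            "bias": est.mean() - truth,
            "relative_bias": (est.mean() - truth) / truth,
            "ci_width": widths.mean(),
            "coverage": ci_coverage(results, p),
            "rrmse": rrmse(est, truth),
        })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Species-tree recovery


def recovery_stats(results: list[ReplicateResult],
                   truth: SpeciesNetwork) -> EvaluationReport:
    """MAP-tree recovery probability, per-clade recovery in the MAP tree,
    and mean posterior probability of each true clade (averaged over all
    replicates, and also restricted to replicates recovering the clade).

    A clade counts as recovered when it is present in the MAP tree
    (not a consensus-tree criterion).
    """
    if any(r.summary.map_tree is None for r in results):
        raise ValueError("replicates lack sampled species trees")
    true_newick = canonical_topology(truth)
    true_clades = _clades_of(true_newick)
    clade_name = {cl: "(" + ",".join(sorted(cl)) + ")" for cl in true_clades}
    n = len(results)
    hits = sum(r.summary.map_tree == true_newick for r in results)
    clade_rec = {clade_name[cl]: 0.0 for cl in true_clades}
    clade_post = {clade_name[cl]: 0.0 for cl in true_clades}
    cond_sum = {clade_name[cl]: 0.0 for cl in true_clades}
    cond_n = {clade_name[cl]: 0 for cl in true_clades}
    for r in results:
        map_clades = _clades_of(r.summary.map_tree)
        for cl in true_clades:
            name = clade_name[cl]
            p = r.summary.clade_probs.get(cl, 0.0)
            if cl in map_clades:
                clade_rec[name] += 1 / n
                cond_sum[name] += p
                cond_n[name] += 1
            clade_post[name] += p / n
    cond = {k: round(cond_sum[k] / cond_n[k], 10)
            for k in cond_sum if cond_n[k]}
    return EvaluationReport(
        recovery_probability=hits / n,
        clade_recovery={k: round(v, 10) for k, v in sorted(clade_rec.items())},
        clade_mean_posterior={k: round(v, 10)
                              for k, v in sorted(clade_post.items())},
        clade_mean_posterior_recovered=cond,
    )


# ---------------------------------------------------------------------------
# Recombination summaries


def recombination_summary(counts) -> tuple[float, float]:
    """Mean recombination events per locus and fraction of loci with no
    events, over all loci of a setting."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("no loci")
    return float(arr.mean()), float((arr == 0).mean())


# ---------------------------------------------------------------------------
# Segment-tree comparisons


def _topology_key(tree: MarginalTree) -> frozenset:
    """Rooted labelled topology as the set of tip-label clades."""
    clades: dict[int, frozenset] = {}

    def walk(v: int) -> frozenset:
        kids = tree.children.get(v, [])
        if not kids:
            clades[v] = frozenset([tree.labels[v]])
        else:
            clades[v] = frozenset().union(*(walk(c) for c in kids))
        return clades[v]

    walk(tree.root)
    return frozenset(clades[v] for v in clades
                     if len(tree.children.get(v, [])) > 0)


def _ages_by_clade(tree: MarginalTree) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}

    def walk(v: int) -> frozenset:
        kids = tree.children.get(v, [])
        if not kids:
            return frozenset([tree.labels[v]])
        cl = frozenset().union(*(walk(c) for c in kids))
        out[cl] = tree.age[v]
        return cl

    walk(tree.root)
    return out


def compare_segment_trees(g: LocusGenealogy, tol: float = 1e-12
                          ) -> tuple[int, list[str]]:
    """Distinct rooted topologies among a locus' segment trees, plus the
    per-breakpoint change class.

    Classes: ``"none"`` (identical topology and node ages — the
    recombination events at that breakpoint are invisible),
    ``"lengths-only"`` (same topology, some coalescent times differ by
    more than ``tol``), ``"topology"``.
    """
    trees = [t for _, _, t in g.segment_trees()]
    topo_keys = [_topology_key(t) for t in trees]
    distinct = len(set(topo_keys))
    classes: list[str] = []
    for a in range(1, len(trees)):
        if topo_keys[a] != topo_keys[a - 1]:
            classes.append("topology")
            continue
        ages_a = _ages_by_clade(trees[a])
        ages_b = _ages_by_clade(trees[a - 1])
        if all(abs(ages_a[cl] - ages_b[cl]) <= tol for cl in ages_a):
            classes.append("none")
        else:
            classes.append("lengths-only")
    return distinct, classes
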