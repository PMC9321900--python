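"""Configuration and orchestration of the factorial simulation experiments.

The study's three experiments share one layout: a named species model, a
factorial grid over sequences-per-species ``S``, loci ``L``, mutation
rate ``theta`` and recombination rate ``rho``, and ``R`` replicates per
cell.  ``expand_grid`` enumerates deterministic (setting, replicate,
seed) jobs; ``run_experiment`` executes them — simulation only, or
simulation followed by MCMC inference — and aggregates an
:class:`~mscrecomb.evaluation.EvaluationReport` per setting.  Completed
jobs are recorded in an on-disk manifest so interrupted runs resume.

Priors follow the study's convention of scaling with the design theta:
``tau0 ~ IG(3, 10*theta)`` (mean ``5*theta``) and
``theta ~ IG(3, 2*theta)`` (mean ``theta``).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arg_simulator import SimulationDesign, simulate_locus
from .evaluation import (EvaluationReport, ReplicateResult, parameter_table,
                         recombination_summary, recovery_stats)
from .msc_inference import (MCMCSettings, PriorSpec, run_a00, run_a01,
                            summarize_posterior)
from .sequence_simulator import evolve_jc
from .species_model import (SpeciesNetwork, build_study_model,
                            make_sample_map)

logger = logging.getLogger("mscrecomb.harness")

__all__ = [
    "ExperimentConfig",
    "prior_for_theta",
    "expand_grid",
    "run_experiment",
    "PRESETS",
    "preset",
]


def prior_for_theta(theta: float, integrated: bool = False) -> PriorSpec:
    """The study's theta-matched inverse-gamma priors.

    For theta=0.0025: tau0 ~ IG(3, 0.025), theta ~ IG(3, 0.005); for
    theta=0.01: tau0 ~ IG(3, 0.1), theta ~ IG(3, 0.02).
    """
    return PriorSpec(tau_alpha=3.0, tau_beta=10.0 * theta,
                     theta_alpha=3.0, theta_beta=2.0 * theta,
                     theta_integrated=integrated)


@dataclass
class ExperimentConfig:
    """One factorial experiment (full scale by default)."""

    analysis: str = "sim-only"          # "A01" | "A00" | "sim-only"
    models: tuple[str, ...] = ("A01-B", "A01-U")
    S_grid: tuple[int, ...] = (2, 8)
    L_grid: tuple[int, ...] = (40, 160)
    theta_grid: tuple[float, ...] = (0.0025, 0.01)
    rho_grid: tuple[float, ...] = (0.05, 0.5, 5.0)
    R: int = 100
    n: int = 500
    seed: int = 2022
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def validate(self) -> "ExperimentConfig":
        if self.analysis not in ("A01", "A00", "sim-only"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if not (self.models and self.S_grid and self.L_grid and
                self.theta_grid and self.rho_grid):
            raise ValueError("empty grid")
        if self.R < 1:
            raise ValueError("R must be at least 1")
        return self

    def scaled(self, R: int | None = None, L_grid=None,
               mcmc: MCMCSettings | None = None) -> "ExperimentConfig":
        """A desk-scale variant of this configuration."""
        cfg = ExperimentConfig(**{**asdict(self),
                                  "mcmc": mcmc or self.mcmc})
        if R is not None:
            cfg.R = R
        if L_grid is not None:
            cfg.L_grid = tuple(L_grid)
        return cfg.validate()


@dataclass(frozen=True)
class Job:
    setting_index: int
    replicate: int
    seed: int
    model: str
    S: int
    L: int
    theta: float
    rho: float

    @property
    def job_id(self) -> str:
        return (f"{self.model}_S{self.S}_L{self.L}_t{self.theta:g}"
                f"_r{self.rho:g}_rep{self.replicate}")

    @property
    def setting_id(self) -> str:
        return f"{self.model}_S{self.S}_L{self.L}_t{self.theta:g}_r{self.rho:g}"


def expand_grid(config: ExperimentConfig) -> list[Job]:
    """Deterministic enumeration of all (setting, replicate, seed) jobs.

    The job count is |grid| x R; seeds derive from the base seed, the
    setting index and the replicate index, so repeated expansion yields
    identical assignments.
    """
    config.validate()
    jobs: list[Job] = []
    settings = list(itertools.product(config.models, config.S_grid,
                                      config.L_grid, config.theta_grid,
                                      config.rho_grid))
    for si, (model, S, L, theta, rho) in enumerate(settings):
        for rep in range(config.R):
            seed = int(np.random.SeedSequence(
                entropy=config.seed,
                spawn_key=(si, rep)).generate_state(1)[0] % (2 ** 31))
            jobs.append(Job(setting_index=si, replicate=rep, seed=seed,
                            model=model, S=S, L=L, theta=theta, rho=rho))
    return jobs


def _simulate_replicate(job: Job, n: int, with_sequences: bool):
    net = build_study_model(job.model, job.theta)
    smap = make_sample_map(net, job.S)
    design = SimulationDesign(S=job.S, L=job.L, n=n, rho=job.rho,
                              theta_base=job.theta, R=1, seed=job.seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=job.seed))
    counts = []
    loci = []
    for _l in range(job.L):
        g = simulate_locus(net, smap, design, rng)
        # benchmark statistic: ms-style segment transitions per locus
        counts.append(g.num_tree_transitions)
        if with_sequences:
            loci.append(evolve_jc(g, rng))
    return net, smap, counts, loci


def _infer_replicate(job: Job, net: SpeciesNetwork, smap, loci,
                     mcmc: MCMCSettings):
    settings = MCMCSettings(**{**asdict(mcmc),
                               "seed": (job.seed + 7919) % (2 ** 31)})
    if job.model.startswith("A00"):
        prior = prior_for_theta(job.theta, integrated=False)
        chain = run_a00(loci, net, smap, prior, settings)
    else:
        prior = prior_for_theta(job.theta, integrated=True)
        chain = run_a01(loci, net, smap, prior, settings)
    return summarize_posterior(chain)


def _truth_params(net: SpeciesNetwork) -> dict[str, float]:
    out: dict[str, float] = {}
    seen_groups = set()
    for v in net.age:
        if not net.children[v]:
            continue
        if v in {net.donor_parent(h) for h in net.hybrid_nodes}:
            continue
        out[f"tau_{v}"] = net.age[v]
        seen_groups.add(v)
    for v, th in net.theta.items():
        out[f"theta_{v}"] = th
    for h in net.hybrid_nodes:
        out[f"phi_{h}"] = net.phi[h][net.donor_parent(h)]
    return out


def run_experiment(config: ExperimentConfig,
                   outdir: str | Path) -> dict[str, EvaluationReport]:
    """Execute all jobs of a configuration and aggregate per setting.

    Per-job results are written under ``outdir`` (counts tables, summary
    JSON) and recorded in ``manifest.json``; jobs already present in the
    manifest are skipped, making interrupted runs resumable.  Returns one
    :class:`EvaluationReport` per setting id.
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "jobs").mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest: dict[str, str] = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    jobs = expand_grid(config)
    infer = config.analysis in ("A00", "A01")
    done = 0
    for job in jobs:
        if job.job_id in manifest:
            done += 1
            continue
        logger.info("job %s (%d/%d)", job.job_id, done + 1, len(jobs))
        net, smap, counts, loci = _simulate_replicate(
            job, config.n, with_sequences=infer)
        record: dict = {"counts": counts, "job": asdict(job)}
        if infer:
            summary = _infer_replicate(job, net, smap, loci, config.mcmc)
            record["means"] = summary.means
            record["hpd"] = {k: list(v) for k, v in summary.hpd.items()}
            record["map_tree"] = summary.map_tree
            record["tree_probs"] = summary.tree_probs
            record["clade_probs"] = {
                "|".join(sorted(cl)): p
                for cl, p in summary.clade_probs.items()}
            record["truth"] = _truth_params(net)
        (outdir / "jobs" / f"{job.job_id}.json").write_text(
            json.dumps(record, sort_keys=True))
        manifest[job.job_id] = "done"
        manifest_path.write_text(json.dumps(manifest, indent=0,
                                            sort_keys=True))
        done += 1
    logger.info("all %d jobs complete; aggregating", len(jobs))
    return aggregate(config, outdir)


def aggregate(config: ExperimentConfig,
              outdir: str | Path) -> dict[str, EvaluationReport]:
    """Aggregate completed job records into per-setting reports."""
    outdir = Path(outdir)
    jobs = expand_grid(config)
    infer = config.analysis in ("A00", "A01")
    by_setting: dict[str, list[Job]] = {}
    for job in jobs:
        by_setting.setdefault(job.setting_id, []).append(job)
    reports: dict[str, EvaluationReport] = {}
    rows = []
    for sid, js in by_setting.items():
        counts: list[int] = []
        results: list[ReplicateResult] = []
        truth_net = build_study_model(js[0].model, js[0].theta)
        for job in js:
            path = outdir / "jobs" / f"{job.job_id}.json"
            if not path.exists():
                raise FileNotFoundError(f"incomplete run: missing {path.name}")
            rec = json.loads(path.read_text())
            counts.extend(rec["counts"])
            if infer:
                from .msc_inference import PosteriorSummary
                summary = PosteriorSummary(
                    means=rec["means"],
                    hpd={k: tuple(v) for k, v in rec["hpd"].items()},
                    ess={},
                    tree_probs=rec.get("tree_probs", {}),
                    clade_probs={frozenset(k.split("|")): p for k, p in
                                 rec.get("clade_probs", {}).items()},
                    map_tree=rec.get("map_tree"))
                results.append(ReplicateResult(
                    replicate=job.replicate, summary=summary,
                    truth_params=rec["truth"],
                    recombination_counts=rec["counts"]))
        mean_ev, frac0 = recombination_summary(counts)
        if infer and js[0].model.startswith("A01"):
            report = recovery_stats(results, truth_net)
        elif infer:
            report = EvaluationReport(parameters=parameter_table(results))
        else:
            report = EvaluationReport()
        report.mean_events_per_locus = mean_ev
        report.fraction_zero_recombination = frac0
        reports[sid] = report
        rows.append({"setting": sid, "mean_events": mean_ev,
                     "fraction_zero": frac0})
    table = pd.DataFrame(rows).set_index("setting").sort_index()
    table.to_csv(outdir / "recombination_summary.tsv", sep="\t")
    with open(outdir / "reports.json", "w") as fh:
        fh.write(json.dumps({sid: json.loads(rep.to_json())
                             for sid, rep in reports.items()},
                            indent=2, sort_keys=True))
    return reports


# ---------------------------------------------------------------------------
# Reproduction presets


def _desk_mcmc() -> MCMCSettings:
    return MCMCSettings(burnin=1000, nsamples=1500, sample_interval=2)


PRESETS = {
    # recombination-event counts, simulation only, full scale
    "counts": ExperimentConfig(
        analysis="sim-only",
        models=("A01-B", "A01-U", "A11-shallow", "A11-deep", "A00-B",
                "A00-U"),
        S_grid=(2, 8), L_grid=(160,), theta_grid=(0.0025, 0.01),
        rho_grid=(0.05, 0.5, 5.0), R=100),
    # species-tree estimation experiment
    "a01": ExperimentConfig(analysis="A01", models=("A01-B", "A01-U")),
    # MSci parameter-estimation experiment
    "a00": ExperimentConfig(analysis="A00", models=("A00-B", "A00-U")),
}


def preset(name: str, scale: float = 1.0) -> ExperimentConfig:
    """A named preset, optionally scaled down for desk runs.

    ``scale < 1`` reduces replicates to ``max(2, round(R*scale))``,
    restricts L to its smallest grid value scaled likewise, and swaps in
    short MCMC chains.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if scale >= 1.0:
        return cfg
    R = max(2, round(cfg.R * scale))
    L = max(5, round(min(cfg.L_grid) * scale))
    return cfg.scaled(R=R, L_grid=(L,), mcmc=_desk_mcmc())
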