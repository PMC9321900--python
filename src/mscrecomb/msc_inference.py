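"""Bayesian MCMC inference under the MSC/MSci assuming no recombination.

Implements the two analysis modes exercised by the simulation study:

* **A00** — the species tree/network topology is fixed; divergence and
  introgression times (``tau``), population sizes (``theta``) and
  introgression probabilities (``phi``) are estimated.  ``theta`` is
  sampled explicitly through its conjugate inverse-gamma full conditional.
* **A01** — the species-tree topology is estimated jointly with ``tau``;
  ``theta`` parameters are integrated out analytically through their
  conjugate inverse-gamma priors.

The sampler treats the per-locus gene trees (rooted, dated) as latent
variables.  Moves: per-locus node-age slides (multiplier for the gene-tree
root) and Wilson-Balding subtree regrafts; flips of hybrid path
indicators; sliding-window updates of each ``tau`` (tied across the two
contemporaneous nodes of a horizontal introgression) with a rubber-band
remapping of gene-node ages between the neighbouring bounds; conjugate
Gibbs updates of ``theta`` and ``phi``; a whole-model rescaling
("mixing") move with Jacobian correction; and, for A01,
nearest-neighbour interchanges of the species tree.  Proposals that would
place a coalescence in a population that does not exist at that age are
rejected through the model density.  Hybrid path indicators required by a
proposed state but absent from the current one are drawn from
``Bernoulli(phi)`` inside the proposal, with the matching Hastings
correction.

Priors: ``tau0`` (the root age) is inverse-gamma; the non-root ``tau``
are jointly uniform over the order-constraint region given ``tau0``
(scaling-homogeneous, contributing ``-d*log(tau0)`` to the log prior for
``d`` free non-root times); each ``theta`` has an independent
inverse-gamma prior; each ``phi`` is uniform on (0,1).

All numerical kernels (Felsenstein pruning over compressed site patterns,
the lineage trace collecting per-population coalescent sufficient
statistics, and the per-iteration move sweeps) are JIT-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
from numba import njit

from .arg_simulator import (LocusGenealogy, MarginalTree, SimulationDesign,
                            simulate_locus)
from .sequence_simulator import Alignment
from .species_model import (NetworkError, SampleMap, SpeciesNetwork,
                            event_schedule)

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorSummary",
    "jc_pruning_loglik",
    "msc_logdensity",
    "msc_logdensity_theta_integrated",
    "indicators_from_routing",
    "run_a00",
    "run_a01",
    "summarize_posterior",
    "hpd_interval",
    "effective_sample_size",
    "clade_probabilities",
    "canonical_topology",
    "convergence_flag",
]


# ---------------------------------------------------------------------------
# Configuration types


@dataclass
class PriorSpec:
    """Priors of the analysis: IG on tau0 and theta, U(0,1) on phi."""

    tau_alpha: float = 3.0
    tau_beta: float = 0.025
    theta_alpha: float = 3.0
    theta_beta: float = 0.005
    theta_integrated: bool = False

    def validate(self) -> "PriorSpec":
        if self.tau_alpha <= 1 or self.theta_alpha <= 1:
            raise ValueError("inverse-gamma shape must exceed 1 (finite mean)")
        if self.tau_beta <= 0 or self.theta_beta <= 0:
            raise ValueError("inverse-gamma scale must be positive")
        return self

    @property
    def tau_mean(self) -> float:
        return self.tau_beta / (self.tau_alpha - 1)

    @property
    def theta_mean(self) -> float:
        return self.theta_beta / (self.theta_alpha - 1)


@dataclass
class MCMCSettings:
    """Chain-length and proposal settings.

    The full-scale defaults mirror the study's runs (32,000 burn-in
    iterations, 1e5 samples taken every 5 iterations); desk-scale
    analyses override them.
    """

    burnin: int = 32000
    nsamples: int = 100000
    sample_interval: int = 5
    autotune: bool = True
    seed: int = 0
    steps: dict = field(default_factory=lambda: {
        "gene_age": 0.5,      # window, relative to tau prior mean
        "gene_root": 0.7,     # log-multiplier half-width
        "tau": 0.3,           # window, relative to tau prior mean
        "mix": 0.4,           # log-multiplier half-width
    })

    def validate(self) -> "MCMCSettings":
        if self.burnin < 0 or self.nsamples < 1 or self.sample_interval < 1:
            raise ValueError("chain length settings must be positive")
        return self


@dataclass
class PosteriorSummary:
    """Posterior means, 95% HPD intervals, tree/clade probabilities."""

    means: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    ess: dict[str, float]
    tree_probs: dict[str, float] = field(default_factory=dict)
    clade_probs: dict[frozenset, float] = field(default_factory=dict)
    map_tree: str | None = None


# ---------------------------------------------------------------------------
# JIT kernels: pruning likelihood, lineage trace, density pieces


@njit(cache=True)
def _nb_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _prune_one(children, age, root, patterns, m, weights):
    """Felsenstein pruning under JC69 with uniform root frequencies.

    No per-node rescaling: with the sample sizes used here (tens of tips)
    the per-site partials stay far above the double-precision floor.
    """
    n = children.shape[0]
    order = np.empty(n, np.int32)
    stack = np.empty(n, np.int32)
    stack[0] = root
    sp = 1
    cnt = 0
    while sp > 0:
        sp -= 1
        v = stack[sp]
        order[cnt] = v
        cnt += 1
        if children[v, 0] >= 0:
            stack[sp] = children[v, 0]
            sp += 1
            stack[sp] = children[v, 1]
            sp += 1
    partial = np.empty((n, 4, m))
    for oi in range(cnt - 1, -1, -1):
        v = order[oi]
        if children[v, 0] < 0:
            continue
        for a in range(4):
            for j in range(m):
                partial[v, a, j] = 1.0
        for ci in range(2):
            c = children[v, ci]
            t = age[v] - age[c]
            if t < 0.0:
                t = 0.0
            e = math.exp(-4.0 * t / 3.0)
            q = (1.0 - e) / 4.0
            if children[c, 0] < 0:  # tip
                for j in range(m):
                    s = patterns[c, j]
                    for a in range(4):
                        if a == s:
                            partial[v, a, j] *= q + e
                        else:
                            partial[v, a, j] *= q
            else:
                for j in range(m):
                    cs = (partial[c, 0, j] + partial[c, 1, j]
                          + partial[c, 2, j] + partial[c, 3, j])
                    for a in range(4):
                        partial[v, a, j] *= e * partial[c, a, j] + q * cs
    ll = 0.0
    for j in range(m):
        site = 0.25 * (partial[root, 0, j] + partial[root, 1, j]
                       + partial[root, 2, j] + partial[root, 3, j])
        if site <= 0.0:
            return -1.0e300
        ll += weights[j] * math.log(site)
    return ll


@njit(cache=True)
def _trace_one(children, age, root, ntips, tip_pop,
               ev_time, ev_kind, ev_src, ev_dest, ev_alt, ev_hyb, phi,
               ind, allow_fill, k, c, phic, needed):
    """Sweep one gene tree through the demographic schedule backward in
    time, collecting per-population coalescent sufficient statistics.

    ``ind`` is (n_nodes, n_hybrids) int8 with -1 for missing; missing
    entries required by the sweep are drawn Bernoulli(phi) in place when
    ``allow_fill``.  Returns (status, logq) where status is 1 on success,
    0 for an incompatible coalescence, -1 for a missing indicator with
    filling disabled, and logq is the log proposal probability of the
    freshly drawn indicators.
    """
    n = children.shape[0]
    npop = ev_src.shape[1]
    nh = phi.shape[0]
    for p in range(npop):
        k[p] = 0.0
        c[p] = 0.0
    for h in range(nh):
        phic[h, 0] = 0
        phic[h, 1] = 0
    for v in range(n):
        for h in range(nh):
            needed[v, h] = -1
    cur = np.full(n, -1, np.int32)
    counts = np.zeros(npop, np.int32)
    for i in range(ntips):
        cur[i] = tip_pop[i]
        counts[tip_pop[i]] += 1
    nint = n - ntips
    internal = np.empty(nint, np.int32)
    ci_ = 0
    for v in range(n):
        if children[v, 0] >= 0:
            internal[ci_] = v
            ci_ += 1
    for a in range(1, nint):  # insertion sort by age
        key = internal[a]
        b = a - 1
        while b >= 0 and age[internal[b]] > age[key]:
            internal[b + 1] = internal[b]
            b -= 1
        internal[b + 1] = key
    ne = ev_time.shape[0]
    ie = 0
    ic = 0
    t_prev = 0.0
    logq = 0.0
    while ie < ne or ic < nint:
        if ie < ne and (ic >= nint or ev_time[ie] <= age[internal[ic]]):
            t_now = ev_time[ie]
            is_demo = True
        else:
            t_now = age[internal[ic]]
            is_demo = False
        if t_now > t_prev:
            dt = t_now - t_prev
            for p in range(npop):
                kk = counts[p]
                if kk >= 2:
                    c[p] += kk * (kk - 1) * 0.5 * dt
            t_prev = t_now
        if is_demo:
            if ev_kind[ie] == 0:  # MERGE
                d = ev_dest[ie]
                for v in range(n):
                    p = cur[v]
                    if p >= 0 and ev_src[ie, p]:
                        cur[v] = d
                        counts[p] -= 1
                        counts[d] += 1
            else:  # ROUTE
                d = ev_dest[ie]
                alt = ev_alt[ie]
                h = ev_hyb[ie]
                ph = phi[h]
                for v in range(n):
                    p = cur[v]
                    if p >= 0 and ev_src[ie, p]:
                        val = ind[v, h]
                        if val < 0:
                            if allow_fill == 0:
                                return -1, 0.0
                            if np.random.random() < ph:
                                val = 1
                                logq += math.log(ph)
                            else:
                                val = 0
                                logq += math.log(1.0 - ph)
                            ind[v, h] = val
                        needed[v, h] = val
                        if val == 1:
                            tgt = d
                            phic[h, 0] += 1
                        else:
                            tgt = alt
                            phic[h, 1] += 1
                        cur[v] = tgt
                        counts[p] -= 1
                        counts[tgt] += 1
            ie += 1
        else:
            v = internal[ic]
            c1 = children[v, 0]
            c2 = children[v, 1]
            p1 = cur[c1]
            p2 = cur[c2]
            if p1 != p2 or p1 < 0:
                return 0, 0.0
            cur[c1] = -1
            cur[c2] = -1
            k[p1] += 1.0
            counts[p1] -= 1
            cur[v] = p1
            ic += 1
    return 1, logq


@njit(cache=True)
def _hastings_drop(needed_old, needed_new, phi):
    """log proposal probability of indicators that the reverse move would
    have to redraw (needed before, unneeded after)."""
    out = 0.0
    n, nh = needed_old.shape
    for v in range(n):
        for h in range(nh):
            o = needed_old[v, h]
            if o >= 0 and needed_new[v, h] < 0:
                out += math.log(phi[h] if o == 1 else 1.0 - phi[h])
    return out


@njit(cache=True)
def _dens_sampled(k, c, theta):
    out = 0.0
    for p in range(theta.shape[0]):
        out += k[p] * math.log(2.0 / theta[p]) - 2.0 * c[p] / theta[p]
    return out


@njit(cache=True)
def _dens_integrated(k, c, a, b):
    # per population: 2^k * b^a * Gamma(a+k) / (Gamma(a) * (b+2c)^(a+k))
    out = 0.0
    for p in range(k.shape[0]):
        out += (k[p] * math.log(2.0) + a * math.log(b)
                + math.lgamma(a + k[p]) - math.lgamma(a)
                - (a + k[p]) * math.log(b + 2.0 * c[p]))
    return out


@njit(cache=True)
def _phi_terms(phic, phi):
    out = 0.0
    for h in range(phic.shape[0]):
        if phic[h, 0] > 0:
            out += phic[h, 0] * math.log(phi[h])
        if phic[h, 1] > 0:
            out += phic[h, 1] * math.log(1.0 - phi[h])
    return out


@njit(cache=True)
def _delta_dens_nb(k_old, c_old, phic_old, k_new, c_new, phic_new,
                   theta, phi, integrated, ig_a, ig_b, k_tot, c_tot):
    d = _phi_terms(phic_new, phi) - _phi_terms(phic_old, phi)
    npop = theta.shape[0]
    if integrated:
        kt = np.empty(npop)
        ct = np.empty(npop)
        for p in range(npop):
            kt[p] = k_tot[p] - k_old[p] + k_new[p]
            ct[p] = c_tot[p] - c_old[p] + c_new[p]
        return d + _dens_integrated(kt, ct, ig_a, ig_b) \
            - _dens_integrated(k_tot, c_tot, ig_a, ig_b)
    for p in range(npop):
        d += (k_new[p] - k_old[p]) * math.log(2.0 / theta[p]) \
            - 2.0 * (c_new[p] - c_old[p]) / theta[p]
    return d


@njit(cache=True)
def _commit_nb(l, k2, c2, phic2, needed2, ll_new,
               karr, carr, phicarr, needed, llarr, k_tot, c_tot):
    npop = k2.shape[0]
    for p in range(npop):
        k_tot[p] += k2[p] - karr[l, p]
        c_tot[p] += c2[p] - carr[l, p]
        karr[l, p] = k2[p]
        carr[l, p] = c2[p]
    nh = phic2.shape[0]
    for h in range(nh):
        phicarr[l, h, 0] = phic2[h, 0]
        phicarr[l, h, 1] = phic2[h, 1]
    n = needed2.shape[0]
    for v in range(n):
        for h in range(nh):
            needed[l, v, h] = needed2[v, h]
    llarr[l] = ll_new


@njit(cache=True)
def _gene_sweep(children, parent, age, root, ntips, tip_pop,
                patterns, pm, weights, has_data,
                ev_time, ev_kind, ev_src, ev_dest, ev_alt, ev_hyb,
                phi, theta, integrated, ig_a, ig_b,
                needed, phicarr, karr, carr, llarr, k_tot, c_tot,
                step_age, step_root, wb_scale,
                n_age, n_spr, n_flip, acc):
    """One sweep of per-locus gene-tree moves over all loci.

    ``acc`` accumulates (accepted, attempted) pairs for the move types
    (0: age slide, 1: root multiplier, 2: subtree regraft).
    """
    L, n = age.shape
    npop = theta.shape[0]
    nh = phi.shape[0]
    ind2 = np.empty((n, nh), np.int8)
    needed2 = np.empty((n, nh), np.int8)
    k2 = np.empty(npop)
    c2 = np.empty(npop)
    phic2 = np.empty((nh, 2), np.int32)
    feas = np.empty(n, np.int32)
    for l in range(L):
        ch = children[l]
        pa = parent[l]
        ag = age[l]

        # ---- node age moves -------------------------------------------
        for _rep in range(n_age):
            v = ntips + int(np.random.random() * (n - ntips))
            old_age = ag[v]
            lo = ag[ch[v, 0]]
            if ag[ch[v, 1]] > lo:
                lo = ag[ch[v, 1]]
            log_h = 0.0
            if v == root[l]:
                fac = math.exp(step_root * (np.random.random() - 0.5))
                new_age = lo + (old_age - lo) * fac
                log_h = math.log(fac)
                mt = 1
            else:
                hi = ag[pa[v]]
                width = hi - lo
                if width <= 0.0:
                    continue
                y = old_age + step_age * (np.random.random() - 0.5)
                y = (y - lo) % (2.0 * width)
                if y < 0.0:
                    y += 2.0 * width
                new_age = lo + (y if y <= width else 2.0 * width - y)
                mt = 0
            ag[v] = new_age
            for vv in range(n):
                for h in range(nh):
                    ind2[vv, h] = needed[l, vv, h]
            st, logqf = _trace_one(ch, ag, root[l], ntips, tip_pop,
                                   ev_time, ev_kind, ev_src, ev_dest,
                                   ev_alt, ev_hyb, phi, ind2, 1,
                                   k2, c2, phic2, needed2)
            acc[mt, 1] += 1
            accept = False
            ll_new = 0.0
            if st == 1:
                if has_data:
                    ll_new = _prune_one(ch, ag, root[l], patterns[l],
                                        pm[l], weights[l])
                else:
                    ll_new = 0.0
                log_r = (ll_new - llarr[l]) + log_h - logqf
                log_r += _hastings_drop(needed[l], needed2, phi)
                log_r += _delta_dens_nb(karr[l], carr[l], phicarr[l],
                                        k2, c2, phic2, theta, phi,
                                        integrated, ig_a, ig_b,
                                        k_tot, c_tot)
                if math.log(np.random.random() + 1e-300) < log_r:
                    accept = True
            if accept:
                acc[mt, 0] += 1
                _commit_nb(l, k2, c2, phic2, needed2, ll_new,
                           karr, carr, phicarr, needed, llarr, k_tot, c_tot)
            else:
                ag[v] = old_age

        # ---- Wilson-Balding subtree regrafts ---------------------------
        if ntips >= 3:
            for _rep in range(n_spr):
                i = int(np.random.random() * (n - 1))
                if i >= root[l]:
                    i += 1
                p = pa[i]
                sib = ch[p, 0] if ch[p, 1] == i else ch[p, 1]
                g = pa[p]
                old_t = ag[p]
                old_root = root[l]
                # prune
                if g >= 0:
                    if ch[g, 0] == p:
                        ch[g, 0] = sib
                    else:
                        ch[g, 1] = sib
                    pa[sib] = g
                else:
                    pa[sib] = -1
                    root[l] = sib
                pruned_root = root[l]
                nf = 0
                for u in range(n):
                    if u == i or u == p:
                        continue
                    if u == pruned_root or (pa[u] >= 0 and pa[u] != p
                                            and ag[pa[u]] > ag[i]):
                        feas[nf] = u
                        nf += 1
                j = feas[int(np.random.random() * nf)]
                lo = ag[i] if ag[i] > ag[j] else ag[j]
                if j == pruned_root:
                    new_t = lo - wb_scale * math.log(np.random.random()
                                                     + 1e-300)
                    log_q_fwd = -math.log(wb_scale) - (new_t - lo) / wb_scale
                else:
                    hi = ag[pa[j]]
                    new_t = lo + np.random.random() * (hi - lo)
                    log_q_fwd = -math.log(hi - lo)
                # reverse density on the pruned tree
                lo_r = ag[i] if ag[i] > ag[sib] else ag[sib]
                if sib == pruned_root:
                    log_q_rev = -math.log(wb_scale) - (old_t - lo_r) / wb_scale
                else:
                    log_q_rev = -math.log(ag[pa[sib]] - lo_r)
                # regraft (reuse node p as the new parent of {i, j})
                gj = pa[j]
                pa[i] = p
                pa[j] = p
                ch[p, 0] = i
                ch[p, 1] = j
                ag[p] = new_t
                if gj >= 0:
                    if ch[gj, 0] == j:
                        ch[gj, 0] = p
                    else:
                        ch[gj, 1] = p
                    pa[p] = gj
                else:
                    pa[p] = -1
                    root[l] = p
                for vv in range(n):
                    for h in range(nh):
                        ind2[vv, h] = needed[l, vv, h]
                st, logqf = _trace_one(ch, ag, root[l], ntips, tip_pop,
                                       ev_time, ev_kind, ev_src, ev_dest,
                                       ev_alt, ev_hyb, phi, ind2, 1,
                                       k2, c2, phic2, needed2)
                acc[2, 1] += 1
                accept = False
                ll_new = 0.0
                if st == 1:
                    if has_data:
                        ll_new = _prune_one(ch, ag, root[l], patterns[l],
                                            pm[l], weights[l])
                    else:
                        ll_new = 0.0
                    log_r = (ll_new - llarr[l]) + (log_q_rev - log_q_fwd) \
                        - logqf
                    log_r += _hastings_drop(needed[l], needed2, phi)
                    log_r += _delta_dens_nb(karr[l], carr[l], phicarr[l],
                                            k2, c2, phic2, theta, phi,
                                            integrated, ig_a, ig_b,
                                            k_tot, c_tot)
                    if math.log(np.random.random() + 1e-300) < log_r:
                        accept = True
                if accept:
                    acc[2, 0] += 1
                    _commit_nb(l, k2, c2, phic2, needed2, ll_new,
                               karr, carr, phicarr, needed, llarr,
                               k_tot, c_tot)
                else:
                    # undo the surgery: regraft back where it was
                    gj2 = pa[p]
                    if gj2 >= 0:
                        if ch[gj2, 0] == p:
                            ch[gj2, 0] = j
                        else:
                            ch[gj2, 1] = j
                        pa[j] = gj2
                    else:
                        pa[j] = -1
                    pa[i] = p
                    pa[sib] = p
                    ch[p, 0] = i
                    ch[p, 1] = sib
                    ag[p] = old_t
                    if g >= 0:
                        if ch[g, 0] == sib:
                            ch[g, 0] = p
                        else:
                            ch[g, 1] = p
                        pa[p] = g
                    else:
                        pa[p] = -1
                    root[l] = old_root

        # ---- hybrid path indicator flips -------------------------------
        if nh > 0:
            for _rep in range(n_flip):
                cnt = 0
                for vv in range(n):
                    for h in range(nh):
                        if needed[l, vv, h] >= 0:
                            cnt += 1
                if cnt == 0:
                    break
                r = int(np.random.random() * cnt)
                fv = -1
                fh = -1
                for vv in range(n):
                    for h in range(nh):
                        if needed[l, vv, h] >= 0:
                            if r == 0:
                                fv = vv
                                fh = h
                            r -= 1
                for vv in range(n):
                    for h in range(nh):
                        ind2[vv, h] = needed[l, vv, h]
                ind2[fv, fh] = 1 - ind2[fv, fh]
                st, logqf = _trace_one(ch, ag, root[l], ntips, tip_pop,
                                       ev_time, ev_kind, ev_src, ev_dest,
                                       ev_alt, ev_hyb, phi, ind2, 1,
                                       k2, c2, phic2, needed2)
                if st == 1:
                    log_r = -logqf
                    log_r += _hastings_drop(needed[l], needed2, phi)
                    log_r += _delta_dens_nb(karr[l], carr[l], phicarr[l],
                                            k2, c2, phic2, theta, phi,
                                            integrated, ig_a, ig_b,
                                            k_tot, c_tot)
                    if math.log(np.random.random() + 1e-300) < log_r:
                        _commit_nb(l, k2, c2, phic2, needed2, llarr[l],
                                   karr, carr, phicarr, needed, llarr,
                                   k_tot, c_tot)


@njit(cache=True)
def _tau_batch(children, age, age2, root, ntips, tip_pop,
               patterns, pm, weights, has_data,
               ev_time, ev_kind, ev_src, ev_dest, ev_alt, ev_hyb, phi,
               needed, needed2, k2arr, c2arr, phic2arr, ll2,
               lo, hi, old, new):
    """Rubber-band tau proposal applied to every locus.

    Writes the transformed ages / traces / likelihoods into the scratch
    arrays; returns (ok, log_jacobian, log_hastings, loglik_new_total).
    """
    L, n = age.shape
    nh = phi.shape[0]
    ind2 = np.empty((n, nh), np.int8)
    log_jac = 0.0
    logq = 0.0
    llsum = 0.0
    fin = math.isfinite(hi)
    r1 = (new - lo) / (old - lo) if old > lo else 1.0
    r2 = (hi - new) / (hi - old) if fin else 1.0
    for l in range(L):
        for v in range(n):
            a = age[l, v]
            if lo < a <= old:
                age2[l, v] = lo + (a - lo) * r1
                if r1 != 1.0:
                    log_jac += math.log(r1)
            elif a > old and (not fin or a < hi):
                if fin:
                    age2[l, v] = hi - (hi - a) * r2
                    log_jac += math.log(r2)
                else:
                    age2[l, v] = a + (new - old)
            else:
                age2[l, v] = a
        for vv in range(n):
            for h in range(nh):
                ind2[vv, h] = needed[l, vv, h]
        st, logqf = _trace_one(children[l], age2[l], root[l], ntips, tip_pop,
                               ev_time, ev_kind, ev_src, ev_dest, ev_alt,
                               ev_hyb, phi, ind2, 1,
                               k2arr[l], c2arr[l], phic2arr[l], needed2[l])
        if st != 1:
            return 0, 0.0, 0.0, 0.0
        logq -= logqf
        logq += _hastings_drop(needed[l], needed2[l], phi)
        if has_data:
            ll2[l] = _prune_one(children[l], age2[l], root[l], patterns[l],
                                pm[l], weights[l])
        else:
            ll2[l] = 0.0
        llsum += ll2[l]
    return 1, log_jac, logq, llsum


@njit(cache=True)
def _trace_batch(children, age, root, ntips, tip_pop,
                 ev_time, ev_kind, ev_src, ev_dest, ev_alt, ev_hyb, phi,
                 needed, needed2, k2arr, c2arr, phic2arr):
    """Re-trace every locus against the current schedule (used by the
    species-topology move); returns (ok, log_hastings)."""
    L, n = age.shape
    nh = phi.shape[0]
    ind2 = np.empty((n, nh), np.int8)
    logq = 0.0
    for l in range(L):
        for vv in range(n):
            for h in range(nh):
                ind2[vv, h] = needed[l, vv, h]
        st, logqf = _trace_one(children[l], age[l], root[l], ntips, tip_pop,
                               ev_time, ev_kind, ev_src, ev_dest, ev_alt,
                               ev_hyb, phi, ind2, 1,
                               k2arr[l], c2arr[l], phic2arr[l], needed2[l])
        if st != 1:
            return 0, 0.0
        logq -= logqf
        logq += _hastings_drop(needed[l], needed2[l], phi)
    return 1, logq


@njit(cache=True)
def _prune_batch_scaled(children, age, root, patterns, pm, weights, x, ll2):
    L = age.shape[0]
    n = age.shape[1]
    ag2 = np.empty(n)
    total = 0.0
    for l in range(L):
        for v in range(n):
            ag2[v] = age[l, v] * x
        ll2[l] = _prune_one(children[l], ag2, root[l], patterns[l], pm[l],
                            weights[l])
        total += ll2[l]
    return total


# ---------------------------------------------------------------------------
# Compiled demographic model


class _CompiledNet:
    """Array/index form of a species network for fast repeated tracing."""

    def __init__(self, net: SpeciesNetwork):
        net.validate()
        self.net = net
        self.rebuild()

    def rebuild(self) -> None:
        """Recompile after a topology change."""
        net = self.net
        self.pops = sorted(net.age)
        self.pop_index = {p: i for i, p in enumerate(self.pops)}
        self.theta = np.array([net.theta[p] for p in self.pops])
        self.hybrids = net.hybrid_nodes
        self.hyb_index = {h: i for i, h in enumerate(self.hybrids)}
        self.phi = np.array([net.phi[h][net.donor_parent(h)]
                             for h in self.hybrids])
        sched = event_schedule(net)
        npop = len(self.pops)
        ne = len(sched.events)
        self._kind = np.zeros(ne, np.int8)
        self._src = np.zeros((ne, npop), np.bool_)
        self._dest = np.zeros(ne, np.int32)
        self._alt = np.zeros(ne, np.int32)
        self._hyb = np.zeros(ne, np.int32)
        self._time_node: list[str] = []
        for i, ev in enumerate(sched.events):
            if ev.kind == "ROUTE":
                self._kind[i] = 1
                self._alt[i] = self.pop_index[ev.alt_dest]
                self._hyb[i] = self.hyb_index[ev.alt_dest]
                self._time_node.append(ev.alt_dest)
            else:
                self._time_node.append(ev.dest)
            self._dest[i] = self.pop_index[ev.dest]
            for s in ev.sources:
                self._src[i, self.pop_index[s]] = True
        self.refresh_times()

    def refresh_times(self) -> None:
        """Re-sort events after node ages changed (topology unchanged)."""
        net = self.net
        times = np.array([net.age[v] for v in self._time_node])
        order = np.lexsort((self._kind, times))
        self.ev_time = np.ascontiguousarray(times[order])
        self.ev_kind = np.ascontiguousarray(self._kind[order])
        self.ev_src = np.ascontiguousarray(self._src[order])
        self.ev_dest = np.ascontiguousarray(self._dest[order])
        self.ev_alt = np.ascontiguousarray(self._alt[order])
        self.ev_hyb = np.ascontiguousarray(self._hyb[order])


# ---------------------------------------------------------------------------
# Pattern compression and public density/likelihood operations


def _compress(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    return np.ascontiguousarray(patterns, dtype=np.int8), \
        counts.astype(np.float64)


def _tree_to_arrays(tree: MarginalTree, samples: SampleMap,
                    cnet: _CompiledNet):
    """Compact a MarginalTree to (children, age, root, tip_pop, remap):
    tips first in sorted-label order, then internal nodes."""
    labs = sorted(tree.labels.values())
    lab_to_tip = {lab: i for i, lab in enumerate(labs)}
    tips = sorted((v for v in tree.age if not tree.children.get(v)),
                  key=lambda v: lab_to_tip[tree.labels[v]])
    internals = [v for v in tree.age if tree.children.get(v)]
    nodes = tips + internals
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    children = np.full((n, 2), -1, np.int32)
    age = np.zeros(n)
    for v in nodes:
        age[idx[v]] = tree.age[v]
        for j, cc in enumerate(tree.children.get(v, [])):
            children[idx[v], j] = idx[cc]
    tip_pop = np.array([cnet.pop_index[samples.assignment[tree.labels[v]]]
                        for v in tips], np.int32)
    return children, age, idx[tree.root], tip_pop, idx


def jc_pruning_loglik(a: Alignment, tree: MarginalTree) -> float:
    """Log-likelihood of one locus' alignment given a dated gene tree.

    Tips are matched to alignment rows by label; the value is invariant
    to root placement on the same unrooted topology (JC69 reversibility).
    """
    if set(tree.labels.values()) != set(a.labels):
        raise ValueError("tree tip labels do not match alignment labels")
    labs = sorted(tree.labels.values())
    order = [a.labels.index(lab) for lab in labs]
    patterns, weights = _compress(a.matrix[order])
    tips = sorted((v for v in tree.age if not tree.children.get(v)),
                  key=lambda v: labs.index(tree.labels[v]))
    internals = [v for v in tree.age if tree.children.get(v)]
    nodes = tips + internals
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    children = np.full((n, 2), -1, np.int32)
    age = np.zeros(n)
    for v in nodes:
        age[idx[v]] = tree.age[v]
        for j, cc in enumerate(tree.children.get(v, [])):
            children[idx[v], j] = idx[cc]
        if v in tree.parent and tree.age[tree.parent[v]] - tree.age[v] < -1e-15:
            raise ValueError("negative branch length")
    return float(_prune_one(children, age, idx[tree.root], patterns,
                            patterns.shape[1], weights))


def indicators_from_routing(g: LocusGenealogy) -> dict:
    """Hybrid path indicators implied by a simulated (rho=0) genealogy.

    Keys are (gene-tree node id, hybrid label); True means the lineage
    took the donor parent.  Only meaningful for single-segment
    genealogies, where every lineage carries one ancestor node.
    """
    out: dict = {}
    for hlabel, node_ids, took_donor in g.routing:
        for nd in node_ids:
            out[(nd, hlabel)] = took_donor
    return out


def _indicator_array(ind_dict: dict | None, remap: dict, cnet: _CompiledNet,
                     n: int) -> np.ndarray:
    arr = np.full((n, len(cnet.hybrids)), -1, np.int8)
    if ind_dict:
        for (nd, h), val in ind_dict.items():
            if nd in remap and h in cnet.hyb_index:
                arr[remap[nd], cnet.hyb_index[h]] = 1 if val else 0
    return arr


def _public_trace(tree: MarginalTree, net_c: _CompiledNet,
                  samples: SampleMap, ind_dict: dict | None):
    children, age, root, tip_pop, remap = _tree_to_arrays(
        tree, samples, net_c)
    n = children.shape[0]
    nh = len(net_c.hybrids)
    npop = len(net_c.pops)
    ind = _indicator_array(ind_dict, remap, net_c, n)
    k = np.zeros(npop)
    c = np.zeros(npop)
    phic = np.zeros((nh, 2), np.int32)
    needed = np.full((n, nh), -1, np.int8)
    allow = 0 if nh else 1
    st, _ = _trace_one(children, age, root, len(tip_pop), tip_pop,
                       net_c.ev_time, net_c.ev_kind, net_c.ev_src,
                       net_c.ev_dest, net_c.ev_alt, net_c.ev_hyb,
                       net_c.phi, ind, allow, k, c, phic, needed)
    if st == -1:
        raise NetworkError("missing hybrid path indicator; supply the "
                           "indicators for every lineage crossing a "
                           "hybrid node")
    return st, k, c, phic


def msc_logdensity(trees: list[MarginalTree], net: SpeciesNetwork,
                   samples: SampleMap,
                   indicators: list[dict] | None = None) -> float:
    """Joint MSC/MSci log-density of dated gene trees given the network.

    Per population with ``j`` lineages the density has factor ``2/theta``
    per coalescence and survival ``exp(-C(j,2)*(2/theta)*dt)`` per
    interval; each hybrid passage contributes ``phi`` or ``1-phi``.
    Returns ``-inf`` for gene trees incompatible with the network.
    """
    cnet = _CompiledNet(net)
    total = 0.0
    for i, tree in enumerate(trees):
        st, k, c, phic = _public_trace(
            tree, cnet, samples, indicators[i] if indicators else None)
        if st != 1:
            return -math.inf
        total += _dens_sampled(k, c, cnet.theta)
        total += _phi_terms(phic, cnet.phi)
    return total


def msc_logdensity_theta_integrated(trees: list[MarginalTree],
                                    net: SpeciesNetwork, samples: SampleMap,
                                    prior: PriorSpec,
                                    indicators: list[dict] | None = None
                                    ) -> float:
    """MSC log-density with every theta integrated against its IG prior."""
    prior.validate()
    cnet = _CompiledNet(net)
    k_tot = np.zeros(len(cnet.pops))
    c_tot = np.zeros(len(cnet.pops))
    phi_total = 0.0
    for i, tree in enumerate(trees):
        st, k, c, phic = _public_trace(
            tree, cnet, samples, indicators[i] if indicators else None)
        if st != 1:
            return -math.inf
        k_tot += k
        c_tot += c
        phi_total += _phi_terms(phic, cnet.phi)
    return _dens_integrated(k_tot, c_tot, prior.theta_alpha,
                            prior.theta_beta) + phi_total


# ---------------------------------------------------------------------------
# The MCMC sampler


class _Sampler:
    """Shared machinery of the A00 and A01 analyses (packed-array state)."""

    def __init__(self, loci: list[Alignment] | None, net: SpeciesNetwork,
                 samples: SampleMap, prior: PriorSpec,
                 settings: MCMCSettings, *, theta_integrated: bool,
                 species_move: bool):
        prior.validate()
        settings.validate()
        net.validate()
        samples.validate(net)
        self.prior = prior
        self.settings = settings
        self.rng = np.random.default_rng(settings.seed)
        _nb_seed(int(self.rng.integers(2 ** 31)))
        self.theta_integrated = theta_integrated
        self.species_move = species_move

        # -- species model state ------------------------------------------
        self.net = SpeciesNetwork(
            age=dict(net.age), parents=dict(net.parents),
            theta=dict(net.theta), phi={h: dict(d) for h, d in net.phi.items()})
        self.samples = samples
        internal = [v for v in self.net.age if self.net.children[v]]
        donor_of: dict[str, str] = {}
        for h in self.net.hybrid_nodes:
            donor_of[self.net.donor_parent(h)] = h
        self.tau_groups: list[tuple[str, ...]] = []
        for v in sorted(internal):
            if v in donor_of:
                continue
            if v in self.net.hybrid_nodes:
                self.tau_groups.append((v, self.net.donor_parent(v)))
            else:
                self.tau_groups.append((v,))
        self.root_label = self.net.root
        # initialize parameters at the prior means, keeping relative order
        scale = prior.tau_mean / self.net.age[self.root_label]
        for v in internal:
            self.net.age[v] *= scale
        for v in self.net.theta:
            self.net.theta[v] = prior.theta_mean
        for h in self.net.phi:
            d = self.net.donor_parent(h)
            p = self.net.primary_parent(h)
            self.net.phi[h] = {d: 0.5, p: 0.5}
        self.cnet = _CompiledNet(self.net)

        # -- packed per-locus state ----------------------------------------
        self.labels = sorted(samples.assignment)
        self.ntips = len(self.labels)
        self.tip_pop = np.array([self.cnet.pop_index[samples.assignment[lab]]
                                 for lab in self.labels], np.int32)
        self.has_data = loci is not None
        L = len(loci) if loci is not None else 1
        self.L = L
        n = 2 * self.ntips - 1
        self.n_nodes = n
        npop = len(self.cnet.pops)
        nh = len(self.cnet.hybrids)
        if self.has_data:
            pats, wts = [], []
            for a in loci:
                order = [a.labels.index(lab) for lab in self.labels]
                p, w = _compress(a.matrix[order])
                pats.append(p)
                wts.append(w)
            mmax = max(p.shape[1] for p in pats)
            self.patterns = np.zeros((L, self.ntips, mmax), np.int8)
            self.weights = np.zeros((L, mmax))
            self.pm = np.zeros(L, np.int32)
            for i, (p, w) in enumerate(zip(pats, wts)):
                self.patterns[i, :, :p.shape[1]] = p
                self.weights[i, :p.shape[1]] = w
                self.pm[i] = p.shape[1]
        else:
            self.patterns = np.zeros((L, self.ntips, 1), np.int8)
            self.weights = np.zeros((L, 1))
            self.pm = np.zeros(L, np.int32)
        self.children = np.full((L, n, 2), -1, np.int32)
        self.parent = np.full((L, n), -1, np.int32)
        self.age = np.zeros((L, n))
        self.age2 = np.zeros((L, n))
        self.root = np.zeros(L, np.int32)
        self.needed = np.full((L, n, nh), -1, np.int8)
        self.needed2 = np.full((L, n, nh), -1, np.int8)
        self.karr = np.zeros((L, npop))
        self.carr = np.zeros((L, npop))
        self.k2arr = np.zeros((L, npop))
        self.c2arr = np.zeros((L, npop))
        self.phicarr = np.zeros((L, nh, 2), np.int32)
        self.phic2arr = np.zeros((L, nh, 2), np.int32)
        self.llarr = np.zeros(L)
        self.ll2 = np.zeros(L)
        self.k_tot = np.zeros(npop)
        self.c_tot = np.zeros(npop)
        self._init_gene_trees()

        # -- proposal step sizes -------------------------------------------
        s = dict(settings.steps)
        self.step = {
            "gene_age": s.get("gene_age", 0.5) * prior.tau_mean,
            "gene_root": s.get("gene_root", 0.7),
            "tau": s.get("tau", 0.3) * prior.tau_mean,
            "mix": s.get("mix", 0.4),
        }
        self.wb_scale = prior.tau_mean / 2.0  # root-edge attachment scale
        self.acc_gene = np.zeros((3, 2), np.int64)  # age, root, spr
        self.accepts = {m: [0, 0] for m in ("tau", "mix", "species")}

    # -- initialization -----------------------------------------------------

    def _init_gene_trees(self) -> None:
        design = SimulationDesign(S=1, L=max(self.L, 1), n=2, rho=0.0,
                                  theta_base=self.prior.theta_mean,
                                  R=1, seed=int(self.rng.integers(2 ** 31)))
        nh = len(self.cnet.hybrids)
        npop = len(self.cnet.pops)
        k2 = np.zeros(npop)
        c2 = np.zeros(npop)
        phic2 = np.zeros((nh, 2), np.int32)
        for l in range(self.L):
            for _attempt in range(200):
                g = simulate_locus(self.net, self.samples, design, self.rng)
                tree = g.tree_at(0)
                children, age, root, tip_pop, remap = _tree_to_arrays(
                    tree, self.samples, self.cnet)
                ind = _indicator_array(indicators_from_routing(g), remap,
                                       self.cnet, self.n_nodes)
                needed2 = np.full((self.n_nodes, nh), -1, np.int8)
                st, _ = _trace_one(children, age, root, self.ntips,
                                   self.tip_pop, self.cnet.ev_time,
                                   self.cnet.ev_kind, self.cnet.ev_src,
                                   self.cnet.ev_dest, self.cnet.ev_alt,
                                   self.cnet.ev_hyb, self.cnet.phi, ind, 1,
                                   k2, c2, phic2, needed2)
                if st == 1:
                    self.children[l] = children
                    self.age[l] = age
                    self.root[l] = root
                    for v in range(self.n_nodes):
                        for j in range(2):
                            if children[v, j] >= 0:
                                self.parent[l, children[v, j]] = v
                    self.parent[l, root] = -1
                    self.needed[l] = needed2
                    self.karr[l] = k2
                    self.carr[l] = c2
                    self.phicarr[l] = phic2
                    if self.has_data:
                        self.llarr[l] = _prune_one(
                            self.children[l], self.age[l], root,
                            self.patterns[l], self.pm[l], self.weights[l])
                    break
            else:
                raise NetworkError("failed to initialize a compatible gene tree")
        self.k_tot = self.karr.sum(axis=0)
        self.c_tot = self.carr.sum(axis=0)

    # -- priors ---------------------------------------------------------------

    def _log_prior_tau(self) -> float:
        a, b = self.prior.tau_alpha, self.prior.tau_beta
        t0 = self.net.age[self.root_label]
        lp = a * log(b) - lgamma(a) - (a + 1) * log(t0) - b / t0
        d = len(self.tau_groups) - 1
        return lp - d * log(t0)

    def _log_prior_theta(self) -> float:
        if self.theta_integrated:
            return 0.0
        a, b = self.prior.theta_alpha, self.prior.theta_beta
        out = 0.0
        for th in self.cnet.theta:
            out += a * log(b) - lgamma(a) - (a + 1) * log(th) - b / th
        return out

    def _total_logdens(self, k_tot=None, c_tot=None, phicarr=None) -> float:
        k_tot = self.k_tot if k_tot is None else k_tot
        c_tot = self.c_tot if c_tot is None else c_tot
        phicarr = self.phicarr if phicarr is None else phicarr
        phi_total = _phi_terms(
            phicarr.sum(axis=0).astype(np.int32).reshape(-1, 2)
            if phicarr.ndim == 3 else phicarr, self.cnet.phi)
        if self.theta_integrated:
            return _dens_integrated(k_tot, c_tot, self.prior.theta_alpha,
                                    self.prior.theta_beta) + phi_total
        return phi_total + _dens_sampled(k_tot, c_tot, self.cnet.theta)

    # -- parameter moves -------------------------------------------------------

    def _tau_bounds(self, group: tuple[str, ...]) -> tuple[float, float]:
        gset = set(group)
        children = self.net.children
        lo, hi = 0.0, math.inf
        for v in group:
            for ch in children[v]:
                if ch not in gset:
                    lo = max(lo, self.net.age[ch])
            for pparent in self.net.parents.get(v, ()):
                if pparent not in gset and \
                        self.net.age[pparent] > self.net.age[v]:
                    hi = min(hi, self.net.age[pparent])
        return lo, hi

    def _move_tau(self, group: tuple[str, ...]) -> None:
        old = self.net.age[group[0]]
        lo, hi = self._tau_bounds(group)
        w = self.step["tau"]
        new = old + w * (self.rng.random() - 0.5)
        if math.isinf(hi):
            new = lo + abs(new - lo)
        else:
            new = _reflect(new, lo, hi)
        is_root = group[0] == self.root_label
        old_prior = self._log_prior_tau() if is_root else 0.0
        for v in group:
            self.net.age[v] = new
        self.cnet.refresh_times()
        st, log_jac, logq, llsum = _tau_batch(
            self.children, self.age, self.age2, self.root, self.ntips,
            self.tip_pop, self.patterns, self.pm, self.weights,
            self.has_data, self.cnet.ev_time, self.cnet.ev_kind,
            self.cnet.ev_src, self.cnet.ev_dest, self.cnet.ev_alt,
            self.cnet.ev_hyb, self.cnet.phi, self.needed, self.needed2,
            self.k2arr, self.c2arr, self.phic2arr, self.ll2, lo, hi, old, new)
        ok = st == 1
        if ok:
            k_tot = self.k2arr.sum(axis=0)
            c_tot = self.c2arr.sum(axis=0)
            log_r = (self._total_logdens(k_tot, c_tot, self.phic2arr)
                     - self._total_logdens())
            log_r += log_jac + logq + llsum - self.llarr.sum()
            if is_root:
                log_r += self._log_prior_tau() - old_prior
            ok = math.log(self.rng.random() + 1e-300) < log_r
        self.accepts["tau"][1] += 1
        if ok:
            self.accepts["tau"][0] += 1
            self._swap_scratch(k_tot, c_tot, ages=True, lls=True)
        else:
            for v in group:
                self.net.age[v] = old
            self.cnet.refresh_times()

    def _swap_scratch(self, k_tot, c_tot, ages: bool, lls: bool) -> None:
        self.needed, self.needed2 = self.needed2, self.needed
        self.karr, self.k2arr = self.k2arr, self.karr
        self.carr, self.c2arr = self.c2arr, self.carr
        self.phicarr, self.phic2arr = self.phic2arr, self.phicarr
        if ages:
            self.age, self.age2 = self.age2, self.age
        if lls:
            self.llarr, self.ll2 = self.ll2, self.llarr
        self.k_tot = k_tot
        self.c_tot = c_tot

    def _gibbs_theta(self) -> None:
        if self.theta_integrated:
            return
        a, b = self.prior.theta_alpha, self.prior.theta_beta
        for p in range(len(self.cnet.pops)):
            th = (b + 2.0 * self.c_tot[p]) / \
                self.rng.gamma(a + self.k_tot[p])
            self.cnet.theta[p] = th
            self.net.theta[self.cnet.pops[p]] = th

    def _gibbs_phi(self) -> None:
        if not len(self.cnet.hybrids):
            return
        tot = self.phicarr.sum(axis=0)  # (nh, 2)
        for h in range(len(self.cnet.hybrids)):
            phi = float(self.rng.beta(1 + tot[h, 0], 1 + tot[h, 1]))
            phi = min(max(phi, 1e-12), 1 - 1e-12)
            self.cnet.phi[h] = phi
            lab = self.cnet.hybrids[h]
            d = self.net.donor_parent(lab)
            p = self.net.primary_parent(lab)
            self.net.phi[lab] = {d: phi, p: 1.0 - phi}

    def _move_mix(self) -> None:
        lam = self.step["mix"]
        x = math.exp(lam * (self.rng.random() - 0.5))
        dim = len(self.tau_groups) + self.L * (self.ntips - 1)
        if not self.theta_integrated:
            dim += len(self.cnet.theta)
        old_prior = self._log_prior_tau() + self._log_prior_theta()
        old_dens = self._total_logdens()
        old_ll = self.llarr.sum()
        for group in self.tau_groups:
            for v in group:
                self.net.age[v] *= x
        if not self.theta_integrated:
            self.cnet.theta *= x
            for p, lab in enumerate(self.cnet.pops):
                self.net.theta[lab] = self.cnet.theta[p]
        self.cnet.refresh_times()
        if self.has_data:
            new_ll = _prune_batch_scaled(self.children, self.age, self.root,
                                         self.patterns, self.pm,
                                         self.weights, x, self.ll2)
        else:
            new_ll = 0.0
            self.ll2[:] = 0.0
        c_tot_new = self.c_tot * x
        log_r = (new_ll - old_ll
                 + self._total_logdens(self.k_tot, c_tot_new) - old_dens
                 + self._log_prior_tau() + self._log_prior_theta() - old_prior
                 + dim * math.log(x))
        self.accepts["mix"][1] += 1
        if math.log(self.rng.random() + 1e-300) < log_r:
            self.accepts["mix"][0] += 1
            self.age *= x
            self.carr *= x
            self.c_tot = c_tot_new
            self.llarr, self.ll2 = self.ll2, self.llarr
        else:
            for group in self.tau_groups:
                for v in group:
                    self.net.age[v] /= x
            if not self.theta_integrated:
                self.cnet.theta /= x
                for p, lab in enumerate(self.cnet.pops):
                    self.net.theta[lab] = self.cnet.theta[p]
            self.cnet.refresh_times()

    def _move_species_nni(self) -> None:
        """Nearest-neighbour interchange on the (hybrid-free) species tree."""
        children = self.net.children
        internal = [v for v in self.net.age
                    if children[v] and v != self.root_label]
        if not internal:
            return
        v = internal[int(self.rng.integers(len(internal)))]
        p = self.net.parents[v][0]
        sibs = [x for x in children[p] if x != v]
        if not sibs:
            return
        s = sibs[0]
        kids = children[v]
        c = kids[int(self.rng.integers(len(kids)))]
        if self.net.age[s] >= self.net.age[v]:
            return  # swapping would break the age order; auto-reject
        saved_parents = dict(self.net.parents)
        new_parents = dict(self.net.parents)
        new_parents[c] = (p,)
        new_parents[s] = (v,)
        self.net.parents = new_parents
        self.cnet.rebuild()
        st, logq = _trace_batch(
            self.children, self.age, self.root, self.ntips, self.tip_pop,
            self.cnet.ev_time, self.cnet.ev_kind, self.cnet.ev_src,
            self.cnet.ev_dest, self.cnet.ev_alt, self.cnet.ev_hyb,
            self.cnet.phi, self.needed, self.needed2, self.k2arr,
            self.c2arr, self.phic2arr)
        ok = st == 1
        if ok:
            k_tot = self.k2arr.sum(axis=0)
            c_tot = self.c2arr.sum(axis=0)
            log_r = (self._total_logdens(k_tot, c_tot, self.phic2arr)
                     - self._total_logdens()) + logq
            ok = math.log(self.rng.random() + 1e-300) < log_r
        self.accepts["species"][1] += 1
        if ok:
            self.accepts["species"][0] += 1
            self._swap_scratch(k_tot, c_tot, ages=False, lls=False)
        else:
            self.net.parents = saved_parents
            self.cnet.rebuild()

    # -- autotuning -----------------------------------------------------------

    def _autotune(self) -> None:
        pairs = [("gene_age", self.acc_gene[0]), ("gene_root", self.acc_gene[1])]
        for name, (a, t) in pairs:
            if t >= 20:
                rate = a / t
                self.step[name] *= float(np.clip(
                    math.exp(1.2 * (rate - 0.3)), 0.5, 2.0))
        self.acc_gene[:] = 0
        for move in ("tau", "mix"):
            a, t = self.accepts[move]
            if t >= 20:
                rate = a / t
                self.step[move] *= float(np.clip(
                    math.exp(1.2 * (rate - 0.3)), 0.5, 2.0))
                self.accepts[move] = [0, 0]

    # -- main loop --------------------------------------------------------------

    def _iterate(self) -> None:
        nh = len(self.cnet.hybrids)
        _gene_sweep(self.children, self.parent, self.age, self.root,
                    self.ntips, self.tip_pop, self.patterns, self.pm,
                    self.weights, self.has_data,
                    self.cnet.ev_time, self.cnet.ev_kind, self.cnet.ev_src,
                    self.cnet.ev_dest, self.cnet.ev_alt, self.cnet.ev_hyb,
                    self.cnet.phi, self.cnet.theta, self.theta_integrated,
                    self.prior.theta_alpha, self.prior.theta_beta,
                    self.needed, self.phicarr, self.karr, self.carr,
                    self.llarr, self.k_tot, self.c_tot,
                    self.step["gene_age"], self.step["gene_root"],
                    self.wb_scale,
                    self.ntips - 1, 2, 2 if nh else 0, self.acc_gene)
        for group in self.tau_groups:
            self._move_tau(group)
        self._gibbs_theta()
        self._gibbs_phi()
        self._move_mix()
        if self.species_move:
            self._move_species_nni()

    def run(self) -> dict:
        st = self.settings
        for it in range(st.burnin):
            self._iterate()
            if st.autotune and it and it % 100 == 0:
                self._autotune()
        self.acc_gene[:] = 0
        for m in self.accepts:
            self.accepts[m] = [0, 0]
        chain: dict[str, list] = {}
        for group in self.tau_groups:
            chain[f"tau_{group[0]}"] = []
        if not self.theta_integrated:
            for lab in self.cnet.pops:
                chain[f"theta_{lab}"] = []
        for h in self.cnet.hybrids:
            chain[f"phi_{h}"] = []
        chain["loglik"] = []
        trees: list[str] = []
        for _s in range(st.nsamples):
            for _ in range(st.sample_interval):
                self._iterate()
            for group in self.tau_groups:
                chain[f"tau_{group[0]}"].append(self.net.age[group[0]])
            if not self.theta_integrated:
                for p, lab in enumerate(self.cnet.pops):
                    chain[f"theta_{lab}"].append(float(self.cnet.theta[p]))
            for hi_, h in enumerate(self.cnet.hybrids):
                chain[f"phi_{h}"].append(float(self.cnet.phi[hi_]))
            chain["loglik"].append(float(self.llarr.sum()))
            if self.species_move:
                trees.append(canonical_topology(self.net))
        out = {key: np.asarray(v) for key, v in chain.items()}
        if self.species_move:
            out["tree"] = trees
        acc = {m: (a / t if t else math.nan)
               for m, (a, t) in self.accepts.items()}
        for i, name in enumerate(("gene_age", "gene_root", "gene_spr")):
            a, t = self.acc_gene[i]
            acc[name] = a / t if t else math.nan
        out["acceptance"] = acc
        return out


def _reflect(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y < 0:
        y += 2.0 * width
    return lo + (y if y <= width else 2.0 * width - y)


# ---------------------------------------------------------------------------
# Public entry points


def run_a00(loci: list[Alignment] | None, net: SpeciesNetwork,
            samples: SampleMap, prior: PriorSpec,
            settings: MCMCSettings) -> dict:
    """A00 analysis: fixed model, estimate tau, theta and phi.

    ``loci=None`` runs the sampler with a flat likelihood (prior
    recovery / detailed-balance checking).  Returns the thinned chain as
    a dict of parameter sample arrays plus per-move acceptance rates.
    """
    sampler = _Sampler(loci, net, samples, prior, settings,
                       theta_integrated=prior.theta_integrated,
                       species_move=False)
    return sampler.run()


def run_a01(loci: list[Alignment] | None, net: SpeciesNetwork,
            samples: SampleMap, prior: PriorSpec,
            settings: MCMCSettings) -> dict:
    """A01 analysis: species-tree estimation with theta integrated out.

    ``net`` supplies the starting topology and the tip set; the chain
    samples rooted species-tree topologies via NNI moves together with
    the divergence times.
    """
    if net.hybrid_nodes:
        raise NetworkError("A01 estimates trees, not networks")
    sampler = _Sampler(loci, net, samples, prior, settings,
                       theta_integrated=True, species_move=True)
    return sampler.run()


# ---------------------------------------------------------------------------
# Posterior summaries


def hpd_interval(samples: np.ndarray, mass: float = 0.95
                 ) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass*N)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty chain")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 + np.arange(n - m + 1)] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS by the initial positive sequence autocorrelation estimator."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n] / np.arange(n, 0, -1)
    acf /= acf[0]
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = acf[t] + (acf[t + 1] if t + 1 < n else 0.0)
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def canonical_topology(net: SpeciesNetwork) -> str:
    """Label-sorted Newick string of a species tree's rooted topology."""
    ch = net.children

    def render(v: str) -> str:
        kids = ch[v]
        if not kids:
            return v
        parts = sorted(render(c) for c in kids)
        return f"({','.join(parts)})"

    return render(net.root) + ";"


def _clades_of(newick: str) -> set[frozenset]:
    """Non-trivial rooted clades of a canonical topology string."""
    stack: list[list] = [[]]
    token = ""
    clades: set[frozenset] = set()

    def flush():
        nonlocal token
        if token:
            stack[-1].append(frozenset([token]))
            token = ""

    for chs in newick:
        if chs == "(":
            stack.append([])
        elif chs == ",":
            flush()
        elif chs == ")":
            flush()
            group = frozenset().union(*stack.pop())
            clades.add(group)
            stack[-1].append(group)
        elif chs == ";":
            flush()
        else:
            token += chs
    return clades


def clade_probabilities(trees: list[str]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for cl in _clades_of(t):
            counts[cl] = counts.get(cl, 0) + 1
    return {cl: c / len(trees) for cl, c in counts.items()}


def summarize_posterior(chain: dict) -> PosteriorSummary:
    """Posterior means, 95% HPD intervals, ESS, and tree/clade summaries.

    The MAP tree is the highest-frequency sampled topology, ties broken
    lexicographically by Newick string.
    """
    means: dict[str, float] = {}
    hpd: dict[str, tuple[float, float]] = {}
    ess: dict[str, float] = {}
    for key, vals in chain.items():
        if key in ("tree", "acceptance"):
            continue
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError("empty chain")
        means[key] = float(arr.mean())
        hpd[key] = hpd_interval(arr)
        ess[key] = effective_sample_size(arr)
    summary = PosteriorSummary(means=means, hpd=hpd, ess=ess)
    trees = chain.get("tree")
    if trees:
        counts: dict[str, int] = {}
        for t in trees:
            counts[t] = counts.get(t, 0) + 1
        total = len(trees)
        summary.tree_probs = {t: c / total for t, c in sorted(counts.items())}
        best = max(counts.values())
        summary.map_tree = min(t for t, c in counts.items() if c == best)
        summary.clade_probs = clade_probabilities(trees)
    return summary


def convergence_flag(s1: PosteriorSummary, s2: PosteriorSummary,
                     threshold: float = 0.05) -> bool:
    """True when two independent runs disagree: any clade (or tree)
    posterior probability differing by more than ``threshold``."""
    keys = set(s1.clade_probs) | set(s2.clade_probs)
    for key in keys:
        if abs(s1.clade_probs.get(key, 0.0)
               - s2.clade_probs.get(key, 0.0)) > threshold:
            return True
    keys = set(s1.tree_probs) | set(s2.tree_probs)
    for key in keys:
        if abs(s1.tree_probs.get(key, 0.0)
               - s2.tree_probs.get(key, 0.0)) > threshold:
            return True
    return False
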