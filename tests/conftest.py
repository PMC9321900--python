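import numpy as np
import pytest

from mscrecomb import (SimulationDesign, SpeciesNetwork, build_study_model,
                       make_sample_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20220404)


@pytest.fixture
def balanced_tree_b():
    return build_study_model("A01-B", 0.0025)


@pytest.fixture
def msci_tree_b():
    return build_study_model("A00-B", 0.0025)


@pytest.fixture
def single_population():
    theta = 0.01
    return SpeciesNetwork(age={"A": 0.0}, parents={},
                          theta={"A": theta}).validate()


@pytest.fixture
def two_population_split():
    """Two species diverging at tau = 2*theta, all theta equal."""
    theta = 0.01
    return SpeciesNetwork(
        age={"A": 0.0, "B": 0.0, "R": 2 * theta},
        parents={"A": ("R",), "B": ("R",)},
        theta={"A": theta, "B": theta, "R": theta}).validate()


@pytest.fixture
def three_species_tree():
    """Asymmetric ((A,B),C) with internal branch 2*theta."""
    theta = 0.01
    return SpeciesNetwork(
        age={"A": 0.0, "B": 0.0, "C": 0.0, "U": 2 * theta, "R": 4 * theta},
        parents={"A": ("U",), "B": ("U",), "U": ("R",), "C": ("R",)},
        theta={k: theta for k in "ABCUR"}).validate()


def simulate_counts(net, S, rho, theta_base, nloci, seed, n=500):
    """Recombination-event counts over nloci independent loci."""
    from mscrecomb import count_recombination_events, simulate_locus

    smap = make_sample_map(net, S)
    design = SimulationDesign(S=S, L=max(nloci, 1), n=n, rho=rho,
                              theta_base=theta_base, R=1, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    return np.array([count_recombination_events(
        simulate_locus(net, smap, design, rng)) for _ in range(nloci)])
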