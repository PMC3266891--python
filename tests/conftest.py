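import numpy as np
import pytest

from pottsge import (
    build_genotype_table,
    build_neighbor_graph,
    genotype_distance,
)
from pottsge.mcmc import CaseControlData
from pottsge.simulate import (
    PopulationModel,
    RiskModelSpec,
    risk_allele_regions,
    simulate_case_control,
)


def two_cluster_risk(alpha2=np.log(2.0), beta2=np.log(4.0)):
    """Region I vs regions II+III with user-chosen strong effects."""
    three = risk_allele_regions(functional_snps=(1, 3, 5))

    def rule(G):
        return (three(G) > 0).astype(int)

    return RiskModelSpec(rule=rule, alpha=np.array([0.0, alpha2]), beta=np.array([0.0, beta2]))


@pytest.fixture(scope="session")
def small_population():
    """Six independent SNPs at the leading reference MAFs."""
    from pottsge.simulate import REFERENCE_MAFS

    return PopulationModel(mafs=REFERENCE_MAFS[:6])


@pytest.fixture(scope="session")
def small_study(small_population):
    """A 300-case/300-control study with a strong 2-cluster interaction."""
    return simulate_case_control(small_population, two_cluster_risk(), 300, 300, seed=11)


@pytest.fixture(scope="session")
def random_table():
    rng = np.random.default_rng(5)
    G = rng.integers(0, 3, size=(60, 5))
    return build_genotype_table(G)


@pytest.fixture(scope="session")
def random_graph(random_table):
    return build_neighbor_graph(genotype_distance(random_table), n_neighbors=4)


@pytest.fixture(scope="session")
def tiny_graph():
    """A 5-genotype graph small enough for exact enumeration."""
    rng = np.random.default_rng(3)
    G = np.array(
        [
            [0, 0, 1],
            [0, 1, 1],
            [1, 1, 1],
            [2, 1, 0],
            [2, 2, 0],
        ]
    )
    # replicate rows so every genotype is observed with positive variance
    reps = rng.integers(1, 4, size=5)
    M = np.repeat(G, reps, axis=0)
    table = build_genotype_table(M)
    return build_neighbor_graph(genotype_distance(table), n_neighbors=2)


def make_tiny_data(seed=0, n=40, H_codes=None):
    """A tiny case-control dataset on a 4-genotype space."""
    rng = np.random.default_rng(seed)
    codes = H_codes if H_codes is not None else np.array(
        [[0, 0], [0, 1], [1, 1], [2, 1]]
    )
    gid = rng.integers(0, len(codes), size=n)
    G = codes[gid]
    table = build_genotype_table(G)
    graph = build_neighbor_graph(genotype_distance(table), n_neighbors=2)
    E = rng.integers(0, 2, size=n).astype(float)
    D = rng.integers(0, 2, size=n)
    return CaseControlData(
        D=D, E=E, X=np.zeros((n, 0)), genotype_id=table.subject_index,
        table=table, graph=graph,
    )
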