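import numpy as np
import pytest

from dewetsim import (
    ContractileState,
    ElasticMaterial,
    FoundationModel,
    LinearSystem,
    assemble_contractile_load,
    assemble_elastic_stiffness,
    assemble_foundation_matrix,
    build_disk_mesh,
    compute_traction,
    elasticity_matrix,
    partition_subdomains,
    solve_equilibrium,
)
from dewetsim.synth import SynthParams


@pytest.fixture(scope="session")
def material():
    return ElasticMaterial(E=1.0, nu=0.46)


@pytest.fixture(scope="session")
def small_mesh():
    """20 elements across the diameter: fast enough for every unit test."""
    return build_disk_mesh(20, 200.0)


@pytest.fixture(scope="session")
def foundation():
    return FoundationModel(k=5e-3, alpha=1.0)


@pytest.fixture(scope="session")
def uniform_solution(small_mesh, material, foundation):
    """Displacement/traction of the uniformly contracting small disk."""
    D = elasticity_matrix(material)
    state = ContractileState(0.05, 0.0, partition_subdomains(small_mesh, small_mesh.radius))
    u = solve_equilibrium(
        LinearSystem(
            assemble_elastic_stiffness(small_mesh, D),
            assemble_foundation_matrix(small_mesh, foundation),
            assemble_contractile_load(small_mesh, D, state),
            small_mesh,
        )
    )
    return u, compute_traction(u, foundation), state


@pytest.fixture(scope="session")
def synth_params():
    return SynthParams(radius=200.0, pixel_size=2.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
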