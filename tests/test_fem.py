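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
    compute_stress,
    compute_traction,
    elasticity_matrix,
    lame_constants,
    partition_subdomains,
    solve_equilibrium,
)
from dewetsim.fem import (
    DisplacementField,
    SolverError,
    element_foundation,
    element_stiffness,
    mean_traction_magnitude,
    traction_balance,
)


@pytest.mark.parametrize(
    "E, nu, lam, mu",
    [
        (1.0, 0.46, 3.938356164383564, 0.3424657534246575),
        (3.0, 0.0, 0.0, 1.5),
        (2.0, 0.25, 0.8, 0.8),
    ],
)
def test_lame_constants(E, nu, lam, mu):
    got_lam, got_mu = lame_constants(E, nu)
    assert got_lam == pytest.approx(lam, rel=1e-12)
    assert got_mu == pytest.approx(mu, rel=1e-12)


@pytest.mark.parametrize("E, nu", [(0.0, 0.3), (-1.0, 0.3), (1.0, 0.5), (1.0, -1.0)])
def test_lame_constants_rejects_invalid(E, nu):
    with pytest.raises(ValueError):
        lame_constants(E, nu)


def test_elasticity_matrix_modes():
    lam, mu = lame_constants(1.0, 0.46)
    D = elasticity_matrix(ElasticMaterial(E=1.0, nu=0.46))
    assert D[0, 0] == pytest.approx(lam + 2 * mu)
    assert D[0, 1] == pytest.approx(lam)
    assert D[2, 2] == pytest.approx(mu)
    # nu = 0: no cross coupling in either mode
    D0 = elasticity_matrix(ElasticMaterial(E=1.0, nu=0.0))
    assert np.allclose(D0, np.diag([1.0, 1.0, 0.5]))
    Dp = elasticity_matrix(ElasticMaterial(E=1.0, nu=0.0, constitutive_mode="plane_stress"))
    assert np.allclose(Dp, np.diag([1.0, 1.0, 0.5]))
    with pytest.raises(ValueError):
        ElasticMaterial(constitutive_mode="3d")


def test_stiffness_symmetry_and_rigid_modes(small_mesh, material):
    K = assemble_elastic_stiffness(small_mesh, elasticity_matrix(material))
    assert abs(K - K.T).max() < 1e-12
    for t in ([1.0, 0.0], [0.0, 1.0]):
        rigid = np.tile(t, small_mesh.n_nodes)
        assert np.abs(K @ rigid).max() < 1e-10


def test_single_element_stiffness_row_sums():
    Ke = element_stiffness(np.diag([1.0, 1.0, 0.5]), 1.0)
    assert np.allclose(Ke, Ke.T)
    # uniform translation of the element produces zero nodal forces
    assert np.abs(Ke @ np.tile([1.0, 0.0], 4)).max() < 1e-14
    assert np.abs(Ke @ np.tile([0.0, 1.0], 4)).max() < 1e-14


def test_patch_test_affine_field_constant_stress(material):
    """Affine displacement reproduces its constant stress exactly (patch test)."""
    mesh = build_disk_mesh(7, 35.0)
    D = elasticity_matrix(material)
    A = np.array([[0.002, 0.001], [-0.0005, 0.003]])
    u = DisplacementField(values=mesh.node_coords @ A.T)
    state = ContractileState(0.0, 0.0, partition_subdomains(mesh, 0.0))
    sig = compute_stress(u, D, state, mesh)
    strain = np.array([A[0, 0], A[1, 1], A[0, 1] + A[1, 0]])
    expected = D @ strain
    assert np.allclose(sig.sxx, expected[0], atol=1e-14)
    assert np.allclose(sig.syy, expected[1], atol=1e-14)
    assert np.allclose(sig.sxy, expected[2], atol=1e-14)


def test_foundation_matrix_scaling(small_mesh):
    Ks1 = assemble_foundation_matrix(small_mesh, FoundationModel(k=2e-3, alpha=1.0))
    Ks_half = assemble_foundation_matrix(small_mesh, FoundationModel(k=2e-3, alpha=0.5))
    assert abs(Ks1 - Ks1.T).max() < 1e-15
    assert abs(Ks_half * 2 - Ks1).max() < 1e-15
    Ks0 = assemble_foundation_matrix(small_mesh, FoundationModel(k=2e-3, alpha=0.0))
    assert Ks0.nnz == 0 or abs(Ks0).max() == 0.0
    # total spring stiffness of one element equals alpha*k*h^2 per direction
    Me = element_foundation(2.0)
    assert Me[0::2, 0::2].sum() == pytest.approx(4.0)


def test_foundation_model_validation():
    with pytest.raises(ValueError):
        FoundationModel(k=-1.0)
    with pytest.raises(ValueError):
        FoundationModel(k=1.0, alpha=1.5)
    with pytest.raises(ValueError):
        FoundationModel(k=1.0, c=-0.1)


def test_contractile_load_linearity(small_mesh, material):
    D = elasticity_matrix(material)
    part = partition_subdomains(small_mesh, small_mesh.radius / 2.0)
    f0 = assemble_contractile_load(small_mesh, D, ContractileState(0.0, 0.0, part))
    assert np.all(f0 == 0.0)
    f1 = assemble_contractile_load(small_mesh, D, ContractileState(0.03, 0.02, part))
    f2 = assemble_contractile_load(small_mesh, D, ContractileState(0.06, 0.04, part))
    assert np.allclose(f2, 2.0 * f1, rtol=1e-13)


def test_uniform_contraction_loads_only_boundary(small_mesh, material):
    """Interior nodes of a uniformly contracting tissue receive no net load."""
    D = elasticity_matrix(material)
    part = partition_subdomains(small_mesh, small_mesh.radius)  # all baseline
    f = assemble_contractile_load(small_mesh, D, ContractileState(0.05, 0.0, part))
    counts = np.bincount(small_mesh.elements.ravel(), minlength=small_mesh.n_nodes)
    interior = counts == 4  # nodes shared by four elements: contributions cancel
    fx = f[0::2]
    fy = f[1::2]
    assert np.abs(fx[interior]).max() < 1e-12
    assert np.abs(fy[interior]).max() < 1e-12
    assert np.abs(fx[~interior]).max() > 0


def test_solve_zero_load_and_linearity(small_mesh, material, foundation):
    D = elasticity_matrix(material)
    K = assemble_elastic_stiffness(small_mesh, D)
    Ks = assemble_foundation_matrix(small_mesh, foundation)
    part = partition_subdomains(small_mesh, small_mesh.radius)
    f = assemble_contractile_load(small_mesh, D, ContractileState(0.05, 0.0, part))
    u0 = solve_equilibrium(LinearSystem(K, Ks, np.zeros_like(f), small_mesh))
    assert np.all(u0.values == 0.0)
    u1 = solve_equilibrium(LinearSystem(K, Ks, f, small_mesh))
    u3 = solve_equilibrium(LinearSystem(K, Ks, 3.0 * f, small_mesh))
    assert np.allclose(u3.values, 3.0 * u1.values, rtol=1e-12)


def test_solve_requires_foundation(small_mesh, material):
    D = elasticity_matrix(material)
    K = assemble_elastic_stiffness(small_mesh, D)
    Ks = assemble_foundation_matrix(small_mesh, FoundationModel(k=1e-3, alpha=0.0))
    with pytest.raises(SolverError):
        solve_equilibrium(LinearSystem(K, Ks, np.ones(2 * small_mesh.n_nodes), small_mesh))


def test_traction_centripetal_and_balanced(small_mesh, foundation, uniform_solution):
    u, T, _ = uniform_solution
    assert np.allclose(T.values, foundation.alpha * foundation.k * u.values)
    assert traction_balance(T, small_mesh) < 1e-8
    # at rim nodes the traction points toward the disk center
    rr = np.hypot(*small_mesh.node_coords.T)
    rim = rr > 0.9 * small_mesh.radius
    inward = -(small_mesh.node_coords[rim] * T.values[rim]).sum(axis=1)
    assert np.all(inward > 0)
    assert mean_traction_magnitude(T, small_mesh) > 0


def test_stress_limit_cases(material):
    """Nearly clamped tissue is under isotropic tension D·{γ,γ,0}; a nearly
    free tissue contracts stress-free."""
    mesh = build_disk_mesh(16, 100.0)
    D = elasticity_matrix(material)
    K = assemble_elastic_stiffness(mesh, D)
    part = partition_subdomains(mesh, mesh.radius)
    gamma = 0.04
    state = ContractileState(gamma, 0.0, part)
    f = assemble_contractile_load(mesh, D, state)
    expected = D @ np.array([gamma, gamma, 0.0])

    clamped = assemble_foundation_matrix(mesh, FoundationModel(k=1e6, alpha=1.0))
    u_c = solve_equilibrium(LinearSystem(K, clamped, f, mesh))
    sig_c = compute_stress(u_c, D, state, mesh)
    interior = np.hypot(*mesh.element_centers.T) < 0.6 * mesh.radius
    assert np.allclose(sig_c.sxx[interior], expected[0], rtol=1e-3)
    assert np.allclose(sig_c.syy[interior], expected[1], rtol=1e-3)

    free = assemble_foundation_matrix(mesh, FoundationModel(k=1e-9, alpha=1.0))
    u_f = solve_equilibrium(LinearSystem(K, free, f, mesh))
    sig_f = compute_stress(u_f, D, state, mesh)
    assert np.abs(sig_f.mean_normal).max() < 1e-3 * np.abs(expected[0])

    zero = compute_stress(
        DisplacementField(values=np.zeros_like(u_f.values)),
        D,
        ContractileState(0.0, 0.0, part),
        mesh,
    )
    assert np.all(zero.sxx == 0) and np.all(zero.sxy == 0)


def test_solution_linear_in_contraction(small_mesh, material, foundation):
    """u, T, σ scale exactly with the contraction magnitudes at fixed α."""
    D = elasticity_matrix(material)
    K = assemble_elastic_stiffness(small_mesh, D)
    Ks = assemble_foundation_matrix(small_mesh, foundation)
    part = partition_subdomains(small_mesh, small_mesh.radius / 3.0)

    def solve(eps0, epsa):
        state = ContractileState(eps0, epsa, part)
        f = assemble_contractile_load(small_mesh, D, state)
        u = solve_equilibrium(LinearSystem(K, Ks, f, small_mesh))
        return u, compute_traction(u, foundation)

    u1, T1 = solve(0.02, 0.01)
    u2, T2 = solve(0.04, 0.02)
    assert np.allclose(u2.values, 2 * u1.values, rtol=1e-11, atol=1e-15)
    assert np.allclose(T2.values, 2 * T1.values, rtol=1e-11, atol=1e-15)
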