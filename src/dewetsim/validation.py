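"""Verification utilities: oracle comparison, convergence, symmetry metrics.

The benchmark problem is the uniformly contracting disk, for which the 2D
finite-element solution can be checked against the 1D axisymmetric
finite-difference oracle. The mesh-convergence study uses a deliberately soft
foundation (``VERIFICATION_K_EFF``): the displacement then varies smoothly on
the coarsest mesh of the sequence, so the measured rate reflects the
discretization order rather than an under-resolved traction boundary layer.
The physically motivated default foundation density for protocol runs is
stiffer (boundary layer ~10–20% of the radius) and lives in
``fem.FoundationModel``.
"""

from __future__ import annotations

import numpy as np

from dewetsim.fem import (
    ContractileState,
    DisplacementField,
    ElasticMaterial,
    FoundationModel,
    LinearSystem,
    TractionFieldFE,
    assemble_contractile_load,
    assemble_elastic_stiffness,
    assemble_foundation_matrix,
    compute_traction,
    elasticity_matrix,
    solve_equilibrium,
)
from dewetsim.mesh import DiskMesh, build_disk_mesh, partition_subdomains
from dewetsim.oracle import axisym_oracle

#: foundation density for order-verification runs (kPa/μm): the displacement
#: varies over a length comparable to the disk radius, smooth on a 25-element
#: diameter.
VERIFICATION_K_EFF = 1e-4


def solve_uniform_contraction(
    n_diameter: int,
    radius: float = 200.0,
    material: ElasticMaterial | None = None,
    k_eff: float = VERIFICATION_K_EFF,
    gamma: float = 0.05,
) -> tuple[DiskMesh, DisplacementField, TractionFieldFE]:
    """Solve the uniformly contracting disk (the axisymmetric benchmark)."""
    if material is None:
        material = ElasticMaterial()
    mesh = build_disk_mesh(n_diameter, radius)
    D = elasticity_matrix(material)
    state = ContractileState(gamma, 0.0, partition_subdomains(mesh, radius))
    foundation = FoundationModel(k=k_eff, alpha=1.0)
    u = solve_equilibrium(
        LinearSystem(
            assemble_elastic_stiffness(mesh, D),
            assemble_foundation_matrix(mesh, foundation),
            assemble_contractile_load(mesh, D, state),
            mesh,
        )
    )
    return mesh, u, compute_traction(u, foundation)


def oracle_displacement_at(
    radii: np.ndarray,
    material: ElasticMaterial,
    k_eff: float,
    gamma: float,
    R: float,
    n_r: int = 2000,
) -> np.ndarray:
    """Evaluate the finite-difference oracle at arbitrary radii.

    Nodes of the staircase mesh may lie slightly beyond R; there the oracle
    profile is continued linearly with its end slope.
    """
    r_o, u_o = axisym_oracle(material.E, material.nu, k_eff, gamma, R, n_r=n_r)
    u = np.interp(radii, r_o, u_o)
    slope = (u_o[-1] - u_o[-2]) / (r_o[-1] - r_o[-2])
    beyond = radii > r_o[-1]
    u[beyond] = u_o[-1] + (radii[beyond] - r_o[-1]) * slope
    return u


def fem_oracle_error(
    n_diameter: int,
    radius: float = 200.0,
    material: ElasticMaterial | None = None,
    k_eff: float = VERIFICATION_K_EFF,
    gamma: float = 0.05,
    n_r: int = 2000,
) -> float:
    """Relative L2 difference between the 2D FEM and the 1D oracle displacement."""
    if material is None:
        material = ElasticMaterial()
    mesh, u, _ = solve_uniform_contraction(n_diameter, radius, material, k_eff, gamma)
    rr = np.hypot(mesh.node_coords[:, 0], mesh.node_coords[:, 1])
    u_r = oracle_displacement_at(rr, material, k_eff, gamma, radius, n_r)
    direction = np.where(
        rr[:, None] > 0, mesh.node_coords / np.maximum(rr, 1e-300)[:, None], 0.0
    )
    u_hat = u_r[:, None] * direction
    return float(np.linalg.norm(u.values - u_hat) / np.linalg.norm(u_hat))


def convergence_study(
    n_diameters=(25, 50, 100),
    radius: float = 200.0,
    k_eff: float = VERIFICATION_K_EFF,
    gamma: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Observed convergence order of the FEM-vs-oracle displacement error.

    Returns (slope of log error vs log h, per-mesh errors).
    """
    errors = np.array(
        [fem_oracle_error(n, radius, k_eff=k_eff, gamma=gamma) for n in n_diameters]
    )
    hs = np.array([2.0 * radius / n for n in n_diameters])
    slope = float(np.polyfit(np.log(hs), np.log(errors), 1)[0])
    return slope, errors


def angular_asymmetry(mesh: DiskMesh, nodal_values: np.ndarray) -> float:
    """Relative angular fluctuation of a nodal magnitude field.

    Nodes are grouped by exact radius (the structured grid yields discrete
    radii); the pooled L2 norm of the deviation from each group's mean,
    relative to the L2 norm of the field, is zero for a perfectly
    axisymmetric solution.
    """
    mag = np.asarray(nodal_values, dtype=float)
    rr2 = np.round(
        (mesh.node_coords[:, 0] ** 2 + mesh.node_coords[:, 1] ** 2)
        / mesh.element_size**2
        * 4.0
    ).astype(np.int64)
    order = np.argsort(rr2, kind="stable")
    keys = rr2[order]
    vals = mag[order]
    boundaries = np.concatenate([[0], np.nonzero(np.diff(keys))[0] + 1, [len(keys)]])
    fluct = np.empty_like(vals)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        fluct[a:b] = vals[a:b] - vals[a:b].mean()
    denom = np.linalg.norm(mag)
    return float(np.linalg.norm(fluct) / denom) if denom > 0 else 0.0


def rim_band_width(mesh: DiskMesh, traction: TractionFieldFE, frac: float = 0.5) -> float:
    """Width of the outer radial band holding ``frac`` of the traction magnitude.

    Sorted from the rim inward, returns R − r at which the cumulative
    area-weighted |T| first reaches the requested fraction — a measure of how
    localized the traction boundary layer is.
    """
    w = mesh.nodal_area_weights()
    m = traction.magnitude * w
    rr = np.hypot(mesh.node_coords[:, 0], mesh.node_coords[:, 1])
    order = np.argsort(rr)[::-1]
    cum = np.cumsum(m[order]) / m.sum()
    r_cut = rr[order][np.searchsorted(cum, frac)]
    return float(mesh.radius - r_cut)
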