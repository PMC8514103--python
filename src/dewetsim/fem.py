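"""Plane elasticity with contractile eigenstrain on a Winkler foundation.

The tissue is a linear elastic sheet (Young modulus E, Poisson ratio ν)
carrying a prescribed isotropic contraction: a constant baseline prestrain
ε0c everywhere and an additional active strain εc in the peripheral subdomain
Ω2. The substrate acts as a bed of springs of stiffness density α·k (the
adhesion constant k weakened by a factor α ∈ [0, 1]), optionally augmented by
a Kelvin–Voigt viscous coefficient c. Quasi-static equilibrium reads

    (K + Ks) u = f,

with K the elastic stiffness assembled from bilinear square elements (2×2
Gauss quadrature), Ks the consistent foundation matrix α·k·∫NᵀN dΩ, and f the
eigenstrain load. Contraction magnitudes are stored as non-negative numbers
and enter with the tension-generating sign: a fully clamped tissue is under
isotropic tension, a free tissue shrinks stress-free, and the resulting
substrate tractions T = α·k·u point centripetally.

Stress follows σ = D(ε + ε_contract·I) with ε the linearized strain of the
solved displacement. Two constitutive modes are provided: ``printed_lame``
(3D Lamé constants λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν)) used directly in 2D)
and the standard ``plane_stress`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from dewetsim.mesh import OMEGA2, DiskMesh, SubdomainPartition

VOIGT_IOTA = np.array([1.0, 1.0, 0.0])  # isotropic unit eigenstrain, Voigt

# local corner coordinates of the reference square [-1,1]^2, CCW
_XI = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0])
_GAUSS = 1.0 / np.sqrt(3.0)


class SolverError(RuntimeError):
    """Raised when the assembled system cannot be solved reliably."""


def lame_constants(E: float, nu: float) -> tuple[float, float]:
    """Lamé constants λ = Eν/((1+ν)(1−2ν)) and μ = E/(2(1+ν)).

    ν is restricted to (−1, 0.5); λ diverges at the incompressible limit.
    """
    if E <= 0:
        raise ValueError(f"Young modulus must be positive, got {E!r}")
    if not -1.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (-1, 0.5), got {nu!r}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@dataclass(frozen=True)
class ElasticMaterial:
    """Linear elastic sheet material.

    ``constitutive_mode`` selects how the 3×3 Voigt matrix D is built:
    ``printed_lame`` uses the 3D Lamé constants directly in the 2D stress
    formula σ = λ tr(ε)I + 2μ ε; ``plane_stress`` uses the standard
    plane-stress matrix E/(1−ν²)·[[1, ν, 0], [ν, 1, 0], [0, 0, (1−ν)/2]].
    """

    E: float = 1.0  # kPa
    nu: float = 0.46
    constitutive_mode: str = "printed_lame"

    def __post_init__(self):
        lame_constants(self.E, self.nu)  # validate
        if self.constitutive_mode not in ("printed_lame", "plane_stress"):
            raise ValueError(f"unknown constitutive_mode {self.constitutive_mode!r}")

    @property
    def lam(self) -> float:
        return lame_constants(self.E, self.nu)[0]

    @property
    def mu(self) -> float:
        return lame_constants(self.E, self.nu)[1]


def elasticity_matrix(material: ElasticMaterial) -> np.ndarray:
    """Constitutive matrix D (Voigt order σxx, σyy, σxy; engineering shear γxy)."""
    if material.constitutive_mode == "printed_lame":
        lam, mu = lame_constants(material.E, material.nu)
        return np.array(
            [
                [lam + 2.0 * mu, lam, 0.0],
                [lam, lam + 2.0 * mu, 0.0],
                [0.0, 0.0, mu],
            ]
        )
    E, nu = material.E, material.nu
    return (E / (1.0 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )


@dataclass(frozen=True)
class FoundationModel:
    """Winkler foundation: spring density k (kPa/μm) weakened by α ∈ [0, 1].

    ``c`` is an optional Kelvin–Voigt viscous coefficient per unit area
    (kPa·h/μm); the quasi-static default is c = 0.
    """

    k: float = 5e-3
    alpha: float = 1.0
    c: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha!r}")
        if self.c < 0:
            raise ValueError(f"c must be non-negative, got {self.c!r}")


@dataclass(frozen=True)
class ContractileState:
    """Contraction magnitudes (≥ 0): baseline eps0 everywhere, eps_active in Ω2."""

    eps0: float
    eps_active: float
    partition: SubdomainPartition

    def __post_init__(self):
        if self.eps0 < 0 or self.eps_active < 0:
            raise ValueError("contraction magnitudes must be non-negative")

    def element_contraction(self) -> np.ndarray:
        """Total contraction per element: eps0, plus eps_active in Ω2."""
        extra = np.where(self.partition.element_labels == OMEGA2, self.eps_active, 0.0)
        return self.eps0 + extra


@dataclass(frozen=True)
class DisplacementField:
    values: np.ndarray  # (n_nodes, 2), μm


@dataclass(frozen=True)
class TractionFieldFE:
    """Nodal substrate traction T = α·k·u (+ c·du/dt if viscous), kPa."""

    values: np.ndarray  # (n_nodes, 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.values[:, 0], self.values[:, 1])


@dataclass(frozen=True)
class StressFieldFE:
    """Per-element stress tensor components at element centers, kPa."""

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray

    @property
    def mean_normal(self) -> np.ndarray:
        """Mean normal stress (σxx + σyy)/2, the 2D \"tension\" map."""
        return 0.5 * (self.sxx + self.syy)

    @property
    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        c = 0.5 * (self.sxx + self.syy)
        r = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.sxy**2)
        return c + r, c - r


@dataclass
class LinearSystem:
    K: sp.csr_matrix
    Ks: sp.csr_matrix
    f: np.ndarray
    mesh: DiskMesh = field(repr=False, default=None)


def _b_matrix(xi: float, eta: float, h: float) -> np.ndarray:
    """Strain-displacement matrix (3×8) of the bilinear square at (ξ, η)."""
    dN_dxi = 0.25 * _XI * (1.0 + _ETA * eta)
    dN_deta = 0.25 * _ETA * (1.0 + _XI * xi)
    dN_dx = dN_dxi * (2.0 / h)
    dN_dy = dN_deta * (2.0 / h)
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def element_stiffness(D: np.ndarray, h: float) -> np.ndarray:
    """8×8 stiffness of one square element, 2×2 Gauss quadrature."""
    Ke = np.zeros((8, 8))
    detJ = (h / 2.0) ** 2
    for xi in (-_GAUSS, _GAUSS):
        for eta in (-_GAUSS, _GAUSS):
            B = _b_matrix(xi, eta, h)
            Ke += B.T @ D @ B * detJ
    return Ke


def element_eigenstrain_load(D: np.ndarray, h: float) -> np.ndarray:
    """∫ Bᵀ D {1,1,0}ᵀ dΩ over one square element (length 8)."""
    g = np.zeros(8)
    detJ = (h / 2.0) ** 2
    s = D @ VOIGT_IOTA
    for xi in (-_GAUSS, _GAUSS):
        for eta in (-_GAUSS, _GAUSS):
            g += _b_matrix(xi, eta, h).T @ s * detJ
    return g


# consistent mass matrix of the bilinear square (per unit density), scalar dofs
_MASS_SCALAR = np.array(
    [[4.0, 2.0, 1.0, 2.0], [2.0, 4.0, 2.0, 1.0], [1.0, 2.0, 4.0, 2.0], [2.0, 1.0, 2.0, 4.0]]
) / 36.0


def element_foundation(h: float) -> np.ndarray:
    """8×8 consistent foundation matrix per unit spring density (∫NᵀN dΩ)."""
    return np.kron(_MASS_SCALAR * h**2, np.eye(2))


def _element_dofs(mesh: DiskMesh) -> np.ndarray:
    """(n_el, 8) dof indices, node-interleaved (ux0, uy0, ux1, ...)."""
    e = mesh.elements
    dofs = np.empty((mesh.n_elements, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * e
    dofs[:, 1::2] = 2 * e + 1
    return dofs


def _assemble(mesh: DiskMesh, element_matrix: np.ndarray) -> sp.csr_matrix:
    """Assemble one identical 8×8 element matrix over every element."""
    dofs = _element_dofs(mesh)
    n_el = mesh.n_elements
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    vals = np.tile(element_matrix.ravel(), n_el)
    n_dof = 2 * mesh.n_nodes
    return sp.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof)).tocsr()


def assemble_elastic_stiffness(mesh: DiskMesh, D: np.ndarray) -> sp.csr_matrix:
    """Global elastic stiffness K (symmetric, rigid modes in the nullspace)."""
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError(f"D must be 3×3, got shape {D.shape}")
    return _assemble(mesh, element_stiffness(D, mesh.element_size))


def assemble_foundation_matrix(mesh: DiskMesh, foundation: FoundationModel) -> sp.csr_matrix:
    """Global foundation matrix Ks = α·k·∫NᵀN dΩ (consistent assembly)."""
    density = foundation.alpha * foundation.k
    return _assemble(mesh, density * element_foundation(mesh.element_size))


def assemble_contractile_load(
    mesh: DiskMesh, D: np.ndarray, state: ContractileState
) -> np.ndarray:
    """Eigenstrain load f = f1 + f2 from the subdomain contraction magnitudes.

    f1 integrates Bᵀ D {1,1,0}ᵀ over Ω1 scaled by ε0c; f2 over Ω2 scaled by
    ε0c + εc. The overall sign makes positive magnitudes contractile (the
    solved displacement points inward).
    """
    if state.partition.element_labels.shape[0] != mesh.n_elements:
        raise ValueError("partition does not match mesh element count")
    g = element_eigenstrain_load(np.asarray(D, dtype=float), mesh.element_size)
    eps = state.element_contraction()
    dofs = _element_dofs(mesh)
    f = np.zeros(2 * mesh.n_nodes)
    np.add.at(f, dofs.ravel(), (-eps[:, None] * g[None, :]).ravel())
    return f


def solve_equilibrium(system: LinearSystem) -> DisplacementField:
    """Solve (K + Ks) u = f by sparse direct factorization.

    Raises ``SolverError`` if the operator is singular (no foundation anywhere
    leaves the rigid modes unconstrained) or the relative residual exceeds
    1e-10.
    """
    A = (system.K + system.Ks).tocsc()
    if system.Ks.nnz == 0 or abs(system.Ks).sum() == 0.0:
        raise SolverError(
            "foundation stiffness is zero everywhere: rigid modes are "
            "unconstrained and the system is singular"
        )
    try:
        lu = spla.splu(A)
        u = lu.solve(system.f)
    except RuntimeError as err:  # pragma: no cover - factorization failure
        raise SolverError(f"sparse factorization failed: {err}") from err
    fnorm = np.linalg.norm(system.f)
    if fnorm > 0:
        residual = np.linalg.norm(A @ u - system.f) / fnorm
        if not np.isfinite(residual) or residual > 1e-10:
            raise SolverError(f"relative residual {residual:.3e} exceeds 1e-10")
    return DisplacementField(values=u.reshape(-1, 2))


def compute_traction(
    u: DisplacementField,
    foundation: FoundationModel,
    u_prev: DisplacementField | None = None,
    dt: float | None = None,
) -> TractionFieldFE:
    """Nodal substrate traction T = α·k·u, plus c·(u−u_prev)/dt when viscous."""
    vals = foundation.alpha * foundation.k * u.values
    if foundation.c > 0.0:
        if u_prev is None or dt is None:
            raise ValueError("viscous traction requires u_prev and dt")
        vals = vals + foundation.c * (u.values - u_prev.values) / dt
    return TractionFieldFE(values=vals)


def traction_balance(traction: TractionFieldFE, mesh: DiskMesh) -> float:
    """Relative imbalance: |area-weighted vector sum| / (area-weighted Σ|T|)."""
    w = mesh.nodal_area_weights()
    net = w @ traction.values
    total = w @ traction.magnitude
    if total == 0.0:
        return 0.0
    return float(np.linalg.norm(net) / total)


def mean_traction_magnitude(traction: TractionFieldFE, mesh: DiskMesh) -> float:
    """Area-weighted mean of |T| over the undeformed domain, kPa."""
    w = mesh.nodal_area_weights()
    return float((w @ traction.magnitude) / w.sum())


def compute_stress(
    u: DisplacementField, D: np.ndarray, state: ContractileState, mesh: DiskMesh
) -> StressFieldFE:
    """Per-element stress at element centers: σ = D(B u + ε_contract·{1,1,0}ᵀ)."""
    D = np.asarray(D, dtype=float)
    B0 = _b_matrix(0.0, 0.0, mesh.element_size)
    dofs = _element_dofs(mesh)
    ue = u.values.reshape(-1)[dofs]  # (n_el, 8)
    strain = ue @ B0.T  # (n_el, 3), Voigt with engineering shear
    eps = state.element_contraction()
    total = strain + eps[:, None] * VOIGT_IOTA[None, :]
    sigma = total @ D.T
    return StressFieldFE(sxx=sigma[:, 0], syy=sigma[:, 1], sxy=sigma[:, 2])
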