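"""Monolayer stress recovery from a balanced traction field.

The forces the substrate exerts back on the tissue (the reaction −T to the
measured traction field) are equilibrated by the internal stress state of the
monolayer. Given a traction field on a pixel grid and the tissue footprint,
this module meshes the footprint with one square element per pixel, applies
−T as a body load with a traction-free boundary, solves the plane elastic
problem for a compatible displacement, and reports the element stress field.
The recovered stress is a property of force balance, not of the assumed
material: scaling the nominal modulus rescales the auxiliary displacement but
leaves the stress unchanged (asserted by test). Rigid modes of the Neumann
problem are removed by pinning three displacement components; because the
load is balanced, the pin reactions vanish and the stress does not depend on
the choice of pinned nodes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from dataclasses import dataclass

from dewetsim.fem import (
    ElasticMaterial,
    SolverError,
    _b_matrix,
    _element_dofs,
    elasticity_matrix,
    element_stiffness,
    _assemble,
)
from dewetsim.mesh import DiskMesh
from dewetsim.traction import BinaryMask, VectorField2D


class BalanceError(ValueError):
    """Input traction field is too far from global force balance."""


@dataclass(frozen=True)
class MonolayerStressField:
    """Recovered per-element (per-pixel) stress, kPa per unit sheet thickness."""

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    mesh: DiskMesh
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    residual: float
    imbalance_in: float

    @property
    def mean_normal(self) -> np.ndarray:
        return 0.5 * (self.sxx + self.syy)

    @property
    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        c = 0.5 * (self.sxx + self.syy)
        r = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.sxy**2)
        return c + r, c - r

    def to_grid(self, component: str = "mean_normal") -> np.ndarray:
        """Scatter an element quantity back onto the pixel grid (NaN outside)."""
        vals = getattr(self, component)
        shape = (
            int(self.pixel_rows.max()) + 1,
            int(self.pixel_cols.max()) + 1,
        )
        grid = np.full(shape, np.nan)
        grid[self.pixel_rows, self.pixel_cols] = vals
        return grid


def mask_to_mesh(mask: BinaryMask) -> tuple[DiskMesh, np.ndarray, np.ndarray]:
    """Mesh the mask footprint with one square element per foreground pixel.

    Node coordinates are centered on the footprint centroid. Returns the mesh
    plus each element's (row, col) pixel index.
    """
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    h = mask.pixel_size
    rows, cols = np.nonzero(mask.data)
    n_cols = mask.data.shape[1]

    def node_id(ix, iy):
        return iy * (n_cols + 1) + ix

    elems_global = np.column_stack(
        [
            node_id(cols, rows),
            node_id(cols + 1, rows),
            node_id(cols + 1, rows + 1),
            node_id(cols, rows + 1),
        ]
    )
    used, inverse = np.unique(elems_global, return_inverse=True)
    elements = inverse.reshape(elems_global.shape).astype(np.int64)
    ux = (used % (n_cols + 1)).astype(float)
    uy = (used // (n_cols + 1)).astype(float)
    centers = np.column_stack([(cols + 0.5) * h, (rows + 0.5) * h])
    centroid = centers.mean(axis=0)
    node_coords = np.column_stack([ux * h, uy * h]) - centroid
    mesh = DiskMesh(
        node_coords=node_coords,
        elements=elements,
        element_centers=centers - centroid,
        element_size=h,
        radius=float(np.sqrt(mask.n_foreground * h**2 / np.pi)),
        n_diameter=max(mask.data.shape),
    )
    return mesh, rows, cols


def recover_monolayer_stress(
    traction: VectorField2D,
    mask: BinaryMask,
    material: ElasticMaterial | None = None,
    balance_tol: float = 0.01,
    pin_nodes: tuple[int, int] | None = None,
) -> MonolayerStressField:
    """Recover the monolayer stress tensor equilibrating a traction field.

    Parameters
    ----------
    traction : pixel-grid traction the tissue exerts on the substrate (kPa).
    mask : tissue footprint (single connected component).
    material : nominal elastic constants for the auxiliary problem (default
        E = 1 kPa, ν = 0.46); the recovered stress is invariant to E.
    balance_tol : maximum allowed net-force imbalance relative to the total
        traction magnitude. Within the tolerance, the residual mean vector is
        projected out before solving; beyond it, ``BalanceError`` is raised.
    pin_nodes : optional pair of node indices used to remove the rigid modes
        (both dofs of the first, the y-dof of the second). The recovered
        stress does not depend on the choice; the default pins node 0 and the
        node farthest from it in x.
    """
    if traction.tx.shape != mask.data.shape:
        raise ValueError("traction and mask shapes differ")
    if material is None:
        material = ElasticMaterial()
    mesh, rows, cols = mask_to_mesh(mask)
    fg = mask.data

    tx = traction.tx[fg].astype(float).copy()
    ty = traction.ty[fg].astype(float).copy()
    total = np.sum(np.hypot(tx, ty))
    if total == 0.0:
        zero = np.zeros(mesh.n_elements)
        return MonolayerStressField(
            sxx=zero, syy=zero.copy(), sxy=zero.copy(), mesh=mesh,
            pixel_rows=rows, pixel_cols=cols, residual=0.0, imbalance_in=0.0,
        )
    imbalance = float(np.hypot(tx.sum(), ty.sum()) / total)
    if imbalance > balance_tol:
        raise BalanceError(
            f"net traction imbalance {imbalance:.3%} exceeds tolerance "
            f"{balance_tol:.1%}; the field cannot be equilibrated by an "
            "internal stress state"
        )
    tx -= tx.mean()
    ty -= ty.mean()

    D = elasticity_matrix(material)
    h = mesh.element_size
    K = _assemble(mesh, element_stiffness(D, h))

    # consistent load for an element-wise constant body force −T: h²/4 per node
    dofs = _element_dofs(mesh)
    f = np.zeros(2 * mesh.n_nodes)
    fe = np.empty((mesh.n_elements, 8))
    fe[:, 0::2] = (-tx * h**2 / 4.0)[:, None]
    fe[:, 1::2] = (-ty * h**2 / 4.0)[:, None]
    np.add.at(f, dofs.ravel(), fe.ravel())

    # pin rigid modes: both dofs of one node, y-dof of the node farthest in x
    if pin_nodes is None:
        i0 = 0
        i1 = int(np.argmax(np.abs(mesh.node_coords[:, 0] - mesh.node_coords[i0, 0])))
    else:
        i0, i1 = pin_nodes
        if i0 == i1 or mesh.node_coords[i0, 0] == mesh.node_coords[i1, 0]:
            raise ValueError("pin nodes must differ in x to block rotation")
    fixed = np.array([2 * i0, 2 * i0 + 1, 2 * i1 + 1])
    free = np.setdiff1d(np.arange(2 * mesh.n_nodes), fixed)
    Kff = K[free][:, free].tocsc()
    try:
        u_free = spla.splu(Kff).solve(f[free])
    except RuntimeError as err:  # pragma: no cover
        raise SolverError(f"stress-recovery factorization failed: {err}") from err
    u = np.zeros(2 * mesh.n_nodes)
    u[free] = u_free
    residual = float(np.linalg.norm(Kff @ u_free - f[free]) / np.linalg.norm(f[free]))

    B0 = _b_matrix(0.0, 0.0, h)
    ue = u[dofs]
    sigma = (ue @ B0.T) @ D.T
    return MonolayerStressField(
        sxx=sigma[:, 0],
        syy=sigma[:, 1],
        sxy=sigma[:, 2],
        mesh=mesh,
        pixel_rows=rows,
        pixel_cols=cols,
        residual=residual,
        imbalance_in=imbalance,
    )
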