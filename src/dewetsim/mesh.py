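"""Structured square-element discretization of a circular tissue domain.

The tissue is a disk of radius ``R`` (μm) meshed with an axis-aligned grid of
square bilinear elements of side ``h = 2R / n_diameter``, centered on the disk
center. An element belongs to the mesh iff its center lies within the disk
(distance ≤ R). With this rule the canonical resolution of 100 elements along
the diameter yields 7860 elements.

The mesh is split into a central subdomain Ω1 (element centers within
``r_inner``) and a peripheral annulus Ω2; Ω2 is the region that develops extra
active contraction as the central radius shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OMEGA1 = 1
OMEGA2 = 2

DEFAULT_RADIUS_UM = 200.0  # 400 μm diameter micropatterns


@dataclass(frozen=True)
class DiskMesh:
    """Conforming structured mesh of squares covering a disk.

    Attributes
    ----------
    node_coords : (n_nodes, 2) float array, μm, origin at the disk center.
    elements : (n_elements, 4) int array, counter-clockwise node indices.
    element_centers : (n_elements, 2) float array, μm.
    element_size : side length h of every element, μm.
    radius : disk radius R, μm.
    n_diameter : number of elements spanning the diameter.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    element_centers: np.ndarray
    element_size: float
    radius: float
    n_diameter: int

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def area(self) -> float:
        """Total meshed area (n_elements · h²), μm²."""
        return self.n_elements * self.element_size**2

    def nodal_area_weights(self) -> np.ndarray:
        """Lumped area per node: h²/4 from each adjacent element."""
        w = np.zeros(self.n_nodes)
        np.add.at(w, self.elements.ravel(), self.element_size**2 / 4.0)
        return w


@dataclass(frozen=True)
class SubdomainPartition:
    """Per-element subdomain labels: 1 for central Ω1, 2 for peripheral Ω2."""

    element_labels: np.ndarray
    r_inner: float

    @property
    def n_omega1(self) -> int:
        return int(np.sum(self.element_labels == OMEGA1))

    @property
    def n_omega2(self) -> int:
        return int(np.sum(self.element_labels == OMEGA2))


def build_disk_mesh(n_diameter: int, radius: float = DEFAULT_RADIUS_UM) -> DiskMesh:
    """Build the structured square-element mesh of a disk.

    Parameters
    ----------
    n_diameter : number of elements spanning the diameter (≥ 1).
    radius : disk radius R in μm (> 0).

    Notes
    -----
    Candidate cells live on the n×n grid covering [−R, R]²; cell (i, j) is kept
    iff its center is within distance R of the origin (inclusive). Node indices
    are row-major over the (n+1)×(n+1) node grid, compressed to the nodes that
    kept elements actually use, preserving order.
    """
    if not isinstance(n_diameter, (int, np.integer)) or n_diameter < 1:
        raise ValueError(f"n_diameter must be a positive integer, got {n_diameter!r}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius!r}")

    n = int(n_diameter)
    h = 2.0 * radius / n
    idx = np.arange(n)
    centers_1d = (idx + 0.5) * h - radius
    cx, cy = np.meshgrid(centers_1d, centers_1d, indexing="xy")
    keep = np.hypot(cx, cy) <= radius
    jj, ii = np.nonzero(keep)  # jj: row (y index), ii: column (x index)

    # global ids on the full node grid, row-major (node (ix, iy) -> iy*(n+1)+ix)
    def node_id(ix, iy):
        return iy * (n + 1) + ix

    elems_global = np.column_stack(
        [
            node_id(ii, jj),
            node_id(ii + 1, jj),
            node_id(ii + 1, jj + 1),
            node_id(ii, jj + 1),
        ]
    )
    used, inverse = np.unique(elems_global, return_inverse=True)
    elements = inverse.reshape(elems_global.shape).astype(np.int64)

    ux = used % (n + 1)
    uy = used // (n + 1)
    node_coords = np.column_stack([ux * h - radius, uy * h - radius]).astype(float)
    element_centers = np.column_stack([cx[keep], cy[keep]])

    return DiskMesh(
        node_coords=node_coords,
        elements=elements,
        element_centers=element_centers,
        element_size=h,
        radius=float(radius),
        n_diameter=n,
    )


def partition_subdomains(mesh: DiskMesh, r_inner: float) -> SubdomainPartition:
    """Label each element Ω1 (center distance ≤ r_inner) or Ω2 (otherwise)."""
    if not 0.0 <= r_inner <= mesh.radius:
        raise ValueError(
            f"r_inner must lie in [0, R={mesh.radius}], got {r_inner!r}"
        )
    dist = np.hypot(mesh.element_centers[:, 0], mesh.element_centers[:, 1])
    labels = np.where(dist <= r_inner, OMEGA1, OMEGA2).astype(np.int8)
    return SubdomainPartition(element_labels=labels, r_inner=float(r_inner))


def write_mesh_csv(mesh: DiskMesh, nodes_path, elements_path) -> None:
    """Dump nodes (x,y) and element connectivity as CSV."""
    np.savetxt(nodes_path, mesh.node_coords, delimiter=",", header="x_um,y_um", comments="")
    np.savetxt(
        elements_path,
        mesh.elements,
        delimiter=",",
        fmt="%d",
        header="n0,n1,n2,n3",
        comments="",
    )


def write_mesh_vtk(mesh: DiskMesh, path, point_data=None, cell_data=None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid of quads.

    ``point_data``/``cell_data`` are optional dicts of name -> array with one
    scalar or one 2-vector (padded to 3D) per node/element.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ndewetsim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.node_coords:
            fh.write(f"{x} {y} 0.0\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}\n")
        for quad in mesh.elements:
            fh.write("4 " + " ".join(str(i) for i in quad) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("9\n" * mesh.n_elements)  # VTK_QUAD
        for header, count, data in (
            ("POINT_DATA", mesh.n_nodes, point_data),
            ("CELL_DATA", mesh.n_elements, cell_data),
        ):
            if not data:
                continue
            fh.write(f"{header} {count}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        fh.write(f"{row[0]} {row[1]} 0.0\n")
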