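"""Axis-aligned structured hexahedral grid with cubic cells.

The chamber is a box [0, Lx] x [0, Ly] x [0, Lz] with z = 0 at the bottom
wall and x along the flow direction.  Nodes are stored in Fortran-like
ordering with x fastest: node index = i + (nx+1)*(j + (ny+1)*k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StructuredGrid"]


@dataclass(frozen=True)
class StructuredGrid:
    """Uniform grid of perfect-cube cells over a box.

    Parameters
    ----------
    extents : tuple of 3 floats
        Box side lengths (Lx, Ly, Lz) [m].
    spacing : float
        Cell edge length h [m]; must divide every extent.
    """

    extents: tuple
    spacing: float

    def __post_init__(self):
        ext = tuple(float(e) for e in self.extents)
        object.__setattr__(self, "extents", ext)
        h = float(self.spacing)
        ncells = []
        for L in ext:
            n = L / h
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(f"spacing {h} does not divide extent {L}")
            ncells.append(int(round(n)))
        object.__setattr__(self, "_ncells", tuple(ncells))

    # --- sizes ------------------------------------------------------------
    @property
    def n_cells_axis(self) -> tuple:
        """(nx, ny, nz) cell counts."""
        return self._ncells

    @property
    def n_nodes_axis(self) -> tuple:
        return tuple(n + 1 for n in self._ncells)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self._ncells
        return nx * ny * nz

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.n_nodes_axis
        return nx * ny * nz

    # --- coordinates ------------------------------------------------------
    @property
    def axes(self) -> tuple:
        """1-D node coordinate arrays (x, y, z)."""
        return tuple(
            np.linspace(0.0, L, n + 1) for L, n in zip(self.extents, self._ncells)
        )

    @property
    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (n_nodes, 3), x-fastest ordering."""
        x, y, z = self.axes
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.column_stack(
            [X.ravel(order="F"), Y.ravel(order="F"), Z.ravel(order="F")]
        )

    def node_index(self, i, j, k):
        nx, ny, _ = self.n_nodes_axis
        return np.asarray(i) + nx * (np.asarray(j) + ny * np.asarray(k))

    def reshape_nodal(self, field: np.ndarray) -> np.ndarray:
        """View a flat nodal field as (nx+1, ny+1, nz+1)."""
        return np.asarray(field).reshape(self.n_nodes_axis, order="F")

    def flatten_nodal(self, field3d: np.ndarray) -> np.ndarray:
        return np.asarray(field3d).ravel(order="F")

    # --- connectivity -----------------------------------------------------
    @property
    def cell_nodes(self) -> np.ndarray:
        """Node indices of each hexahedral cell, shape (n_cells, 8).

        Local node order: (0,0,0), (1,0,0), (0,1,0), (1,1,0) then the same
        square shifted by one layer in z.
        """
        nx, ny, nz = self._ncells
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        i = i.ravel(order="F")
        j = j.ravel(order="F")
        k = k.ravel(order="F")
        base = self.node_index(i, j, k)
        nxn, nyn, _ = self.n_nodes_axis
        dx, dy, dz = 1, nxn, nxn * nyn
        offsets = np.array(
            [0, dx, dy, dx + dy, dz, dx + dz, dy + dz, dx + dy + dz]
        )
        return base[:, None] + offsets[None, :]

    def cell_mean(self, nodal: np.ndarray) -> np.ndarray:
        """Average a nodal field over each cell's 8 corners."""
        return np.asarray(nodal)[self.cell_nodes].mean(axis=1)

    # --- boundary sets ----------------------------------------------------
    def boundary_nodes(self, face: str) -> np.ndarray:
        """Flat node indices of one boundary face.

        ``face`` is one of x-, x+, y-, y+, z-, z+ (z- is the bottom wall,
        x- the inlet, x+ the outlet).
        """
        nx, ny, nz = self.n_nodes_axis
        I, J, K = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        sel = {
            "x-": I == 0,
            "x+": I == nx - 1,
            "y-": J == 0,
            "y+": J == ny - 1,
            "z-": K == 0,
            "z+": K == nz - 1,
        }[face]
        return self.node_index(I[sel], J[sel], K[sel])

    def nodal_gradient(self, field: np.ndarray) -> np.ndarray:
        """Second-order nodal gradient of a scalar field, shape (n_nodes, 3)."""
        f = self.reshape_nodal(field)
        g = np.gradient(f, self.spacing, edge_order=2)
        return np.column_stack([self.flatten_nodal(gi) for gi in g])
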