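"""Trilinear hexahedral finite-element assembly on uniform cube grids.

All cells are identical cubes, so shape-function values and physical
gradients at the 2x2x2 Gauss points are shared by every element; elemental
matrices reduce to per-element scalar/vector coefficients contracted against
precomputed reference blocks.  Matrices are returned in CSR format.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

_GPTS = np.array([-1.0, 1.0]) / np.sqrt(3.0)


@lru_cache(maxsize=8)
def _reference(h: float):
    """Shape values N (G,8), physical gradients dN (G,8,3) and weight*detJ."""
    g = []
    for c in _GPTS:
        for b in _GPTS:
            for a in _GPTS:
                g.append((a, b, c))
    g = np.array(g)  # (8, 3) in (xi, eta, zeta)
    signs = []
    # local node order must match StructuredGrid.cell_nodes: x fastest, then y, z
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                signs.append((2 * dx - 1, 2 * dy - 1, 2 * dz - 1))
    signs = np.array(signs, dtype=float)  # (8, 3)
    G, n = len(g), len(signs)
    N = np.empty((G, n))
    dN = np.empty((G, n, 3))
    for q in range(G):
        xi = g[q]
        for i in range(n):
            s = signs[i]
            terms = (1 + s * xi) / 2.0
            N[q, i] = terms.prod()
            for d in range(3):
                grad = s[d] / 2.0
                for e in range(3):
                    if e != d:
                        grad *= terms[e]
                dN[q, i, d] = grad * (2.0 / h)  # map ref -> physical
    wdet = (h / 2.0) ** 3  # unit Gauss weights
    return N, dN, wdet


def element_blocks(h: float):
    """Precontracted reference integrals over one cube cell.

    Returns dict with
      NN    : (8,8)      int N_i N_j dV
      GG    : (8,8)      int grad N_i . grad N_j dV
      NG    : (3,8,8)    int N_i dN_j/dx_d dV        (advection, a.grad w vs v)
      GN    : (3,8,8)    int dN_i/dx_d N_j dV        (SUPG test vs w)
      GdG   : (3,3,8,8)  int dN_i/dx_d dN_j/dx_e dV  (SUPG adv-adv)
      N1    : (8,)       int N_i dV
      G1    : (3,8)      int dN_i/dx_d dV
    """
    N, dN, wdet = _reference(h)
    NN = wdet * np.einsum("gi,gj->ij", N, N)
    GG = wdet * np.einsum("gid,gjd->ij", dN, dN)
    NG = wdet * np.einsum("gi,gjd->dij", N, dN)
    GN = wdet * np.einsum("gid,gj->dij", dN, N)
    GdG = wdet * np.einsum("gid,gje->deij", dN, dN)
    N1 = wdet * N.sum(axis=0)
    G1 = wdet * dN.sum(axis=0).T
    return {"NN": NN, "GG": GG, "NG": NG, "GN": GN, "GdG": GdG, "N1": N1, "G1": G1}


def assemble_csr(grid, elem_mats: np.ndarray) -> sp.csr_matrix:
    """Scatter per-element 8x8 matrices (E,8,8) into a global CSR matrix."""
    conn = grid.cell_nodes.astype(np.int32)
    rows = np.repeat(conn, 8, axis=1).ravel()
    cols = np.tile(conn, (1, 8)).ravel()
    A = sp.coo_matrix(
        (elem_mats.ravel(), (rows, cols)), shape=(grid.n_nodes, grid.n_nodes)
    )
    return A.tocsr()


def scatter_vector(grid, elem_vecs: np.ndarray) -> np.ndarray:
    """Scatter per-element load vectors (E,8) into a global nodal vector."""
    out = np.zeros(grid.n_nodes)
    np.add.at(out, grid.cell_nodes.ravel(), elem_vecs.ravel())
    return out


def stiffness(grid, k_elem: np.ndarray) -> sp.csr_matrix:
    """Global stiffness for  -div(k grad p)  with elementwise-constant k."""
    B = element_blocks(grid.spacing)
    return assemble_csr(grid, k_elem[:, None, None] * B["GG"][None, :, :])


def mass(grid, c_elem: np.ndarray) -> sp.csr_matrix:
    B = element_blocks(grid.spacing)
    return assemble_csr(grid, c_elem[:, None, None] * B["NN"][None, :, :])


def element_gradient(grid, nodal: np.ndarray) -> np.ndarray:
    """Cell-centred gradient of a nodal field from shape-function derivatives."""
    N, dN, _ = _reference(grid.spacing)
    # gradient at the cell centre equals the mean over the symmetric Gauss set
    dNc = dN.mean(axis=0)  # (8, 3)
    vals = nodal[grid.cell_nodes]  # (E, 8)
    return vals @ dNc  # (E, 3)


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray, values):
    """Return (A', b') with Dirichlet rows eliminated symmetrically.

    Column contributions of constrained nodes are moved to the RHS, then the
    rows/columns are replaced by the identity.  Keeps SPD systems SPD.
    """
    b = b.copy()
    vals = np.broadcast_to(np.asarray(values, float), nodes.shape)
    x = np.zeros(A.shape[0])
    x[nodes] = vals
    b -= A @ x
    mask = np.zeros(A.shape[0], dtype=bool)
    mask[nodes] = True
    keep = sp.diags((~mask).astype(float))
    A = keep @ A @ keep + sp.diags(mask.astype(float))
    b[nodes] = vals
    return A.tocsr(), b
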