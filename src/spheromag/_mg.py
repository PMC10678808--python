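"""Geometric multigrid preconditioner for structured-grid FEM systems.

Trilinear prolongation operators are built as Kronecker products of 1-D
stencils (injection at coincident nodes, averaging at midpoints); coarse
operators are Galerkin products P^T A P, so a symmetric fine operator stays
symmetric on every level.  A V-cycle with damped-Jacobi smoothing and a
direct coarsest-level solve serves as the preconditioner for CG (SPD
systems) or BiCGSTAB/GMRES (advection-dominated transport systems).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_COARSE_MAX_NODES = 50_000
_JACOBI_OMEGA = 0.7
_SMOOTH_STEPS = 2


def _prolong_1d(n_coarse: int) -> sp.csr_matrix:
    n_fine = 2 * (n_coarse - 1) + 1
    rows, cols, vals = [], [], []
    for i in range(n_coarse):
        rows.append(2 * i)
        cols.append(i)
        vals.append(1.0)
        if i + 1 < n_coarse:
            rows += [2 * i + 1, 2 * i + 1]
            cols += [i, i + 1]
            vals += [0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))


def _prolongation(node_dims) -> sp.csr_matrix | None:
    """3-D trilinear prolongation, or None if the grid cannot be halved."""
    coarse = []
    for n in node_dims:
        cells = n - 1
        if cells % 2 != 0 or cells < 2:
            return None
        coarse.append(cells // 2 + 1)
    Px, Py, Pz = (_prolong_1d(c) for c in coarse)
    # node ordering is x-fastest: index = i + nx*(j + ny*k)
    return sp.kron(Pz, sp.kron(Py, Px)).tocsr()


class MGSolver:
    """V-cycle-preconditioned Krylov solver bound to one assembled matrix."""

    def __init__(self, A: sp.csr_matrix, node_dims, symmetric: bool = True):
        self.symmetric = symmetric
        self.levels = [A.tocsr()]
        self.prolong = []
        dims = tuple(node_dims)
        while self.levels[-1].shape[0] > _COARSE_MAX_NODES:
            P = _prolongation(dims)
            if P is None:
                break
            Ac = (P.T @ self.levels[-1] @ P).tocsr()
            self.prolong.append(P)
            self.levels.append(Ac)
            dims = tuple((n - 1) // 2 + 1 for n in dims)
        self.inv_diag = []
        for A_l in self.levels:
            d = A_l.diagonal()
            d = np.where(d != 0, d, 1.0)
            self.inv_diag.append(1.0 / d)
        self.coarse_lu = spla.splu(self.levels[-1].tocsc())

    def _vcycle(self, level: int, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if level == len(self.levels) - 1:
            return self.coarse_lu.solve(b)
        A = self.levels[level]
        dinv = self.inv_diag[level]
        x = np.zeros_like(b)
        for _ in range(_SMOOTH_STEPS):
            x += _JACOBI_OMEGA * dinv * (b - A @ x)
        r = b - A @ x
        P = self.prolong[level]
        x += P @ self._vcycle(level + 1, P.T @ r)
        for _ in range(_SMOOTH_STEPS):
            x += _JACOBI_OMEGA * dinv * (b - A @ x)
        return x

    def preconditioner(self) -> spla.LinearOperator:
        n = self.levels[0].shape[0]
        return spla.LinearOperator((n, n), matvec=lambda b: self._vcycle(0, b))

    def solve(self, b: np.ndarray, rtol: float = 1e-12, maxiter: int = 400) -> np.ndarray:
        A = self.levels[0]
        if len(self.levels) == 1 and A.shape[0] <= _COARSE_MAX_NODES:
            return self.coarse_lu.solve(b)
        M = self.preconditioner()
        if self.symmetric:
            x, info = spla.cg(A, b, rtol=rtol, maxiter=maxiter, M=M)
        else:
            x, info = spla.gmres(A, b, rtol=rtol, maxiter=maxiter, restart=50, M=M)
        if info != 0:
            res = np.linalg.norm(b - A @ x) / max(np.linalg.norm(b), 1e-300)
            raise RuntimeError(
                f"multigrid-preconditioned solve failed (info={info}, rel. residual {res:.2e})"
            )
        return x
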