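"""Linear (P1) triangular finite-element assembly.

Small vectorized assembly kernel used by the flow and transport solvers:
scalar stiffness/mass/advection matrices, boundary (facet) mass and load
vectors, Dirichlet elimination, and consistent boundary-flux recovery.
Coordinates are expected in metres here; callers convert from the mm mesh.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "tri_areas",
    "tri_gradients",
    "stiffness_matrix",
    "mass_matrix",
    "advection_matrix",
    "boundary_mass_matrix",
    "boundary_load",
    "apply_dirichlet",
    "element_gradient",
]


def tri_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])


def tri_gradients(nodes: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constant shape-function gradients per element.

    Returns ``(grads, areas)`` with ``grads[t, i]`` the 2-vector gradient of
    the hat function of local vertex i on triangle t.
    """
    p = nodes[tris]
    areas = tri_areas(nodes, tris)
    # edge opposite to vertex i, rotated by +90 deg, over 2A
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    rot = lambda e: np.stack([-e[:, 1], e[:, 0]], axis=1)  # noqa: E731
    grads = np.stack([rot(e0), rot(e1), rot(e2)], axis=1) / (2.0 * areas)[:, None, None]
    return grads, areas


def _assemble(rows, cols, vals, n):
    return sp.csr_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n))


def stiffness_matrix(
    nodes: np.ndarray, tris: np.ndarray, coeff: float | np.ndarray = 1.0
) -> sp.csr_matrix:
    """Assemble ``sum_T coeff_T int grad(u) . grad(v)``."""
    grads, areas = tri_gradients(nodes, tris)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), len(tris))
    local = np.einsum("tid,tjd->tij", grads, grads) * (areas * coeff)[:, None, None]
    rows = np.repeat(tris, 3, axis=1)
    cols = np.tile(tris, (1, 3))
    return _assemble(rows, cols, local.reshape(len(tris), 9), len(nodes))


def mass_matrix(
    nodes: np.ndarray,
    tris: np.ndarray,
    coeff: float | np.ndarray = 1.0,
    lumped: bool = False,
) -> sp.csr_matrix:
    areas = tri_areas(nodes, tris)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), len(tris))
    w = areas * coeff
    n = len(nodes)
    if lumped:
        diag = np.zeros(n)
        np.add.at(diag, tris, (w / 3.0)[:, None])
        return sp.diags(diag).tocsr()
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    local = base[None, :, :] * w[:, None, None]
    rows = np.repeat(tris, 3, axis=1)
    cols = np.tile(tris, (1, 3))
    return _assemble(rows, cols, local.reshape(len(tris), 9), n)


def advection_matrix(nodes: np.ndarray, tris: np.ndarray, vel: np.ndarray) -> sp.csr_matrix:
    """Assemble ``int (v . grad u) w`` with elementwise-constant velocity."""
    grads, areas = tri_gradients(nodes, tris)
    vdotg = np.einsum("td,tjd->tj", vel, grads)  # (ntri, 3)
    local = np.repeat((areas / 3.0)[:, None], 3, axis=1)[:, :, None] * vdotg[:, None, :]
    rows = np.repeat(tris, 3, axis=1)
    cols = np.tile(tris, (1, 3))
    return _assemble(rows, cols, local.reshape(len(tris), 9), len(nodes))


def edge_lengths(nodes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    d = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    return np.hypot(d[:, 0], d[:, 1])


def boundary_mass_matrix(
    nodes: np.ndarray, edges: np.ndarray, coeff: float | np.ndarray = 1.0
) -> sp.csr_matrix:
    """Facet mass matrix ``sum_e coeff_e int_e u v`` (Robin terms)."""
    if len(edges) == 0:
        return sp.csr_matrix((len(nodes), len(nodes)))
    L = edge_lengths(nodes, edges)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), len(edges))
    w = L * coeff
    base = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    local = base[None, :, :] * w[:, None, None]
    rows = np.repeat(edges, 2, axis=1)
    cols = np.tile(edges, (1, 2))
    return _assemble(rows, cols, local.reshape(len(edges), 4), len(nodes))


def boundary_load(
    nodes: np.ndarray, edges: np.ndarray, n_nodes: int, value: float | np.ndarray = 1.0
) -> np.ndarray:
    """Facet load vector ``sum_e value_e int_e v``."""
    b = np.zeros(n_nodes)
    if len(edges) == 0:
        return b
    L = edge_lengths(nodes, edges)
    value = np.broadcast_to(np.asarray(value, dtype=float), len(edges))
    np.add.at(b, edges, (0.5 * L * value)[:, None])
    return b


def apply_dirichlet(
    A: sp.csr_matrix, b: np.ndarray, idx: np.ndarray, values: np.ndarray | float
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Eliminate Dirichlet dofs symmetric-free style (row replacement)."""
    A = A.tolil(copy=True)
    b = b.copy()
    vals = np.broadcast_to(np.asarray(values, dtype=float), len(idx))
    b -= A[:, idx].tocsr() @ vals
    A[idx, :] = 0.0
    A[:, idx] = 0.0
    A[idx, idx] = 1.0
    b[idx] = vals
    return A.tocsr(), b


def element_gradient(nodes: np.ndarray, tris: np.ndarray, u: np.ndarray) -> np.ndarray:
    grads, _ = tri_gradients(nodes, tris)
    return np.einsum("tjd,tj->td", grads, u[tris])
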