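"""Steady fluid flow: intravascular Stokes and interstitial Darcy/Starling.

The tumor interstitium is a porous medium: Darcy's law v_i = -K grad(P_i)
with the steady continuity equation div(v_i) = phi_B - phi_L, where phi_B
is the Starling transmural fluid exchange

    phi_B = L_p (S/V) (P_B - P_i - sigma_s (pi_B - pi_i))

and lymphatic drainage phi_L = 0 in tumor tissue. Two coupling modes are
supported:

``distributed``
    phi_B acts as a volumetric source with the constant tabulated vascular
    pressure P_B everywhere; no explicit lumens needed. On a disc this has
    the modified-Bessel closed form used as the verification oracle.

``wall_coupled``
    Lumens are resolved: a stabilized P1-P1 Stokes solve gives the
    intravascular pressure (IBP) and velocity (IBV); the transmural flux
    L_p (IBP - P_i - sigma_s (pi_B - pi_i)) is applied on the vessel-wall
    facets as a Robin condition (per wall area, so S/V does not enter).

Pressures are Pa, velocities m/s; the mm mesh is converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from . import fem
from .errors import IsolatedLumenError, NotSolvedError, SolverDivergedError
from .meshing import LUMEN, TISSUE, SimMesh
from .units import MM_TO_M, mmhg_to_pa

__all__ = [
    "TissueParams",
    "FlowBCs",
    "FlowSolution",
    "starling_phi_B",
    "solve_intravascular",
    "solve_interstitial",
    "solve_flow",
    "flow_summary",
]


@dataclass
class TissueParams:
    """Tumor tissue / vessel-wall fluid-exchange constants (SI).

    Defaults are the tabulated tumor values: interstitial hydraulic
    conductivity K, vessel-wall hydraulic conductivity L_p, vessel surface
    density S/V, reference vascular pressure P_B, plasma/interstitial
    osmotic pressures pi_B/pi_i, osmotic reflection coefficient sigma_s.
    Blood viscosity mu only enters the lumen (Stokes) solve.
    """

    K: float = 3e-14            # m^2 Pa^-1 s^-1
    L_p: float = 2.1e-11        # m Pa^-1 s^-1
    S_over_V: float = 2e4       # m^-1
    P_B: float = 2.1e3          # Pa
    pi_B: float = 2.7e3         # Pa
    pi_i: float = 2e3           # Pa
    sigma_s: float = 0.9
    phi_L: float = 0.0          # s^-1, no functional lymphatics in tumor
    mu: float = 3e-3            # Pa s

    def __post_init__(self):
        if not (self.K > 0 and self.S_over_V > 0):
            raise ValueError("K and S/V must be positive")
        if self.L_p < 0:
            # L_p = 0 (sealed walls) is a legitimate degenerate limit
            raise ValueError("L_p must be nonnegative")
        if not 0.0 <= self.sigma_s <= 1.0:
            raise ValueError("sigma_s must lie in [0, 1]")

    @property
    def effective_pressure(self) -> float:
        """Starling equilibrium pressure P_e = P_B - sigma_s (pi_B - pi_i)."""
        return self.P_B - self.sigma_s * (self.pi_B - self.pi_i)

    @property
    def alpha(self) -> float:
        """Distributed-source decay rate sqrt(L_p (S/V) / K), 1/m."""
        return float(np.sqrt(self.L_p * self.S_over_V / self.K))


@dataclass
class FlowBCs:
    """Terminal and surface pressure boundary conditions (Pa)."""

    inlet_pressure: float = mmhg_to_pa(25.0)
    outlet_pressure: float = mmhg_to_pa(10.0)
    surface_pressure: float = 0.0

    def __post_init__(self):
        if not self.inlet_pressure > self.outlet_pressure >= 0.0:
            raise ValueError("need inlet_pressure > outlet_pressure >= 0")

    def terminal_pressure(self, role: str) -> float:
        return self.inlet_pressure if role == "inlet" else self.outlet_pressure


def starling_phi_B(
    P_i: float | np.ndarray, params: TissueParams, P_B_local: float | np.ndarray | None = None
) -> float | np.ndarray:
    """Starling transmural volumetric exchange rate (1/s); may be negative."""
    P_B = params.P_B if P_B_local is None else P_B_local
    return params.L_p * params.S_over_V * (
        P_B - P_i - params.sigma_s * (params.pi_B - params.pi_i)
    )


@dataclass
class FlowSolution:
    """Steady flow fields on a :class:`SimMesh`.

    Nodal pressures are NaN outside their subdomain. Velocities are
    elementwise-constant (P1 gradients); ``wall_flux`` is the transmural
    volumetric flux per wall area (m/s, positive into the tissue) per
    vessel-wall facet.
    """

    mesh: SimMesh
    params: TissueParams
    bcs: FlowBCs
    coupling_mode: str
    IFP: np.ndarray | None = None          # (n_nodes,) Pa
    IFV: np.ndarray | None = None          # (n_tri, 2) m/s, zero on lumen elems
    IBP: np.ndarray | None = None          # (n_nodes,) Pa
    IBV: np.ndarray | None = None          # (n_tri, 2) m/s, zero on tissue elems
    wall_flux: np.ndarray | None = None    # per vessel_wall facet, m/s
    phi_B_nodal: np.ndarray | None = None  # distributed mode source field, 1/s
    surface_outflow: float | None = field(default=None, repr=False)  # m^3/s per unit depth
    wall_inflow: float | None = field(default=None, repr=False)


def _lumen_components_with_terminals(mesh: SimMesh, lumen_nodes: np.ndarray) -> None:
    tris = mesh.triangles[mesh.region == LUMEN]
    n = mesh.n_nodes
    rows = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2]])
    cols = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
    g = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(g[lumen_nodes][:, lumen_nodes], directed=False)
    terminal_nodes = np.concatenate(
        [mesh.boundary_nodes(t) for t in mesh.terminal_roles] or [np.array([], dtype=int)]
    )
    local = {node: i for i, node in enumerate(lumen_nodes)}
    term_labels = {labels[local[t]] for t in terminal_nodes if t in local}
    missing = set(range(ncomp)) - term_labels
    if missing:
        raise IsolatedLumenError(
            f"isolated-lumen: {len(missing)} lumen component(s) have no terminal"
        )


def solve_intravascular(
    mesh: SimMesh,
    bcs: FlowBCs | None = None,
    mu: float = 3e-3,
    stab_beta: float = 0.1,
    terminal_pressures: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Laminar (Stokes) flow in the lumen subdomain.

    Equal-order P1-P1 velocity/pressure discretization with
    Brezzi-Pitkaranta pressure stabilization; no-slip on vessel walls and
    prescribed-pressure (do-nothing traction) conditions on the inlet and
    outlet terminal facets. Returns nodal pressure IBP (NaN off-lumen),
    elementwise velocity IBV (zero off-lumen), and the nodal velocity field
    (NaN off-lumen) used for exact facet flux quadrature.
    """
    bcs = bcs or FlowBCs()
    lumen_mask = mesh.region == LUMEN
    if not lumen_mask.any():
        raise IsolatedLumenError("isolated-lumen: mesh has no lumen subdomain")
    tris_g = mesh.triangles[lumen_mask]
    lumen_nodes = np.unique(tris_g)
    _lumen_components_with_terminals(mesh, lumen_nodes)

    glob2loc = -np.ones(mesh.n_nodes, dtype=int)
    glob2loc[lumen_nodes] = np.arange(len(lumen_nodes))
    nodes = mesh.nodes[lumen_nodes] * MM_TO_M
    tris = glob2loc[tris_g]
    nl = len(lumen_nodes)

    grads, areas = fem.tri_gradients(nodes, tris)
    K = fem.stiffness_matrix(nodes, tris)
    # C_d[i, j] = int phi_j d(phi_i)/dx_d  (pressure-gradient coupling)
    rows = np.repeat(tris, 3, axis=1)
    cols = np.tile(tris, (1, 3))
    C = []
    for d in range(2):
        # C_d[i, j] = sum_T (A_T / 3) d(phi_i)/dx_d  -- constant over j
        local = np.broadcast_to(
            (grads[:, :, d] * (areas / 3.0)[:, None])[:, :, None], (len(tris), 3, 3)
        )
        C.append(
            sp.csr_matrix(
                (local.reshape(len(tris), 9).ravel(), (rows.ravel(), cols.ravel())),
                shape=(nl, nl),
            )
        )
    h2 = 2.0 * areas  # ~ h_T^2
    S = fem.stiffness_matrix(nodes, tris, coeff=stab_beta * h2 / mu)

    A = sp.bmat(
        [
            [mu * K, None, -C[0]],
            [None, mu * K, -C[1]],
            [C[0].T, C[1].T, S],
        ],
        format="csr",
    )
    b = np.zeros(3 * nl)

    # prescribed-pressure traction on terminal facets
    pressures = {
        label: (terminal_pressures or {}).get(label, bcs.terminal_pressure(role))
        for label, role in mesh.terminal_roles.items()
    }
    lumen_tri_index = np.flatnonzero(lumen_mask)
    # orientation helper: outward normal of a boundary edge w.r.t. the lumen
    tri_lookup = {}
    for t in tris_g:
        for i in range(3):
            e = (min(t[i], t[(i + 1) % 3]), max(t[i], t[(i + 1) % 3]))
            tri_lookup.setdefault(e, []).append(t)
    for label, pbar in pressures.items():
        for e in mesh.edges_with(label):
            key = (min(e), max(e))
            owners = tri_lookup.get(key)
            if not owners:
                continue
            t = owners[0]
            third = [v for v in t if v not in key][0]
            p0, p1 = mesh.nodes[e[0]] * MM_TO_M, mesh.nodes[e[1]] * MM_TO_M
            tvec = p1 - p0
            nvec = np.array([tvec[1], -tvec[0]])
            if nvec @ (mesh.nodes[third] * MM_TO_M - p0) > 0:
                nvec = -nvec  # point away from the lumen triangle
            # int_e (-pbar n) . v  -> load on vx, vy rows
            li = glob2loc[np.asarray(e)]
            b[li] += -pbar * nvec[0] / 2.0
            b[nl + li] += -pbar * nvec[1] / 2.0

    wall_nodes = glob2loc[np.intersect1d(mesh.boundary_nodes("vessel_wall"), lumen_nodes)]
    dir_idx = np.concatenate([wall_nodes, nl + wall_nodes])
    A, b = fem.apply_dirichlet(A, b, dir_idx, 0.0)
    sol = spsolve(A.tocsc(), b)
    resid = np.linalg.norm(A @ sol - b) / max(np.linalg.norm(b), 1e-30)
    if not np.isfinite(sol).all() or resid > 1e-8:
        raise SolverDivergedError(f"solver-diverged: Stokes residual {resid:.2e}")

    ux, uy, p = sol[:nl], sol[nl : 2 * nl], sol[2 * nl :]
    IBP = np.full(mesh.n_nodes, np.nan)
    IBP[lumen_nodes] = p
    IBV = np.zeros((mesh.n_triangles, 2))
    IBV[lumen_tri_index, 0] = ux[tris].mean(axis=1)
    IBV[lumen_tri_index, 1] = uy[tris].mean(axis=1)
    IBV_nodal = np.full((mesh.n_nodes, 2), np.nan)
    IBV_nodal[lumen_nodes, 0] = ux
    IBV_nodal[lumen_nodes, 1] = uy
    return IBP, IBV, IBV_nodal


def solve_interstitial(
    mesh: SimMesh,
    params: TissueParams | None = None,
    bcs: FlowBCs | None = None,
    coupling_mode: str = "wall_coupled",
    IBP: np.ndarray | None = None,
    rtol: float = 1e-10,
) -> FlowSolution:
    """Darcy interstitial flow with Starling exchange.

    Solves -K lap(P_i) = phi_B on the tissue subdomain with P_i fixed at
    ``bcs.surface_pressure`` on the tumor surface. In ``distributed`` mode
    the exchange is volumetric with the constant P_B; in ``wall_coupled``
    mode it is a vessel-wall Robin flux using the local intravascular
    pressure ``IBP`` (computed here if not supplied). The sparse system is
    solved directly; the relative residual is checked against ``rtol``.
    """
    params = params or TissueParams()
    bcs = bcs or FlowBCs()
    nodes = mesh.nodes * MM_TO_M
    tissue_tris = mesh.triangles[mesh.region == TISSUE]
    n = mesh.n_nodes
    tissue_nodes = np.unique(tissue_tris)

    A = fem.stiffness_matrix(nodes, tissue_tris, coeff=params.K)
    a_coef = params.L_p * params.S_over_V
    IBV = None
    if coupling_mode == "distributed":
        M = fem.mass_matrix(nodes, tissue_tris)
        A = A + a_coef * M
        b = a_coef * params.effective_pressure * (M @ np.ones(n))
    elif coupling_mode == "wall_coupled":
        if not (mesh.region == LUMEN).any():
            # avascular domain: no exchange at all, pure Laplace with zero
            # surface pressure (the vessel-free comparator case)
            b = np.zeros(n)
            IBP = None
        else:
            if IBP is None:
                IBP, IBV, _ = solve_intravascular(mesh, bcs, mu=params.mu)
            wall_edges = mesh.edges_with("vessel_wall")
            MG = fem.boundary_mass_matrix(nodes, wall_edges)
            A = A + params.L_p * MG
            drive = np.where(np.isnan(IBP), 0.0, IBP) - params.sigma_s * (
                params.pi_B - params.pi_i
            )
            b = params.L_p * (MG @ drive)
    else:
        raise ValueError(f"unknown coupling mode {coupling_mode!r}")

    # pin nodes that belong to no tissue element (lumen interior)
    outside = np.setdiff1d(np.arange(n), tissue_nodes)
    surface_nodes = mesh.boundary_nodes("tumor_surface")
    A0, b0 = A.copy(), b.copy()
    dir_idx = np.concatenate([surface_nodes, outside])
    dir_val = np.concatenate(
        [np.full(len(surface_nodes), bcs.surface_pressure), np.zeros(len(outside))]
    )
    A, b = fem.apply_dirichlet(A, b, dir_idx, dir_val)
    P = spsolve(A.tocsc(), b)
    resid = np.linalg.norm(A @ P - b) / max(np.linalg.norm(b), 1e-30)
    if not np.isfinite(P).all() or resid > rtol:
        raise SolverDivergedError(f"solver-diverged: relative residual {resid:.2e}")

    IFP = np.full(n, np.nan)
    IFP[tissue_nodes] = P[tissue_nodes]
    Pfill = np.where(np.isnan(IFP), 0.0, IFP)
    IFV = np.zeros((mesh.n_triangles, 2))
    tissue_index = np.flatnonzero(mesh.region == TISSUE)
    IFV[tissue_index] = -params.K * fem.element_gradient(nodes, tissue_tris, Pfill)

    sol = FlowSolution(
        mesh=mesh, params=params, bcs=bcs, coupling_mode=coupling_mode,
        IFP=IFP, IFV=IFV,
    )
    if coupling_mode == "wall_coupled" and IBP is not None:
        sol.IBP = IBP
        if IBV is not None:
            sol.IBV = IBV
        wall_edges = mesh.edges_with("vessel_wall")
        mid_P = Pfill[wall_edges].mean(axis=1)
        mid_Pv = np.where(np.isnan(IBP), 0.0, IBP)[wall_edges].mean(axis=1)
        sol.wall_flux = params.L_p * (
            mid_Pv - mid_P - params.sigma_s * (params.pi_B - params.pi_i)
        )
        lengths = fem.edge_lengths(nodes, wall_edges)
        sol.wall_inflow = float((sol.wall_flux * lengths).sum())
    else:
        sol.phi_B_nodal = np.where(
            np.isnan(IFP), 0.0, starling_phi_B(Pfill, params)
        )
    # consistent boundary flux: residual of the unconstrained system at the
    # surface nodes equals -(outward Darcy flux integral)
    r = A0 @ P - b0
    sol.surface_outflow = float(-r[surface_nodes].sum())
    return sol


def terminal_fluxes(mesh: SimMesh, IBV_nodal: np.ndarray) -> dict[str, float]:
    """Volumetric flux (m^2/s per unit depth) out of the lumen per terminal.

    Exact trapezoidal integral of the P1 nodal velocity across each
    terminal facet. Positive values leave the lumen, so inlets come out
    negative (inflow) under the usual pressure drop.
    """
    lumen_tris = mesh.triangles[mesh.region == LUMEN]
    edge_owner: dict[tuple[int, int], int] = {}
    lumen_idx = np.flatnonzero(mesh.region == LUMEN)
    for k, t in zip(lumen_idx, lumen_tris):
        for i in range(3):
            e = (min(t[i], t[(i + 1) % 3]), max(t[i], t[(i + 1) % 3]))
            edge_owner[e] = k
    u = np.where(np.isnan(IBV_nodal), 0.0, IBV_nodal)
    out = {}
    for label in mesh.terminal_roles:
        Q = 0.0
        for e in mesh.edges_with(label):
            key = (min(e), max(e))
            k = edge_owner.get(key)
            if k is None:
                continue
            p0, p1 = mesh.nodes[e[0]] * MM_TO_M, mesh.nodes[e[1]] * MM_TO_M
            tvec = p1 - p0
            nvec = np.array([tvec[1], -tvec[0]])  # length-weighted normal
            t = mesh.triangles[k]
            third = [v for v in t if v not in key][0]
            if nvec @ (mesh.nodes[third] * MM_TO_M - p0) > 0:
                nvec = -nvec
            Q += float(0.5 * (u[e[0]] + u[e[1]]) @ nvec)
        out[label] = Q
    return out


def solve_flow(
    mesh: SimMesh,
    params: TissueParams | None = None,
    bcs: FlowBCs | None = None,
    coupling_mode: str = "wall_coupled",
) -> FlowSolution:
    """Full steady flow solve (intravascular where needed + interstitial)."""
    return solve_interstitial(mesh, params, bcs, coupling_mode=coupling_mode)


def flow_summary(sol: FlowSolution) -> dict:
    """Area-weighted IFP statistics, peak IFV and IBP spread ratios."""
    if sol.IFP is None or sol.IFV is None:
        raise NotSolvedError("not-solved: interstitial fields missing")
    mesh = sol.mesh
    tissue = mesh.region == TISSUE
    areas = mesh.areas()[tissue]
    tri_mean = np.nanmean(sol.IFP[mesh.triangles[tissue]], axis=1)
    mean_ifp = float((tri_mean * areas).sum() / areas.sum())
    max_ifp = float(np.nanmax(sol.IFP))
    speed = np.hypot(sol.IFV[:, 0], sol.IFV[:, 1])
    out = {
        "mean_IFP_Pa": mean_ifp,
        "max_IFP_Pa": max_ifp,
        "max_IFV_m_per_s": float(speed.max()),
    }
    if sol.IBP is not None:
        ibp = sol.IBP[np.isfinite(sol.IBP)]
        out["IBP_ratio_max_over_min"] = float(ibp.max() / ibp.min())
        out["IBP_ratio_min_over_max"] = float(ibp.min() / ibp.max())
    return out
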