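"""Poiseuille blood flow on a vascular graph.

Two solvers are provided.  :func:`solve_poiseuille` is the classical
nodal-pressure solve when every terminal node carries a pressure or flux
condition.  :func:`estimate_flow` implements the constrained-optimisation
scheme used when most terminal conditions are unknown: nodal pressures
are chosen to minimise the weighted squared deviation from target
pressures and target wall shear stresses, subject to mass conservation
at every node whose flux is known (interior nodes and explicit flux
boundaries).  The shear target enters with the sign of the current flow
direction, so the stationary solve is repeated until no segment changes
direction.

Internally pressures are mmHg, lengths cm, viscosities mmHg*s and flows
cm^3/s; reported flows are nl/min and shear stresses dyn/cm^2.

The effective viscosity is the empirical in-vivo apparent-viscosity law
for blood flowing in narrow tubes (the Fahraeus-Lindqvist effect and its
in-vivo correction), a function of lumen diameter (um) and discharge
haematocrit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from scipy.sparse.linalg import spsolve

from . import units
from .exceptions import SolverError
from .network import VascularNetwork

__all__ = [
    "HaemodynamicParameters",
    "NetworkConductance",
    "FlowSolution",
    "effective_viscosity",
    "relative_viscosity_invivo",
    "assemble_conductance",
    "solve_poiseuille",
    "wall_shear_stress",
    "estimate_flow",
]


@dataclass
class HaemodynamicParameters:
    """Blood rheology and estimation targets.

    haematocrit : discharge haematocrit, uniform across the network
    plasma_viscosity_cP : plasma viscosity in cP
    p_target_mmHg : target nodal pressure p0 for the estimation objective
        (scalar, or an array over nodes)
    tau_target_dyn_cm2 : target wall shear stress magnitude tau0
        (scalar, or an array over segments; a signed array fixes the
        direction targets too)
    k_p : pressure-deviation weight
    k_tau : shear-deviation weight; ``None`` balances the two penalty
        terms on the initial solve
    direction_iter_cap : cap on flow-direction fixed-point iterations
    """

    haematocrit: float = 0.45
    plasma_viscosity_cP: float = 1.05
    p_target_mmHg: object = 31.0
    tau_target_dyn_cm2: object = 15.0
    k_p: float = 0.1
    k_tau: float | None = None
    direction_iter_cap: int = 100

    def __post_init__(self):
        if not (0.0 <= self.haematocrit < 1.0):
            raise ValueError("haematocrit must lie in [0, 1)")
        if self.k_p <= 0:
            raise ValueError("k_p must be positive")


def relative_viscosity_invivo(diameter_um, haematocrit):
    """In-vivo relative apparent viscosity of blood in a tube.

    ``eta_rel = [1 + (eta45 - 1) * f(H) * (d/(d-1.1))^2] * (d/(d-1.1))^2``
    with ``eta45 = 6 exp(-0.085 d) + 3.2 - 2.44 exp(-0.06 d^0.645)`` and
    ``f(H) = ((1-H)^C - 1)/((1-0.45)^C - 1)``,
    ``C = (0.8 + e^{-0.075 d})(-1 + 1/(1+1e-11 d^12)) + 1/(1+1e-11 d^12)``.
    Diameter in um; the 1.1 um offset models the endothelial surface
    layer, so the law requires d > 1.1 um.
    """
    d = np.asarray(diameter_um, dtype=float)
    H = np.asarray(haematocrit, dtype=float)
    if np.any(d <= 1.1):
        raise ValueError("diameter must exceed 1.1 um for the in-vivo law")
    if np.any((H < 0) | (H >= 1)):
        raise ValueError("haematocrit must lie in [0, 1)")
    eta45 = 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    inv = 1.0 / (1.0 + 1e-11 * d**12)
    C = (0.8 + np.exp(-0.075 * d)) * (-1.0 + inv) + inv
    with np.errstate(divide="ignore", invalid="ignore"):
        fH = np.where(
            H > 0,
            ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0),
            0.0,
        )
    wall = (d / (d - 1.1)) ** 2
    return (1.0 + (eta45 - 1.0) * fH * wall) * wall


def effective_viscosity(diameter_um, haematocrit=0.45, plasma_viscosity_cP=1.05):
    """Effective blood viscosity in cP for a vessel of given diameter."""
    return plasma_viscosity_cP * relative_viscosity_invivo(diameter_um, haematocrit)


@dataclass
class NetworkConductance:
    """Incidence and conductance matrices of the network.

    ``L`` is the (n_nodes x n_segments) signed incidence matrix (-1 at a
    segment's start node, +1 at its end); ``M`` (n_segments x n_nodes)
    holds +/- pi d^4/(128 mu l) at the segment's endpoints; ``K = L M``
    maps nodal pressures (mmHg) to nodal net outflow (cm^3/s) with the
    sign convention ``K p = -Q0``.
    """

    L: sparse.csr_matrix
    M: sparse.csr_matrix
    K: sparse.csr_matrix
    viscosities_cP: np.ndarray
    conductance_cm3_s_mmHg: np.ndarray  # per segment, positive magnitude


def assemble_conductance(
    network: VascularNetwork, params: HaemodynamicParameters | None = None
) -> NetworkConductance:
    params = params or HaemodynamicParameters()
    network.validate()
    mu_cP = effective_viscosity(
        network.diameters, params.haematocrit, params.plasma_viscosity_cP
    )
    mu = mu_cP * units.CP_TO_MMHG_S
    d_cm = network.diameters * units.UM_TO_CM
    l_cm = network.lengths * units.UM_TO_CM
    g = np.pi * d_cm**4 / (128.0 * mu * l_cm)  # cm^3 / (s mmHg)

    n, m = network.n_nodes, network.n_segments
    start, end = network.segments[:, 0], network.segments[:, 1]
    rows_seg = np.r_[np.arange(m), np.arange(m)]
    L = sparse.csr_matrix(
        (np.r_[-np.ones(m), np.ones(m)], (np.r_[start, end], np.r_[np.arange(m), np.arange(m)])),
        shape=(n, m),
    )
    M = sparse.csr_matrix(
        (np.r_[g, -g], (rows_seg, np.r_[start, end])), shape=(m, n)
    )
    K = (L @ M).tocsr()
    return NetworkConductance(L, M, K, mu_cP, g)


@dataclass
class FlowSolution:
    """Result of a vascular flow solve."""

    pressures_mmHg: np.ndarray
    segment_flow_cm3_s: np.ndarray  # positive start -> end
    boundary_flux_cm3_s: dict  # node -> inflow (cm^3/s, positive into network)
    shear_dyn_cm2: np.ndarray
    viscosities_cP: np.ndarray
    lagrange: np.ndarray | None = None
    node_weights_um: np.ndarray | None = None
    direction_iterations: int = 0
    direction_converged: bool = True
    objective_history: list = field(default_factory=list)

    @property
    def segment_flow_nl_min(self) -> np.ndarray:
        return self.segment_flow_cm3_s * units.CM3_S_TO_NL_MIN

    @property
    def boundary_flux_nl_min(self) -> dict:
        return {k: v * units.CM3_S_TO_NL_MIN for k, v in self.boundary_flux_cm3_s.items()}

    def velocity_mm_s(self, network: VascularNetwork) -> np.ndarray:
        area_cm2 = np.pi * (network.diameters * units.UM_TO_CM / 2.0) ** 2
        return self.segment_flow_cm3_s / area_cm2 * units.CM_S_TO_MM_S

    def mass_balance_residual(
        self, network: VascularNetwork, cond: NetworkConductance, exclude=()
    ) -> float:
        """Max net flow at flux-conserving nodes relative to the mean |Q|.

        ``exclude`` lists nodes that legitimately exchange flux with the
        exterior (pressure-condition nodes).
        """
        net = np.asarray(cond.L @ self.segment_flow_cm3_s).ravel()
        keep = np.setdiff1d(network.interior_nodes, np.asarray(list(exclude), dtype=int))
        scale = np.abs(self.segment_flow_cm3_s).mean() or 1.0
        if len(keep) == 0:
            return 0.0
        return float(np.abs(net[keep]).max() / scale)


def _segment_flows(network, cond, p):
    start, end = network.segments[:, 0], network.segments[:, 1]
    return cond.conductance_cm3_s_mmHg * (p[start] - p[end])


def wall_shear_stress(
    network: VascularNetwork,
    viscosities_cP: np.ndarray,
    flows_cm3_s: np.ndarray,
    signed: bool = False,
) -> np.ndarray:
    """Wall shear stress per segment, tau = 32 mu |Q| / (pi d^3), dyn/cm^2."""
    mu = viscosities_cP * units.CP_TO_MMHG_S
    d_cm = network.diameters * units.UM_TO_CM
    q = flows_cm3_s if signed else np.abs(flows_cm3_s)
    tau_mmHg = 32.0 * mu * q / (np.pi * d_cm**3)
    return tau_mmHg * units.MMHG_TO_DYN_CM2


def _check_pressure_anchoring(network, pressure_nodes):
    ncomp, labels = network.component_labels()
    anchored = set(labels[list(pressure_nodes)]) if pressure_nodes else set()
    missing = [c for c in range(ncomp) if c not in anchored]
    if missing:
        raise SolverError(
            "no pressure condition in connected component(s) "
            f"{missing}; the pressure level there is undetermined"
        )


def solve_poiseuille(
    network: VascularNetwork,
    conductance: NetworkConductance,
    pressure_bcs: dict,
    flux_bcs: dict | None = None,
) -> FlowSolution:
    """Direct nodal solve ``K p = -Q0`` with Dirichlet pressures.

    ``pressure_bcs`` maps node index -> mmHg; ``flux_bcs`` maps node
    index -> inflow in nl/min (positive into the network).  Interior
    nodes carry zero net flux.  Every boundary node must appear in
    exactly one of the two maps.
    """
    flux_bcs = flux_bcs or {}
    bset = set(network.boundary_nodes.tolist())
    pset = set(pressure_bcs)
    fset = set(flux_bcs)
    if pset & fset:
        raise ValueError("a node cannot carry both a pressure and a flux condition")
    uncovered = bset - pset - fset
    if uncovered:
        raise ValueError(f"boundary nodes without a condition: {sorted(uncovered)}")
    if not pset:
        raise SolverError("at least one pressure condition is required (gauge)")
    _check_pressure_anchoring(network, pset)

    n = network.n_nodes
    K = conductance.K
    p = np.zeros(n)
    fixed = np.array(sorted(pset), dtype=np.int64)
    free = np.array(sorted(set(range(n)) - pset), dtype=np.int64)
    p[fixed] = [pressure_bcs[i] for i in fixed]

    q0 = np.zeros(n)  # prescribed inflow, cm^3/s
    for i, v in flux_bcs.items():
        q0[i] = v * units.NL_MIN_TO_CM3_S

    if len(free):
        A = K[free][:, free]
        rhs = -q0[free] - np.asarray(K[free][:, fixed] @ p[fixed]).ravel()
        p[free] = spsolve(A.tocsc(), rhs)

    q = _segment_flows(network, conductance, p)
    net_out = np.asarray(conductance.L @ q).ravel()  # = K p
    flux = {int(i): float(-net_out[i]) for i in network.boundary_nodes}
    tau = wall_shear_stress(network, conductance.viscosities_cP, q)
    return FlowSolution(p, q, flux, tau, conductance.viscosities_cP.copy())


def _node_weights_cm(network: VascularNetwork) -> np.ndarray:
    """w_k: half the summed length of segments incident to node k (cm)."""
    w = np.zeros(network.n_nodes)
    l_cm = network.lengths * units.UM_TO_CM
    np.add.at(w, network.segments[:, 0], 0.5 * l_cm)
    np.add.at(w, network.segments[:, 1], 0.5 * l_cm)
    return w


def estimate_flow(
    network: VascularNetwork,
    conductance: NetworkConductance,
    pressure_bcs: dict,
    params: HaemodynamicParameters,
    flux_bcs: dict | None = None,
) -> FlowSolution:
    """Constrained-optimisation flow estimation with unknown boundaries.

    Minimises ``1/2 k_p sum_k w_k (p_k - p0)^2
    + 1/2 k_tau sum_j l_j (tau_j - s_j tau0)^2`` subject to
    ``(K p)_i = -Q0_i`` at interior nodes and flux boundaries.  Boundary
    nodes in ``pressure_bcs`` are fixed; those in ``flux_bcs`` (nl/min,
    e.g. blind ends at 0) are constrained; the remainder are left free
    and their fluxes estimated.  The shear-target sign ``s_j`` follows
    the current flow direction and the solve is iterated to a direction
    fixed point.
    """
    flux_bcs = flux_bcs or {}
    if not pressure_bcs:
        raise SolverError("at least one known pressure condition is required")
    if set(pressure_bcs) & set(flux_bcs):
        raise ValueError("a node cannot carry both a pressure and a flux condition")
    _check_pressure_anchoring(network, set(pressure_bcs))

    n, m = network.n_nodes, network.n_segments
    start, end = network.segments[:, 0], network.segments[:, 1]
    d_cm = network.diameters * units.UM_TO_CM
    l_cm = network.lengths * units.UM_TO_CM

    fixed = np.array(sorted(pressure_bcs), dtype=np.int64)
    free = np.array(sorted(set(range(n)) - set(pressure_bcs)), dtype=np.int64)
    col_of = np.full(n, -1, dtype=np.int64)
    col_of[free] = np.arange(len(free))

    # constraint nodes: interior + flux boundaries (Q0 known there);
    # pressure-fixed nodes exchange flux freely and carry no constraint
    bset = set(network.boundary_nodes.tolist())
    cons = sorted(((set(range(n)) - bset) | set(flux_bcs)) - set(pressure_bcs))
    cons = np.array(cons, dtype=np.int64)
    q0 = np.zeros(n)
    for i, v in flux_bcs.items():
        q0[i] = v * units.NL_MIN_TO_CM3_S

    p_fix = np.array([pressure_bcs[i] for i in fixed], dtype=float)
    p_full = np.zeros(n)
    p_full[fixed] = p_fix

    # shear as a linear map of nodal pressure: tau_j = d_j/(4 l_j) (p_s - p_e)
    c = d_cm / (4.0 * l_cm)  # mmHg shear per mmHg pressure drop
    C = sparse.csr_matrix(
        (np.r_[c, -c], (np.r_[np.arange(m), np.arange(m)], np.r_[start, end])),
        shape=(m, n),
    )
    w = _node_weights_cm(network)
    W = sparse.diags(w)
    Ll = sparse.diags(l_cm)

    tau0 = np.broadcast_to(
        np.asarray(params.tau_target_dyn_cm2, dtype=float) * units.DYN_CM2_TO_MMHG, (m,)
    ).copy()
    tau0_mag = np.abs(tau0)
    p0 = np.broadcast_to(np.asarray(params.p_target_mmHg, dtype=float), (n,)).copy()
    k_p = params.k_p

    K = conductance.K
    Kc = K[cons]

    def objective(p, s, k_tau):
        tau = np.asarray(C @ p).ravel()
        return 0.5 * k_p * float(w @ (p - p0) ** 2) + 0.5 * k_tau * float(
            l_cm @ (tau - s * tau0_mag) ** 2
        )

    def solve_for_signs(s, k_tau):
        H = (k_p * W + k_tau * (C.T @ Ll @ C)).tocsr()
        g0 = k_p * w * p0 + k_tau * np.asarray(C.T @ (l_cm * (s * tau0_mag))).ravel()
        # eliminate fixed pressures
        Hff = H[free][:, free]
        rhs_top = g0[free] - np.asarray(H[free][:, fixed] @ p_fix).ravel()
        A12 = Kc[:, free].T
        rhs_bot = -q0[cons] - np.asarray(Kc[:, fixed] @ p_fix).ravel()
        A = sparse.bmat(
            [[Hff, A12], [A12.T, None]], format="csc"
        )
        rhs = np.r_[rhs_top, rhs_bot]
        try:
            lu = sparse.linalg.splu(A)
        except RuntimeError as e:
            raise SolverError(f"singular saddle system in flow estimation: {e}") from e
        sol = lu.solve(rhs)
        sol += lu.solve(rhs - A @ sol)  # one refinement step for tight mass balance
        if not np.all(np.isfinite(sol)):
            raise SolverError("singular saddle system in flow estimation")
        p = p_full.copy()
        p[free] = sol[: len(free)]
        lam = sol[len(free):]
        return p, lam

    # initial directions: from signed targets when supplied, otherwise
    # from a pressure-target-only pre-solve
    p, lam = solve_for_signs(np.zeros(m), 0.0)
    q = _segment_flows(network, conductance, p)
    if np.any(tau0 < 0):
        s = np.where(tau0 < 0, -1.0, 1.0)
    else:
        s = np.where(q >= 0, 1.0, -1.0)

    # balance the two penalty terms on the initial configuration
    if params.k_tau is None:
        tau = np.asarray(C @ p).ravel()
        sp = float(w @ (p - p0) ** 2)
        st = float(l_cm @ (tau - s * tau0_mag) ** 2)
        k_tau = k_p * sp / st if st > 0 else k_p
    else:
        k_tau = params.k_tau

    history = []
    converged = False
    iters = 0
    for iters in range(1, params.direction_iter_cap + 1):
        p, lam = solve_for_signs(s, k_tau)
        q = _segment_flows(network, conductance, p)
        history.append(objective(p, s, k_tau))
        s_new = np.where(q > 0, 1.0, np.where(q < 0, -1.0, s))
        if np.array_equal(s_new, s):
            converged = True
            break
        # near-zero-flow segments can flip signs indefinitely without
        # moving the objective; a plateau is an acceptable fixed point
        if len(history) >= 2 and abs(history[-1] - history[-2]) <= 1e-12 * abs(
            history[-1]
        ):
            converged = True
            break
        s = s_new

    net_out = np.asarray(K @ p).ravel()
    flux = {int(i): float(-net_out[i]) for i in network.boundary_nodes}
    tau_mag = wall_shear_stress(network, conductance.viscosities_cP, q)
    return FlowSolution(
        p,
        q,
        flux,
        tau_mag,
        conductance.viscosities_cP.copy(),
        lagrange=lam,
        node_weights_um=w * units.CM_TO_UM,
        direction_iterations=iters,
        direction_converged=converged,
        objective_history=history,
    )
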