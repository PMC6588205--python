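"""Green's-function Darcy model of interstitial fluid transport.

The interstitium is a porous medium obeying Darcy's law, u = -kappa
grad p, with pressure tending to a far-field value p_inf.  The
vasculature enters as a discrete set of point sources of fluid flux,
each regularized over a sphere whose radius equals the local vessel
radius.  The pressure response of one unit source is the radially
symmetric kernel

    G(r) = [3 - (r/r0)^2] / (8 pi kappa r0)   for r <= r0,
    G(r) = 1 / (4 pi kappa r)                 for r >  r0,

continuous with continuous gradient at the vessel wall r = r0.  Source
strengths are set by Starling's law across the endothelium,
J_v = L_p S (dp - sigma dPi), which closes a dense linear system

    sum_j (G_ij - (kappa_i / L_p,i) dG_ij/dr) q_j
        = p_b,i - p_inf - sigma_i (Pi_b - Pi_v),

whose solution superposes to the interstitial pressure and velocity at
any point.  Strengths may be positive (filtration, vessel -> tissue) or
negative (reabsorption).

Self-interaction term
---------------------
The kernel gradient vanishes at r = 0, which would decouple an isolated
source's strength from the wall conductance L_p.  By default the
self-gradient is evaluated at the vessel wall (r = r0), giving
``A_ii = 3/(8 pi kappa_i r0_i) + 1/(4 pi L_p,i r0_i^2)``; this
reproduces both physical limits (L_p -> 0 gives q -> 0 and p -> p_inf;
L_p -> infinity gives the pure Green's system).  An alternative closure
identifying J_v,i with q_i (``A_ii = G(0) + 1/(L_p,i S_i)``) is
available via ``self_term="lumped"``.

Units: kappa cm^2/(mmHg s), L_p cm/(mmHg s), pressures mmHg, strengths
cm^3/s internally (ul/min in reports), geometry um at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.sparse.linalg import LinearOperator, gmres

from . import units
from .exceptions import SolverError
from .network import VascularNetwork
from .vascular import FlowSolution

__all__ = [
    "InterstitialParameters",
    "SourceSet",
    "SourceSystem",
    "InterstitialField",
    "distribute_sources",
    "greens_function",
    "greens_gradient",
    "assemble_source_system",
    "solve_source_strengths",
    "transvascular_flux",
]

DENSE_LIMIT = 20_000  # sources; beyond this the solver goes matrix-free


@dataclass
class InterstitialParameters:
    """Interstitial and transvascular transport parameters.

    kappa : interstitial hydraulic conductivity, cm^2 mmHg^-1 s^-1
    L_p : vascular hydraulic conductance of the wall, cm mmHg^-1 s^-1
    sigma : oncotic reflection coefficient (0..1)
    Pi_b, Pi_v : oncotic pressures of blood and at the vessel wall, mmHg
    p_inf : far-field interstitial fluid pressure, mmHg
    self_term : "wall" (default) or "lumped" self-interaction closure
    """

    p_inf: float = 0.0
    kappa: float = 1.7e-7
    L_p: float = 2.8e-7
    sigma: float = 0.82
    Pi_b: float = 20.0
    Pi_v: float = 15.0
    self_term: str = "wall"
    solver_rtol: float = 1e-10

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.L_p < 0:
            raise ValueError("L_p must be non-negative")
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError("sigma must lie in [0, 1]")
        if self.self_term not in ("wall", "lumped"):
            raise ValueError("self_term must be 'wall' or 'lumped'")

    @property
    def oncotic_drop_mmHg(self) -> float:
        return self.sigma * (self.Pi_b - self.Pi_v)


@dataclass
class SourceSet:
    """Discrete sources of transvascular flux along the vasculature.

    positions_um : (N, 3) source centres
    r0_um : regularization (source) radii, equal to vessel radii
    rv_um : vessel radii
    length_um : vessel sub-segment length carried by each source
    pb_mmHg : vascular blood pressure at the source
    segment_index : originating segment of each source
    kappa, L_p, sigma : per-source transport parameters
    strengths_cm3_s : solved source strengths (None until solved)
    spacing_um : the maximum spacing delta used to distribute sources
    """

    positions_um: np.ndarray
    r0_um: np.ndarray
    rv_um: np.ndarray
    length_um: np.ndarray
    pb_mmHg: np.ndarray
    segment_index: np.ndarray
    kappa: np.ndarray
    L_p: np.ndarray
    sigma: np.ndarray
    spacing_um: float
    strengths_cm3_s: np.ndarray | None = None

    @property
    def n_sources(self) -> int:
        return len(self.r0_um)

    @property
    def surface_area_cm2(self) -> np.ndarray:
        """Vessel wall area per source, S_i = 2 pi r_v l_i."""
        return (
            2.0 * np.pi * (self.rv_um * units.UM_TO_CM) * (self.length_um * units.UM_TO_CM)
        )

    @property
    def wall_resistance(self) -> np.ndarray:
        """K_i = 1/(L_p,i S_i), mmHg s / cm^3 (inf where L_p = 0)."""
        with np.errstate(divide="ignore"):
            return np.where(
                self.L_p > 0, 1.0 / (self.L_p * self.surface_area_cm2), np.inf
            )

    @property
    def strengths_ul_min(self) -> np.ndarray:
        if self.strengths_cm3_s is None:
            raise ValueError("strengths not solved yet")
        return self.strengths_cm3_s * units.CM3_S_TO_UL_MIN

    def with_params(self, params: InterstitialParameters) -> "SourceSet":
        n = self.n_sources
        return replace(
            self,
            kappa=np.full(n, params.kappa),
            L_p=np.full(n, params.L_p),
            sigma=np.full(n, params.sigma),
        )


def distribute_sources(
    network: VascularNetwork,
    flow: FlowSolution,
    delta_um: float,
    params: InterstitialParameters | None = None,
) -> SourceSet:
    """Place point sources along every segment with maximum spacing delta.

    A segment of length l is split into ceil(l/delta) equal sub-segments
    with one source at each sub-segment midpoint (positions along the
    straight chord).  Vascular pressure at a source is linearly
    interpolated between the segment's nodal pressures, consistent with
    the linear Poiseuille pressure profile.
    """
    if delta_um <= 0:
        raise ValueError("delta_um must be positive")
    params = params or InterstitialParameters()
    pos, r0, rv, ls, pb, seg_idx = [], [], [], [], [], []
    p = flow.pressures_mmHg
    for j, (a, b) in enumerate(network.segments):
        l = network.lengths[j]
        nsub = int(np.ceil(l / delta_um))
        frac = (np.arange(nsub) + 0.5) / nsub
        xa, xb = network.coords[a], network.coords[b]
        pos.append(xa[None, :] + frac[:, None] * (xb - xa)[None, :])
        r0.append(np.full(nsub, network.diameters[j] / 2.0))
        rv.append(np.full(nsub, network.diameters[j] / 2.0))
        ls.append(np.full(nsub, l / nsub))
        pb.append(p[a] + frac * (p[b] - p[a]))
        seg_idx.append(np.full(nsub, j, dtype=np.int64))
    n = sum(len(x) for x in r0)
    return SourceSet(
        positions_um=np.vstack(pos),
        r0_um=np.concatenate(r0),
        rv_um=np.concatenate(rv),
        length_um=np.concatenate(ls),
        pb_mmHg=np.concatenate(pb),
        segment_index=np.concatenate(seg_idx),
        kappa=np.full(n, params.kappa),
        L_p=np.full(n, params.L_p),
        sigma=np.full(n, params.sigma),
        spacing_um=float(delta_um),
    )


# ---------------------------------------------------------------------------
# kernels (arguments in cm; kappa in cm^2/(mmHg s))


def greens_function(r, r0, kappa):
    """Regularized kernel G(r); continuous at r = r0."""
    r = np.asarray(r, dtype=float)
    inner = (3.0 - (r / r0) ** 2) / (8.0 * np.pi * kappa * r0)
    with np.errstate(divide="ignore"):
        outer = 1.0 / (4.0 * np.pi * kappa * r)
    return np.where(r <= r0, inner, outer)


def greens_gradient(r, r0, kappa):
    """dG/dr; continuous at r = r0 and zero at r = 0."""
    r = np.asarray(r, dtype=float)
    inner = -r / (4.0 * np.pi * kappa * r0**3)
    with np.errstate(divide="ignore"):
        outer = -1.0 / (4.0 * np.pi * kappa * r**2)
    return np.where(r <= r0, inner, outer)


# ---------------------------------------------------------------------------
# source system


@dataclass
class SourceSystem:
    """The dense linear system A q = b for the source strengths."""

    A: np.ndarray | LinearOperator
    b: np.ndarray
    sources: SourceSet
    params: InterstitialParameters
    rtol: float = 1e-10


def _kernel_rows(R, r0_row, kap_row):
    """G and dG for a block of rows; kernel uses the evaluating source's
    own radius and conductivity (row-dependent)."""
    r0c = r0_row[:, None]
    kapc = kap_row[:, None]
    with np.errstate(divide="ignore"):
        Rsafe = np.maximum(R, 1e-150)
        G = np.where(
            R <= r0c,
            (3.0 - (R / r0c) ** 2) / (8.0 * np.pi * kapc * r0c),
            1.0 / (4.0 * np.pi * kapc * Rsafe),
        )
        dG = np.where(
            R <= r0c,
            -R / (4.0 * np.pi * kapc * r0c**3),
            -1.0 / (4.0 * np.pi * kapc * Rsafe**2),
        )
    return G, dG


def _row_chunks(n: int, max_elems: float = 4e6):
    step = max(1, int(max_elems // max(n, 1)))
    for lo in range(0, n, step):
        yield lo, min(lo + step, n)


def assemble_source_system(
    sources: SourceSet, params: InterstitialParameters
) -> SourceSystem:
    """Build A q = b from Starling's law and the regularized kernels."""
    n = sources.n_sources
    if np.any(sources.L_p <= 0):
        # L_p = 0 seals the wall: q = 0 identically; signalled by b = 0, A = I
        if np.all(sources.L_p == 0):
            return SourceSystem(np.eye(n), np.zeros(n), sources, params, params.solver_rtol)
        raise ValueError("mixed zero/non-zero L_p per source is not supported")
    x = sources.positions_um * units.UM_TO_CM
    r0 = sources.r0_um * units.UM_TO_CM
    kappa = sources.kappa
    ratio = sources.kappa / sources.L_p
    A = np.empty((n, n))
    coincident = False
    for lo, hi in _row_chunks(n):
        R = cdist(x[lo:hi], x)
        rows = np.arange(hi - lo)
        R[rows, rows + lo] = np.inf  # mask diagonal for the coincidence check
        if np.any(R.min(axis=1) == 0):
            coincident = True
        R[rows, rows + lo] = 0.0
        G, dG = _kernel_rows(R, r0[lo:hi], kappa[lo:hi])
        A[lo:hi] = G
        A[lo:hi] -= ratio[lo:hi, None] * dG
    if coincident:
        warnings.warn(
            "coincident distinct sources; inner regularized branch used",
            RuntimeWarning,
        )
    idx = np.arange(n)
    G0 = 3.0 / (8.0 * np.pi * kappa * r0)
    if params.self_term == "wall":
        # gradient evaluated at the wall r = r0 instead of the centre
        dG_wall = -1.0 / (4.0 * np.pi * kappa * r0**2)
        A[idx, idx] = G0 - ratio * dG_wall
    else:  # lumped: identify J_v,i with q_i
        A[idx, idx] = G0 + sources.wall_resistance
    b = sources.pb_mmHg - params.p_inf - sources.sigma * (params.Pi_b - params.Pi_v)
    return SourceSystem(A, b, sources, params, params.solver_rtol)


def solve_source_strengths(system: SourceSystem) -> np.ndarray:
    """Solve A q = b for the source strengths (cm^3/s)."""
    A, b = system.A, system.b
    n = len(b)
    if isinstance(A, np.ndarray) and n <= DENSE_LIMIT:
        q = np.linalg.solve(A, b)
        res = np.linalg.norm(A @ q - b)
    else:
        q, info = gmres(A, b, rtol=system.rtol, atol=0.0, maxiter=2000)
        if info != 0:
            raise SolverError(f"iterative source solve failed (info={info})")
        res = np.linalg.norm(A @ q - b)
    scale = np.linalg.norm(b) or 1.0
    if res / scale > max(system.rtol * 100, 1e-8):
        raise SolverError(f"source solve residual {res/scale:.2e} above tolerance")
    system.sources.strengths_cm3_s = q
    return q


def transvascular_flux(sources: SourceSet, params: InterstitialParameters) -> np.ndarray:
    """Starling flux per source, J_v,i = -2 pi kappa_i r_v,i l_i sum_j dG_ij q_j.

    Positive values are filtration (vasculature -> interstitium).  Uses
    the same self-term convention as the assembled system.
    """
    q = sources.strengths_cm3_s
    if q is None:
        raise ValueError("solve strengths before computing transvascular flux")
    n = sources.n_sources
    if np.all(sources.L_p == 0):
        return np.zeros(n)
    x = sources.positions_um * units.UM_TO_CM
    r0 = sources.r0_um * units.UM_TO_CM
    kappa = sources.kappa
    grad_sum = np.empty(n)
    for lo, hi in _row_chunks(n):
        R = cdist(x[lo:hi], x)
        _, dG = _kernel_rows(R, r0[lo:hi], kappa[lo:hi])
        rows = np.arange(hi - lo)
        if params.self_term == "wall":
            dG[rows, rows + lo] = -1.0 / (4.0 * np.pi * kappa[lo:hi] * r0[lo:hi] ** 2)
        else:
            dG[rows, rows + lo] = 0.0
        grad_sum[lo:hi] = dG @ q
    rv_cm = sources.rv_um * units.UM_TO_CM
    l_cm = sources.length_um * units.UM_TO_CM
    base = -2.0 * np.pi * kappa * rv_cm * l_cm * grad_sum
    if params.self_term == "wall":
        return base
    # lumped closure: the self contribution is the source strength itself
    return base + q


# ---------------------------------------------------------------------------
# field evaluation


class InterstitialField:
    """Evaluator of IFP and IFV by superposition of solved sources."""

    def __init__(self, sources: SourceSet, params: InterstitialParameters):
        if sources.strengths_cm3_s is None and sources.n_sources > 0:
            raise ValueError("source strengths must be solved first")
        self.sources = sources
        self.params = params

    def _blocks(self, points_um: np.ndarray):
        pts = np.atleast_2d(np.asarray(points_um, dtype=float)) * units.UM_TO_CM
        x = self.sources.positions_um * units.UM_TO_CM
        return pts, x

    def pressure(self, points_um) -> np.ndarray:
        """IFP in mmHg at the given points (um).

        p(x) = p_inf + sum_j G(|x - x_j|; r0_j, kappa_j) q_j, using each
        source's own radius and conductivity in its kernel.
        """
        pts, x = self._blocks(points_um)
        out = np.full(len(pts), self.params.p_inf, dtype=float)
        if self.sources.n_sources == 0:
            return out
        q = self.sources.strengths_cm3_s
        r0 = self.sources.r0_um * units.UM_TO_CM
        kap = self.sources.kappa
        # chunk over evaluation points to bound memory
        chunk = max(1, int(2e7 // max(len(x), 1)))
        for lo in range(0, len(pts), chunk):
            R = cdist(pts[lo : lo + chunk], x)
            G = np.where(
                R <= r0[None, :],
                (3.0 - (R / r0[None, :]) ** 2) / (8.0 * np.pi * kap[None, :] * r0[None, :]),
                1.0 / (4.0 * np.pi * kap[None, :] * np.maximum(R, 1e-150)),
            )
            out[lo : lo + chunk] += G @ q
        return out

    def velocity(self, points_um) -> np.ndarray:
        """IFV in um/s at the given points (um).

        u(x) = -sum_j kappa_j dG/dr(|x-x_j|) q_j (x-x_j)/|x-x_j|; the
        conductivity of each source's kernel cancels, so outside the
        regularization sphere each source contributes q/(4 pi r^2)
        radially.  Contributions at a source centre are zero.
        """
        pts, x = self._blocks(points_um)
        out = np.zeros((len(pts), 3))
        if self.sources.n_sources == 0:
            return out
        q = self.sources.strengths_cm3_s
        r0 = self.sources.r0_um * units.UM_TO_CM
        kap = self.sources.kappa
        chunk = max(1, int(2e7 // max(len(x), 1)))
        for lo in range(0, len(pts), chunk):
            P = pts[lo : lo + chunk]
            diff = P[:, None, :] - x[None, :, :]
            R = np.linalg.norm(diff, axis=2)
            dG = np.where(
                R <= r0[None, :],
                -R / (4.0 * np.pi * kap[None, :] * r0[None, :] ** 3),
                -1.0 / (4.0 * np.pi * kap[None, :] * np.maximum(R, 1e-150) ** 2),
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = diff / R[:, :, None]
            unit = np.nan_to_num(unit)
            contrib = -(kap[None, :] * dG * q[None, :])[:, :, None] * unit
            out[lo : lo + chunk] = contrib.sum(axis=1)
        return out * units.CM_S_TO_UM_S
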