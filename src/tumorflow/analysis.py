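"""Radial profiles, field maps, sensitivity sweeps and normalization.

Radial profiles bin a scalar field by normalised tumour radius (0 at
the hull centroid, 1 on the surface along each point's ray).  Field
maps rasterise IFP, interstitial speed or vascular perfusion density
onto a plane of isotropic pixels (140 um by default, the resolution of
the reference perfusion maps).  Vascular-normalization scenarios ramp
vessel diameters and transport parameters linearly in normalised radius
from tumour values at the core to physiological values at the
periphery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coupling import couple
from .exceptions import ConfigurationError
from .geometry import TumourHull
from .interstitium import InterstitialParameters, SourceSet
from .network import VascularNetwork

__all__ = [
    "RadialProfile",
    "NormalizationScenario",
    "radial_profile",
    "rasterize_field",
    "source_sink_ratio_profile",
    "sweep_parameter",
    "apply_normalization",
]


@dataclass
class RadialProfile:
    """Binned radial statistics of a scalar field."""

    bin_centres: np.ndarray  # normalised radius
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_norm": self.bin_centres,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.count,
            }
        )


def radial_profile(
    points_um: np.ndarray,
    values: np.ndarray,
    hull: TumourHull,
    n_bins: int = 10,
) -> RadialProfile:
    """Mean/SD of ``values`` in equal bins of normalised radius [0, 1].

    Points beyond the hull surface (r_norm > 1) fall in the outermost
    bin; empty bins report NaN with count 0.
    """
    r = hull.normalized_radius(points_um)
    values = np.asarray(values, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = values[sel].mean()
            sd[b] = values[sel].std()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centres, mean, sd, count)


def rasterize_field(
    points_um: np.ndarray,
    values: np.ndarray,
    axis: int = 2,
    plane_um: float = 0.0,
    pixel_um: float = 140.0,
    slab_um: float | None = None,
) -> tuple[np.ndarray, tuple]:
    """Per-pixel mean of a scalar on a plane slab.

    ``axis`` is the plane normal (0/1/2 for x/y/z), ``plane_um`` its
    offset; points within ``slab_um`` (default one pixel) of the plane
    are averaged into isotropic ``pixel_um`` pixels.  Returns the 2-D
    map (NaN where empty) and the (u_edges, v_edges) pixel grid.
    """
    pts = np.atleast_2d(np.asarray(points_um, float))
    values = np.asarray(values, dtype=float)
    slab = slab_um if slab_um is not None else pixel_um
    keep = np.abs(pts[:, axis] - plane_um) <= slab / 2.0
    uv_axes = [i for i in range(3) if i != axis]
    uv = pts[np.ix_(keep, uv_axes)]
    vals = values[keep]
    if len(uv) == 0:
        return np.full((1, 1), np.nan), (np.array([0, pixel_um]), np.array([0, pixel_um]))
    lo = uv.min(axis=0)
    hi = uv.max(axis=0)
    nu = max(1, int(np.ceil((hi[0] - lo[0]) / pixel_um)))
    nv = max(1, int(np.ceil((hi[1] - lo[1]) / pixel_um)))
    u_edges = lo[0] + pixel_um * np.arange(nu + 1)
    v_edges = lo[1] + pixel_um * np.arange(nv + 1)
    iu = np.clip(((uv[:, 0] - lo[0]) / pixel_um).astype(int), 0, nu - 1)
    iv = np.clip(((uv[:, 1] - lo[1]) / pixel_um).astype(int), 0, nv - 1)
    sums = np.zeros((nu, nv))
    counts = np.zeros((nu, nv))
    np.add.at(sums, (iu, iv), vals)
    np.add.at(counts, (iu, iv), 1.0)
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return grid, (u_edges, v_edges)


def source_sink_ratio_profile(
    sources: SourceSet, hull: TumourHull, n_bins: int = 10
) -> RadialProfile:
    """Per-radial-bin (n - m)/(n + m) of source vs sink counts.

    n counts strictly positive strengths (filtration), m strictly
    negative (reabsorption); zero strengths count in neither.  Empty
    bins are NaN.
    """
    if sources.strengths_cm3_s is None:
        raise ValueError("strengths not solved")
    r = hull.normalized_radius(sources.positions_um)
    q = sources.strengths_cm3_s
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    ratio = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        n = int(np.sum(q[sel] > 0))
        m = int(np.sum(q[sel] < 0))
        count[b] = n + m
        if n + m:
            ratio[b] = (n - m) / (n + m)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centres, ratio, np.full(n_bins, np.nan), count)


SWEEPABLE = ("p_inf", "sigma", "L_p", "kappa", "delta", "r0_scale")


def sweep_parameter(
    sources: SourceSet,
    params: InterstitialParameters,
    hull: TumourHull,
    name: str,
    values,
    probe_points_um: np.ndarray,
    n_bins: int = 10,
    tolerance_ul_min: float = 1e-6,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Re-run the coupled solve per parameter value on a fixed source set.

    The boundary-condition realisation (the source set and its vascular
    pressures) is held fixed so the sweep isolates the parameter effect.
    Emits a tidy frame of IFP and IFV-magnitude radial profiles per
    value.
    """
    if name not in SWEEPABLE:
        raise ConfigurationError(f"unknown sweep parameter {name!r}; one of {SWEEPABLE}")
    frames = []
    base_pb = sources.pb_mmHg.copy()
    for value in values:
        src = replace(
            sources,
            pb_mmHg=base_pb.copy(),
            strengths_cm3_s=None,
            kappa=sources.kappa.copy(),
            L_p=sources.L_p.copy(),
            sigma=sources.sigma.copy(),
        )
        prm = params
        if name == "p_inf":
            prm = replace(params, p_inf=float(value))
        elif name == "sigma":
            prm = replace(params, sigma=float(value))
            src.sigma = np.full(src.n_sources, float(value))
        elif name == "L_p":
            prm = replace(params, L_p=float(value))
            src.L_p = np.full(src.n_sources, float(value))
        elif name == "kappa":
            prm = replace(params, kappa=float(value))
            src.kappa = np.full(src.n_sources, float(value))
        elif name == "delta":
            raise ConfigurationError(
                "delta sweeps require re-distributing sources; rebuild the "
                "source set per value with distribute_sources"
            )
        elif name == "r0_scale":
            src.r0_um = sources.r0_um * float(value)
        state, fld = couple(src, prm, tolerance_ul_min, max_iter)
        ifp = fld.pressure(probe_points_um)
        ifv = np.linalg.norm(fld.velocity(probe_points_um), axis=1)
        for label, vals in (("ifp_mmHg", ifp), ("ifv_um_s", ifv)):
            prof = radial_profile(probe_points_um, vals, hull, n_bins)
            f = prof.to_frame()
            f.insert(0, "field", label)
            f.insert(0, "value", value)
            f.insert(0, "parameter", name)
            f["converged"] = state.converged
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class NormalizationScenario:
    """Vascular-normalization parameter ramp.

    Each flagged quantity ranges linearly in normalised radius rho from
    its tumour baseline at the core (rho = 0) to a physiological value
    at the periphery (rho = 1): vessel diameters shrink towards d/1.99,
    wall conductance towards 0.44e-7 cm/(mmHg s), reflection coefficient
    towards 0.91, and interstitial conductivity towards 8.53e-9
    cm^2/(mmHg s).
    """

    diameter_factor: float = 1.99
    L_p_normalized: float = 0.44e-7
    sigma_normalized: float = 0.91
    kappa_normalized: float = 8.53e-9
    normalize_diameter: bool = True
    normalize_L_p: bool = True
    normalize_sigma: bool = True
    normalize_kappa: bool = False

    def __post_init__(self):
        if self.diameter_factor < 1.0:
            raise ConfigurationError("diameter reduction factor must be >= 1")


def apply_normalization(
    network: VascularNetwork,
    sources: SourceSet,
    scenario: NormalizationScenario,
    hull: TumourHull,
) -> tuple[VascularNetwork, SourceSet]:
    """Apply a normalization scenario; returns modified copies.

    Segment diameters are ramped at each segment midpoint's normalised
    radius; per-source transport parameters at each source's.  All flags
    off is the identity.
    """
    net = network.copy()
    if scenario.normalize_diameter:
        mid = 0.5 * (net.coords[net.segments[:, 0]] + net.coords[net.segments[:, 1]])
        rho = np.clip(hull.normalized_radius(mid), 0.0, 1.0)
        net.diameters = net.diameters * (1.0 - rho * (1.0 - 1.0 / scenario.diameter_factor))

    rho_s = np.clip(hull.normalized_radius(sources.positions_um), 0.0, 1.0)
    new_Lp = sources.L_p.copy()
    new_sigma = sources.sigma.copy()
    new_kappa = sources.kappa.copy()
    new_r0 = sources.r0_um.copy()
    new_rv = sources.rv_um.copy()
    if scenario.normalize_L_p:
        new_Lp = new_Lp + rho_s * (scenario.L_p_normalized - new_Lp)
    if scenario.normalize_sigma:
        new_sigma = new_sigma + rho_s * (scenario.sigma_normalized - new_sigma)
    if scenario.normalize_kappa:
        new_kappa = new_kappa + rho_s * (scenario.kappa_normalized - new_kappa)
    if scenario.normalize_diameter:
        shrink = 1.0 - rho_s * (1.0 - 1.0 / scenario.diameter_factor)
        new_r0 = new_r0 * shrink
        new_rv = new_rv * shrink
    src = replace(
        sources,
        L_p=new_Lp,
        sigma=new_sigma,
        kappa=new_kappa,
        r0_um=new_r0,
        rv_um=new_rv,
        strengths_cm3_s=None,
    )
    return net, src
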