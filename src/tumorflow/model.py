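"""Model/Results interface over the coupled transport framework.

:class:`TumourFluidModel` bundles a vascular network with haemodynamic,
boundary and interstitial configuration; :meth:`fit` runs the full
pipeline — hull construction, stochastic boundary assignment, vascular
flow estimation, source distribution and the Starling-coupled
interstitial solve — and returns a :class:`TumourFluidResults` holding
the flow solution, the interstitial field evaluator, the coupling trace
and derived summaries (perfusion, radial profiles, maps).

    >>> model = TumourFluidModel.from_synthetic(SyntheticNetworkSpec(seed=1))
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    NormalizationScenario,
    apply_normalization,
    radial_profile,
    source_sink_ratio_profile,
)
from .boundary import BoundaryAssignment, BoundaryPolicy, assign_boundary_conditions
from .coupling import CouplingState, couple
from .exceptions import ConfigurationError
from .geometry import TumourHull, compute_hull, total_perfusion
from .interstitium import InterstitialField, InterstitialParameters, distribute_sources
from .network import VascularNetwork, network_statistics, validate_and_clean
from .synthetic import SyntheticNetworkSpec, make_fixture
from .vascular import (
    FlowSolution,
    HaemodynamicParameters,
    assemble_conductance,
    estimate_flow,
)

__all__ = ["RunConfig", "TumourFluidModel", "TumourFluidResults", "run_baseline", "run_replicates"]


@dataclass
class RunConfig:
    """Complete configuration of one coupled run."""

    haemodynamics: HaemodynamicParameters = field(default_factory=HaemodynamicParameters)
    boundary: BoundaryPolicy = field(default_factory=BoundaryPolicy)
    interstitial: InterstitialParameters = field(default_factory=InterstitialParameters)
    source_spacing_um: float = 50.0
    coupling_tolerance_ul_min: float = 1e-6
    coupling_max_iter: int = 50
    hull_subdivision: int = 1
    seed: int = 0

    def manifest(self) -> dict:
        doc = {
            "haemodynamics": asdict(self.haemodynamics),
            "boundary": asdict(self.boundary),
            "interstitial": asdict(self.interstitial),
            "source_spacing_um": self.source_spacing_um,
            "coupling_tolerance_ul_min": self.coupling_tolerance_ul_min,
            "coupling_max_iter": self.coupling_max_iter,
            "hull_subdivision": self.hull_subdivision,
            "seed": self.seed,
        }
        payload = json.dumps(doc, sort_keys=True).encode()
        doc["config_hash"] = hashlib.sha256(payload).hexdigest()[:16]
        return doc


class TumourFluidModel:
    """Coupled vascular-interstitial fluid transport on one network."""

    def __init__(self, network: VascularNetwork, config: RunConfig | None = None):
        network.validate()
        self.network = network
        self.config = config or RunConfig()
        self._hull: TumourHull | None = None

    @classmethod
    def from_synthetic(
        cls, spec: SyntheticNetworkSpec, config: RunConfig | None = None
    ) -> "TumourFluidModel":
        net = make_fixture(spec)
        net, _ = validate_and_clean(net)
        return cls(net, config)

    @classmethod
    def from_file(cls, path: str, dialect: str = "csv", config: RunConfig | None = None):
        from .network import load_network

        return cls(load_network(path, dialect), config)

    @property
    def hull(self) -> TumourHull:
        if self._hull is None:
            self._hull = compute_hull(
                self.network.coords, subdivision=self.config.hull_subdivision
            )
        return self._hull

    def fit(self, seed: int | None = None) -> "TumourFluidResults":
        """Run the full coupled pipeline and return results.

        ``seed`` overrides the boundary-policy seed; every stochastic
        element derives from it, so identical (config, seed) pairs give
        identical numbers.
        """
        cfg = self.config
        policy = cfg.boundary if seed is None else replace(cfg.boundary, seed=seed)
        assignment = assign_boundary_conditions(self.network, self.hull, policy)
        cond = assemble_conductance(self.network, cfg.haemodynamics)
        flow = estimate_flow(
            self.network, cond, assignment.pressure_bcs, cfg.haemodynamics,
            assignment.flux_bcs,
        )
        sources = distribute_sources(
            self.network, flow, cfg.source_spacing_um, cfg.interstitial
        )
        state, fld = couple(
            sources,
            cfg.interstitial,
            cfg.coupling_tolerance_ul_min,
            cfg.coupling_max_iter,
        )
        return TumourFluidResults(
            model=self,
            policy=policy,
            assignment=assignment,
            flow=flow,
            sources=sources,
            coupling=state,
            field=fld,
        )


@dataclass
class TumourFluidResults:
    """Fitted flow and interstitial solution with derived summaries."""

    model: TumourFluidModel
    policy: BoundaryPolicy
    assignment: BoundaryAssignment
    flow: FlowSolution
    sources: object
    coupling: CouplingState
    field: InterstitialField

    # -- derived quantities ----------------------------------------------
    def perfusion(self, **kw):
        return total_perfusion(
            self.flow, self.model.hull, self.field, self.model.network, **kw
        )

    def probe_points(self, n_per_axis: int = 12) -> np.ndarray:
        """Regular grid of probe points inside the hull."""
        hull = self.model.hull
        lo = hull.vertices_um.min(axis=0)
        hi = hull.vertices_um.max(axis=0)
        axes = [np.linspace(lo[i], hi[i], n_per_axis + 2)[1:-1] for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
        return pts[hull.contains(pts)]

    def ifp_profile(self, n_bins: int = 10, n_per_axis: int = 12):
        pts = self.probe_points(n_per_axis)
        return radial_profile(pts, self.field.pressure(pts), self.model.hull, n_bins)

    def ifv_profile(self, n_bins: int = 10, n_per_axis: int = 12):
        pts = self.probe_points(n_per_axis)
        speed = np.linalg.norm(self.field.velocity(pts), axis=1)
        return radial_profile(pts, speed, self.model.hull, n_bins)

    def source_sink_profile(self, n_bins: int = 10):
        return source_sink_ratio_profile(self.sources, self.model.hull, n_bins)

    def normalized(self, scenario: NormalizationScenario) -> "TumourFluidResults":
        """Re-solve under a vascular-normalization scenario.

        The boundary realisation and vascular solution are recomputed on
        the modified network; the interstitial system is re-coupled with
        the ramped per-source parameters.
        """
        cfg = self.model.config
        net, _ = apply_normalization(
            self.model.network, self.sources, scenario, self.model.hull
        )
        cond = assemble_conductance(net, cfg.haemodynamics)
        flow = estimate_flow(
            net, cond, self.assignment.pressure_bcs, cfg.haemodynamics,
            self.assignment.flux_bcs,
        )
        sources = distribute_sources(net, flow, cfg.source_spacing_um, cfg.interstitial)
        # ramp per-source transport parameters at the new source positions
        _, sources = apply_normalization(
            net, sources, replace(scenario, normalize_diameter=False), self.model.hull
        )
        state, fld = couple(
            sources, cfg.interstitial, cfg.coupling_tolerance_ul_min, cfg.coupling_max_iter
        )
        clone = TumourFluidModel(net, cfg)
        clone._hull = self.model._hull
        return TumourFluidResults(
            clone, self.policy, self.assignment, flow, sources, state, fld
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        net = self.model.network
        stats = network_statistics(net, self.model.hull.volume_cm3)
        perf = self.perfusion()
        pts = self.probe_points()
        ifp = self.field.pressure(pts)
        ifv = np.linalg.norm(self.field.velocity(pts), axis=1)
        q = self.flow.segment_flow_nl_min
        lines = [
            "Coupled tumour fluid-transport results",
            "=" * 54,
            f"{'Nodes / segments':34s}{net.n_nodes} / {net.n_segments}",
            f"{'Boundary nodes':34s}{stats.n_boundary_nodes}",
            f"{'Mean vessel diameter (um)':34s}{stats.mean_diameter_um:.2f} +/- {stats.sd_diameter_um:.2f}",
            f"{'Vascular density (%)':34s}{stats.vascular_density_pct:.3f}",
            f"{'Hull volume (cm^3)':34s}{self.model.hull.volume_cm3:.4e}",
            "-" * 54,
            f"{'Blood pressure (mmHg)':34s}{self.flow.pressures_mmHg.mean():.2f} +/- {self.flow.pressures_mmHg.std():.2f}",
            f"{'Blood flow (nl/min)':34s}{np.abs(q).mean():.3g} +/- {np.abs(q).std():.3g}",
            f"{'Wall shear stress (dyn/cm^2)':34s}{self.flow.shear_dyn_cm2.mean():.2f} +/- {self.flow.shear_dyn_cm2.std():.2f}",
            f"{'Direction iterations':34s}{self.flow.direction_iterations} (converged: {self.flow.direction_converged})",
            "-" * 54,
            f"{'Sources':34s}{self.sources.n_sources} (spacing {self.sources.spacing_um:g} um)",
            f"{'Coupling iterations':34s}{self.coupling.iterations} (converged: {self.coupling.converged})",
            f"{'IFP (mmHg)':34s}{ifp.mean():.3g} +/- {ifp.std():.3g}",
            f"{'IFV (um/s)':34s}{ifv.mean():.3g} +/- {ifv.std():.3g}",
            "-" * 54,
            f"{'Perfusion (ml/min/100g)':34s}{perf.perfusion_ml_min_100g:.2f}",
            f"{'  vascular (ml/min)':34s}{perf.vascular_ml_min:.3e}",
            f"{'  interstitial inflow (ml/min)':34s}{perf.interstitial_ml_min:.3e}",
        ]
        return "\n".join(lines)

    def node_table(self) -> pd.DataFrame:
        net = self.model.network
        return pd.DataFrame(
            {
                "node": np.arange(net.n_nodes),
                "x_um": net.coords[:, 0],
                "y_um": net.coords[:, 1],
                "z_um": net.coords[:, 2],
                "pressure_mmHg": self.flow.pressures_mmHg,
            }
        )

    def segment_table(self) -> pd.DataFrame:
        net = self.model.network
        return pd.DataFrame(
            {
                "segment": np.arange(net.n_segments),
                "from": net.segments[:, 0],
                "to": net.segments[:, 1],
                "diameter_um": net.diameters,
                "length_um": net.lengths,
                "flow_nl_min": self.flow.segment_flow_nl_min,
                "shear_dyn_cm2": self.flow.shear_dyn_cm2,
                "viscosity_cP": self.flow.viscosities_cP,
            }
        )

    def plot_profiles(self, ax=None):
        """IFP/IFV radial profiles on a matplotlib axis pair."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
        for a, prof, label in (
            (ax[0], self.ifp_profile(), "IFP (mmHg)"),
            (ax[1], self.ifv_profile(), "IFV (um/s)"),
        ):
            a.errorbar(prof.bin_centres, prof.mean, yerr=prof.sd, fmt="o-")
            a.set_xlabel("normalised radius")
            a.set_ylabel(label)
        return ax


def run_baseline(network: VascularNetwork, config: RunConfig) -> TumourFluidResults:
    """Execute the full pipeline under one configuration."""
    return TumourFluidModel(network, config).fit(seed=config.seed)


def run_replicates(
    network: VascularNetwork, config: RunConfig, seeds
) -> tuple[list[TumourFluidResults], pd.DataFrame]:
    """Repeat the stochastic boundary assignment over a seed list.

    Returns the individual results and an ensemble summary with the
    per-node SD of vascular pressure across replicates plus perfusion
    and mean-IFP columns per seed.
    """
    seeds = list(seeds)
    if not seeds:
        raise ConfigurationError("need at least one seed")
    model = TumourFluidModel(network, config)
    results = [model.fit(seed=s) for s in seeds]
    pressures = np.stack([r.flow.pressures_mmHg for r in results])
    rows = []
    for s, r in zip(seeds, results):
        pts = r.probe_points()
        rows.append(
            {
                "seed": s,
                "perfusion_ml_min_100g": r.perfusion().perfusion_ml_min_100g,
                "mean_ifp_mmHg": float(r.field.pressure(pts).mean()),
                "coupling_iterations": r.coupling.iterations,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["pressure_sd_mmHg"] = pressures.std(axis=0)
    return results, summary
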