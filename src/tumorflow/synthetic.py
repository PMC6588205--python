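"""Seeded generators of test networks.

The real whole-tumour graphs behind the study conditions (a murine
glioma and a human colorectal xenograft) are not distributable, so this
module produces stand-ins: deterministic micro-fixtures (single vessel,
Y junction, 3-D lattice) with exactly known topology, and a seeded
stochastic ``tumour_like`` generator that emulates the summary
statistics of segmented tumour vasculature — log-normal vessel
diameters, branch lengths of tens of um, and a prescribed vascular
density inside an ellipsoidal tissue domain.

The tumour-like generator grows branching trees inward from roots on
the ellipsoid surface and then joins the trees into a single connected
component.  It is statistical scaffolding: it matches first- and
second-moment architecture targets, not angiogenic mechanism.  All
randomness flows through one ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError
from .network import VascularNetwork

__all__ = ["SyntheticNetworkSpec", "make_fixture", "reference_configuration"]

KINDS = ("single_vessel", "y_junction", "lattice3d", "tumour_like")


@dataclass
class SyntheticNetworkSpec:
    """Targets for a generated network.

    kind : one of single_vessel | y_junction | lattice3d | tumour_like
    extent_um : tissue domain extent per axis (ellipsoid axes for
        tumour_like, lattice span for lattice3d)
    mean_diameter_um, sd_diameter_um : log-normal diameter targets
    mean_branch_length_um, sd_branch_length_um : branch-length targets
    vascular_density_pct : target vessel volume as % of domain volume
    lattice_k : nodes per edge for lattice3d
    seed : fixes all randomness
    """

    kind: str = "tumour_like"
    extent_um: tuple = (1500.0, 1500.0, 1500.0)
    mean_diameter_um: float = 8.9
    sd_diameter_um: float = 2.8
    mean_branch_length_um: float = 88.8
    sd_branch_length_um: float = 30.0
    vascular_density_pct: float = 0.8
    lattice_k: int = 3
    lattice_spacing_um: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown fixture kind {self.kind!r}")
        if any(e <= 0 for e in self.extent_um):
            raise ConfigurationError("extents must be positive")
        if not (0.0 < self.vascular_density_pct < 100.0):
            raise ConfigurationError("vascular density must lie in (0, 100) %")


def _single_vessel(diameter=10.0, length=100.0) -> VascularNetwork:
    coords = np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]])
    return VascularNetwork(coords, [[0, 1]], [diameter], [length])


def _y_junction(diameter=10.0, length=100.0) -> VascularNetwork:
    # one interior node at the origin, three arms 120 deg apart in-plane
    ang = np.deg2rad([90.0, 210.0, 330.0])
    tips = np.c_[length * np.cos(ang), length * np.sin(ang), np.zeros(3)]
    coords = np.vstack([[0.0, 0.0, 0.0], tips])
    segs = [[1, 0], [0, 2], [0, 3]]
    return VascularNetwork(coords, segs, [diameter] * 3, [length] * 3)


def _lattice3d(k: int, spacing: float, diameter: float) -> VascularNetwork:
    idx = np.arange(k)
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    coords = np.c_[X.ravel(), Y.ravel(), Z.ravel()] * spacing

    def nid(i, j, l):
        return (i * k + j) * k + l

    segs = []
    for i in range(k):
        for j in range(k):
            for l in range(k):
                if i + 1 < k:
                    segs.append([nid(i, j, l), nid(i + 1, j, l)])
                if j + 1 < k:
                    segs.append([nid(i, j, l), nid(i, j + 1, l)])
                if l + 1 < k:
                    segs.append([nid(i, j, l), nid(i, j, l + 1)])
    m = len(segs)
    return VascularNetwork(coords, segs, np.full(m, diameter), np.full(m, spacing))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, s) of a log-normal with the requested mean and SD."""
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def _tumour_like(spec: SyntheticNetworkSpec) -> VascularNetwork:
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.extent_um, dtype=float) / 2.0  # ellipsoid semi-axes
    domain_volume = 4.0 / 3.0 * np.pi * np.prod(a)
    target_volume = spec.vascular_density_pct / 100.0 * domain_volume

    # feasibility: at target diameter, required total length must fit
    seg_area = np.pi * (spec.mean_diameter_um / 2.0) ** 2
    need_length = target_volume / seg_area
    if spec.vascular_density_pct > 20.0:
        raise ConfigurationError(
            f"target density {spec.vascular_density_pct}% cannot be packed as "
            "a vessel tree inside the domain"
        )

    mu_l, s_l = _lognormal_params(
        spec.mean_branch_length_um, max(spec.sd_branch_length_um, 1e-6)
    )

    n_roots = max(6, int(round(need_length / spec.mean_branch_length_um / 400)) * 6)
    # roots spread over the ellipsoid surface
    u = rng.normal(size=(n_roots, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    roots = u * a

    coords = [r for r in roots]
    segs: list[list[int]] = []
    seg_len: list[float] = []
    parent_dir: dict[int, np.ndarray] = {}
    frontier: list[int] = []
    for i, r in enumerate(roots):
        parent_dir[i] = -r / np.linalg.norm(r / a)  # inward-ish
        parent_dir[i] /= np.linalg.norm(parent_dir[i])
        frontier.append(i)

    total_len = 0.0
    max_segments = 60_000
    while frontier and total_len < need_length and len(segs) < max_segments:
        new_frontier: list[int] = []
        for node in frontier:
            if total_len >= need_length or len(segs) >= max_segments:
                break
            # bifurcate at every junction: degree-3 interior nodes, so a
            # branching vessel is one segment and the branch-length target
            # applies to the segment draw directly
            n_children = 2
            base = parent_dir[node]
            for _ in range(n_children):
                length = float(
                    np.clip(rng.lognormal(mu_l, s_l), 5.0, 6 * spec.mean_branch_length_um)
                )
                # inward bias plus angular jitter
                centre_pull = -coords[node] / np.maximum(np.linalg.norm(coords[node]), 1.0)
                direction = base + 0.35 * centre_pull + 0.55 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                child = coords[node] + direction * length
                # keep inside the ellipsoid (retreat towards the centre)
                rad = np.linalg.norm(child / a)
                if rad >= 0.98:
                    child = child / rad * 0.9
                    length = float(np.linalg.norm(child - coords[node]))
                    if length < 5.0:
                        continue
                idx = len(coords)
                coords.append(child)
                segs.append([node, idx])
                seg_len.append(length)
                total_len += length
                parent_dir[idx] = direction
                new_frontier.append(idx)
        frontier = new_frontier

    coords_arr = np.asarray(coords)
    segs_arr = np.asarray(segs, dtype=np.int64)
    if len(segs_arr) == 0:
        raise ConfigurationError("tumour_like generation produced no segments")

    # join separate trees into one component with connector segments
    n_nodes = len(coords_arr)
    parent = np.arange(n_nodes)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for s, e in segs_arr:
        ra, rb = find(s), find(e)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    labels = np.array([find(i) for i in range(n_nodes)])
    comps = np.unique(labels)
    extra_segs = []
    extra_len = []
    tree = cKDTree(coords_arr)
    main = comps[0]
    while len(comps) > 1:
        for c in comps[1:]:
            nodes_c = np.flatnonzero(labels == c)
            nodes_main = np.flatnonzero(labels != c)
            tree_main = cKDTree(coords_arr[nodes_main])
            dist, j = tree_main.query(coords_arr[nodes_c])
            k = int(np.argmin(dist))
            na, nb = int(nodes_c[k]), int(nodes_main[j[k]])
            if dist[k] < 1e-6 or find(na) == find(nb):
                continue
            extra_segs.append([na, nb])
            extra_len.append(float(dist[k]))
            parent[max(find(na), find(nb))] = min(find(na), find(nb))
        labels = np.array([find(i) for i in range(n_nodes)])
        comps = np.unique(labels)

    all_segs = np.vstack([segs_arr] + ([np.asarray(extra_segs, np.int64)] if extra_segs else []))
    all_len = np.concatenate([np.asarray(seg_len), np.asarray(extra_len)]) if extra_len else np.asarray(seg_len)

    # diameters: draw from the target log-normal, thickest nearest the roots
    mu_d, s_d = _lognormal_params(spec.mean_diameter_um, max(spec.sd_diameter_um, 1e-6))
    diam = rng.lognormal(mu_d, s_d, size=len(all_segs))
    diam = np.clip(diam, 1.5, None)  # viscosity law needs d > 1.1 um
    depth = np.linalg.norm(
        (coords_arr[all_segs[:, 0]] + coords_arr[all_segs[:, 1]]) / 2.0 / a, axis=1
    )
    order_depth = np.argsort(-depth)  # shallow (near surface) first
    diam_sorted = np.sort(diam)[::-1]
    out = np.empty_like(diam)
    out[order_depth] = diam_sorted
    diam = out

    net = VascularNetwork(coords_arr, all_segs, diam, all_len)
    net.validate()
    return net


def make_fixture(spec: SyntheticNetworkSpec) -> VascularNetwork:
    """Generate the network described by ``spec`` (same seed, same bytes)."""
    if spec.kind == "single_vessel":
        return _single_vessel(spec.mean_diameter_um, spec.mean_branch_length_um)
    if spec.kind == "y_junction":
        return _y_junction(spec.mean_diameter_um, spec.mean_branch_length_um)
    if spec.kind == "lattice3d":
        return _lattice3d(spec.lattice_k, spec.lattice_spacing_um, spec.mean_diameter_um)
    return _tumour_like(spec)


def reference_configuration(name: str):
    """Minimal (network, source-set) pairs with closed-form fields.

    one_source : a single vessel with one source at the origin
    two_source_symmetric : two equal sources mirrored about the y-z plane
    central_source_sphere : nodes on a sphere (defining a round hull) with
        one source at the centroid
    """
    from .interstitium import InterstitialParameters, SourceSet

    params = InterstitialParameters()

    def stub(positions, r0=10.0, l=50.0, pb=25.0):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        return SourceSet(
            positions_um=positions,
            r0_um=np.full(n, r0),
            rv_um=np.full(n, r0),
            length_um=np.full(n, l),
            pb_mmHg=np.full(n, pb),
            segment_index=np.zeros(n, dtype=np.int64),
            kappa=np.full(n, params.kappa),
            L_p=np.full(n, params.L_p),
            sigma=np.full(n, params.sigma),
            spacing_um=l,
        )

    if name == "one_source":
        net = _single_vessel(20.0, 100.0)
        net.coords -= np.array([50.0, 0.0, 0.0])  # origin at the midpoint
        return net, stub([[0.0, 0.0, 0.0]])
    if name == "two_source_symmetric":
        net = _single_vessel(20.0, 200.0)
        net.coords -= np.array([100.0, 0.0, 0.0])
        return net, stub([[-50.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
    if name == "central_source_sphere":
        # golden-spiral sphere of radius 300 um joined as a ring + centre spoke
        n_pts = 40
        k = np.arange(n_pts)
        phi = np.arccos(1 - 2 * (k + 0.5) / n_pts)
        theta = np.pi * (1 + 5**0.5) * (k + 0.5)
        pts = 300.0 * np.c_[
            np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
        ]
        coords = np.vstack([[0.0, 0.0, 0.0], pts])
        segs = [[0, i + 1] for i in range(n_pts)]
        lens = np.linalg.norm(pts, axis=1)
        net = VascularNetwork(coords, segs, np.full(n_pts, 10.0), lens)
        return net, stub([[0.0, 0.0, 0.0]])
    raise ConfigurationError(f"unknown reference configuration {name!r}")
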