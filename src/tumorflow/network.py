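"""Spatial-graph data model for segmented microvascular networks.

A network is a set of nodes with 3-D coordinates (um) joined by vessel
segments carrying a diameter and a centerline length (um).  Degree-1
nodes are boundary nodes: they either connect to unresolved peritumoural
vessels or terminate blind inside the tissue.  Segment lengths are taken
from the file (skeletonisation centerline lengths) and may exceed the
chord between endpoints; they must never be shorter than it.

File dialects
-------------
``csv``  : a directory (or path prefix) holding ``nodes.csv`` with
           columns ``id,x,y,z`` and ``segments.csv`` with columns
           ``id,from,to,diameter,length``; a ``# units: um`` comment
           header is written and ignored on read.
``json`` : one file ``{"units": "um", "nodes": [...], "segments": [...]}``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .exceptions import NetworkParseError, NetworkValidationError

__all__ = [
    "VascularNetwork",
    "NetworkStatistics",
    "CleaningReport",
    "load_network",
    "save_network",
    "validate_and_clean",
    "network_statistics",
    "branch_decomposition",
]


@dataclass
class VascularNetwork:
    """A vascular spatial graph.

    Parameters
    ----------
    coords : (n_nodes, 3) float array, um
    segments : (n_segments, 2) int array of endpoint node indices
    diameters : (n_segments,) float array, um
    lengths : (n_segments,) float array, um (centerline length)
    node_ids, segment_ids : original file labels (contiguous ints if absent)
    """

    coords: np.ndarray
    segments: np.ndarray
    diameters: np.ndarray
    lengths: np.ndarray
    node_ids: np.ndarray | None = None
    segment_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.segments = np.asarray(self.segments, dtype=np.int64).reshape(-1, 2)
        self.diameters = np.asarray(self.diameters, dtype=float).ravel()
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        if self.node_ids is None:
            self.node_ids = np.arange(self.n_nodes, dtype=np.int64)
        if self.segment_ids is None:
            self.segment_ids = np.arange(self.n_segments, dtype=np.int64)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.segment_ids = np.asarray(self.segment_ids, dtype=np.int64)

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.segments.ravel(), 1)
        return deg

    @property
    def boundary_nodes(self) -> np.ndarray:
        """Indices of degree-1 nodes (network terminations)."""
        return np.flatnonzero(self.degrees == 1)

    @property
    def interior_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.degrees != 1)

    def chord_lengths(self) -> np.ndarray:
        a, b = self.segments[:, 0], self.segments[:, 1]
        return np.linalg.norm(self.coords[a] - self.coords[b], axis=1)

    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_nodes
        a, b = self.segments[:, 0], self.segments[:, 1]
        data = np.ones(2 * self.n_segments)
        return sparse.csr_matrix(
            (data, (np.r_[a, b], np.r_[b, a])), shape=(n, n)
        )

    def component_labels(self) -> tuple[int, np.ndarray]:
        if self.n_nodes == 0:
            return 0, np.zeros(0, dtype=int)
        return connected_components(self.adjacency(), directed=False)

    def validate(self) -> None:
        """Raise :class:`NetworkValidationError` on any invariant breach."""
        if self.n_nodes == 0 or self.n_segments == 0:
            raise NetworkValidationError("network has no nodes or no segments")
        if self.segments.min(initial=0) < 0 or self.segments.max(initial=-1) >= self.n_nodes:
            bad = np.flatnonzero(
                (self.segments < 0).any(axis=1) | (self.segments >= self.n_nodes).any(axis=1)
            )
            raise NetworkValidationError(
                f"segments {bad.tolist()} reference nodes outside [0, {self.n_nodes})"
            )
        if np.any(self.segments[:, 0] == self.segments[:, 1]):
            bad = np.flatnonzero(self.segments[:, 0] == self.segments[:, 1])
            raise NetworkValidationError(f"segments {bad.tolist()} are self-loops")
        if np.any(self.diameters <= 0):
            raise NetworkValidationError("non-positive segment diameter")
        if np.any(self.lengths <= 0):
            raise NetworkValidationError("non-positive segment length")
        chord = self.chord_lengths()
        # small relative slack for float round-off in stored lengths
        if np.any(self.lengths < chord * (1 - 1e-9) - 1e-9):
            bad = np.flatnonzero(self.lengths < chord * (1 - 1e-9) - 1e-9)
            raise NetworkValidationError(
                f"segments {bad.tolist()} are shorter than the chord between endpoints"
            )

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            self.coords.copy(),
            self.segments.copy(),
            self.diameters.copy(),
            self.lengths.copy(),
            self.node_ids.copy(),
            self.segment_ids.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, VascularNetwork):
            return NotImplemented
        return (
            np.array_equal(self.coords, other.coords)
            and np.array_equal(self.segments, other.segments)
            and np.array_equal(self.diameters, other.diameters)
            and np.array_equal(self.lengths, other.lengths)
        )


@dataclass
class NetworkStatistics:
    """Summary statistics of a network inside a tumour hull."""

    n_segments: int
    n_nodes: int
    n_boundary_nodes: int
    mean_diameter_um: float
    sd_diameter_um: float
    mean_branch_length_um: float
    sd_branch_length_um: float
    tissue_dimensions_mm: tuple[float, float, float]
    vascular_density_pct: float
    surface_to_volume_cm1: float

    def as_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "n_nodes": self.n_nodes,
            "n_boundary_nodes": self.n_boundary_nodes,
            "mean_diameter_um": self.mean_diameter_um,
            "sd_diameter_um": self.sd_diameter_um,
            "mean_branch_length_um": self.mean_branch_length_um,
            "sd_branch_length_um": self.sd_branch_length_um,
            "tissue_dimensions_mm": list(self.tissue_dimensions_mm),
            "vascular_density_pct": self.vascular_density_pct,
            "surface_to_volume_cm1": self.surface_to_volume_cm1,
        }


# ---------------------------------------------------------------------------
# I/O


def _csv_paths(path: str) -> tuple[str, str]:
    if os.path.isdir(path):
        return os.path.join(path, "nodes.csv"), os.path.join(path, "segments.csv")
    return path + "_nodes.csv", path + "_segments.csv"


def load_network(path: str, dialect: str = "csv") -> VascularNetwork:
    """Read a network and return it validated, with node ids remapped to a
    contiguous internal index.  Coordinates and lengths are um."""
    if dialect == "csv":
        npath, spath = _csv_paths(path)
        try:
            nodes = pd.read_csv(npath, comment="#", float_precision="round_trip")
            segs = pd.read_csv(spath, comment="#", float_precision="round_trip")
        except FileNotFoundError as e:
            raise NetworkParseError(str(e)) from e
        except Exception as e:  # pragma: no cover - pandas error text varies
            raise NetworkParseError(f"failed to parse {path!r}: {e}") from e
        for col in ("id", "x", "y", "z"):
            if col not in nodes.columns:
                raise NetworkParseError(f"{npath}: missing column {col!r}")
        for col in ("id", "from", "to", "diameter", "length"):
            if col not in segs.columns:
                raise NetworkParseError(f"{spath}: missing column {col!r}")
        node_ids = nodes["id"].to_numpy(np.int64)
        coords = nodes[["x", "y", "z"]].to_numpy(float)
        seg_ids = segs["id"].to_numpy(np.int64)
        raw_ends = segs[["from", "to"]].to_numpy(np.int64)
        diam = segs["diameter"].to_numpy(float)
        length = segs["length"].to_numpy(float)
    elif dialect == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except FileNotFoundError as e:
            raise NetworkParseError(str(e)) from e
        except json.JSONDecodeError as e:
            raise NetworkParseError(f"{path}: invalid JSON at line {e.lineno}") from e
        try:
            node_ids = np.array([n["id"] for n in doc["nodes"]], dtype=np.int64)
            coords = np.array([[n["x"], n["y"], n["z"]] for n in doc["nodes"]], float)
            seg_ids = np.array([s["id"] for s in doc["segments"]], dtype=np.int64)
            raw_ends = np.array([[s["from"], s["to"]] for s in doc["segments"]], np.int64)
            diam = np.array([s["diameter"] for s in doc["segments"]], float)
            length = np.array([s["length"] for s in doc["segments"]], float)
        except (KeyError, TypeError) as e:
            raise NetworkParseError(f"{path}: malformed record ({e})") from e
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(np.unique(node_ids)) != len(node_ids):
        raise NetworkParseError("duplicate node ids")
    index = {int(i): k for k, i in enumerate(node_ids)}
    ends = np.empty_like(raw_ends)
    for row, (a, b) in enumerate(raw_ends):
        try:
            ends[row, 0] = index[int(a)]
            ends[row, 1] = index[int(b)]
        except KeyError as e:
            raise NetworkValidationError(
                f"segment record {row} (id {seg_ids[row]}) references missing node {e}"
            ) from e
    net = VascularNetwork(coords, ends, diam, length, node_ids, seg_ids)
    net.validate()
    return net


def save_network(network: VascularNetwork, path: str, dialect: str = "csv") -> None:
    """Write ``network`` so that :func:`load_network` inverts it exactly."""
    network.validate()
    if dialect == "csv":
        npath, spath = _csv_paths(path)
        if os.path.isdir(path):
            os.makedirs(path, exist_ok=True)
        nodes = pd.DataFrame(
            {
                "id": network.node_ids,
                "x": network.coords[:, 0],
                "y": network.coords[:, 1],
                "z": network.coords[:, 2],
            }
        )
        segs = pd.DataFrame(
            {
                "id": network.segment_ids,
                "from": network.node_ids[network.segments[:, 0]],
                "to": network.node_ids[network.segments[:, 1]],
                "diameter": network.diameters,
                "length": network.lengths,
            }
        )
        for frame, p in ((nodes, npath), (segs, spath)):
            with open(p, "w") as fh:
                fh.write("# units: um\n")
                frame.to_csv(fh, index=False, float_format="%.17g")
    elif dialect == "json":
        doc = {
            "units": "um",
            "nodes": [
                {"id": int(i), "x": float(x), "y": float(y), "z": float(z)}
                for i, (x, y, z) in zip(network.node_ids, network.coords)
            ],
            "segments": [
                {
                    "id": int(sid),
                    "from": int(network.node_ids[a]),
                    "to": int(network.node_ids[b]),
                    "diameter": float(d),
                    "length": float(l),
                }
                for sid, (a, b), d, l in zip(
                    network.segment_ids, network.segments, network.diameters, network.lengths
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# cleaning


@dataclass
class CleaningReport:
    merged_nodes: int = 0
    removed_zero_length_segments: int = 0
    removed_duplicate_segments: int = 0
    n_components: int = 1
    removed_component_sizes: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return (
            self.merged_nodes == 0
            and self.removed_zero_length_segments == 0
            and self.removed_duplicate_segments == 0
            and self.n_components == 1
            and not self.removed_component_sizes
        )


def validate_and_clean(
    network: VascularNetwork,
    merge_tolerance_um: float = 1e-3,
    keep_largest: bool = False,
) -> tuple[VascularNetwork, CleaningReport]:
    """Merge duplicate nodes, drop degenerate segments, report components.

    Duplicate nodes are merged when closer than ``merge_tolerance_um``
    (default 1e-3 um: below imaging resolution, above float noise).  With
    ``keep_largest`` only the largest connected component survives.
    """
    report = CleaningReport()
    coords = network.coords.copy()
    segs = network.segments.copy()
    diam = network.diameters.copy()
    length = network.lengths.copy()

    # merge nodes within tolerance (union by proximity pairs)
    if len(coords):
        tree = cKDTree(coords)
        pairs = tree.query_pairs(merge_tolerance_um, output_type="ndarray")
        if len(pairs):
            parent = np.arange(len(coords))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for a, b in pairs:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            roots = np.array([find(i) for i in range(len(coords))])
            keep = np.unique(roots)
            remap = np.full(len(coords), -1, dtype=np.int64)
            remap[keep] = np.arange(len(keep))
            report.merged_nodes = len(coords) - len(keep)
            coords = coords[keep]
            segs = remap[roots[segs]]

    # degenerate segments: self-loops after merge or non-positive length
    self_loop = segs[:, 0] == segs[:, 1]
    zero_len = length <= 0
    drop = self_loop | zero_len
    report.removed_zero_length_segments = int(drop.sum())
    segs, diam, length = segs[~drop], diam[~drop], length[~drop]

    # exact duplicate segments (same unordered endpoint pair)
    if len(segs):
        key = np.sort(segs, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        dup = np.ones(len(segs), bool)
        dup[first] = False
        report.removed_duplicate_segments = int(dup.sum())
        segs, diam, length = segs[~dup], diam[~dup], length[~dup]

    if len(segs) == 0 or len(coords) == 0:
        raise NetworkValidationError("network empty after cleaning")

    # drop nodes no longer referenced
    used = np.unique(segs)
    if len(used) != len(coords):
        remap = np.full(len(coords), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        coords = coords[used]
        segs = remap[segs]

    cleaned = VascularNetwork(coords, segs, diam, np.maximum(length, cleaned_min(coords, segs, length)))
    ncomp, labels = cleaned.component_labels()
    report.n_components = int(ncomp)
    if ncomp > 1 and keep_largest:
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        node_keep = np.flatnonzero(labels == main)
        remap = np.full(cleaned.n_nodes, -1, dtype=np.int64)
        remap[node_keep] = np.arange(len(node_keep))
        seg_keep = np.all(remap[cleaned.segments] >= 0, axis=1)
        report.removed_component_sizes = sorted(
            int(s) for i, s in enumerate(sizes) if i != main
        )
        cleaned = VascularNetwork(
            cleaned.coords[node_keep],
            remap[cleaned.segments[seg_keep]],
            cleaned.diameters[seg_keep],
            cleaned.lengths[seg_keep],
        )
        report.n_components = 1
    cleaned.validate()
    return cleaned, report


def cleaned_min(coords, segs, length):
    # after merging nodes the chord may exceed a stored length by float dust
    chord = np.linalg.norm(coords[segs[:, 0]] - coords[segs[:, 1]], axis=1)
    return np.where(length < chord, chord, length)


# ---------------------------------------------------------------------------
# statistics


def branch_decomposition(network: VascularNetwork) -> list[np.ndarray]:
    """Partition segments into branching vessels.

    A branching vessel is a maximal chain of segments joined through
    degree-2 nodes, running between junction (degree >= 3) or boundary
    (degree 1) nodes.  Pure cycles of degree-2 nodes form one branch.
    Every segment belongs to exactly one branch.
    """
    deg = network.degrees
    n_seg = network.n_segments
    # incident segment lists
    incident: list[list[int]] = [[] for _ in range(network.n_nodes)]
    for j, (a, b) in enumerate(network.segments):
        incident[a].append(j)
        incident[b].append(j)

    visited = np.zeros(n_seg, dtype=bool)
    branches: list[np.ndarray] = []

    def walk(seg: int, start_node: int) -> list[int]:
        chain = [seg]
        visited[seg] = True
        a, b = network.segments[seg]
        node = b if a == start_node else a
        while deg[node] == 2:
            nxt = [s for s in incident[node] if not visited[s]]
            if not nxt:
                break
            seg = nxt[0]
            visited[seg] = True
            chain.append(seg)
            a, b = network.segments[seg]
            node = b if a == node else a
        return chain

    for node in np.flatnonzero(deg != 2):
        for seg in incident[node]:
            if not visited[seg]:
                branches.append(np.array(walk(seg, node), dtype=np.int64))
    # remaining segments sit in pure degree-2 cycles
    for seg in range(n_seg):
        if not visited[seg]:
            start = network.segments[seg, 0]
            branches.append(np.array(walk(seg, start), dtype=np.int64))
    return branches


def network_statistics(network: VascularNetwork, hull_volume_cm3: float) -> NetworkStatistics:
    """Summary statistics against a tumour volume.

    Vessel volume is sum(pi (d/2)^2 l), vascular surface S = sum(pi d l);
    vascular density = 100 * vessel volume / hull volume and S/V is
    reported in 1/cm.  Branching-vessel lengths merge chains of degree-2
    nodes.
    """
    if hull_volume_cm3 <= 0:
        raise ValueError("hull_volume_cm3 must be positive")
    network.validate()
    d, l = network.diameters, network.lengths
    vessel_volume_um3 = float(np.sum(np.pi * (d / 2.0) ** 2 * l))
    surface_um2 = float(np.sum(np.pi * d * l))
    hull_volume_um3 = hull_volume_cm3 * 1e12
    density = 100.0 * vessel_volume_um3 / hull_volume_um3
    s_over_v = (surface_um2 * 1e-8) / hull_volume_cm3  # cm^2 / cm^3

    branches = branch_decomposition(network)
    blens = np.array([l[idx].sum() for idx in branches])
    span = network.coords.max(axis=0) - network.coords.min(axis=0)
    return NetworkStatistics(
        n_segments=network.n_segments,
        n_nodes=network.n_nodes,
        n_boundary_nodes=int(len(network.boundary_nodes)),
        mean_diameter_um=float(d.mean()),
        sd_diameter_um=float(d.std()),
        mean_branch_length_um=float(blens.mean()),
        sd_branch_length_um=float(blens.std()),
        tissue_dimensions_mm=tuple(float(s) / 1e3 for s in span),
        vascular_density_pct=density,
        surface_to_volume_cm1=s_over_v,
    )
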