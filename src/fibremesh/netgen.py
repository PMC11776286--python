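"""Random 2D fiber networks with jointed cross-links and embedded cell clusters.

Collagen fibers are coarse-grained as straight chains of beads connected by
spring bonds. Wherever beads of two different fibers come close, they are
merged into a single jointed node (a cross-link) so force is transmitted
between fibers. Cell clusters are embedded as circles of discrete boundary
nodes (83 per cluster by default); each cell node is tethered to its nearest
matrix node so prescribed cluster contraction loads the network.

The simulation frame is dimensionless; a single scale (``um_per_unit``)
maps micropattern layouts (μm) into it. Every bond's rest length is set to
its as-built geometric length, so a freshly built network carries zero
elastic energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ClusterLayout

__all__ = [
    "NetworkSpec",
    "ClusterSpec",
    "FiberNetwork",
    "build_network",
    "embed_clusters",
    "layout_to_sim",
    "write_network",
    "read_network",
]


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the as-built fiber network (dimensionless units).

    ``um_per_unit`` maps layout micrometers to simulation length units when
    clusters are embedded. With ``pin_boundary`` (the default), beads lying
    in the margin outside the core analysis domain are immobilized — the
    hydrogel surround anchored at the dish, mirroring the fixed outer
    boundary of the continuum model. Without anchoring, cluster contraction
    merely translates the far field inward and no inter-cluster anisotropy
    can develop.
    """

    domain_size: float = 60.0
    n_fibers: int = 200
    fiber_length: float = 20.0
    segment_rest_length: float = 0.5
    crosslink_merge_radius: float = 0.15
    um_per_unit: float = 25.0
    pin_boundary: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_size <= 0:
            raise NetworkError("degenerate domain")
        if self.n_fibers < 1:
            raise NetworkError("need at least one fiber")
        if not self.segment_rest_length < self.fiber_length:
            raise NetworkError("segment_rest_length must be < fiber_length")
        if not self.crosslink_merge_radius < self.segment_rest_length:
            raise NetworkError("crosslink_merge_radius must be < segment_rest_length")


@dataclass(frozen=True)
class ClusterSpec:
    """Discretization of one cell cluster: boundary node count and coupling.

    ``coupling_factor`` × segment rest length is the search radius for
    tethering each cell node to its nearest matrix node.
    """

    n_boundary_nodes: int = 83
    coupling_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_boundary_nodes < 3:
            raise NetworkError("n_boundary_nodes must be >= 3")


@dataclass
class FiberNetwork:
    """Bead–spring fiber network state (topology + as-built geometry).

    Attributes
    ----------
    positions : (N, 2) float array, simulation units
    bonds : (B, 2) int array of node indices
    rest_lengths : (B,) float array
    fiber_id : (B,) int array — which fiber chain each bond belongs to;
        cell–matrix tether bonds carry fiber_id = -1
    is_crosslink : (N,) bool — node shared by >= 2 fibers
    is_cell : (N,) bool — cluster boundary node
    is_pinned : (N,) bool — anchored margin node (immobile, not a cell)
    cell_cluster_id : (N,) int — owning cluster for cell nodes, else -1
    cluster_centers : (C, 2) float, simulation units
    cluster_radius : float, simulation units (0 clusters → radius 0)
    spec : generating NetworkSpec
    """

    positions: np.ndarray
    bonds: np.ndarray
    rest_lengths: np.ndarray
    fiber_id: np.ndarray
    is_crosslink: np.ndarray
    is_cell: np.ndarray
    is_pinned: np.ndarray
    cell_cluster_id: np.ndarray
    cluster_centers: np.ndarray
    cluster_radius: float
    spec: NetworkSpec

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bond_lengths(self) -> np.ndarray:
        d = self.positions[self.bonds[:, 1]] - self.positions[self.bonds[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def copy(self) -> "FiberNetwork":
        return FiberNetwork(
            positions=self.positions.copy(),
            bonds=self.bonds.copy(),
            rest_lengths=self.rest_lengths.copy(),
            fiber_id=self.fiber_id.copy(),
            is_crosslink=self.is_crosslink.copy(),
            is_cell=self.is_cell.copy(),
            is_pinned=self.is_pinned.copy(),
            cell_cluster_id=self.cell_cluster_id.copy(),
            cluster_centers=self.cluster_centers.copy(),
            cluster_radius=self.cluster_radius,
            spec=self.spec,
        )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_network(spec: NetworkSpec) -> FiberNetwork:
    """Lay down straight bead–spring fibers and merge cross-link nodes.

    Each fiber is a chain of beads at ``segment_rest_length`` spacing with a
    uniformly random midpoint in the square domain and a uniform random
    orientation. Beads of *different* fibers within ``crosslink_merge_radius``
    are merged into a single jointed node placed at their mean position.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_seg = max(1, int(round(spec.fiber_length / spec.segment_rest_length)))
    n_beads = n_seg + 1
    L = spec.domain_size

    positions = []
    bead_fiber = []
    chains = []  # per fiber: list of global bead indices
    idx = 0
    # midpoints sampled in a margin-enlarged box so bead density is uniform
    # throughout the analysis domain (no edge depletion); the fiber count is
    # scaled so n_fibers keeps its meaning of fibers per core-domain area
    margin = spec.fiber_length / 2.0
    n_total = int(round(spec.n_fibers * ((L + 2 * margin) / L) ** 2))
    for f in range(n_total):
        mid = rng.uniform(-margin, L + margin, size=2)
        theta = rng.uniform(0.0, np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        t = (np.arange(n_beads) - (n_beads - 1) / 2.0) * spec.segment_rest_length
        pts = mid[None, :] + t[:, None] * u[None, :]
        positions.append(pts)
        bead_fiber.append(np.full(n_beads, f))
        chains.append(np.arange(idx, idx + n_beads))
        idx += n_beads
    positions = np.concatenate(positions)
    bead_fiber = np.concatenate(bead_fiber)

    # merge inter-fiber bead pairs within the merge radius (union-find)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(spec.crosslink_merge_radius, output_type="ndarray")
    uf = _UnionFind(len(positions))
    for a, b in pairs:
        if bead_fiber[a] != bead_fiber[b]:
            uf.union(a, b)
    roots = np.array([uf.find(i) for i in range(len(positions))])
    uniq, new_index = np.unique(roots, return_inverse=True)

    n_new = len(uniq)
    new_pos = np.zeros((n_new, 2))
    counts = np.bincount(new_index, minlength=n_new).astype(float)
    np.add.at(new_pos, new_index, positions)
    new_pos /= counts[:, None]

    # a merged node touching >1 distinct fiber is a cross-link joint
    n_fiber_touch = np.zeros(n_new, dtype=int)
    for f, chain in enumerate(chains):
        touched = np.unique(new_index[chain])
        n_fiber_touch[touched] += 1
    is_crosslink = n_fiber_touch >= 2

    bonds = []
    fiber_ids = []
    seen = set()
    for f, chain in enumerate(chains):
        mapped = new_index[chain]
        for a, b in zip(mapped[:-1], mapped[1:]):
            if a == b:
                continue  # degenerate after merge
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            bonds.append(key)
            fiber_ids.append(f)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    fiber_ids = np.asarray(fiber_ids, dtype=np.int64)

    d = new_pos[bonds[:, 1]] - new_pos[bonds[:, 0]]
    rest = np.hypot(d[:, 0], d[:, 1])

    n = len(new_pos)
    if spec.pin_boundary:
        pinned = (
            (new_pos[:, 0] < 0.0) | (new_pos[:, 0] > L)
            | (new_pos[:, 1] < 0.0) | (new_pos[:, 1] > L)
        )
    else:
        pinned = np.zeros(n, dtype=bool)
    return FiberNetwork(
        positions=new_pos,
        bonds=bonds,
        rest_lengths=rest,
        fiber_id=fiber_ids,
        is_crosslink=is_crosslink,
        is_cell=np.zeros(n, dtype=bool),
        is_pinned=pinned,
        cell_cluster_id=np.full(n, -1, dtype=np.int64),
        cluster_centers=np.zeros((0, 2)),
        cluster_radius=0.0,
        spec=spec,
    )


def choose_scale(
    layout: ClusterLayout,
    domain_size: float = 60.0,
    base: float = 25.0,
    clearance: float = 0.45,
    granularity: float = 5.0,
) -> float:
    """μm-per-unit scale for a layout: the base scale, coarsened in steps of
    ``granularity`` until the layout's bounding circle (plus cluster radius)
    stays within ``clearance`` × domain size of the domain center.

    Keeps contracting clusters well away from the anchored rim, where
    boundary artifacts would otherwise dominate the local response.
    """
    rel = layout.centers - layout.centroid()
    extent_um = float(np.hypot(rel[:, 0], rel[:, 1]).max()) + layout.radius
    scale = base
    while extent_um / scale > clearance * domain_size:
        scale += granularity
    return scale


def layout_to_sim(layout: ClusterLayout, spec: NetworkSpec) -> tuple[np.ndarray, float]:
    """Map layout cluster centers (μm) into the simulation frame.

    The layout centroid is placed at the domain center; lengths are divided
    by ``spec.um_per_unit``.
    """
    scale = spec.um_per_unit
    center = np.array([spec.domain_size / 2.0] * 2)
    centers = (layout.centers - layout.centroid()) / scale + center
    return centers, layout.radius / scale


def embed_clusters(
    network: FiberNetwork, layout: ClusterLayout, cspec: ClusterSpec | None = None
) -> FiberNetwork:
    """Embed cell clusters as circles of boundary nodes tied to the matrix.

    Matrix nodes strictly inside any cluster circle are removed with their
    bonds. Each cluster contributes ``cspec.n_boundary_nodes`` cell nodes
    uniformly spaced on its circle; each cell node is tethered to its nearest
    matrix node within ``coupling_factor`` × segment rest length (rest length
    = as-built distance, so embedding adds no stress).
    """
    if cspec is None:
        cspec = ClusterSpec()
    if layout.n_clusters == 0:
        return network.copy()

    centers, radius = layout_to_sim(layout, network.spec)
    L = network.spec.domain_size
    if np.any(centers - radius < 0) or np.any(centers + radius > L):
        raise NetworkError("cluster circles must lie inside the simulation domain")

    pos = network.positions
    keep = np.ones(network.n_nodes, dtype=bool)
    for c in centers:
        keep &= np.hypot(pos[:, 0] - c[0], pos[:, 1] - c[1]) >= radius
    old_to_new = np.full(network.n_nodes, -1, dtype=np.int64)
    old_to_new[keep] = np.arange(keep.sum())

    bond_keep = keep[network.bonds[:, 0]] & keep[network.bonds[:, 1]]
    bonds = old_to_new[network.bonds[bond_keep]]
    rest = network.rest_lengths[bond_keep]
    fiber_id = network.fiber_id[bond_keep]

    new_pos = [pos[keep]]
    is_crosslink = [network.is_crosslink[keep]]
    is_cell = [np.zeros(keep.sum(), dtype=bool)]
    is_pinned = [network.is_pinned[keep]]
    cluster_id = [np.full(keep.sum(), -1, dtype=np.int64)]

    matrix_tree = cKDTree(pos[keep])
    coupling_radius = cspec.coupling_factor * network.spec.segment_rest_length
    extra_bonds = []
    extra_rest = []
    next_idx = keep.sum()
    for ci, c in enumerate(centers):
        ang = 2.0 * np.pi * np.arange(cspec.n_boundary_nodes) / cspec.n_boundary_nodes
        ring = c[None, :] + radius * np.column_stack([np.cos(ang), np.sin(ang)])
        dist, nearest = matrix_tree.query(ring)
        within = dist <= coupling_radius
        if not np.any(within):
            raise NetworkError(
                f"cluster {ci} has no matrix node within the coupling radius "
                f"({coupling_radius:.3f}); network too sparse"
            )
        ids = np.arange(next_idx, next_idx + cspec.n_boundary_nodes)
        next_idx += cspec.n_boundary_nodes
        new_pos.append(ring)
        is_crosslink.append(np.zeros(len(ring), dtype=bool))
        is_cell.append(np.ones(len(ring), dtype=bool))
        is_pinned.append(np.zeros(len(ring), dtype=bool))
        cluster_id.append(np.full(len(ring), ci, dtype=np.int64))
        for k in np.flatnonzero(within):
            extra_bonds.append((ids[k], nearest[k]))
            extra_rest.append(dist[k])

    positions = np.concatenate(new_pos)
    bonds_all = np.concatenate([bonds, np.asarray(extra_bonds, dtype=np.int64)])
    rest_all = np.concatenate([rest, np.asarray(extra_rest, dtype=float)])
    fiber_all = np.concatenate([fiber_id, np.full(len(extra_bonds), -1, dtype=np.int64)])

    return FiberNetwork(
        positions=positions,
        bonds=bonds_all,
        rest_lengths=rest_all,
        fiber_id=fiber_all,
        is_crosslink=np.concatenate(is_crosslink),
        is_cell=np.concatenate(is_cell),
        is_pinned=np.concatenate(is_pinned),
        cell_cluster_id=np.concatenate(cluster_id),
        cluster_centers=centers,
        cluster_radius=radius,
        spec=network.spec,
    )


# ---------------------------------------------------------------------------
# I/O — JSON with deterministic ordering (bit-exact round trips)


def write_network(network: FiberNetwork, path: str | Path) -> None:
    obj = {
        "spec": asdict(network.spec),
        "positions": network.positions.tolist(),
        "bonds": network.bonds.tolist(),
        "rest_lengths": network.rest_lengths.tolist(),
        "fiber_id": network.fiber_id.tolist(),
        "is_crosslink": network.is_crosslink.astype(int).tolist(),
        "is_cell": network.is_cell.astype(int).tolist(),
        "is_pinned": network.is_pinned.astype(int).tolist(),
        "cell_cluster_id": network.cell_cluster_id.tolist(),
        "cluster_centers": network.cluster_centers.tolist(),
        "cluster_radius": network.cluster_radius,
    }
    Path(path).write_text(json.dumps(obj, sort_keys=True))


def read_network(path: str | Path) -> FiberNetwork:
    obj = json.loads(Path(path).read_text())
    return FiberNetwork(
        positions=np.asarray(obj["positions"], dtype=float).reshape(-1, 2),
        bonds=np.asarray(obj["bonds"], dtype=np.int64).reshape(-1, 2),
        rest_lengths=np.asarray(obj["rest_lengths"], dtype=float),
        fiber_id=np.asarray(obj["fiber_id"], dtype=np.int64),
        is_crosslink=np.asarray(obj["is_crosslink"], dtype=bool),
        is_cell=np.asarray(obj["is_cell"], dtype=bool),
        is_pinned=np.asarray(obj["is_pinned"], dtype=bool),
        cell_cluster_id=np.asarray(obj["cell_cluster_id"], dtype=np.int64),
        cluster_centers=np.asarray(obj["cluster_centers"], dtype=float).reshape(-1, 2),
        cluster_radius=float(obj["cluster_radius"]),
        spec=NetworkSpec(**obj["spec"]),
    )
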