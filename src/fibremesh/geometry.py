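"""Micropattern cluster layouts and their pairwise-distance structure.

Cell clusters are seeded into photopatterned circular wells (200 μm diameter)
arranged in designed geometries: a single pair, regular polygons (triangle
through hexagon, 600 μm sides), square / parallelogram arrays (800 μm
spacing), or a random array with neighbour separations in 600–1000 μm.
These layouts drive both the fiber-network simulation and the continuum
stress-field calculation; the pairwise-distance graph of a layout is the
expected "bundle graph" — collagen bundles are predicted along the shortest
(side) edges.

All coordinates are in micrometers, origin at the layout centroid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatternSpec",
    "ClusterLayout",
    "PairGraph",
    "make_layout",
    "two_pairs",
    "pair_graph",
    "write_layout",
    "read_layout",
    "KINDS",
]

#: number of vertices of each single-polygon kind
POLYGON_SIDES = {"triangle": 3, "square": 4, "pentagon": 5, "hexagon": 6}

KINDS = (
    "pair",
    "square_array",
    "parallelogram_array",
    "random_array",
    "triangle",
    "parallelogram",
    "square",
    "pentagon",
    "hexagon",
)

#: default center spacing (μm): arrays use 800, everything else 600
ARRAY_KINDS = ("square_array", "parallelogram_array")
DEFAULT_SPACING = {k: 800.0 for k in ARRAY_KINDS}


class LayoutError(ValueError):
    """Raised for invalid pattern specifications or infeasible placements."""


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a micropattern cluster arrangement.

    Parameters
    ----------
    kind
        One of :data:`KINDS`.
    side_spacing
        Center-to-center spacing (μm) of adjacent clusters. Defaults to
        800 μm for arrays and 600 μm for all other kinds.
    cluster_diameter
        Diameter of each circular cluster well (μm); 200 μm by default.
    n_rows, n_cols
        Grid dimensions (array kinds only).
    rng_seed, min_sep, max_sep, n_clusters
        Random-array parameters: seed, the allowed neighbour-separation
        band (μm), and the number of clusters to place.
    """

    kind: str
    side_spacing: float | None = None
    cluster_diameter: float = 200.0
    n_rows: int = 3
    n_cols: int = 3
    rng_seed: int = 0
    min_sep: float = 600.0
    max_sep: float = 1000.0
    n_clusters: int = 5

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise LayoutError(f"unknown pattern kind {self.kind!r}; expected one of {KINDS}")
        if self.side_spacing is None:
            object.__setattr__(self, "side_spacing", DEFAULT_SPACING.get(self.kind, 600.0))
        if self.side_spacing <= self.cluster_diameter:
            raise LayoutError(
                f"side_spacing ({self.side_spacing} μm) must exceed cluster_diameter "
                f"({self.cluster_diameter} μm)"
            )
        if self.min_sep > self.max_sep:
            raise LayoutError("min_sep must not exceed max_sep")
        if self.n_rows < 1 or self.n_cols < 1 or self.n_clusters < 1:
            raise LayoutError("counts must be >= 1")


@dataclass(frozen=True)
class ClusterLayout:
    """Concrete cluster positions: centers (μm), common radius (μm), kind."""

    centers: np.ndarray
    radius: float
    kind: str

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centers", centers)
        if len(centers) >= 2:
            d = _pairwise_distances(centers)
            dmin = d[np.triu_indices(len(centers), k=1)].min()
            if dmin < 2 * self.radius - 1e-9:
                raise LayoutError(
                    f"clusters overlap: min center distance {dmin:.3f} μm "
                    f"< diameter {2 * self.radius:.3f} μm"
                )

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def centroid(self) -> np.ndarray:
        return self.centers.mean(axis=0)


@dataclass(frozen=True)
class PairGraph:
    """All unordered cluster pairs with distances and edge classes.

    ``edges`` is a DataFrame with columns (i, j, distance, kind) where
    kind is "side" (shortest distance class), "diagonal" (within-polygon /
    within-unit longer edges) or "inter-unit" (everything beyond).
    """

    edges: pd.DataFrame

    def side_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kind"] == "side"]

    def edges_of_kind(self, kind: str) -> pd.DataFrame:
        return self.edges[self.edges["kind"] == kind]


def _pairwise_distances(centers: np.ndarray) -> np.ndarray:
    diff = centers[:, None, :] - centers[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def _regular_polygon(n: int, side: float) -> np.ndarray:
    # circumradius from side length; vertex 0 on +x axis
    rc = side / (2.0 * math.sin(math.pi / n))
    ang = 2.0 * math.pi * np.arange(n) / n
    return rc * np.column_stack([np.cos(ang), np.sin(ang)])


def _rhombus(side: float) -> np.ndarray:
    # 60° rhombus: the short diagonal equals the side length
    a = np.array([side, 0.0])
    b = np.array([side * math.cos(math.pi / 3), side * math.sin(math.pi / 3)])
    return np.array([[0.0, 0.0], a, a + b, b])


def _grid(basis_u: np.ndarray, basis_v: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(n_cols), np.arange(n_rows), indexing="xy")
    pts = ii.ravel()[:, None] * basis_u[None, :] + jj.ravel()[:, None] * basis_v[None, :]
    return pts


def _random_array(spec: PatternSpec) -> np.ndarray:
    """Sequential rejection sampling of cluster centers.

    Every accepted center is at least ``min_sep`` from all others and within
    ``max_sep`` of at least one previously accepted center, mirroring the
    neighbour-separation band of the experimental random patterns.
    """
    rng = np.random.default_rng(spec.rng_seed)
    # domain sized so expected density matches a 3x3 array at max_sep
    half = spec.max_sep * 1.5
    max_attempts = 10_000
    accepted: list[np.ndarray] = []
    for k in range(spec.n_clusters):
        for attempt in range(max_attempts):
            cand = rng.uniform(-half, half, size=2)
            if not accepted:
                accepted.append(cand)
                break
            d = np.hypot(*(np.asarray(accepted) - cand).T)
            if d.min() >= spec.min_sep and d.min() <= spec.max_sep:
                accepted.append(cand)
                break
        else:
            raise LayoutError(
                f"random_array placement infeasible: placed {k} of "
                f"{spec.n_clusters} clusters within {max_attempts} attempts "
                f"(min_sep={spec.min_sep}, max_sep={spec.max_sep})"
            )
    return np.asarray(accepted)


def make_layout(spec: PatternSpec) -> ClusterLayout:
    """Generate the cluster centers for a named micropattern geometry.

    Regular polygons have every side equal to ``spec.side_spacing``; arrays
    tile the basis vectors ``n_rows`` × ``n_cols`` times; the single
    parallelogram is a 60° rhombus (short diagonal equal to the side).
    """
    s = float(spec.side_spacing)
    if spec.kind == "pair":
        centers = np.array([[-s / 2.0, 0.0], [s / 2.0, 0.0]])
    elif spec.kind in POLYGON_SIDES:
        centers = _regular_polygon(POLYGON_SIDES[spec.kind], s)
    elif spec.kind == "parallelogram":
        centers = _rhombus(s)
    elif spec.kind == "square_array":
        centers = _grid(np.array([s, 0.0]), np.array([0.0, s]), spec.n_rows, spec.n_cols)
    elif spec.kind == "parallelogram_array":
        u = np.array([s, 0.0])
        v = np.array([s * math.cos(math.pi / 3), s * math.sin(math.pi / 3)])
        centers = _grid(u, v, spec.n_rows, spec.n_cols)
    elif spec.kind == "random_array":
        centers = _random_array(spec)
    else:  # pragma: no cover - guarded by PatternSpec
        raise LayoutError(f"unknown kind {spec.kind!r}")
    centers = centers - centers.mean(axis=0)
    return ClusterLayout(centers=centers, radius=spec.cluster_diameter / 2.0, kind=spec.kind)


def two_pairs(
    pair_spacing: float = 500.0,
    pair_separation: float = 1000.0,
    cluster_diameter: float = 200.0,
) -> ClusterLayout:
    """Two cluster pairs: within-pair spacing 500 μm, pairs 1000 μm apart.

    The four-cluster configuration used to contrast bundling between close
    pairs against the larger inter-pair distance.
    """
    centers = np.array(
        [
            [-pair_separation / 2.0, -pair_spacing / 2.0],
            [-pair_separation / 2.0, pair_spacing / 2.0],
            [pair_separation / 2.0, -pair_spacing / 2.0],
            [pair_separation / 2.0, pair_spacing / 2.0],
        ]
    )
    centers = centers - centers.mean(axis=0)
    return ClusterLayout(centers=centers, radius=cluster_diameter / 2.0, kind="pair")


def pair_graph(layout: ClusterLayout, rel_tol: float = 1e-6) -> PairGraph:
    """All unordered cluster pairs with Euclidean distances and classes.

    Edges at the minimum distance class are "side". For single polygons all
    longer edges are "diagonal". For arrays, edges up to the within-unit-cell
    diagonal are "diagonal" and longer ones "inter-unit"; for pair and random
    layouts, non-side edges are "inter-unit".
    """
    n = layout.n_clusters
    if n < 2:
        raise LayoutError("pair_graph needs at least 2 clusters")
    d = _pairwise_distances(layout.centers)
    iu, ju = np.triu_indices(n, k=1)
    dist = d[iu, ju]
    dmin = dist.min()
    is_side = dist <= dmin * (1.0 + rel_tol)

    if layout.kind in POLYGON_SIDES or layout.kind == "parallelogram":
        other = "diagonal"
        unit_diag = np.inf
    elif layout.kind in ARRAY_KINDS:
        other = None
        # longest within-unit-cell diagonal: sqrt(2)s (square), sqrt(3)s (rhombic)
        factor = math.sqrt(2.0) if layout.kind == "square_array" else math.sqrt(3.0)
        unit_diag = dmin * factor * (1.0 + rel_tol)
    else:
        other = "inter-unit"
        unit_diag = np.inf

    kinds = []
    for s_flag, dd in zip(is_side, dist):
        if s_flag:
            kinds.append("side")
        elif other is not None:
            kinds.append(other)
        else:
            kinds.append("diagonal" if dd <= unit_diag else "inter-unit")

    edges = pd.DataFrame({"i": iu, "j": ju, "distance": dist, "kind": kinds})
    return PairGraph(edges=edges)


# ---------------------------------------------------------------------------
# I/O: CSV of centers + JSON sidecar of the generating spec


def write_layout(layout: ClusterLayout, path: str | Path, spec: PatternSpec | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "cluster_id": np.arange(layout.n_clusters),
            "x_um": layout.centers[:, 0],
            "y_um": layout.centers[:, 1],
            "radius_um": layout.radius,
        }
    )
    df.to_csv(path, index=False)
    sidecar = {"kind": layout.kind, "radius_um": layout.radius}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_layout(path: str | Path) -> ClusterLayout:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    centers = df[["x_um", "y_um"]].to_numpy(dtype=float)
    return ClusterLayout(centers=centers, radius=float(meta["radius_um"]), kind=meta["kind"])
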