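"""Bundling quantification from trajectories and images.

Four measurements:

* ``fl_ratio`` — the fluorescence bundle-strength metric used on microscopy
  images: average an intensity profile across a rectangular ROI crossing the
  putative bundle, sum the 7 samples centered on the profile maximum
  (S_max), sum 7 samples taken from the two profile ends (S_min, 4 from the
  left end and 3 from the right), and report Ratio = S_max / S_min. A
  uniform image yields exactly 1.0.
* ``bundle_scores`` — corridor node-density enrichment in a simulated
  network: matrix-node density inside the rectangular corridor between two
  cluster edges divided by the density in the background (outside all
  corridors and cluster disks). ≈1 for an unremodeled isotropic network,
  >1 where fibers have bundled.
* ``node_force_map`` — net bond-force vector on every node, for rendering
  force-concentration maps.
* ``area_trace`` — shoelace areas of a polygon followed over time, as the
  remaining-area percentage relative to t=0 (pattern stability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .dynamics import BondPotential, SimState, _node_forces
from .geometry import ClusterLayout, PairGraph
from .netgen import FiberNetwork

__all__ = [
    "RectROI",
    "FLProfile",
    "fl_ratio",
    "bundle_scores",
    "bundle_score",
    "node_force_map",
    "AreaTrace",
    "area_trace",
]

#: S_min end convention: 4 samples from the left end, 3 from the right
_SMIN_LEFT = 4
_SMIN_RIGHT = 3


@dataclass(frozen=True)
class RectROI:
    """Rotated rectangular ROI in image pixel coordinates.

    The profile axis runs along ``angle_deg`` (counterclockwise from the +x
    image axis) through ``center``; the bundle should cross this axis so it
    produces a central peak. ``length`` is the profile extent in pixels,
    ``width`` the averaging extent perpendicular to it.
    """

    center: tuple[float, float]
    length: float
    width: float
    angle_deg: float = 0.0


@dataclass(frozen=True)
class FLProfile:
    """Averaged intensity profile with the 7-point peak / end sums."""

    profile: np.ndarray
    s_max: float
    s_min: float
    ratio: float
    peak_index: int


def fl_ratio(image: np.ndarray, roi: RectROI) -> FLProfile:
    """Profile-based bundle fluorescence ratio for one ROI.

    The image is sampled bilinearly on a unit-spaced grid along the ROI,
    averaged across the short axis, and summarized as
    Ratio = S_max / S_min with the 7-point sums described in the module
    docstring. The 7-sample peak window is clamped to stay inside the
    profile.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2D grayscale array")
    n = int(round(roi.length)) + 1
    if n < 14:
        raise ValueError(f"profile length {n} < 14 samples")
    nw = max(1, int(round(roi.width)) + 1)
    ang = np.radians(roi.angle_deg)
    u = np.array([np.cos(ang), np.sin(ang)])  # profile axis (x, y)
    v = np.array([-np.sin(ang), np.cos(ang)])
    s = np.arange(n) - (n - 1) / 2.0
    t = np.arange(nw) - (nw - 1) / 2.0
    cx, cy = roi.center
    X = cx + s[:, None] * u[0] + t[None, :] * v[0]
    Y = cy + s[:, None] * u[1] + t[None, :] * v[1]
    h, w = image.shape
    if X.min() < 0 or Y.min() < 0 or X.max() > w - 1 or Y.max() > h - 1:
        raise ValueError("ROI extends outside the image")
    samples = map_coordinates(image, [Y.ravel(), X.ravel()], order=1, mode="nearest")
    profile = samples.reshape(n, nw).mean(axis=1)

    # S_max: the 7-consecutive-sample window of maximal sum. Equivalent to
    # centering on the peak for a clean unimodal curve, but unbiased for a
    # noisy flat-topped ridge (plain argmax drifts to the plateau edges and
    # drags baseline samples into the window).
    win = np.convolve(profile, np.ones(7), mode="valid")
    lo = int(np.argmax(win))
    peak = lo + 3
    s_max = float(profile[lo : lo + 7].sum())
    s_min = float(profile[:_SMIN_LEFT].sum() + profile[-_SMIN_RIGHT:].sum())
    if s_min <= 0:
        raise ValueError("S_min is non-positive (all-zero or negative curve ends)")
    return FLProfile(profile=profile, s_max=s_max, s_min=s_min,
                     ratio=s_max / s_min, peak_index=peak)


# ---------------------------------------------------------------------------
# corridor bundle score


def _corridor_mask(
    pts: np.ndarray, a: np.ndarray, b: np.ndarray, radius: float, width: float
) -> np.ndarray:
    """Points inside the rectangle between the edges of clusters at a, b."""
    u = b - a
    d = np.hypot(*u)
    u = u / d
    rel = pts - a[None, :]
    t = rel[:, 0] * u[0] + rel[:, 1] * u[1]
    perp = np.abs(-rel[:, 0] * u[1] + rel[:, 1] * u[0])
    return (t >= radius) & (t <= d - radius) & (perp <= width / 2.0)


def bundle_scores(
    positions: np.ndarray,
    network: FiberNetwork,
    graph: PairGraph,
    width: float | None = None,
    radius: float | None = None,
    grid_n: int = 256,
) -> pd.DataFrame:
    """Corridor density enrichment for every edge of the pair graph.

    ``positions`` is a node-position snapshot of ``network`` (so scores can
    be computed at any trajectory frame); pass ``radius`` to score a
    contracted state so the corridor reaches the current cluster edges.
    Width defaults to the as-built cluster radius, matching the measured
    transverse extent of simulated bundles.
    Densities use matrix nodes only; areas of the corridor and the
    background (domain minus corridors minus cluster disks) are measured on
    a ``grid_n``² mask of the simulation domain.
    """
    if network.cluster_centers.shape[0] < 2:
        raise ValueError("bundle scores need an embedded layout with >= 2 clusters")
    centers = network.cluster_centers
    if radius is None:
        radius = network.cluster_radius
    if width is None:
        width = network.cluster_radius
    L = network.spec.domain_size
    pts = positions[~network.is_cell]
    in_domain = (pts[:, 0] >= 0) & (pts[:, 0] <= L) & (pts[:, 1] >= 0) & (pts[:, 1] <= L)
    pts = pts[in_domain]
    if len(pts) == 0:
        raise ValueError("no matrix nodes in the domain")

    g = np.linspace(0.0, L, grid_n)
    GX, GY = np.meshgrid(g, g, indexing="xy")
    gpts = np.column_stack([GX.ravel(), GY.ravel()])
    cell_area = (L / (grid_n - 1)) ** 2

    in_any_corridor_pts = np.zeros(len(pts), dtype=bool)
    in_any_corridor_grid = np.zeros(len(gpts), dtype=bool)
    corridor = {}
    for _, e in graph.edges.iterrows():
        i, j = int(e["i"]), int(e["j"])
        m_pts = _corridor_mask(pts, centers[i], centers[j], radius, width)
        m_grid = _corridor_mask(gpts, centers[i], centers[j], radius, width)
        corridor[(i, j)] = (m_pts, m_grid)
        in_any_corridor_pts |= m_pts
        in_any_corridor_grid |= m_grid

    in_disk_pts = np.zeros(len(pts), dtype=bool)
    in_disk_grid = np.zeros(len(gpts), dtype=bool)
    for c in centers:
        in_disk_pts |= np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) < radius
        in_disk_grid |= np.hypot(gpts[:, 0] - c[0], gpts[:, 1] - c[1]) < radius

    bg_count = int((~in_any_corridor_pts & ~in_disk_pts).sum())
    bg_area = float((~in_any_corridor_grid & ~in_disk_grid).sum()) * cell_area
    if bg_count == 0 or bg_area == 0:
        raise ValueError("zero background density")
    bg_density = bg_count / bg_area

    rows = []
    for _, e in graph.edges.iterrows():
        i, j = int(e["i"]), int(e["j"])
        m_pts, m_grid = corridor[(i, j)]
        area = float(m_grid.sum()) * cell_area
        density = int(m_pts.sum()) / area if area > 0 else np.nan
        rows.append(
            {"i": i, "j": j, "distance": e["distance"], "kind": e["kind"],
             "corridor_count": int(m_pts.sum()), "score": density / bg_density}
        )
    return pd.DataFrame(rows)


def bundle_score(
    positions: np.ndarray,
    network: FiberNetwork,
    edge: tuple[int, int],
    graph: PairGraph,
    width: float | None = None,
) -> float:
    """Score of a single edge (see :func:`bundle_scores`)."""
    df = bundle_scores(positions, network, graph, width=width)
    row = df[(df["i"] == edge[0]) & (df["j"] == edge[1])]
    if row.empty:
        row = df[(df["i"] == edge[1]) & (df["j"] == edge[0])]
    if row.empty:
        raise KeyError(f"edge {edge} not in pair graph")
    return float(row["score"].iloc[0])


def node_force_map(state: SimState) -> pd.DataFrame:
    """Net bond-force vector, magnitude, and direction at every node."""
    f = _node_forces(state.positions, state.network.bonds, state.rest_lengths, state.potential)
    mag = np.hypot(f[:, 0], f[:, 1])
    return pd.DataFrame(
        {
            "x": state.positions[:, 0],
            "y": state.positions[:, 1],
            "fx": f[:, 0],
            "fy": f[:, 1],
            "magnitude": mag,
            "direction_deg": np.degrees(np.arctan2(f[:, 1], f[:, 0])),
            "is_cell": state.network.is_cell,
        }
    )


# ---------------------------------------------------------------------------
# area stability


@dataclass(frozen=True)
class AreaTrace:
    """Polygon areas over time and the remaining-area percentages."""

    areas: np.ndarray
    remaining_percent: np.ndarray


def area_trace(polygons: list[np.ndarray]) -> AreaTrace:
    """Remaining-area percentage series 100·A(t)/A(0) for polygon snapshots.

    Each element of ``polygons`` is an (n, 2) vertex array of a simple
    polygon. Self-intersecting polygons are rejected.
    """
    if not polygons:
        raise ValueError("need at least one polygon")
    areas = []
    for verts in polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.shape[0] < 3:
            raise ValueError("polygon needs >= 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError("self-intersecting (invalid) polygon")
        areas.append(poly.area)
    areas = np.asarray(areas)
    if areas[0] <= 0:
        raise ValueError("initial polygon area must be positive")
    return AreaTrace(areas=areas, remaining_percent=100.0 * areas / areas[0])
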