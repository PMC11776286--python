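"""Continuum stress field of a fixed-boundary elastic plate with contracting
circular cell regions.

The collagen hydrogel is idealized as an isotropic linear elastic plane in
plane stress. Each cell cluster is a circular hole; contraction is imposed
as a uniform inward radial traction on the hole edge (the matrix is pulled
toward the cluster center). The outer boundary of the plate is fixed.

The solver is a constant-strain-triangle finite-element discretization on a
structured triangulation whose nodes are snapped onto the cluster circles,
so the hole boundary is polygonal with vertices exactly on the circle.
Derived maps are the maximum shear stress

    τ_max = sqrt( ((σxx − σyy)/2)² + σxy² )

whose spatial ridges predict where fiber bundles form, and the first
principal direction θ1 = ½·atan2(2σxy, σxx − σyy), along which bundles
align.

Stress magnitudes scale linearly with the traction; reported fields are
meaningful up to that factor (use :meth:`StressField.normalized` for the
max-normalized convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.sparse.linalg import spsolve

from .geometry import ClusterLayout, PairGraph

__all__ = ["ElasticParams", "StressField", "solve", "ridge_profile", "principal_alignment"]


@dataclass(frozen=True)
class ElasticParams:
    """Plane-stress model parameters (normalized units).

    ``domain_size`` (μm) is the side of the square plate, centered on the
    layout centroid; ``None`` picks the layout extent plus a generous margin.
    ``n_cells`` is the number of structured cells per side; ``grid_n`` the
    resolution of the regular output grid.
    """

    young: float = 1.0
    poisson: float = 0.3
    traction: float = 1.0
    domain_size: float | None = None
    n_cells: int = 160
    grid_n: int = 161

    def __post_init__(self) -> None:
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("poisson ratio must be in [0, 0.5)")
        if self.traction < 0:
            raise ValueError("traction must be >= 0")


@dataclass
class StressField:
    """Gridded plane-stress tensor components with derived maps.

    Component arrays are indexed [iy, ix]; points inside cluster disks are
    NaN. ``x``/``y`` are the grid coordinates in μm.
    """

    x: np.ndarray
    y: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    layout: ClusterLayout
    params: ElasticParams

    @property
    def tau_max(self) -> np.ndarray:
        return np.sqrt(((self.sxx - self.syy) / 2.0) ** 2 + self.sxy**2)

    @property
    def theta1_deg(self) -> np.ndarray:
        """First principal direction in degrees, in (−90, 90]."""
        th = 0.5 * np.degrees(np.arctan2(2.0 * self.sxy, self.sxx - self.syy))
        th = np.where(th <= -90.0, th + 180.0, th)
        return np.where(th > 90.0, th - 180.0, th)

    def normalized(self) -> "StressField":
        """Scale all components so the domain maximum of τ_max is 1."""
        m = np.nanmax(self.tau_max)
        if m == 0:
            return self
        return StressField(
            x=self.x, y=self.y, sxx=self.sxx / m, syy=self.syy / m, sxy=self.sxy / m,
            layout=self.layout, params=self.params,
        )


def _structured_mesh(x0: float, y0: float, side: float, n: int):
    xs = np.linspace(x0, x0 + side, n + 1)
    ys = np.linspace(y0, y0 + side, n + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(ix, iy):
        return iy * (n + 1) + ix

    ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
    ix, iy = ix.ravel(), iy.ravel()
    n00 = nid(ix, iy)
    n10 = nid(ix + 1, iy)
    n01 = nid(ix, iy + 1)
    n11 = nid(ix + 1, iy + 1)
    # alternate the diagonal direction for an isotropy-friendly union-jack-ish mesh
    flip = ((ix + iy) % 2).astype(bool)
    t1 = np.where(flip[:, None], np.column_stack([n00, n10, n11]), np.column_stack([n00, n10, n01]))
    t2 = np.where(flip[:, None], np.column_stack([n00, n11, n01]), np.column_stack([n10, n11, n01]))
    tris = np.vstack([t1, t2])
    return nodes, tris


def _solve_fem(layout: ClusterLayout, params: ElasticParams):
    """Assemble and solve; returns (nodes, tris, u, nodal stresses)."""
    centers = layout.centers
    radius = layout.radius
    if len(centers) > 1:
        dd = centers[:, None, :] - centers[None, :, :]
        dmin = np.hypot(dd[..., 0], dd[..., 1])[np.triu_indices(len(centers), 1)].min()
        if dmin < 2 * radius:
            raise ValueError("overlapping clusters")
    if params.domain_size is None:
        extent = 0.0
        if len(centers) > 1:
            d = centers[:, None, :] - centers[None, :, :]
            extent = np.hypot(d[..., 0], d[..., 1]).max()
        margin = max(6.0 * radius, 0.5 * extent, 4.0 * radius + extent * 0.25)
        side = extent + 2.0 * margin
    else:
        side = float(params.domain_size)
    cen = layout.centroid()
    x0, y0 = cen[0] - side / 2.0, cen[1] - side / 2.0
    h = side / params.n_cells
    if h > radius / 8.0:
        raise ValueError(
            f"grid too coarse: cell size {h:.3g} must resolve the cluster radius "
            f"with >= 8 cells (needs n_cells >= {int(np.ceil(side / (radius / 8.0)))})"
        )
    for c in centers:
        if (c[0] - radius <= x0 + h or c[0] + radius >= x0 + side - h
                or c[1] - radius <= y0 + h or c[1] + radius >= y0 + side - h):
            raise ValueError("cluster touches the outer boundary; enlarge the domain")

    # Delaunay mesh of a structured point cloud with exact on-circle rings:
    # grid points near a circle (within ~0.7h) are dropped and replaced by
    # uniformly spaced ring points, so hole boundaries are polygons inscribed
    # in the circles and no sliver or inverted element can arise.
    from scipy.spatial import Delaunay

    xs = np.linspace(x0, x0 + side, params.n_cells + 1)
    GX, GY = np.meshgrid(xs, xs, indexing="xy")
    grid_pts = np.column_stack([GX.ravel(), GY.ravel()])
    keep_pts = np.ones(len(grid_pts), dtype=bool)
    ring_pts = []
    for c in centers:
        d = np.hypot(grid_pts[:, 0] - c[0], grid_pts[:, 1] - c[1])
        keep_pts &= d > radius + 0.7 * h
        n_theta = max(16, int(np.ceil(2.0 * np.pi * radius / h)))
        ang = 2.0 * np.pi * np.arange(n_theta) / n_theta
        ring_pts.append(c + radius * np.column_stack([np.cos(ang), np.sin(ang)]))
    nodes = np.vstack([grid_pts[keep_pts]] + ring_pts)

    tris = Delaunay(nodes).simplices
    cent = nodes[tris].mean(axis=1)
    inside = np.zeros(len(tris), dtype=bool)
    for c in centers:
        inside |= np.hypot(cent[:, 0] - c[0], cent[:, 1] - c[1]) < radius
    p = nodes[tris]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    keep = ~inside & (np.abs(area2) > 1e-12 * h * h)
    tris = tris[keep]
    neg = area2[keep] < 0
    tris[neg] = tris[neg][:, [0, 2, 1]]

    used = np.unique(tris)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes_u = nodes[used]
    tris = remap[tris]
    nn = len(nodes_u)

    # --- element matrices (vectorized CST, plane stress, unit thickness)
    E, nu = params.young, params.poisson
    D = (E / (1.0 - nu * nu)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    p = nodes_u[tris]  # (ne,3,2)
    x1, y1 = p[:, 0, 0], p[:, 0, 1]
    x2, y2 = p[:, 1, 0], p[:, 1, 1]
    x3, y3 = p[:, 2, 0], p[:, 2, 1]
    area = 0.5 * ((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
    b = np.stack([y2 - y3, y3 - y1, y1 - y2], axis=1)
    cc = np.stack([x3 - x2, x1 - x3, x2 - x1], axis=1)
    ne = len(tris)
    B = np.zeros((ne, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for k in range(3):
        B[:, 0, 2 * k] = b[:, k] * inv2A
        B[:, 1, 2 * k + 1] = cc[:, k] * inv2A
        B[:, 2, 2 * k] = cc[:, k] * inv2A
        B[:, 2, 2 * k + 1] = b[:, k] * inv2A
    Ke = np.einsum("eki,kl,elj->eij", B, D, B) * area[:, None, None]

    dof = np.empty((ne, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * tris
    dof[:, 1::2] = 2 * tris + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(2 * nn, 2 * nn)).tocsr()

    # --- loads: inward radial traction on hole boundary edges
    edge_count: dict[tuple[int, int], int] = {}
    edges_all = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    keys = np.sort(edges_all, axis=1)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    boundary_edges = uniq[counts == 1]

    f = np.zeros(2 * nn)
    tol = 1e-6 * radius
    for c in centers:
        d = np.hypot(nodes_u[:, 0] - c[0], nodes_u[:, 1] - c[1])
        on_this = np.abs(d - radius) < tol
        mask = on_this[boundary_edges[:, 0]] & on_this[boundary_edges[:, 1]]
        for a, bn in boundary_edges[mask]:
            pa, pb = nodes_u[a], nodes_u[bn]
            elen = np.hypot(*(pb - pa))
            mid = 0.5 * (pa + pb)
            toward = c - mid
            toward /= np.hypot(*toward)
            t = params.traction * toward * elen / 2.0
            f[2 * a : 2 * a + 2] += t
            f[2 * bn : 2 * bn + 2] += t

    # --- fixed outer boundary
    eps = 1e-9 * side
    outer = (
        (np.abs(nodes_u[:, 0] - x0) < eps)
        | (np.abs(nodes_u[:, 0] - (x0 + side)) < eps)
        | (np.abs(nodes_u[:, 1] - y0) < eps)
        | (np.abs(nodes_u[:, 1] - (y0 + side)) < eps)
    )
    fixed = np.zeros(2 * nn, dtype=bool)
    fixed[2 * np.flatnonzero(outer)] = True
    fixed[2 * np.flatnonzero(outer) + 1] = True
    free = ~fixed

    u = np.zeros(2 * nn)
    Kff = K[free][:, free].tocsc()
    u[free] = spsolve(Kff, f[free])

    # --- element stresses and area-weighted nodal averages
    ue = u[dof]  # (ne,6)
    sig_e = np.einsum("kl,elj,ej->ek", D, B, ue)  # (ne,3)
    nodal = np.zeros((nn, 3))
    wsum = np.zeros(nn)
    for k in range(3):
        np.add.at(nodal, tris[:, k], sig_e * area[:, None])
        np.add.at(wsum, tris[:, k], area)
    nodal /= wsum[:, None]
    return nodes_u, tris, (x0, y0, side), nodal


def solve(layout: ClusterLayout, params: ElasticParams | None = None) -> StressField:
    """Plane-stress equilibrium field for a cluster layout.

    Outer boundary fixed (u = 0); uniform inward radial traction of
    magnitude ``params.traction`` on every cluster-circle edge. Returns the
    stress tensor interpolated onto a regular grid, NaN inside clusters.
    """
    params = params or ElasticParams()
    nodes, tris, (x0, y0, side), nodal = _solve_fem(layout, params)

    gx = np.linspace(x0, x0 + side, params.grid_n)
    gy = np.linspace(y0, y0 + side, params.grid_n)
    GX, GY = np.meshgrid(gx, gy, indexing="xy")
    interp = LinearNDInterpolator(nodes, nodal, fill_value=np.nan)
    vals = interp(np.column_stack([GX.ravel(), GY.ravel()]))
    vals = vals.reshape(params.grid_n, params.grid_n, 3)

    mask = np.zeros(GX.shape, dtype=bool)
    for c in layout.centers:
        mask |= np.hypot(GX - c[0], GY - c[1]) < layout.radius
    vals[mask] = np.nan
    return StressField(
        x=gx, y=gy, sxx=vals[..., 0], syy=vals[..., 1], sxy=vals[..., 2],
        layout=layout, params=params,
    )


def _segment_samples(field: StressField, i: int, j: int, n_samples: int) -> np.ndarray:
    """Sample points on the open segment between the edges of clusters i, j."""
    c = field.layout.centers
    r = field.layout.radius
    u = c[j] - c[i]
    d = np.hypot(*u)
    u = u / d
    t = np.linspace(r + 1e-6 * d, d - r - 1e-6 * d, n_samples)
    return c[i][None, :] + t[:, None] * u[None, :]


def _grid_interp(field: StressField, comp: np.ndarray):
    return RegularGridInterpolator(
        (field.y, field.x), comp, bounds_error=False, fill_value=np.nan
    )


def ridge_profile(
    field: StressField,
    graph: PairGraph,
    n_samples: int = 200,
    corridor_width: float | None = None,
) -> pd.DataFrame:
    """Mean τ_max along each cluster-connecting segment vs. background.

    Background is the domain mean of τ_max excluding all cluster disks and
    all edge corridors of width ``corridor_width`` (default: the cluster
    diameter). Returns a DataFrame with one row per edge and the background
    in a ``background`` column.
    """
    tau = field.tau_max
    interp = _grid_interp(field, tau)
    c = field.layout.centers
    r = field.layout.radius
    if corridor_width is None:
        corridor_width = 2.0 * r

    GX, GY = np.meshgrid(field.x, field.y, indexing="xy")
    excl = ~np.isfinite(tau)
    for cc in c:
        excl |= np.hypot(GX - cc[0], GY - cc[1]) < r

    rows = []
    for _, e in graph.edges.iterrows():
        i, j = int(e["i"]), int(e["j"])
        pts = _segment_samples(field, i, j, n_samples)
        vals = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
        rows.append(
            {"i": i, "j": j, "distance": e["distance"], "kind": e["kind"],
             "ridge_mean": float(np.nanmean(vals))}
        )
        # corridor exclusion for the background
        u = c[j] - c[i]
        d = np.hypot(*u)
        u = u / d
        relx, rely = GX - c[i][0], GY - c[i][1]
        t = relx * u[0] + rely * u[1]
        perp = np.abs(-relx * u[1] + rely * u[0])
        excl |= (t >= r) & (t <= d - r) & (perp <= corridor_width / 2.0)

    background = float(np.nanmean(np.where(excl, np.nan, tau)))
    out = pd.DataFrame(rows)
    out["background"] = background
    return out


def principal_alignment(
    field: StressField,
    graph: PairGraph,
    n_samples: int = 200,
    degenerate_rel: float = 1e-3,
) -> pd.DataFrame:
    """Mean angular deviation between θ1 and each edge direction.

    Deviations are folded into [0°, 90°] (orientations, not directions).
    Samples where τ_max is below ``degenerate_rel`` × the domain maximum are
    degenerate (principal direction undefined) and are excluded; their count
    is reported per edge.
    """
    tau_ref = np.nanmax(field.tau_max)
    i_sxx = _grid_interp(field, field.sxx)
    i_syy = _grid_interp(field, field.syy)
    i_sxy = _grid_interp(field, field.sxy)
    c = field.layout.centers

    rows = []
    for _, e in graph.edges.iterrows():
        i, j = int(e["i"]), int(e["j"])
        pts = _segment_samples(field, i, j, n_samples)
        q = np.column_stack([pts[:, 1], pts[:, 0]])
        sxx, syy, sxy = i_sxx(q), i_syy(q), i_sxy(q)
        tau = np.sqrt(((sxx - syy) / 2.0) ** 2 + sxy**2)
        ok = np.isfinite(tau) & (tau > degenerate_rel * tau_ref)
        theta1 = 0.5 * np.degrees(np.arctan2(2.0 * sxy[ok], (sxx - syy)[ok]))
        edge_ang = np.degrees(np.arctan2(c[j][1] - c[i][1], c[j][0] - c[i][0]))
        dev = np.abs((theta1 - edge_ang) % 180.0)
        dev = np.minimum(dev, 180.0 - dev)
        rows.append(
            {"i": i, "j": j, "distance": e["distance"], "kind": e["kind"],
             "mean_deviation_deg": float(dev.mean()) if len(dev) else np.nan,
             "n_degenerate": int(len(tau) - ok.sum())}
        )
    return pd.DataFrame(rows)
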