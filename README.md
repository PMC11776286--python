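# fibremesh

Contracting clusters of cells remodel the collagen I hydrogel around them
over distances of hundreds of micrometers, pulling the fibril matrix into
dense, aligned bundles along the lines connecting neighbouring clusters.
`fibremesh` is a simulation and analysis toolkit for this phenomenon,
aimed at researchers in cell mechanobiology and extracellular-matrix
mechanics. It provides:

* **Micropattern geometry** — the cluster layouts used in such
  experiments (pairs, single polygons from triangles to hexagons, square /
  parallelogram / random arrays of 200 μm circular wells) and their
  pairwise-distance "bundle graphs".
* **Fiber-network simulation** — a coarse-grained 2D bead–spring collagen
  network with jointed cross-links, evolved by overdamped Langevin
  dynamics. Bonds are piecewise harmonic about their rest length l0 with
  tension–compression asymmetry k_t = 100·k_c (fibers resist stretch,
  buckle cheaply); clusters are circles of 83 boundary nodes whose radius
  is shrunk 5% per increment (r = r0·0.95^m); and cross-links remodel
  irreversibly — a bond with |l − l0|/l0 > 0.5 has l0 reset to l, locking
  in the deformed geometry.
* **Continuum stress fields** — a plane-stress finite-element solver for
  the same layouts (fixed outer boundary, inward radial traction on the
  cell edges) producing maximum-shear-stress maps
  τ_max = √(((σxx−σyy)/2)² + σxy²) and first-principal-direction maps
  θ1 = ½·atan2(2σxy, σxx−σyy), whose ridges predict where bundles form.
* **Quantification** — corridor bundle scores (node-density enrichment
  between cluster edges), node force maps, polygon-area stability traces,
  and the fluorescence bundle metric Ratio = S_max/S_min computed from
  averaged intensity profiles across an ROI (7-point peak sum over 7-point
  end sum).
* **Synthetic microscopy** — rendering of simulated networks as
  fluorescence-like images (anti-aliased fiber segments, Gaussian PSF,
  background, Gaussian/Poisson noise, 8/16-bit), with analytic
  ground-truth ridge images for validating the quantification.

## Worked example

Contract a 500 μm cluster pair and quantify the emerging bundle:

```python
from fibremesh.geometry import PatternSpec, make_layout, pair_graph
from fibremesh.netgen import NetworkSpec, build_network, embed_clusters, choose_scale
from fibremesh.dynamics import ContractionSchedule, LangevinParams, RemodelRule, run
from fibremesh.metrics import RectROI, bundle_scores, fl_ratio
from fibremesh.synthmicro import RenderSpec, render

layout = make_layout(PatternSpec(kind="pair", side_spacing=500))
spec = NetworkSpec(rng_seed=1, um_per_unit=choose_scale(layout))
network = embed_clusters(build_network(spec), layout)

traj = run(network,
           schedule=ContractionSchedule(steps_per_increment=2500, n_increments=25),
           rule=RemodelRule(check_interval=250),
           params=LangevinParams(rng_seed=101, timestep=0.2))

graph = pair_graph(layout)
before = bundle_scores(traj.initial["positions"], network, graph)["score"].iloc[0]
after = bundle_scores(traj.final["positions"], network, graph,
                      radius=float(traj.final["radii"][0]))["score"].iloc[0]
print(f"corridor bundle score: {before:.2f} (before) -> {after:.2f} (after)")

image = render(network, positions=traj.final["positions"], spec=RenderSpec(rng_seed=0))
mid = network.cluster_centers.mean(axis=0) * spec.um_per_unit / 2.0
prof = fl_ratio(image, RectROI(center=(mid[0], mid[1]), length=300, width=50,
                               angle_deg=90.0))
print(f"fluorescence ratio across the bundle: {prof.ratio:.2f}")
```

Output:

```
corridor bundle score: 1.38 (before) -> 1.65 (after)
fluorescence ratio across the bundle: 2.07
```

The corridor between the clusters (a rectangle one cluster-radius wide
between the current cluster edges) starts at a density ratio near 1 —
this seed happens to start high; the seed average is ≈1 — and becomes
significantly enriched after contraction, and the rendered image shows a
bright fiber bundle along the connecting line: the profile across it
yields an S_max/S_min ratio of 2.07 against ≈1.0 for a uniform field.
Rankings across geometries behave as expected: with two pairs at
500/1000 μm the close partners bundle, not the distant ones, and in
600 μm hexagons the sides bundle while the 1200 μm diagonals do not.

The same workflow is scriptable from the shell:

```sh
fibremesh layout --kind hexagon --spacing 600 --out layout.csv
fibremesh pipeline --config config.yaml --out runs/hex --set schedule.n_increments=25
fibremesh compare runs/* --out comparison.csv
```

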