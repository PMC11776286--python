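# Methods

`fibremesh` models how micropatterned clusters of contractile cells remodel
the collagen I hydrogel around them into anisotropic fiber bundles, and
provides the quantification used to compare simulated and imaged outcomes.
This note documents the model, its parameters, the numerical choices, and
what the synthetic tests do and do not establish about real data.

## Pattern geometry

Cell clusters occupy circular wells of 200 μm diameter arranged in named
geometries: a single pair (500 μm default center spacing), single regular
polygons from triangle to hexagon (600 μm sides), square and parallelogram
arrays (800 μm spacing), and random arrays. The single "parallelogram" is a
60° rhombus, the unique rhombus whose short diagonal equals its side, so a
600 μm-sided unit also has a 600 μm diagonal. The pentagon is regular; its
diagonal is φ·side ≈ 971 μm for 600 μm sides. Random arrays are placed by
rejection sampling: every accepted center is at least `min_sep` (600 μm)
from all others and within `max_sep` (1000 μm) of at least one neighbour.
Requiring *all* pairwise separations to stay below `max_sep` would bound
the whole pattern inside a 1000 μm disk and is geometrically infeasible
beyond ~5 clusters, so the upper bound is enforced as a nearest-neighbour
(connectivity) constraint, matching how neighbour spacing is controlled in
the micropatterning protocol.

The pair graph of a layout classifies every cluster pair as `side`
(shortest distance class), `diagonal` (longer within-polygon / within-unit
edges), or `inter-unit`. Bundles are predicted along side edges.

## Fiber network

Collagen fibers are bead–spring chains: beads every 0.5 units, straight at
birth, with uniformly random midpoint and orientation. Where beads of two
*different* fibers fall within the merge radius (0.15 units) they are
merged into a single jointed node — a cross-link that transmits force
between fibers. Rest lengths are set to as-built geometry, so a fresh
network is stress-free. Defaults: a 60×60-unit domain with 200 fibers of
length 20 per core-domain area (≈3 cross-link incidences per fiber).
Fiber length matters qualitatively: fibers must be comparable to or longer
than the inter-cluster gap (~12 units for the 500 μm pair) for tension
chords connecting two clusters to exist; with much shorter fibers the
network responds as an unstructured elastic blob and no bundles form.

Midpoints are sampled in a box enlarged by half a fiber length so bead
density is uniform across the analysis domain. Beads that land outside the
core domain are *pinned* (immobile): they represent the hydrogel surround
anchored in the dish, the discrete counterpart of the fixed outer boundary
in the continuum model. Anchoring is essential — a free-floating network
simply translates inward under contraction and develops no inter-cluster
anisotropy.

Layouts (μm) map into the simulation frame through a single scale,
25 μm/unit by default. `choose_scale` coarsens this in 5 μm steps until
the pattern's bounding circle stays within 45% of the domain half-extent
(e.g. 30 μm/unit for 600 μm hexagons), keeping contracting clusters clear
of the anchored rim where boundary artifacts dominate.

Each cluster is a circle of 83 boundary nodes. Cell nodes are tethered to
their nearest matrix node within 2× the segment rest length; tethering
adds no stress.

## Dynamics

Matrix nodes obey first-order overdamped Langevin dynamics,
`dx = (F/γ)dt + sqrt(2kT dt/γ) ξ`, the relevant regime for
hydrogel-embedded fibers. Bonds are piecewise harmonic about their rest
length with tensile stiffness 100× the compressive stiffness
(k_t = 1, k_c = 0.01 in reduced units): fibers resist stretch and buckle
cheaply. The explicit Euler–Maruyama step is stable for
dt < 2γ/k_t; dt = 0.05 by default, 0.2 in the desk-scale runs (validated
against the single-bond closed form). Thermal energy defaults to
kT = 1e-5, far below the bond energy scale ½k_t l0²; at 1e-4 and above,
noise alone drives spurious buckling-remodeling events, contradicting the
intent that plasticity be contraction-driven.

Cell nodes are position-prescribed: every increment the cluster radius
shrinks by 5% and cell nodes move radially onto the new circle
(r = r0·0.95^m after m increments). The production schedule runs 50,000
integration steps per increment; desk-scale runs use 2,500 steps at
dt = 0.2, which is quasi-static at the network's relaxation time.

Remodeling is irreversible rest-length plasticity: every 1,000 steps (250
in desk-scale runs) any fiber bond whose strain relative to its rest
length exceeds 50% has its rest length reset to the current length,
zeroing its stored energy. Cell–matrix tethers are excluded (switchable):
they are short, cross the threshold on the first increment, and resetting
them silently detaches the cells from the matrix. Total contraction
defaults to 25 increments (radius → 28% of initial). This depth is not
cosmetic: at ≤10 increments the peak strain anywhere in the network stays
below the 50% threshold and *no* remodeling occurs at zero temperature, so
the plastic mechanism never engages; at 25 increments the near-cluster
region remodels extensively and deformation ratchets outward.

Under these conditions a contracted pair run reproduces the expected
phenomenology: a thin (≈2–4 unit, i.e. 50–100 μm) straight bundle of
fibers along the line connecting the clusters, radial spokes around each
cluster, elevated bond tension in the corridor, and corridor node-density
enrichment that grows with contraction.

## Continuum stress field

The plane-stress solver treats the gel as an isotropic linear elastic
plate (E normalized to 1, ν = 0.3) with circular holes at the clusters,
u = 0 on the outer square boundary, and uniform radial traction on each
hole edge pointing toward the cluster center (the contracting cells pull
the matrix inward). Stress patterns are traction- and E-independent up to
scale; `StressField.normalized()` applies the max-τ normalization
convention.

Discretization: constant-strain triangles on a Delaunay mesh of a
structured point cloud in which grid points within 0.7h of a circle are
replaced by uniformly spaced points lying exactly on the circle, so holes
are inscribed polygons and no sliver or inverted element can occur. (An
earlier snap-nodes-to-circle variant tangled elements at some resolutions
and converged erratically; the Delaunay construction reproduces the
pressurized-hole closed form to <0.5% at h = a/8.) Elements must resolve
the cluster radius with ≥8 cells, enforced. Nodal stresses are
area-weighted element averages, interpolated to a regular output grid and
masked inside the holes.

Derived maps: maximum shear stress τ_max = √(((σxx−σyy)/2)² + σxy²) and
first principal direction θ1 = ½·atan2(2σxy, σxx−σyy) ∈ (−90°, 90°].
`ridge_profile` samples mean τ_max on the open segment between two cluster
edges and compares it with the domain mean outside all corridors and
disks; `principal_alignment` reports the mean angular deviation (folded
into [0°, 90°]) between θ1 and each edge direction, excluding samples
where τ_max is below 1e-3 of the domain maximum (principal directions are
undefined in hydrostatic regions; such samples are counted, not averaged).

## Bundle quantification

*Corridor score.* Matrix-node density inside the rectangular corridor
between two cluster edges divided by the density outside all corridors
and cluster disks. Corridor width defaults to one cluster radius (100 μm),
the measured transverse extent of simulated bundles. For contracted
states the corridor is taken between the *current* cluster edges, since
accreted material at the shrunken rim is part of the bundle. The score is
≈1 for an isotropic network, with substantial seed-to-seed variance
(beads are correlated along fibers, so corridor counts fluctuate far more
than Poisson); ordering claims are therefore made on seed averages over 5
replicates.

*Fluorescence ratio.* For images, an averaged intensity profile is taken
across a rectangular ROI whose axis crosses the bundle, and
Ratio = S_max/S_min, where S_max is the maximal sum of 7 consecutive
profile samples and S_min sums 7 end samples (4 from the left end, 3 from
the right — a fixed, test-pinned convention). The max-window form of
S_max is equivalent to centering on the peak for a clean unimodal profile
but is unbiased for noisy flat-topped ridges, where a plain argmax drifts
to plateau edges. A uniform image gives exactly 1.0; a flat-topped ridge
of amplitude A on baseline B gives exactly (B+A)/B.

*Stability.* Pattern shrinkage is traced as remaining polygon area,
100·A(t)/A(0), using shoelace areas of the polygon through each cluster's
far-side boundary point, which contracts monotonically with the schedule.

## Synthetic microscopy

Rendered images emulate fluorescently labeled collagen: bonds drawn as
anti-aliased segments with intensity proportional to physical fiber length
(50 counts/μm default), Gaussian PSF (1 px), uniform background (20
counts), additive Gaussian noise (σ = 2% of the 8-bit range) or Poisson
noise, quantized to 8/16-bit at 2 μm/px. Ground-truth ridge images with
analytically known ratios exercise the quantification end to end. Not
emulated: optical sectioning, photobleaching, illumination drift, and the
out-of-focus background structure of real gels — so passing image tests
validates the measurement pipeline, not robustness to real microscopy
artifacts.

## What desk-scale agreement does and does not show

The simulations here run on ~10⁴-node networks with shortened relaxation
blocks and are compared through seed-averaged *orderings* (pair corridor
enriched; near pairs beat far pairs; hexagon sides beat long diagonals),
plus exact worked examples and the Lamé oracle for the continuum solver.
Published fluorescence ratios and area percentages are wet-lab
measurements and are not reproduced quantitatively. The model contains no
cell migration, mechanosensing feedback, 3D structure, fiber bending
stiffness, or new bond formation; bundle *maintenance* and long-time
stability are outside its scope.
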