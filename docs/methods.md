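# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `cartmorph`, and what the synthetic validation does and does
not demonstrate.

## Coordinate conventions

All meshes are in millimetres.  The working frame is a left-knee
convention: +x medial, +y anterior, +z proximal.  Right-sided models are
mirrored in the sagittal plane x = 0 on load (winding flipped so outward
normals stay outward); a `side` flag in the cohort manifest records which
models were mirrored so the stored files remain "as scanned".

## Synthetic cohort generator

**Base shape.**  The base surface is a surface of revolution about the
mediolateral (x) axis with radial profile

r(x) = r₀ + h·[G(x; +c, w) + G(x; −c, w)] − g·G(x; 0, w_g),

where G is a unit Gaussian bump, c is the condylar half-separation, h/w the
lobe height/width and g/w_g the groove depth/width.  This is a deliberate
idealisation, not an anatomical atlas: what matters is that the geometry is
*exactly aligned with the measurement construction*.  A plane perpendicular
to the axis cuts the surface in a circle of radius r(x) (always convex);
a plane containing the axis cuts it in the profile curve with signed
curvature radius −(1 + r′²)^{3/2}/r″ (convex + on the lobes, concave − in
the groove).  Probe-point ground truth is therefore closed-form, and an
independent finite-difference oracle checks it in the tests.

Defaults (chosen once for anatomical plausibility): condyle radius 22 mm,
separation 46 mm, groove depth 5 mm, lobe height 3 mm / width 8 mm, groove
width 9 mm, AP arc 60 mm, ML width 80 mm.  These give apex section radii of
≈ 21.8 mm (AP) and ≈ +16.8 mm (ML) and groove radii of ≈ +14.1 / −13.8 mm —
the same order as condylar and trochlear radii reported for adult knees.

**Planted variation.**  Deformation fields are fixed low-order
trigonometric scalars times the surface normal, first projected orthogonal
to the six infinitesimal rigid motions of the base shape (otherwise
Procrustes alignment absorbs part of the planted variance), then
orthonormalised.  Mode coefficients are N(0, σᵢ²) with default σ =
(2, 1, 0.5) mm; vertex noise is isotropic N(0, 0.05 mm); each model gets a
random rigid transform (5° / 5 mm SD) and a 50 % chance of being
right-sided (mirrored before export).

**Defects.**  Defect centres scatter around a medial-condyle hotspot
(5 mm SD); areas are log-normal around a 270 mm² median (log-SD 0.60) and
aspect ratios log-normal around 1.6 (log-SD 0.25), matching the strictly
positive, right-skewed size distributions seen clinically.  The defect mesh
is the elliptical patch of native faces around the centre (major axis AP),
extruded 2 mm inward; its articulating faces are labelled and listed first,
so a manifest column is enough to recover the mask after I/O.

**What the generator does not emulate:** segmentation error structure,
cartilage thickness variation, anatomical asymmetry between condyles,
multi-region hotspots, and defects that straddle region boundaries.
Passing tests demonstrate correctness of the estimators under known truth,
not clinical accuracy on patient imaging.

## Correspondence

Rigid ICP uses closest-point matching against target vertices + face
centroids with Kabsch updates, after centroid pre-alignment; the residual
history is non-increasing.  Non-rigid correspondence is a locally affine,
stiffness-relaxed ICP: per-vertex 3×4 affines X minimise
‖W(DX − U)‖² + α²‖(M ⊗ G)X‖² with M the edge incidence matrix,
G = diag(1,1,1,γ), γ = 1, and α relaxed over 8 levels (50 → 0.4), up to 10
inner iterations per level, convergence tolerance 1e-4.  Matches are
rejected when source/target normals differ by > 60° or distance exceeds
10 mean edge lengths, and matches landing on the target boundary are
flagged invalid rather than extrapolated.  These defaults are package
choices; they are exposed as estimator parameters.

When all cohort members already share the reference topology (always true
for generated cohorts), the pipeline's `correspondence: auto` mode skips
the non-rigid stage — the shapes are already corresponded and GPA handles
pose — which keeps end-to-end runs fast without changing any downstream
result.  `full` forces registration, as needed for externally supplied
mesh directories.

## Shape model

GPA iterates centering, rotation to the current mean (orthogonal
Procrustes) and mean recomputation to a 1e-9 mm tolerance.  Scaling is OFF
for model construction (cartilage size is retained as real variation) and
ON for heat-map alignment, where each native model is similarity-fitted to
the mean shape in closed form.  The GPA mean is defined only up to a global
rotation (the gauge inherits from the first shape); invariance statements
about the mean are therefore evaluated after a closed-form rigid Procrustes
alignment of one mean onto the other.

PCA is computed by thin SVD of the centred k×3m matrix (k ≪ 3m).  Modes are
dropped when their variance falls below 1e-12 of the leading mode, with an
absolute floor tied to the mean-shape scale so an all-identical cohort
yields q = 0.  Sampling truncates coefficients at ±3√λ to avoid implausible
extrapolation (configurable).  Evaluation: compactness is the cumulative
variance fraction; accuracy the training-shape reconstruction RMS (vertex
distance) versus mode count; generalisation the leave-one-out analogue —
LOO was chosen because the cohort sizes involved make held-out splits
wasteful.

AP length is the distance from the most anterior vertex to the line joining
the most posterior vertex of each condyle; ML width is the x-extent between
the most medial vertex of the medial condyle and the most lateral of the
lateral (coordinate extent resolves the tie among equally extreme points).

## Defect metrics and heat map

The defect major axis is the diameter (maximum pairwise distance) of the
articulating vertices — convex-hull accelerated with an exact O(n²) scan as
oracle and fallback.  The minor length is the diameter of the projection of
those vertices onto the plane perpendicular to the major axis, i.e. the
maximal extent over all perpendicular directions; for near-planar defects
this reduces to "the most distant points in the perpendicular direction".
Collinear sets are flagged degenerate.  Measurement uses articulating
vertices only by default (the extruded walls are reconstruction artefacts);
a flag widens it to all vertices.

"Overlap" for the heat map is explicit: a defect counts at a mean-shape
vertex when the unsigned closest-point distance from the vertex to the
defect's articulating surface is ≤ τ, default 1.0 mm (the coarsest voxel
dimension of typical knee MRI).  Distances are exact point-to-triangle
values, computed with a KD-tree band prefilter.  Counts are integer,
order-invariant and monotone in τ.  Because the similarity scale is
transferred verbatim from the native alignment, defect footprints are
scaled by the same factor; reports retain the per-model scales so the
distortion is inspectable.  Per-region maps are obtained by masking the
mean shape's labels; vertices outside the region are still reported,
flagged `in_region = 0`.

## Radii of curvature

The cylinder fit minimises Σ(distance-to-axis − r)², seeded from each
principal axis of the point covariance and refined by trust-region least
squares; the best seed wins, making the fit deterministic.  A fit is
flagged ill-conditioned when the RMS residual exceeds 2 % of the radius or
the Jacobian condition number exceeds 1e8 (spheres and planes trip this).

Circle fitting is a Pratt algebraic fit refined by geometric Gauss–Newton.
`fit_circle_in_plane` projects its input orthogonally into the plane first.
`measure_roc` feeds it the *section* of the elliptical patch by each plane
(mesh–plane intersection points) rather than the projection of the whole
patch: projecting a 3-D patch thickens the curve by O(R·Δθ²) and biases the
radius by several percent at the default patch size, while the section is
the curve the radius is defined on.  The signed radius is positive when the
fitted centre lies on the inward (anti-normal, bone) side of the surface at
the probe — convex — and negative otherwise.  Radii above 500 mm, or
degenerate fits (collinear sections, e.g. a cylinder cut along its axis),
are reported as flat rather than as huge signed numbers.

The elliptical region of interest defaults to area 2.70 cm² with aspect
ratio 1.70 (full axes 24.2 × 14.2 mm), major axis along AP.  Note that a
2.70 cm² ellipse with aspect 1.6 would have axes 23.5 × 14.7 mm; the
package takes (area, aspect) as explicit inputs and uses the internally
consistent (2.70 cm², 1.70) pairing as its default.  Membership is decided
in the probe's tangent frame (AP tangent = intersection of the AP plane
with the tangent plane), then restricted to the connected component
containing the probe; geodesic discs are out of scope.  Patches clipped by
the mesh boundary carry a flag.  The finite patch averages curvature over
its extent: on the synthetic condyle the ML radius error decreases
monotonically from ≈ 17 % at 2.7 cm² to < 5 % at 0.5 cm², while AP radii
are exact at all sizes (the sections are true circles); the torus saddle
fixture is exact in both planes by construction.

Probe points are placed equally spaced in arc length along the AP section
through the anchor; the anchor is the heat-map argmax vertex (condyle
mode) or a user-supplied point (trochlea mode — hotspot data there is
typically too sparse, so the anchor is an explicit input).  Default spacing
is half the patch major axis, shrunk when the available arc is shorter;
regions with zero defect coverage get no probes, since an argmax over an
all-zero count field would be arbitrary.

## Pipeline and determinism

`run_pipeline` executes simulate → correspond → GPA/SSM → sample → heat map
→ defect metrics → curvature, writing every artefact as PLY/CSV/JSON plus a
run report with versions, seed and stage timings.  Quartiles everywhere use
the linear-interpolation definition (stated in the output metadata).  All
randomness derives from the single run seed through named, CRC-keyed child
seeds; two runs with the same configuration are byte-identical (verified in
the tests down to mesh file bytes).  Default problem sizes in the test
suite are scaled down (cohorts of 6–70 meshes of ~500–2300 vertices,
populations of 6–200) — chosen so the whole suite and the demo runs execute
in well under a minute each while keeping k = 70 where sampling-error
claims depend on it.

## Known limitations

- Correspondence quality is only validated against same-topology synthetic
  targets; re-meshed or partially scanned inputs exercise the gating but
  have no ground truth here.
- The finite-patch curvature bias is inherent to the region-of-interest
  definition, not an estimator defect; comparisons between studies must
  match patch areas.
- The heat map applies no surface smoothing or significance testing; single
  vertices decide the argmax in flat count fields.
- The synthetic trochlea spans the full AP arc of the sheet (a modelling
  convenience); probes there rely on user anchors, as in practice.
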