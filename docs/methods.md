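# Methods

`cartstrain` quantifies exercise-induced compressive strain in glenohumeral
articular cartilage from segmented MRI contour stacks, and validates every
stage of that pipeline by parameter recovery on a synthetic shoulder
phantom with exact ground truth. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## The measurement model

Articular cartilage is biphasic: sustained load expresses interstitial
fluid, thinning the tissue, and the thickness recovers over tens of
minutes after unloading. Imaging a joint immediately before and after
exercise therefore captures a measurable compressive deformation.
The pipeline mirrors the established MRI-based workflow for this
measurement:

1. **Segmentation contours** — per axial slice (0.5 mm apart), ordered
   point lists for the humeral and glenoid bony cortices and cartilage
   articular surfaces, at ~0.3 mm in-plane point density. These are the
   pipeline input; the package does not touch image intensities.
2. **Surface reconstruction** — contours of one tissue are lofted into a
   triangulated surface (details below).
3. **Bone registration** — each post-exercise bone surface is rigidly
   aligned to its pre-exercise counterpart by point-to-point ICP, so that
   cartilage can be compared site-specifically on a common bone frame.
   Bones are registered independently; cartilage never participates in
   matching.
4. **Thickness maps** — thickness at a bone vertex is the Euclidean
   distance to the *nearest vertex* of the corresponding cartilage outer
   (articular) surface. The cartilage footprint is the set of bone
   vertices whose nearest cartilage vertex lies within a 5 mm cutoff and
   in front of the outward surface normal (positive dot product). The
   cutoff only needs to exceed the largest plausible cartilage thickness
   (~2 mm) with a safety margin; results are insensitive to it inside a
   wide band. A point-to-triangle distance refinement exists behind
   `ThicknessConfig(use_point_to_triangle=True)` (default off) for
   sensitivity analysis; on the phantoms the two definitions agree within
   one cartilage mesh edge length.
5. **Regional sampling** — thickness is averaged within 2-mm-radius
   regions: a 3x3 grid on the glenoid (anterior/central/posterior x
   superior/central/inferior) and 18 regions on the humeral head, laid
   out as 2 superoinferior bands of 3x3. Region centres sit at the
   20/50/80% quantiles of the footprint's anteroposterior and
   superoinferior coordinates (per band for the humeral head), snapped to
   the nearest footprint vertex. Quantile placement adapts the evenly
   spread grid to the footprint shape deterministically; the humeral
   layout can be overridden with an explicit table, since the 18-region
   arrangement is an interpretation of the two-band presentation of such
   grids rather than a published construction rule. Regions may overlap
   on small footprints (a warning is logged); vertices may contribute to
   several regions.
6. **Strain** — per region, `strain = (t_pre - t_post) / t_pre`, positive
   in compression. Compartmental strain is the unweighted mean of the
   regional strains; the strain of compartment-mean thicknesses is also
   reported, clearly labeled, because summary arithmetic on printed mean
   thicknesses corresponds to the latter. Cross-subject summaries are
   mean ± t-distribution 95% CI.
7. **Statistics** — one-way within-subject (repeated-measures) ANOVA with
   `F = MS_factor / MS_(factor x subject)`; regions sharing a factor level
   are averaged within subject first (e.g. three anterior glenoid regions
   into one anterior value). Tukey post hoc comparisons use the
   studentized range on the same within-subject error term. An
   uncorrected p is primary; a Greenhouse–Geisser corrected p is emitted
   alongside, labeled, for sphericity-sensitive readers. Pearson
   correlations (two-sided t test) relate per-subject covariates such as
   BMI or body weight to compartment strain.

### Anatomical frame

Axes are fitted from the bone surface itself: the mediolateral axis is
the direction from the patch centroid to the centre of a least-squares
sphere fit (for the concave glenoid that centre lies on the joint side;
for the convex humeral head it lies behind the bone — the same formula
gives the lateral direction in both cases). The superoinferior axis is
the footprint's in-plane principal axis (superior chosen toward +z), and
anteroposterior completes the frame, with the anterior sign set by
laterality: left shoulders mirror the anteroposterior axis. A footprint
whose in-plane principal axes are isotropic within 1% is rejected as
orientationally ambiguous.

## Surface reconstruction by lofting

Adjacent contours of one tissue are resampled to a common point count by
arc length, corresponded (cyclic-shift alignment minimizing summed squared
distance for closed rings; endpoint alignment for open arcs), and stitched
with triangle strips. Closed stacks are capped with a fan whose apex
extrapolates the osculating sphere of the last two rings — exact when a
spherical end is sliced short of its pole — falling back to a planar
centroid cap for cylinder-like ends. One intermediate ring is interpolated
between slices by default (`z_subdivisions=1`), making the ~0.25 mm
vertex spacing along z commensurate with the ~0.3 mm in-plane spacing;
the nearest-vertex thickness bias grows with the square of the largest
vertex gap, so isotropic sampling minimizes it.

Lofting was chosen over signed-distance rasterization plus isosurface
extraction because the cartilage surfaces are open sheets: a distance
isosurface either tubes an open arc or requires closure and trimming that
leaves rim artifacts comparable to the tolerances of interest, whereas
loft vertices lie exactly on the input contours, so no systematic offset
enters the thickness maps. The cost is that branching contours (multiple
same-label contours in one slice) are not supported; they do not occur
for these anatomies.

Reconstruction accuracy on a noiselessly sliced 10 mm sphere
(0.5 mm slices, 0.3 mm points): every surface point within 0.15 mm of the
sphere, area within 0.2% of 4πr²; the error decreases under mesh
refinement and the operation is rigid-equivariant to 1e-6 mm.

## Registration details

Point-to-point ICP with nearest-neighbour matching via a KD-tree and a
closed-form Kabsch (SVD) update per iteration; vertices are subsampled by
a deterministic stride to at most 20 000 points. Initialization aligns
centroids, and principal axes when the eigenvalue spread exceeds 5%
(all four sign combinations with det +1 are scored by starting residual;
near-isotropic shapes start from the identity rotation, which is the
right default when the two sessions share an approximate pose).
Convergence is declared when the rms residual changes by less than
1e-4 mm, with a 100-iteration cap; failure to converge is reported in the
`RegistrationReport`, not raised. The per-iteration rms trace is
non-increasing. On noiseless phantom bones a known 5°/3 mm offset is
recovered to ~1e-6, and with 0.04 mm vertex noise to well under
0.2°/0.05 mm; the convergence basin comfortably covers 15° and 10 mm
initial misalignment.

## The synthetic phantom

The phantom stands in for the study cohort (no imaging data are
deposited) and is engineered so that every recovered quantity has an
exact ground truth.

* **Geometry.** Humeral head: spherical cap, radius 24 mm, half-angle
  60°. Glenoid: shallow spherical socket, radius of curvature 30 mm,
  elliptical footprint 35 mm (superoinferior) x 25 mm (anteroposterior).
  These dimensions are literature-typical adult values and configurable;
  they are not fitted to any cohort. Both bone surfaces carry a fixed
  ~2% low-order radial asphericity (a quadratic-plus-cubic polynomial in
  the direction components) because a perfect sphere leaves ICP rotation
  unconstrained about its centre — a degeneracy real bones do not have.
  The asphericity breaks every rotational and 180° symmetry.
* **Cartilage.** The outer surface offsets the bone radially by a
  thickness field: humeral default constant 1.0 mm; glenoid default
  1.2 mm at the centre rising quadratically to 1.5 mm at the
  anteroinferior rim (periphery everywhere thicker than the centre, with
  an anteroinferior directional bias). With 2% asphericity the
  radial-versus-normal offset discrepancy is second order (<0.002 mm).
* **Deformation.** The post-exercise session scales thickness pointwise
  by `1 - strain`, where the strain field is constant, linear in the
  anatomical coordinates, radial, or piecewise-constant per third (a 3x3
  glenoid or 2x(3x3) humeral target table whose third boundaries sit at
  the 35/65% footprint coordinate quantiles — midway between the grid's
  region-centre quantiles, so 2-mm sampling disks never straddle an
  imposed boundary). The whole post scene is then moved by a configurable
  rigid offset (experiments use 5° / 3 mm).
* **Contours and noise.** Scenes are sectioned by the exact analytic
  surface (vectorized bisection on the radial parameterization; points on
  the surface to solver precision, ~1e-7 mm), resampled at ~0.3 mm, with
  independent zero-mean Gaussian displacement of SD 0.04 mm applied per
  point along the in-plane contour normal — the segmentation-level
  repeatability of the manual process being emulated. Plain meshes
  without an analytic source are sectioned through trimesh. All noise
  derives from explicit seeds; identical seed and spec give bit-identical
  stacks.

**What the phantom does not emulate:** image intensities and their
artifacts (partial volume, banding), reader bias that is spatially
correlated across slices or sessions, anatomical variation beyond the
configurable dimensions (no labrum, no rotator cuff, no true humeral
shaft), and non-rigid inter-session changes other than the imposed
cartilage deformation. Passing recovery tests therefore demonstrates the
correctness and numerical stability of the geometry-processing chain at
realistic noise and resolution — not the accuracy of manual segmentation
on real images.

## Known numerical behaviour

* The nearest-vertex thickness definition is biased upward by
  ~`g²/(8t)` for vertex gap `g` and thickness `t`; because the bias is
  larger for the thinner post-exercise cartilage, recovered strain runs
  ~0.3–0.6 percentage points below the imposed value on the humeral head
  (recovered ≈16.5% for an imposed 17%). This is inherent to the stated
  distance definition at the stated resolutions, well inside the ±1.5
  percentage-point recovery tolerance, and shrinks quadratically with
  mesh refinement (`z_subdivisions`).
* Regional (single-region, single-subject) strains at 0.04 mm contour
  noise scatter by roughly ±1 percentage point; compartment means and
  seed averages are stable to a few tenths.
* Degenerate near-tangent sections (e.g. a slice plane grazing a pole)
  are dropped rather than emitted as micro-contours.
* All computations are deterministic given seeds; region placement,
  correspondence and subsampling use no randomness at all.

## Problem sizes

Validation experiments run the full pipeline at the study's stated
resolutions (0.5 mm slices, 0.3 mm points, 0.04 mm noise): a glenoid-only
subject is ~22 000 contour points per session, a humeral-only subject
~50 000. Recovery experiments average 5 independent noise/pose seeds
(8 for the cohort-level ANOVA experiment), sizes chosen to keep the whole
validation suite in the minutes range on one CPU while leaving the
recovery tolerances comfortably resolvable.
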