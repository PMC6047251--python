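# cartstrain

Site-specific measurement of exercise-induced glenohumeral articular
cartilage strain from segmented MRI contour stacks.

Articular cartilage is biphasic: joint loading expresses interstitial
fluid and thins the tissue, which recovers only over tens of minutes.
Imaging a shoulder immediately before and after loaded exercise therefore
captures a measurable compressive deformation. `cartstrain` implements
the full analysis chain for that measurement:

* **reconstruction** of triangulated humeral-head and glenoid bone and
  cartilage surfaces from labeled per-slice segmentation contours,
* **rigid registration** of the post-exercise bony surfaces onto the
  pre-exercise ones (point-to-point ICP, Kabsch updates), so cartilage is
  compared at the same anatomical sites,
* **thickness maps** t(v) on the bone surface — the distance from each
  bone vertex to the nearest vertex of the cartilage articular surface,
* **regional aggregation** in 2-mm-radius sampling regions
  (18 on the humeral head, 9 on the glenoid, labeled
  anterior/central/posterior x superior/central/inferior), and
* **compressive strain** per region,

      eps = (t_pre - t_post) / t_pre,

  summarized per compartment as mean ± 95% CI across subjects, with
  repeated-measures ANOVAs along the anatomical axes, Tukey post hoc
  tests, and Pearson correlations against subject covariates.

Because no imaging data accompany the underlying study design, the
package ships a first-class **synthetic shoulder phantom**
(`cartstrain.phantom`): spherical-cap humeral head and shallow-socket
glenoid with configurable thickness and strain fields, segmentation-level
Gaussian contour noise (SD 0.04 mm), and a rigid inter-session offset —
all with exact ground truth, so every pipeline stage is verifiable by
parameter recovery. See `docs/methods.md` for the models and numerical
choices.

## Worked example

Recover an imposed uniform 15% glenoid strain through the whole pipeline
(phantom → noisy contours → reconstruction → ICP → thickness → regions):

```python
from cartstrain import PhantomSpec, RigidTransform
from cartstrain.pipeline import RunConfig, phantom_subject_stacks, run_subject

spec = PhantomSpec(
    compartments=("glenoid",),
    glenoid_strain_field=0.15,                       # uniform 15% compression
    rigid_offset=RigidTransform.from_axis_angle(     # unknown pose change
        [0.2, 0.7, 1.0], 5.0, [2.0, 1.0, 0.5]),      # 5 deg, ~2.3 mm
    seed=21,
)
pre, post, truth = phantom_subject_stacks(spec, subject="demo", seed=21)
res = run_subject(pre, post, RunConfig(compartments=("glenoid",)))

pre_t = res.pre_region_means["glenoid"].mean_thickness_mm
post_t = res.post_region_means["glenoid"].mean_thickness_mm
strain = (pre_t - post_t) / pre_t
print(f"mean pre-exercise thickness: {pre_t.mean():.2f} mm")
print(f"recovered compartment strain: {100 * strain.mean():.1f} %")
print(f"ICP residual: {res.registrations['glenoid'].rms_residual:.3f} mm")
```

Output:

```
mean pre-exercise thickness: 1.29 mm
recovered compartment strain: 15.3 %
ICP residual: 0.109 mm
```

The 1.29 mm mean reflects the phantom's default baseline pattern (1.2 mm
central glenoid thickness rising to 1.5 mm at the anteroinferior rim),
and the recovered compartment strain matches the imposed 15% despite
contour noise and the unknown pose offset.

A command-line interface covers the same stages
(`cartstrain simulate | reconstruct | register | thickness | strain |
stats | run-cohort`); meshes are exchanged as PLY/OBJ/STL (PLY carries a
per-vertex `thickness_mm` channel) and contour stacks as documented JSON.

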