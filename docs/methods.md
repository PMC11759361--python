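# Methods

This note documents the models, conventions and numerical choices behind
`axonwrap`, and what the synthetic-data validation does and does not show
about real data.

## Data model and conventions

Voxel arrays are indexed `(channel, z, y, x)`, z index 0 being the first
acquired slice; coordinates are 0-based with pixel centers at integer
positions. Physical calibration (in-plane pixel size, µm/px, and axial
step, µm) travels with the array and survives TIFF round trips inside the
file's shaped description. Explicit calibration arguments always override
file metadata (with a logged warning): exported TIFFs routinely lack or
corrupt physical metadata, and silent disagreement is worse than a
deliberate override. Both 8- and 16-bit integer and 32-bit float inputs
are accepted; NaN voxels are rejected at write time.

## Wrapping quantification

**Outline and coverage.** For every pillar cross-section the external
1-pixel outline is the set of pixels 8-adjacent to the cross-section but
not inside it (pure set algebra, no image-boundary clipping; off-image
outline pixels simply count as uncovered). A slice's coverage is the
fraction of outline pixels whose `(2r+1)`-square neighborhood intersects
the myelin mask, with contact radius `r = 1` px by default: this tolerates
one pixel of thresholding erosion without crediting MBP+ cell bodies lying
farther from the pillar wall. An angular-bin variant (36 bins) is provided
for cross-checking but is not the scored quantity.

**Classification.** Sheath segments are maximal runs of adjacent slices
with coverage strictly above θc = 0.8. A run of n slices has length
n·Δz — each slice owns one z-step of height — so with Δz = 2 µm the
strict "> 6 µm" rule requires at least 4 adjacent qualifying slices. The
alternative (n−1)·Δz convention is selectable (`length_convention="gaps"`)
but non-default. Both thresholds are strict inequalities. The wrapping
index divides the fully-wrapped count by the nuclei count; a field with
zero countable nuclei has no defined WI and is flagged and excluded from
aggregation rather than imputed as zero.

**Measurement bias.** On a ~10 µm pillar at 0.31 µm/px the outline has
~100 pixels, so coverage is quantized at ~0.01 and the contact-radius
dilation adds roughly +2/(π·d_px) ≈ +0.02 at arc endpoints. The effective
decision boundary therefore sits at a true coverage of ~0.78 rather than
exactly 0.80. Coverage within ~±0.03 of the threshold is inherently
undecidable at this resolution — a limitation shared by any
outline-counting implementation, not a defect of this one.

## Thresholding

The public thresholding operation defaults to Otsu computed once on the
pooled 3-D histogram (never per slice), with `fixed:<v>` available per
channel. The end-to-end pipeline, however, thresholds the *sparse*
channels (myelin, nuclei) with a robust background rule,
`median + 6·1.4826·MAD`: when a field contains little or no myelin, Otsu's
two-class criterion collapses onto the noise distribution and labels
roughly half the voxels as foreground, which would classify every pillar
as wrapped. The MAD rule agrees with Otsu when signal is present and
degrades gracefully to an empty mask when it is not (a 6-sigma detection
limit). The dense, strongly bimodal axon channel keeps Otsu.

## Segmentation

Pillars are per-slice 8-connected components (≥ 30 px by default), linked
across adjacent slices by greedy nearest-centroid matching within a 10 px
default gate (half the minimum 20 µm array pitch at 0.31 µm/px is ~32 px,
so the gate is conservative). No split/merge handling is attempted:
pillars are printed at ≥ 20 µm pitch and cannot touch. Traces seen in
fewer than half the slices are dropped as debris (pillars span the full
imaged height); traces touching the image border are excluded by default.
Output ordering is deterministic (first slice, then centroid row-major).
Excluded pillars enter neither the pillar count nor the WI.

Nuclei are counted on the z maximum projection by plain component
labeling with a minimum area equal to a 4 µm disk; no watershed splitting
is attempted, because the WI normalizes by a plain count and clump
splitting would add a tunable step for marginal benefit. Pillar diameter
is the equivalent-circle diameter `2·√(A/π)` at the median per-slice area.

## Hertzian contact fitting

The spherical Hertz model `F = (4/3)·E/(1−ν²)·√R·(δ−δ₀)^{3/2}` is fit
over effective depths in (0, 200 nm]; the shallow-indentation cutoff keeps
the half-space assumption defensible for micron-scale hydrogel structures.
ν = 0.5 (incompressible hydrogel) is the default, reported with every fit,
and exposed as a parameter, since the measured modulus scales with
1/(1−ν²). At fixed contact point the model is **linear** in E, so the
least-squares modulus is solved in closed form on the native scale; when
the contact point δ₀ is estimated it is profiled out by bounded scalar
minimization of the mean squared residual over δ₀ ∈ [−200, +200] nm. This
avoids the gradient-scale stalling a generic optimizer exhibits on
~10⁻¹⁰ N residuals. Deflection-to-indentation conversion (δ = z − F/k) is
provided as a helper; spring-constant calibration is out of scope.

## Statistics and hit calling

Per-field WI values are pooled across all wells of a condition; the SEM
uses the field count as n, matching the assay's replicate structure. The
Mann–Whitney test enumerates all rank assignments exactly for combined
n ≤ 12 (midranks handle ties) and otherwise uses the tie-corrected normal
approximation; Kruskal–Wallis and one-way ANOVA come from scipy, with
Bonferroni implemented as multiply-by-C(k,2)-and-cap. The hit rule is
strict: mean WI > control mean + 2·sd of the control's per-field WI, the
only replicate structure the pooled design provides. Ranking is by scaled
WI descending with alphabetical tie-break, so it is a pure function of
the scaled means.

## Synthetic data: what it emulates, and what it does not

Fields are rendered at the study's acquisition geometry — 8 slices at a
2 µm step, 0.31 µm/px (a 20× air-objective class calibration; the actual
in-plane pixel size of such acquisitions is an assumption documented
here), pillars of 10 µm diameter on a 20 µm square pitch. Myelin is an
annular arc of 0.6 µm thickness hugging the pillar wall with a controlled
angular coverage and contiguous slice span; nuclei are 8 µm spheres placed
by rejection sampling in the inter-pillar space, with a blur-scaled
minimum separation (2r + 4σ + 2 px) so that rendered objects remain
resolvable after the PSF — without that margin the blur merges adjacent
nuclei into one component and the count ground truth is unattainable by
*any* non-splitting counter. Blur is an in-plane isotropic Gaussian
(σ = 0.4 µm; axial PSF out of scope), followed by optional Poisson
resampling and Gaussian read noise (σ = 5 intensity units on a 0–255
range), clipped to the dynamic range. Ground truth (per-slice coverage via
exact angular-interval union, sheath runs, fully-wrapped flags, expected
WI) is computed analytically before blur and noise.

The randomized recovery study (`random_field_spec`) gives each pillar at
most one sheath with probability 0.6, drawing coverage from a bimodal
mixture — U(0.05, 0.6) "abortive contact" and U(0.85, 1.0) "processive
wrapping" — and nuclei counts from U{5..12}. The mixture reflects that
ensheathment is cooperative (intermediate coverage pinned at the 80%
boundary is transient and rare in fixed samples) and keeps the study's
classification question well-posed given the ±0.03 boundary resolution
discussed above; 12 is the packing limit for 8 µm nuclei with resolvable
separations in a 60×60 µm field.

What passing these studies does **not** show about real data: thresholding
real MBP staining must contend with MBP+ cell bodies touching pillars (no
exclusion rule is applied beyond thresholding), clumped nuclei are not
split, axial PSF and depth-dependent attenuation are not modeled, and
pillar autofluorescence bleed-through between channels is absent. The
studies validate the measurement logic, not the staining physics.

## Validation problem sizes

The standard validation conditions are: a 4 coverage × 3 span sweep with
20 seeds per cell (2160 pillars per noise regime), 100 randomized fields
per noise regime for WI recovery, 30 replicate force curves per material
at 2% force noise, and 200 simulated screens for the hit-rule operating
characteristics. `scripts/acceptance.py --seed N --out f.json` re-runs all
of them from scratch in a couple of minutes on one CPU.

## Known limitations

* Coverage near the 80% threshold is undecidable at pixel resolution
  (above); sheath-length granularity is one z-step (2 µm).
* Greedy linkage assumes pillars are vertical and well separated; tilted
  or touching structures are out of design range.
* The Poisson ratio of the pillar material is assumed, not measured;
  reported moduli scale by 1/(1−ν²).
* The manifest/aggregation layer assumes one stack file per (well, field);
  multi-position files must be split upstream.
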