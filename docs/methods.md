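# Methods

This note documents the models, algorithms and numerical choices behind
`poroct`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Segmentation chain

**Thresholding.** `otsu_threshold` maximises the between-class variance
over the 255 boundaries of a 256-bin histogram spanning the observed
intensity range, restricted to the ROI when one is given. Class weights
and means are taken from the raw (unbinned) values at each candidate
boundary, so the result agrees exactly with an exhaustive search; the
histogram only fixes the candidate set. The threshold is global and 3D —
per-slice thresholds would make volume-level metrics inconsistent.
Real scans segmented in practice with a manually chosen global value are
supported through `CorticalConfig.pore_threshold`.

**Morphology.** Closing uses a Euclidean ball; for radii above 2 voxels
it is computed with two distance transforms (dilate = EDT of the
complement ≤ r; erode = EDT of the dilation > r), which is exact for the
Euclidean structuring element and much faster than voxel-kernel
morphology at 10 μm-scale radii. Grid borders are edge-replicated, so
structures touching the window faces are not eroded.

**Despeckling** removes connected components of one phase by physical
volume. Foreground uses 26-connectivity, background holes 6-connectivity
(the standard complementary pair; the choice is a documented surrogate
for unpublished tool behaviour). The comparison is strict — a component
survives iff its volume ≥ the threshold — matching the convention that
speckles "less than" the stated volume are removed. The upper despeckle
bound removes components with V ≥ the bound so that it composes exactly
with the half-open class boundaries below.

**Cortical ROI.** The largest bone component is closed with a ball
(default radius 10 μm: larger than a lacunar radius, far smaller than the
marrow cavity — it must bridge pores without annexing marrow), then each
cross-section's enclosed background regions are filled except the largest
one, taken to be the marrow cavity. The result is the solid annulus: it
contains the bone and exactly the intracortical voids, so the pore mask
is ROI ∖ bone, and the thickness of the ROI is the porosity-free wall
thickness. A volume whose mid-slice encloses no cavity is rejected as
non-annular.

## Local thickness

Thickness follows the maximal-sphere (distance-ridge) definition: the
value at a voxel is the diameter of the largest inscribed sphere
containing it. Discretely, the sphere centred on foreground voxel c has
radius EDT(c) — it reaches, but does not include, the nearest background
voxel centre — spans 2·EDT(c) − 1 voxels across, and contains p when
|p − c| ≤ EDT(c). This calibration returns t for a t-voxel slab and d for
a d-voxel digital sphere; slabs of even physical width in voxels read one
voxel low (the EDT maximum falls between voxel centres), so recovery is
accurate to ±1 voxel by construction.

The implementation is an opening ladder: for each candidate radius ρ
(descending), the set of voxels within ρ of a centre with EDT ≥ ρ is
marked with diameter 2ρ − 1; a voxel keeps the first (largest) value.
Candidates form a ladder up to the EDT maximum, dense (half-voxel steps)
just below the maximum where shell- and plate-like structures concentrate
their voxels, and coarser below, capped at `max_candidates` (default 32)
EDT passes. Sparser candidates can only under-report — they never invent
a larger sphere. On grids of ≤ 32³ voxels every distinct EDT value is
used, which is exact for the discrete definition and is what the
brute-force oracle in the test suite checks against. Early exit once all
voxels are covered makes near-uniform structures (cortical walls, plates)
cost only a handful of EDT passes.

**Boundary semantics.** By default the structure is assumed to continue
beyond the grid faces (scipy's EDT semantics), which is correct for a
scan window cut from a longer bone — the cortical wall does not end at
the top slice. `boundary="background"` ends the structure at the faces,
optionally per axis; lattice phantoms whose structure faces coincide with
the domain faces are measured exactly with
`("background", "continue", "continue")`.

**Means and histograms** are volume-weighted: each foreground voxel
contributes its local value, making the reported mean consistent with the
thickness distribution. Tb.N is (BV/TV)/Tb.Th (model-free convention),
reported per mm.

## Cortical outer diameter

Ct.OD is computed per 2D section from area A and perimeter P. The
`as_printed` variant evaluates the plate-model expression 2/(P/A) = 2A/P,
which for a circular section equals the **radius**; `cylinder_corrected`
(4A/P, the hydraulic diameter) equals the true diameter and is what the
phantom-recovery checks use. Both are exposed because the printed formula
and a geometrically consistent diameter cannot be reconciled from the
formula alone. The perimeter is estimated with the 4-direction Crofton
formula (multigrid-convergent, ≤ 0.3% error on a digitised disc of
r = 150 px); marching-squares contour length was measured at +5.7% on the
same disc — enough to break a 2% diameter recovery — and voxel-edge
counting overestimates by up to 4/π.

## Pore classification

Pore components (26-connectivity) are partitioned by volume with
half-open classes: V < 280 μm³ removed as noise, 280 ≤ V < 4000 μm³
lacunae, V ≥ 4000 μm³ canals. At 2 μm voxels the lower bound operates at
35 voxels, at 1 μm at 280. Class porosity uses Ct.TV — the volume of the
solid cortical ROI, pores included — as the denominator, so densities are
per mm³ of cortex. Per-component diameter is the volume-weighted mean
local thickness of the component (structure-thickness convention),
computed on a padded bounding-box crop; the equivalent-sphere diameter is
stored alongside for comparison. Discrete maximal spheres under-read
narrow cylinders by roughly one voxel, so canal diameters carry a ~1
voxel negative bias at the render resolution. Components touching the
volume faces are counted by default; `exclude_border=True` reclassifies
them as removed.

The despeckle sensitivity sweep relabels nothing: components are labelled
once and reclassified per lower bound (150–550 μm³, fixed upper bound),
which makes the monotonicity of lacuna count and volume in the bound a
structural property rather than a numerical one.

## Phantoms

The cortical phantom is a hollow cylinder (defaults: outer diameter
280 μm, wall 80 μm, length 200 μm, rendered at 1 μm) whose wall contains
cylindrical canals within a few degrees of the shaft axis and ellipsoidal
lacunae (default aspect ratios 1 : 0.55 : 0.4, long axis within 30° of
the shaft axis). Canal diameters and lacuna volumes are truncated normal
draws; lacuna volumes are clipped to [350, 3500] μm³ so every lacuna sits
strictly inside its volume class, and canals (default 16 ± 3 μm diameter
over a 200 μm length) sit far above the 4000 μm³ boundary. The field of
view is desk-scale — a ~0.3 mm shaft segment rather than a whole mouse
tibia — chosen so the full pipeline runs in seconds to minutes on one
CPU; structure sizes themselves are realistic. Canal/lacuna size
distributions are order-of-magnitude choices: published values at these
scales appear in figures rather than tables.

Structures are placed by rejection sampling with a 2 μm clearance from
each other and from the wall surfaces; an impossible request fails with
an explicit infeasible-packing error rather than degrading silently. The
non-touching constraint is what makes component-count ground truth exact.

**Rendering** assigns each voxel a gray level from the signed distance of
its centre to the nearest structure surface, clipped to a one-voxel ramp
(bone 200, background/pores 20). Boundary voxels thus carry
partial-volume values, and thresholding at the mid level reduces to
centre-inclusion digitisation — unbiased for smooth convex structures.
(A 2× supersampled rasterisation was tried first and rejected: occupancy
quantised to eighths plus a deterministic tie rule produced a systematic
~5% deficit of the pore phase.)

**Trabecular lattices** are plates (slabs normal to the scan axis), rods
(three orthogonal cylinder families on a cubic lattice; BV/TV truth from
inclusion–exclusion with the Steinmetz bi- and tri-cylinder volumes), or
a mixed plate-and-rod form. With zero jitter the BV/TV truth is exact;
positional jitter is available for qualitative realism only.

**Scan simulation** applies Gaussian blur of stated FWHM (default 2× the
target voxel, a typical detector blur scale), block-average downsampling
by an integer factor, and additive Gaussian noise, in that order — the
order matters, as noise is applied at the target resolution. Mean
intensity is conserved up to edge effects (edge-replicated blur).

## Resolution-bias experiment

For each seed a thin-canal phantom (12 canals of 5.5 ± 0.5 μm diameter,
250 μm long — long enough that a 5 μm canal still exceeds the 4000 μm³
canal class at full segmentation; 40 lacunae) is rendered at 1 μm and
acquired at 1 μm and 2 μm with matched blur model and noise (σ = 5
intensity units), then analysed with one fixed global pore threshold
(110, the mid gray level). At 2 μm the partial-volume effect raises the
apparent intensity inside narrow canals and fragments their delineation;
fragments fall below the canal volume class, so canal density and
vascular porosity drop — in these conditions by roughly 70–85% relative
to 1 μm, consistently across seeds. The paired comparison reports
100·(mean₂μm − mean₁μm)/mean₁μm, i.e. the bias of the coarse acquisition
relative to the fine one (bounded below by −100%); note that the same
bias described relative to the coarse value can exceed 100%.

The experiment is run with pore metrics only (cortical thickness skipped)
to keep the five-seed experiment in the minutes range; the bias statement
concerns the canal metrics alone.

## Statistics

The group-comparison flow mirrors common practice for 7–8 animals per
group: Shapiro–Wilk per group at α = 0.05; if both groups pass, a
two-sided F-test on the variance ratio selects the pooled or Welch
t-test; otherwise Levene's test (median-centred) documents the variance
comparison and the groups are compared with Kruskal–Wallis (named as
such; with k = 2 it is the rank test equivalent to Mann–Whitney up to tie
handling, with midranks for ties). Dixon's two-sided Q (r10) with the
classical α = 0.05 critical table (3 ≤ n ≤ 30) screens for outliers;
flags are reported but values are never removed. No multiple-testing
correction is applied. Under H0 with n = 8 per group the empirical
type-I error of the full flow is ~0.05 (audited at 2000 replicates in the
acceptance script).

Percent differences and fold changes are rounded to one decimal, half
away from zero, matching how such effects are conventionally printed;
unrounded values are available via `ndigits=None`, and
fold = 1 + pct/100 holds exactly before rounding.

HOMA-IR = (fasting glucose [mg/dL] × fasting insulin [mU/L]) / 405; the
constant absorbs the units. The viable-osteocyte density multiplies the
microCT lacunar density by the TUNEL-negative fraction — it assumes one
osteocyte per lacuna and that the stained sections are representative of
the scanned volume.

## What the synthetic validation shows — and what it does not

Passing phantom recovery demonstrates that the chain of threshold → ROI →
despeckle → volume classes → metrics is implemented consistently and that
its discretisation errors are within the stated bounds (counts exact,
Ct.Th/Ct.OD within 2%, class porosities within 3% at 1 μm). It does not
validate biological accuracy on real tissue: phantoms have clean bimodal
contrast, smooth convex structures, no beam hardening, no ring artefacts,
no canal branching, and non-touching pores. In real bone, touching or
branching canal networks merge into single components, mineral-density
gradients blur the histogram, and the manual global threshold becomes a
genuine operator choice. The resolution-bias experiment likewise
reproduces the direction and rough magnitude of the partial-volume
effect, not scanner-specific values.

## Known limitations

* Thickness is accurate to ±1 voxel; even-width structures read one voxel
  low. Narrow cylinders (canals a few voxels across) read ~1 voxel low.
* `fit_cortical_roi` assumes one dominant shaft with an annular topology
  per slice; fragmentary cortices are rejected rather than repaired.
* Canal network topology (branching, connectivity) and sub-micron
  canalicular porosity are out of scope.
* `align_to_axis` is a principal-axis helper with nearest-neighbour
  resampling; it is not a registration tool.
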