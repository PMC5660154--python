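# Methods

`grainstack` quantifies punctate fluorescence in situ hybridization (FISH)
signal ("grains") in 3-D wide-field image stacks of postmortem human
cortex, where age-accumulated lipofuscin autofluoresces across every
channel and masquerades as signal. The package implements the full
quantitative chain -- spot-enhancing filtering, automatic thresholding,
iterative volume-gated segmentation, lipofuscin exclusion, grain-to-cell
assignment, cell classification, unbiased-counting-frame stereology, and
covariate-adjusted group statistics -- together with a synthetic-stack
generator that provides voxel-level ground truth for end-to-end
validation.

## Image model and generator

A stack is four registered channels (nuclear stain, grain fluorophore,
somatic counterstain, autofluorescence) over an `n_z x n_y x n_x` voxel
grid with pitch `(dx, dy, dz)` in micrometres. Geometry presets mirror
common acquisitions: 1024-pixel fields of ~111 um (60x, 0.25 um z-steps)
or ~333 um (20x, 0.75 um steps) through a 14-um cryosection; reduced
fields keep the voxel pitch and shrink only the field of view.

The generator samples:

- **Somata** as spheres (default radius 5 um) at a Poisson density
  (default 9e4 somata/mm^3, ~ the density of NeuroTrace-detectable
  neurons in cortex) with a hard-core minimum separation -- cell bodies do
  not interpenetrate. A fraction (default 5%, matching cortical SST
  interneuron abundance) expresses the target transcript. Each soma
  carries a concentric nucleus (half radius) in the nuclear channel.
- **Grains** as anti-aliased solid spheres with target volumes uniform in
  0.04-0.09 um^3 and amplitude 1200 counts/ms. Expressing cells draw
  Poisson(40) grains, background cells Poisson(2), placed uniformly
  within 0.85 of the soma radius under a 0.7-um hard-core spacing:
  amplified FISH grains are discrete, resolvable objects, and the
  detection gate (below) acts on threshold-dependent *apparent* volumes,
  so true sizes are kept inside the gate with margin rather than censored
  at its edges. An extracellular Poisson background (2e5 grains/mm^3)
  models neuropil signal.
- **Lipofuscin** as irregular aggregates (unions of 2-5 overlapping
  lobes, total volume 0.5-3 um^3) rendered into *all four channels* at
  >= 2x grain amplitude -- the broad-spectrum false-positive signal the
  exclusion stage exists for. Aged cortex carries abundant lipofuscin, so
  the default rate keeps aggregates present in essentially every field.
- **Optics and camera**: forward Gaussian blur (sigma_xy 0.13 um,
  sigma_z 0.30 um), per-channel exposure scaling, Poisson shot noise and
  Gaussian read noise (default 10 counts). The noise level represents
  post-deconvolution image quality: the pipeline consumes stacks as
  given, and deconvolution is deliberately outside its scope.

All randomness flows from one master seed through `numpy` `SeedSequence`
spawning (per subject, per stack), so identical inputs are bit-identical
and cohorts of any size are reproducible. What the generator does *not*
emulate: optical aberrations and depth-dependent PSF variation, spectral
bleed-through, tissue deformation, uneven illumination, and non-spherical
cell morphology. Passing tests therefore demonstrate the pipeline's
correctness and calibration under a controlled forward model, not its
performance on real tissue.

## Detection chain

1. **Exposure normalization** divides each channel by its exposure time
   (counts/ms), putting differently exposed acquisitions on one scale.
2. **Difference of Gaussians** with sigmas 0.7 and 2 in x/y pixel units;
   the z sigma is scaled by `dx/dz` so smoothing is isotropic in
   micrometres. The signed band-pass output is used for segmentation
   only; negatives are clamped to zero at thresholding.
3. **Ridler-Calvard (ISODATA) threshold**: iterate
   `T <- (mean(v < T) + mean(v >= T)) / 2` from the global mean on a
   256-bin histogram until the update falls below half a bin width. The
   algorithm assumes meaningful foreground mass; on effectively unimodal
   images (pure noise) the fixed point can sit inside the noise, which is
   why generator conditions guarantee adequate signal.
4. **Iterative volume-gated segmentation**: starting at the
   Ridler-Calvard value, segment at thresholds increasing by 25 intensity
   units per pass. Connected components (26-neighborhood by default)
   whose physical volume falls in the gate **0.03-0.1 um^3** (inclusive
   at both ends) are accepted and their voxels removed; components below
   the gate are dropped (they can only shrink at higher thresholds);
   passes continue while any component exceeds the upper gate.
   Thresholds are strictly increasing and bounded by the maximum
   intensity, so termination is guaranteed. Each accepted object records
   its accepting threshold for audit. If the voxel volume exceeds the
   lower gate (e.g. the 0.03-0.1 um^3 gate at 20x pitch) a warning flags
   the gate as unresolvable.
5. **Lipofuscin segmentation**: a single Ridler-Calvard pass on the
   DoG-processed autofluorescence channel (a raw-channel switch exists),
   no size gate. Any grain sharing >= 1 voxel with a lipofuscin object is
   excluded.

Object labeling is deterministic (components numbered by the C-order
index of their first voxel), so identical inputs give identical tables on
any platform.

## Cells, frames, densities

Cell masks are consumed as pre-drawn 3-D label volumes (in simulation,
the generator's true masks). A mask is counted only if it (a) overlaps
the nuclear-channel foreground, (b) spans >= 3 contiguous z-planes, and
(c) has its centre plane -- the plane of largest cross-sectional area,
ties to the lower index -- interior to the stack. The nuclear foreground
uses a robust background threshold, `median + max(6 * 1.4826 * MAD, 5% of
the range above the median)`: a class-balancing threshold is unstable on
fields with few or no nuclei, and an instability there would bias group
comparisons through differential validation failure.

Counting uses the classical unbiased (Gundersen) frame, default ~68 x 68
um at 60x and ~250 x 250 um at 20x, centred in the field: two inclusion
edges and two exclusion edges (default left + bottom) whose extensions
run to the field boundary; an object counts iff it intersects the frame
and touches no exclusion line. For uniform random points the expected
count is exactly density x frame area.

Grains are assigned to the cell mask with the largest voxel overlap (ties
to the lowest cell id); assigned + unassigned always equals the
post-exclusion total. Classification: at 60x a cell is SST-positive iff
it holds >= 20 grains; at 20x, iff its grain objects form >= 10
single-linkage clusters at a 1.5-um linking radius (at low magnification
grains fuse into cluster-like structures, and the visual cluster rule
needs an explicit geometric definition in software). Cell density is
counted cells over frame area x section thickness (mm^-3); tissue grain
density is surviving grains over field area x section thickness. Whether
the denominator should use nominal or shrinkage-corrected section
thickness is left open; thickness is a configuration input.

## Group statistics

Subjects carry postmortem interval (PMI), RNA integrity number (RIN) and
tissue pH. Group comparisons fit `measurement ~ group + PMI + RIN + pH`
by OLS and report the group effect from the full model; covariates with
p < 0.05 are flagged at reporting time (the model is never re-selected,
which would silently change the group estimate). Constant or collinear
covariates are dropped with a warning. Independent and paired t-tests and
Pearson correlations are two-tailed at alpha 0.05; summaries are mean +/-
sample s.d. qPCR relative expression is
`2^-(Ct_target - sqrt(Ct_ref1 * Ct_ref2))` with ACTB and GAPDH as
references and triplicates collapsed by arithmetic mean; the literal
geometric mean of cycle numbers is the default, with the
arithmetic-mean-of-cycles ("efficiency") alternative exposed as an
option since the phrase is ambiguous. The paired-t degenerate case of
perfectly identical samples returns t = 0, p = 1 rather than NaN.

## Desk-scale study

The validation study (`grainstack.study`) runs the entire workflow at
sizes a laptop handles: 256 x 256 x 20-voxel fields at the 60x xy pitch
with 0.5-um z-steps (27.7 x 27.7 x 10 um), 3.5-um somata at 9e5/mm^3
(preserving a handful of countable cells per field), 50% expressing
fraction, a 20 x 20 um counting frame, and 5 + 5 subjects x 20 stacks.
The z-step is coarsened from 0.25 to 0.5 um because a 5-um-deep stack
cannot hold somata large enough to keep 40 grains at resolvable spacing.
The older group's cell density is scaled by 0.36 (a planted 64%
reduction); grains per cell are left equal, mirroring a scenario where
expression is lost cell-wise rather than per cell. Detection recall under
these noisy, lipofuscin-laden conditions is ~0.7 and is deliberately
*equal across groups*, so the planted density ratio is preserved through
classification; the recovered percent reduction lands within a few points
of the planted value, limited by Poisson sampling of ~100-200 counted
cells per group. Null calibration (group effects 1.0) repeats the cohort
draw 100 times on generator bookkeeping alone and checks the group test
rejects at ~5%.

## Numerical choices and limitations

- Histograms for ISODATA: 256 equal-width bins over [min, max];
  convergence tolerance half a bin.
- Gate bounds inclusive; volume = voxel count x voxel volume exactly.
- 26-connectivity default (grains span few voxels; face-only
  connectivity fragments diagonal contacts); configurable to 6.
- Sub-voxel localization is out of scope; centroids use the voxel-centre
  convention.
- Two grains closer than the optical merge distance are detected as one;
  the generator's hard-core spacing keeps this below ~2% of grains at
  default conditions, and the residual loss is symmetric across groups.
- Stage artifacts (CSV/JSON/TIFF) are written eagerly so any stage can be
  re-run or inspected from intermediates; all result CSVs use fixed
  float formatting and are byte-identical across reruns of the same
  config + seed.
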