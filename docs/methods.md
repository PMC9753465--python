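# Methods

This note documents the measurement model behind `amisquant`: what each
statistic computes, the conventions and defaults chosen where the
procedure leaves room, what the synthetic-scene generator emulates, and
what the tests do and do not establish about real microscopy data.

## Coordinate and calibration contract

All geometry (paths, disc centres, truth records) is expressed in μm
and converted to pixel indices only at sampling time. Indices are
0-based; the physical coordinate of voxel centre `(iz, iy, ix)` is
`(iz·z_step, iy·pixel_size, ix·pixel_size)`, points are `(x, y[, z])`
with x fastest. Stacks carry their calibration (`pixel_size_um`,
`z_step_um`, `frame_interval_s`); OME-TIFF round-trips preserve voxels
bit-exactly and calibration to double precision. A TIFF with no
calibration metadata and no explicit override is rejected rather than
silently measured in pixels.

## Projections

Two conventions are implemented: maximum-value projection over the
whole stack (cluster counting, overview) and over exactly the three
central slices (all quantitative measurements, suppressing
out-of-plane membrane signal). For `n` slices the central three are
`{n//2 − 1, n//2, n//2 + 1}`; for even `n` there is no canonical
middle slice, and this symmetric-around-`n//2` choice is recorded in
the projection's provenance. Projections retain input bit depth and
apply no rescaling, so downstream ratios remain gain-faithful.

## Interface line-scans

A polyline annotation (band width 0.8 μm by default) is sampled once
per pixel-size of arc length; at each sample the value is the mean of
bilinearly interpolated sub-samples along the perpendicular segment.
The sub-sample count is `ceil(width/pixel_size)` forced odd with
pixel-size spacing, so one sub-sample lies on the path and a 0.8 μm
band at 0.2 μm pixels uses 5 sub-samples. Interface ends are the
F-actin argmax in each half of the path (split at the sample midpoint —
the half boundary is a convention, as is the tie-break: first maximum
in the first half, last in the second, keeping mirror-symmetric
profiles symmetric). A minimum-prominence guard (5% of the profile's
dynamic range) rejects flat halves instead of returning an arbitrary
index. The delimited span is partitioned into 20 contiguous near-equal
index ranges — remainder samples go to the earliest bins, a
deterministic and order-independent rule reused everywhere the package
partitions samples (heatmap axes, kymograph sections). Bin means are
therefore exactly reproducible by direct index-range averaging, which
the tests exploit as an oracle.

Centre-vs-side scans run perpendicular across the interface: a 3-μm
band at the interface midpoint and one on each side centred one band
width away, so the three regions tile the chord without overlap. The
two side scans are averaged and compared with the centre by trapezoidal
area under the curve.

## Regional enrichment statistics

Discs are rasterized by pixel-centre inclusion — deterministic, and
within one circumference-row of the analytic area. The
central-vs-surround ratio divides the disc mean (default diameter 4 μm,
placed on the multi-cellular junction) by the mean over the cluster
mask minus the disc. The core-vs-whole-cell ratio divides a core-disc
mean by the mean over the entire cell mask; because different core
diameters are in legitimate use for glass-cultured cells (6 μm circles
and 2.5 μm cores both appear in practice), the core diameter has **no
default** and must be stated per analysis. Zero denominators raise an
error; ratios are never silently NaN. Masks come from drawn
annotations or synthetic truth — the package deliberately performs no
segmentation.

Heatmaps reduce a square ROI (fitted to the cell body) to 10×10 block
means, 10% of each axis per unit, remainder pixels to the earliest
rows/columns. "Central 20%" is read as the central 2×2 unit block (20%
of each axis); a central-20%-of-units-by-distance reading is also
conceivable, so the block is isolated in one function
(`heatmap_central_level`) where the convention is documented and easy
to swap.

## FRAP

Normalization uses the mean of the pre-bleach frames as `F(i)` and the
first post-bleach frame as `F(0)`: `FRAP(t) = (F(t) − F(0)) / (F(i) −
F(0))`, times rebased to zero at the `F(0)` frame. The formula is
invariant under affine intensity transforms, which the tests assert to
1e-9. The recovery model is the exponential one-phase association with
the intercept fixed at zero, `Y(t) = P(1 − e^(−kt))`; the plateau `P`
is the mobile fraction. Fitting is unweighted least squares (no
per-point variance is available from a single trace) with bounds
`P ∈ [0, 2]` (allowing overshoot noise while excluding nonsense) and
`k ∈ [0, 10] s⁻¹`; initialization uses the tail mean for `P` and
ln 2 / half-rise time for `k`, with a fixed, seeded schedule of three
perturbed restarts on non-convergence. An all-zero normalized trace is
returned as `P = 0` without invoking the optimizer (the model is
degenerate in `k` there). Traces are fitted per trace and pooled
downstream by default; a pooled mode fits the pointwise mean curve
instead, for cohorts that share a time base. Bleach depth
`1 − F(0)/F(i)` is exposed as the QC statistic for accepting a bleach
event (deep bleaches, >0.8, are typical at interfaces).

## Morphometrics

Centrosome separation is the inter-centrosome distance normalised to
the doublet long-axis length (scale-invariant; in [0, 1] when both
centrosomes lie in the doublet hull). The long axis of a mask is its
Feret diameter, computed over convex-hull vertices. Kymographs average
path samples into 0.2 μm sections per frame with the same
remainder-to-earliest rule; the section count is
`round(length/section)`. The polarized-centre classifier thresholds
the central-vs-surround ratio (default 1.5, ties positive). It exists
because such scoring is done by eye in practice; it is a surrogate for
benchmarking against synthetic truth and is not claimed to reproduce
human counts on real images — any output should record the threshold
used.

## Synthetic scenes

The generator emulates the statistical structure the measurements
assume, not microscope optics. Cell bodies are spheres with a
soft-edged membrane shell (Gaussian cross-section, σ = half the
membrane width); a doublet's spheres are clipped at the mid-plane and
each contributes a membrane term on the shared interface disc, giving
the interface ≈2× the free-membrane amplitude and the two-peak actin
profile the end detector requires, with the chord endpoints, midpoint,
long axis and nominal centrosome positions recorded as truth. The
PAR-3 channel is a uniform cell-body baseline (the unpolarized, largely
cytosolic pool) plus a Gaussian focus at the interface midpoint (or
multi-cell junction) whose peak total is `E ×` baseline — `E = 1` is
the exact unpolarized null in which every enrichment statistic equals
1 — plus optional peripheral puncta whose amplitude is a free parameter
(their real intensity distribution is uncharacterised). Noise follows
the standard camera model: optional Gaussian blur, Poisson noise on
the scaled signal, additive Gaussian read noise, clipped at zero to
keep intensities non-negative. Identical parameters and seed give
bit-identical output.

Defaults: 30 × 30 × 12 μm volume at 0.2 μm pixels; 7 z-slices at a
2 μm step (the live-imaging axial sampling; an odd count so the
central slice passes through the cell equators and the central-section
projection sees the full cell outline); cell radius 6 μm; doublet
centre spacing 1.2 × radius (interface chord ≈ 9.6 μm, long enough to
host centre + side 3-μm scan regions); membrane amplitude 100 a.u.;
focus σ = 1.2 μm (FWHM ≈ 2.8 μm, a junction-filling focus commensurate
with the 4-μm measurement disc). FRAP simulation follows the
acquisition protocol the analysis targets — 3 pre- and 30 post-bleach
frames at 10 s, bleach depth 0.85 — with the recovery drawn from the
one-phase model itself plus Gaussian noise. The moving-focus
time-lapse translates a Gaussian spot at constant speed along a
straight path, recording the per-frame truth position.

What this does **not** emulate: realistic point-spread optics,
diffusion-coupled FRAP (recovery is one-phase by construction, so FRAP
tests verify estimator correctness, not model adequacy for real
membranes), lumen/cavity-stage geometry, cell shape irregularity, and
background/autofluorescence structure. Passing tests therefore
establish that the measurement chain is correct and well-calibrated on
data satisfying its assumptions — they do not validate the biological
model on real images, where path annotation quality and segmentation-free
masks remain the analyst's responsibility.

## Problem sizes and determinism

The verification suite uses deliberately modest sizes — 150×150×7
voxel scenes, 100-scene classifier benchmarks, 15 traces per FRAP
condition, 200 detection profiles, 1,000 binning oracles — chosen so
the full chain (including two complete pipeline reruns compared
byte-for-byte) verifies the contracts with wide margins. All
randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the pipeline manifest echoes the full
configuration and a parameter hash, so any result table can be
regenerated from its manifest alone.
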