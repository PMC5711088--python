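# Methods

## Scope and data model

`beamcheck` compares beam data from three roles: a *measured* reference
(water-phantom scans, ion chamber, film), a treatment planning system
(*TPS*) and an independent verification system (*VS*). Three containers
carry everything: `ScanCurve` (a 1D PDD or lateral profile with
geometry metadata), `DoseGrid` (regular 2D/3D dose array with origin
and spacing in mm) and `PointDoseRecord` (one patient's TPS/VS/IC dose
triplet). Readers validate invariants and never hand back partial
objects; raw scanner units are preserved on disk, and all percent
scales are produced by the normalization operations, never by I/O.

## Curve analysis

Every curve is linearly resampled to a 1 mm grid before analysis; all
interpolation in the package is linear — dose curves are smooth at the
millimetre scale and linear interpolation keeps every metric exactly
reproducible by hand.

**PDD error.** Curves are renormalized so their maximum is 100 (ties
broken toward the shallower depth). The signed difference
test − reference (percentage points of Dmax) is averaged over the
window from the *reference* curve's Dmax depth to 250 mm; using the
reference's Dmax is a convention chosen because the measured curve is
the designated reference. A pure output-scale difference therefore
cancels by construction — PDD discrepancies must come from shape
(attenuation) differences, which is how the synthetic dataset injects
them.

**Region segmentation.** Profiles are normalized to 100 at the
interpolated central-axis value. Field sizes are interpreted as defined
at the nominal SSD plane (default 1000 mm; configurable) and projected
to the scan depth by similar triangles, `w·(ssd + d)/ssd`. The in-field
interval is the central 80% of the projected width; each penumbra spans
the 20%→80% crossing positions found by linear interpolation; each tail
extends 15 mm outward from the 20% position. Intervals are closed:
boundary grid points are included. When noise yields several crossings
at a level, the one nearest that side's 50% crossing is used — robust
against tail noise. For MLC fields ≤ 2 cm the 80% position falls inside
the central-80% window (the whole field is gradient); segmentation
reports this as `overlaps_infield` rather than failing, and the
pipeline scores such fields with the small-field DTA path.

**Difference statistics.** Differences are signed (test − reference)
and pooled across all depths of a field size before computing mean and
sample (n−1) standard deviation; per-profile composite-DTA pass
fractions are averaged (and spread) across depths. Swapping the
arguments flips every mean and preserves every sd.

## DTA, composite test and gamma

DTA is found by subsampling the reference (0.1 mm for curves, a fine
bilinear lattice for planes) and locating the dose level set by linear
interpolation between samples, so reported distances are exact up to
the subsampling resolution. The composite x%/y mm test passes a point
on dose difference *or* DTA — the conventional point-acceptance test —
with a gamma ≤ 1 mode available as an alternative, since published
"DTA criteria" tables are often ambiguous between the two.

The gamma engine subsamples the reference to ≤ ⅓ of the distance
tolerance (subdivision keeps the original nodes, so identical
distributions give γ = 0 exactly) and searches a radius of 3×dist_tol
with a k-d tree; values that would exceed the radius-limited bound are
capped at that bound (3) and counted, which cannot affect pass/fail.
Three dose normalizations are supported: percent of 100 for
CAX-normalized curves (`global_cax`), percent of the reference maximum
for planes (`global_max`, the default planar convention here — vendor
tools differ and the choice is explicit and configurable), and percent
of local reference dose (`local`). No low-dose cutoff is applied unless
requested. An exhaustive brute-force implementation with the same
subsampling and cap ships alongside and is asserted equal (≤ 1e-6) in
the tests; because points outside the search radius carry a distance
term above the cap, the radius-limited and exhaustive searches agree
exactly.

## Chamber ROI and ratio statistics

Point doses from 3D grids are the mean over voxels whose centers fall
inside a cylinder of radius 2 mm and length 3.6 mm (a small thimble
chamber of the CC04 class; dimensions are an assumption and
configurable). Voxel-center inclusion was chosen over partial-volume
weighting because it is exactly reproducible by an explicit loop; the
tests do exactly that. Ratios are reported in percent with sample
(n−1) sds for Total, VMAT and IMRT groups.

## Synthetic beam model

The generators aim at *qualitative* realism — enough structure for
every metric to be exercised and for injected discrepancies to be
recovered — and claim no match to any named accelerator:

* PDD: `v(z) ∝ (1 − e^(−βz))·e^(−μz)`; peak at `z* = ln((β+μ)/μ)/β`.
  Presets: 6x-like (μ = 0.0046/mm, β = 0.27/mm, z* ≈ 15 mm), 15x-like
  (0.0036, 0.128, ≈ 28 mm), 18x-like (0.0034, 0.11, ≈ 32 mm) — typical
  effective attenuation and build-up for those energies in water.
* Profile: difference of two error-function edges at ± the projected
  half-width with width σ (2.2–3.0 mm by energy), a parabolic horn
  (1.5–3%) and a constant tail pedestal (1.5–2% of CAX), renormalized
  to 100 on axis. With horn and tail off, the 50% level sits at the
  projected half-width to within the sampling step.
* Perturbations: lateral shift (profiles only), output scale, extra
  edge blur by Gaussian convolution, then additive Gaussian noise in
  percent-of-CAX units, applied last, always with an explicit seed.
* Planar dose: superposed rectangles/Gaussian blobs smoothed by a 4 mm
  kernel with zero padding (integral-conserving up to boundary
  leakage), in Gy.
* Point-dose cohorts: per-patient true dose uniform in 1.5–3.0 Gy;
  chamber, TPS and VS readings are true·(1 + bias + ε) with
  per-technique biases and seeded Gaussian ε.

**Study conditions of the full dataset** (`make_commissioning_dataset`):
three energies; jaw fields 3×3–40×40 cm plus MLC 1×1 and 2×2 cm;
profiles at four depths from Dmax to 220 mm (five, to 300 mm, for 15x);
SSD 1000 mm; crossline scans. Source discrepancies: TPS = μ×0.99,
σ+0.2 mm, tail+0.2%, 0.2 mm shift, 0.1% noise; VS = μ×1.03, σ+0.5 mm,
tail+0.8%, 0.5 mm shift, 0.1% noise; measured carries 0.15% noise.
These sizes put the resulting tables in the same regime clinical
commissioning reports show (PDD errors a fraction of a percent to ~1%,
in-field errors ≲ 0.8%, penumbral DTA near 100%, planar gamma > 99%).
The point-dose cohort is 40 patients at 30% VMAT (12/28 split) with
TPS biases (−0.2%, +2.2%) and VS biases (−0.2%, +1.5%) for
(IMRT, VMAT), sds 1.5%/0.9%/0.5% for TPS/VS/IC. Six planar cases at
61×61 × 2 mm cover the gamma table. An `identity=True` dataset writes
byte-identical curves/planes/doses for all three sources and must
yield all-zero error tables and 100% pass rates — the strongest
end-to-end self-check.

What the generator does **not** emulate: real MLC leaf transmission and
tongue-and-groove structure, heterogeneity, beam divergence effects
beyond the similar-triangle projection, detector volume averaging, or
any correlated scanner noise. Passing tests therefore demonstrate that
the *analysis* is correct and self-consistent, not that any particular
dose engine is accurate.

## Numerical choices and degenerate inputs

Curves with descending positions are sorted on read (scanners sweep
both directions); exact duplicate positions are an error, never
averaged. Edge detection refuses profiles with no crossing at the
requested level (e.g. flat curves). Profiles too short for the 15 mm
tails are skipped with a logged notice rather than failing the whole
run, mirroring how commissioning reports mark truncated scans as "not
completed". Reports iterate in sorted key order and render with fixed
formats, so a run is byte-reproducible from (dataset, config). Text
formats round-trip numbers at 12 significant digits (≤ 1e-9 relative).

## Known limitations

3D gamma is supported only at toy grid sizes (the fine subsampled
lattice grows cubically). Film dosimetry/calibration is out of scope —
"film" is simply the role of a third planar dose source. No
flatness/symmetry/FWHM metrics beyond the regions defined above, no
wedge/electron/FFF curve handling, and no partial-volume weighting in
the chamber ROI.
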