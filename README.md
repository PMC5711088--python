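# beamcheck

Commissioning analysis for secondary dose-calculation **verification
systems** in radiotherapy.

When a clinic adopts an independent verification system (VS) as a second
check on its treatment planning system (TPS), the VS must itself be
commissioned: its calculated beams compared against water-phantom
measurements and the TPS model for simple geometries, and its patient
dose predictions compared against ion-chamber and planar measurements
for IMRT/VMAT plans. `beamcheck` implements that analysis chain as a
library (plus a thin CLI), together with a synthetic beam-data generator
so the whole pipeline can be exercised and validated with *known*,
controllable discrepancies.

## What it computes

**Curve metrics.** All scans are resampled at 1 mm. PDDs are
renormalized to Dmax (= 100) and the signed per-point difference
(test − reference) is averaged from the reference Dmax down to 25 cm
depth. Profiles are normalized to the central axis (CAX = 100) and split
into three regions:

* **in-field** — the central 80% of the geometric field size projected
  to the scan depth, `w(d) = w₀·(SSD + d)/SSD`; scored as the pooled
  mean ± sd difference across depths;
* **penumbra** — between the 80% and 20% dose levels on each side;
  scored as the fraction of points passing a composite 2%/2 mm test;
* **tail** — from the 20% level a further 1.5 cm outward; scored as the
  pooled mean ± sd difference.

MLC-collimated fields of 2 cm and below have no flat core, so their
in-field is scored as a 1.5%/1.5 mm DTA pass rate instead of a mean.

**Point tests.** The composite criterion passes a point when
`|ΔD| ≤ dose_tol` **or** DTA ≤ `dist_tol`, where DTA is the distance to
the nearest reference location with the same dose. The gamma index is

γ(x) = min over reference positions r of √( |r − x|²/dist_tol² + (D_ref(r) − D_eval(x))²/dose_tol² )

with a point passing when γ ≤ 1; planar comparisons use 3%/3 mm with a
90% clinical pass threshold. A radius-limited k-d-tree search is
validated against an exhaustive brute-force scan.

**Point doses.** Per patient, the ratios TPS/IC, VS/IC and TPS/VS
(percent) are tabulated and summarized as mean ± sd for all cases and
for VMAT and IMRT separately; TPS/VS doses can be extracted from 3D
grids as the mean over a cylindrical chamber-sized ROI.

## Worked example

`examples/` holds one short script per capability. For instance,
`examples/01_pdd_and_profiles.py` compares a 6x-like measured beam
against a verification model with a 3% harder attenuation coefficient,
a 0.5 mm wider penumbra and a raised tail:

```
Dmax depth: 15 mm
PDD error (VS - measured, Dmax..25 cm): -0.82 ± 0.32 points of Dmax over 236 depths
projected width at 10 cm depth: 110.0 mm; in-field interval: [-44.0, 44.0] mm
in-field error: -0.01 ± 0.00 points of CAX (89 points)
penumbral DTA (2%/2 mm): 100.0% of points pass
tail (out-of-field) error: +1.87 ± 1.72 points of CAX
```

The harder beam under-doses at depth once both PDDs are pinned to 100 at
Dmax (−0.82 points); the flat in-field is untouched; the widened edge
stays within 2 mm of the reference so every penumbra point passes; and
the raised tail shows up directly as a hot out-of-field mean.

The CLI wraps the same library calls:

```
beamcheck synth --out data/ --seed 42        # full synthetic dataset
beamcheck run --data data/ --out report/     # all commissioning tables
beamcheck gamma ref.txt eval.txt --dose-tol 3 --dist-tol 3
beamcheck point-doses point_doses.csv
```

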