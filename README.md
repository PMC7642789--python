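# chipscan

Optical-scan analysis and shot planning for fixed-target *in situ* serial
crystallography chips.

In fixed-target serial crystallography, protein crystals are grown directly
on a transparent chip — here a Z-cut monocrystalline α-quartz wafer — and
rastered through the X-ray beam, so every crystal diffracts from the very
spot where it grew. Before any X-rays are fired, the chip is scanned
optically: overlapping IR transmission micrographs are stitched into a
montage, crystals are recognized and ranked, non-overlapping X-ray shot
positions are planned, ordered, and written out as a machine-readable
instruction file for the translation stages and shutters. `chipscan`
implements that desk-side computational chain, plus the diffraction-geometry
calculation specific to a crystalline substrate: how far the quartz wafer
itself may oscillate before one of its own Bragg reflections floods the
detector.

The package is aimed at beamline scientists and method developers who want a
reproducible, scriptable version of this pipeline; every stage can be
exercised end-to-end on synthetic chips with known ground truth.

## The substrate oscillation limit

For a trigonal reciprocal cell (a\* = b\*, c\*), the reflection (hkl) has
reciprocal spacing

    d* = (j² a*² + l² c*²)^½,   j = (h² + hk + k²)^½,

where *j* acts as a joint in-plane index. With the wafer perpendicular to
the beam, the reciprocal vector of (hkl) is tilted out of the wafer plane by
α = arctan(|l| c\* / (j a\*)), and it meets the Ewald sphere when tilted
upstream by the Bragg offset ψ = arcsin(λ d\*/2). Rotating about an in-plane
axis, at the worst-case azimuth, the wafer may therefore oscillate

    ω_hkl = |α − ψ|

degrees before (hkl) (or a Friedel/azimuthal mate) diffracts; if
λ d\*/2 > 1 the reflection can never diffract. For α-quartz
(a\* = b\* = 0.235 Å⁻¹, c\* = 0.185 Å⁻¹) the reflections that matter below a
1.55 Å resolution cutoff are (100) and (201): the chip may oscillate ±6.7°
at λ = 1.0 Å and ±4.9° at 1.13 Å (11 keV). A brute-force Ewald rotation-scan
oracle (`ewald_first_crossing`) verifies the closed form to ≤ 0.01°.

## The optical pipeline

- `fixtures` — synthetic raster scans: convex-polygon crystals (flat or
  foreshortened "upright") with dark edges on a textured bright background,
  tile jitter, noise, clusters and debris, all with ground truth.
- `montage` — stitching by normalized cross-correlation of overlap strips
  with sub-pixel peak refinement and confidence-weighted least squares over
  the tile grid; 2D elliptical-Gaussian fitting of the direct-beam image.
- `finder` — line-segment detection (Canny + probabilistic Hough), length
  filtering, pairing by parallelism/gap/overlap, darkness validation of the
  region between paired edges, convex-hull candidates with cluster/irregular
  flags, ranking by area × minimum caliper width (pluggable scorer).
- `planner` — per-crystal shots: a primary shot at the pole of
  inaccessibility of the polygon eroded by half the beam FWHM, subsequent
  shots on a FWHM-pitch hexagonal grid (each exposure hits fresh volume),
  pump-laser exclusion zones, rank cutoffs, and hit-rate / diffraction-yield
  economy metrics.
- `router` — visiting order by crystal rank, or an open near-shortest path
  (nearest neighbour + 2-opt).
- `runfile` — pixel→motor transform anchored at the fitted beam position
  (±12 mm travel limits) and a schema-validated XML instruction file
  (move / laser / wait / xray / readout per shot).

## Worked example

```python
from chipscan import (ChipSpec, render_chip, assemble, find_crystals,
                      BeamParams, plan_shots, ranked_route, tsp_route)

spec = ChipSpec(window_mm=(4.0, 4.0), n_crystals=30, seed=11)
tiles, truth = render_chip(spec)           # 25 tiles, 5 x 5 grid
m = assemble(tiles, spec.overlap_fraction, spec.pixel_scale)
cands = find_crystals(m.pixels)            # 26 candidates, 24 accepted
plan = plan_shots(cands, BeamParams(xray_fwhm=50.0),
                  pixel_scale=spec.pixel_scale)
print(len(plan.shots), len(plan.excluded))           # 22 shots, 4 excluded
print(round(ranked_route(plan).total_length_mm, 1))  # 54.8
print(round(tsp_route(plan).total_length_mm, 1))     # 14.6
```

The 22 planned shots sit inside the recognized crystal hulls, pairwise at
least one beam FWHM apart; the near-shortest route cuts the total stage
motion from 54.8 mm to 14.6 mm. The oscillation-limit table prints the
headline geometry numbers:

```python
from chipscan import QUARTZ_CELL, limit_curve
print(limit_curve(QUARTZ_CELL, [1.00, 1.13]))
#  wavelength_A  energy_keV  omega_deg  limiting_h  limiting_k  limiting_l
#          1.00      12.398      6.748           1           0           0
#          1.13      10.972      4.904           2           0           1
```

The same stages are available from the shell (`chipscan scan | stitch |
beam | find | plan | route | runfile | limits`); see `chipscan --help`.

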