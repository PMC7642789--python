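# Methods

This note records the models, parameter choices and numerical decisions
behind `chipscan`, and what the synthetic benchmarks do and do not show.

## Substrate oscillation geometry

**Model.** The chip substrate is a Z-cut trigonal single crystal (α-quartz,
a\* = b\* = 0.235 Å⁻¹, c\* = 0.185 Å⁻¹) whose surface is perpendicular to the
beam at the oscillation start. The reciprocal vector of reflection (hkl)
has in-plane magnitude j·a\* with joint index j = (h² + hk + k²)^½ and
out-of-plane component l·c\*, hence d\* = (j²a\*² + l²c\*²)^½. Placing the
in-plane component in the rotation plane (worst-case azimuth) and rotating
about an in-wafer axis perpendicular to the beam, the Ewald condition
|P + s₀/λ| = 1/λ is first met at ω = |α − ψ| with α = arctan(|l|c\*/(j·a\*))
and ψ = arcsin(λd\*/2). Friedel mates and both rotation senses are implied
by the absolute values. If λd\*/2 > 1 the reflection can never diffract and
the limit is reported as infinite.

Worst-case azimuth makes ω a *guarantee*: at any other azimuth the first
crossing occurs later. Whether published limit curves include symmetry
mates at non-worst-case azimuths is not generally stated; the conservative
bound is the useful one for planning an oscillation range.

**Oracle.** `ewald_first_crossing` re-derives the limit numerically: scan
both rotation senses and both signs of the out-of-plane component in
0.001° steps up to 90°, detect the first sign change of
f(ω) = |R(ω)P₀ + s₀/λ| − 1/λ, and refine by bisection to 1e−6°. The closed
form and the oracle agree to ≤ 0.01° over λ ∈ [0.8, 1.5] Å for the low-index
reflections; the oracle also handles starts inside the Ewald sphere (exit
crossings), which occur for c\*-dominated reflections.

**Resolution cutoff.** Substrate reflections at higher resolution than the
protein data do not interfere, so candidates are restricted to d strictly
greater than a cutoff. The default cutoff is 1.55 Å: protein diffraction
rarely exceeds ~1.5 Å, and quartz (211) sits at d = 1.5416 Å, so the
default keeps (100) and (201) as the limiting pair — (100) at 1.0 Å
(ω = 6.75°) and (201) at 1.13 Å (ω = 4.90°). The cutoff is exposed as a
parameter; lowering it admits more reflections and can only lower the
envelope. Systematic absences of α-quartz are not modelled — every
enumerated reflection is a candidate, which again errs conservative.
Degrees are used throughout the API; radians internally.

## Synthetic chips (fixtures)

The generator emulates IR transmission micrographs of crystals grown on a
20 × 20 mm crystallization window imaged at 2 µm/pixel (monochromatic: IR
illumination carries no colour). Defaults: 512 px tiles with 15% overlap;
crystal long axis 50–150 µm (plates of roughly 50 × 50 × 100 µm are
typical), aspect 0.5–0.9, 30% with a chamfered hexagonal habit; 20% of
crystals "upright" — foreshortened to 0.6 of their length and attenuating
3× more, as thicker material absorbs more transmitted light; 10% grown
overlapping a neighbour (clusters); small dark precipitate blobs as debris;
additive Gaussian noise of 2% of the dynamic range per tile; integer stage
jitter up to 3 px. Intensity model: bright background (0.78) with
stationary low-amplitude texture (so featureless overlaps still correlate),
crystal interiors attenuated by 0.10 (0.30 upright), 3 px borders darkened
by a further 0.28.

Integer jitter makes every tile an exact crop of a common chip image:
ground-truth offsets are exact, noiseless overlap strips are pixel-identical
by construction, and stitching accuracy can be judged without an
interpolation confound.

**What this does not emulate:** optics (defocus, depth of field, vignetting),
birefringence, real crystal habits and texture, illumination drift, and
stage rotation/scale errors. Passing benchmarks on these fixtures shows the
geometry and bookkeeping of the pipeline are correct under controlled,
favourable contrast; it does not certify recognition performance on real
micrographs, where contrast and clutter are harsher.

## Stitching and beam registration

Pairwise tile offsets maximize the normalized cross-correlation of the
nominal overlap strips (search margin ±8 px around the stage-predicted
shift), refined to sub-pixel by quadratic interpolation of the correlation
peak. Both strips are Gaussian low-passed (σ = 1.5 px) first: sensor noise
is uncorrelated between exposures while the scene texture is shared, so the
low-pass raises the peak without biasing its position. The peak correlation
is the pair's confidence; below 0.3 (featureless overlap) the nominal
offset is used instead. Global positions are solved per axis by
confidence-weighted linear least squares on the grid graph with tile (0, 0)
anchored, and tiles are composited with linear feathering. Only
translations are solved — stage axes are assumed parallel to the sensor
axes.

The direct-beam image is fitted with an axis-aligned 2D elliptical Gaussian
plus constant background (Levenberg–Marquardt, moment-based
initialization, 96 px half-window around the smoothed peak). A flat image
(peak < 6 robust σ above the median) or a border spot raises an error. On
the synthetic benchmark (FWHM 20 px, 2% noise, 50 seeds) the fitted center
stays within 0.2 px of truth.

## Crystal recognition

The segment backend is pluggable; the bundled one is Canny (σ = 1.5)
followed by a probabilistic Hough transform with a fixed random stream, so
detection is deterministic per image and parameter set. Defaults were
calibrated to the minimum useful crystal size at 2 µm/pixel: segments
shorter than 12 px (24 µm) are discarded — upright, foreshortened crystals
present 10–30 px edges, so a longer filter silently drops a class of real
crystals — and pairs require angular deviation ≤ 10° (25° in curved-edge
mode), perpendicular gap in [6, 300] px (the lower bound rejects duplicate
detections of the same edge), and longitudinal overlap ≥ 0.3 of the shorter
projection.

Pairing is purely geometric; validation against the image happens when
candidates are formed: the region between a paired couple of edges is
sampled on a 5 × 11 grid and at least 85% of samples must be darker than
the image median by 0.04. A genuine crystal interior is dark throughout,
while an accidental pairing of edges from two nearby objects spans bright
background — without this test, chips at moderate density lose several
percent recall to cross-crystal merges. Validated pairs sharing segments
form connected components; each component's convex hull of segment
endpoints (clipped to the image) is a candidate. Components whose hulls
overlap by more than 50% of the smaller area are two views of the same
crystal (e.g. the long-edge pair and the short-edge pair) and are merged;
remaining intersecting hulls are flagged `cluster`, and hulls with area
outside [400, 1e6] px² or aspect ratio above 8 are flagged `irregular`.

Ranking uses area × minimum caliper width — a volume proxy, since only the
2D projection is observable — with deterministic (score, area, id)
tie-breaking; a user scorer can replace it.

**Benchmark conditions and scoring.** The recognition benchmark runs 20
chips of 50 crystals on a 5 × 5 mm window (~2 crystals/mm², moderate
density) with single-exposure noise applied to the chip image — the noise
level a stitched montage carries — and matches a candidate to a truth
crystal when its centroid lies inside the truth polygon and IoU ≥ 0.3.
Recall counts truth crystals matched by any candidate; precision counts
matched candidates among the unflagged ones (the set actually proposed for
targeting — flagged candidates are explicit rejects, not false claims).
Pooled over the benchmark this yields recall ≈ 0.95 at precision ≈ 1.0.

## Shot planning

Crystal polygons are eroded by half the X-ray FWHM so the beam footprint
stays inside the crystal. The primary shot sits at the pole of
inaccessibility of the eroded polygon (deepest interior point — robust for
elongated or L-shaped hulls where the centroid can fall outside);
subsequent shots fill a hexagonal grid of pitch one FWHM inside the eroded
polygon, so each exposure probes fresh, previously unexposed volume.
"Non-overlapping" is operationalized as center separation ≥ one FWHM.
Shots that would fall within one FWHM of an already retained shot are
dropped; if that removes a crystal's primary shot the crystal is excluded
(`shot_conflict`) rather than shot only partially. In pump–probe mode,
crystals whose polygon comes within the exclusion radius (default: the
500 µm laser FWHM) of any retained shot are excluded outright
(`laser_proximity`), evaluated greedily in rank order so higher-ranked
crystals win. Rank/score cutoffs exclude the tail (`below_cutoff`).

Economy metrics follow the standard definitions: hit rate = hit images /
images taken; diffraction yield = hit images / crystals prepared; the
effective variants count only images successfully indexed and merged.

## Routing

The ranked route visits crystals in descending rank, primary shot first.
The near-shortest option routes individual shots: nearest-neighbour
construction from the shot closest to the chip origin, improved by
best-improvement 2-opt (open path — the stage simply ends at the last
shot), capped at 50 full passes with the local-optimality flag reported.
Whether one should route whole crystals or individual shots is a genuine
choice; routing shots minimizes total motion, and the ranked route is the
one that keeps a crystal's shots contiguous. On 200 uniformly scattered
shots the 2-opt route is shorter than the ranked order in ≥ 95 of 100
instances, typically by 3–4×.

## Run files

Motor coordinates are mm relative to the fitted beam center, with
configurable axis signs (default x right, y up — montage rows grow
downward, hence sign −1 on y) and a ±12 mm travel limit checked on every
move. The XML vocabulary (`<run>` of `<shot>` blocks containing
`move / laser / wait / xray / readout`) is this package's own, shipped with
an XSD and validated on write and on parse; no wire compatibility with any
particular beamline controller is attempted. Default timing: 250 ms laser
pre-illumination, 10 ms pump-probe delay, 1 ms X-ray exposure.

## Problem sizes used in the benchmarks

Oscillation-limit checks run over λ ∈ {0.80, …, 1.50} Å × five low-index
reflections; stitching on a 5 × 5 grid of 512 px tiles at 2% noise; beam
fitting over 50 noise seeds; recognition on 20 chips × 50 crystals at
5 × 5 mm; planning invariants on 100 sampled chips; routing on 100
instances of 200 shots. These sizes exercise every code path at the same
densities and noise levels as the full-scale platform while keeping the
suite quick to run; the generator's physical defaults (20 × 20 mm window)
are unchanged.

## Known limitations

- Recognition assumes dark convex crystals on a brighter background;
  curved-edge mode relaxes parallelism but true arbitrary-shape
  segmentation (e.g. learned detectors) is out of scope.
- Stitching solves translation only; rotation or scale error between stage
  and sensor axes is not estimated.
- The oscillation-limit model treats the substrate kinematically: no
  structure factors or intensities, so it predicts *where* substrate
  reflections fire, not how strong they are.
- Planner geometry is 2D; crystal thickness enters only through the
  ranking proxy.
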