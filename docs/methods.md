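# Methods

This note records the models, conventions and numerical choices behind
`epiwound`, and what the synthetic-data validation does and does not
establish.

## Conventions

Arrays are `(t, y, x)`; pixel coordinates are 0-based, origin at the
top-left pixel centre, continuous coordinates referring to pixel centres.
The image x-axis is taken to be the worm's anterior–posterior (AP) axis —
acquisition orientation is the user's responsibility. All physical
quantities are µm and seconds; the pixel→µm conversion happens once, at
measurement time, using the `Movie` calibration (`pixel_size_um`,
`frame_interval_s`). Calibration is stored in a JSON sidecar next to each
TIFF; ImageJ-style TIFF metadata is read when present, the sidecar winning
on conflict. Angles of motion and texture are *axial* (orientations, not
directions) in [0°, 180°) from +x, except the wound-referenced quantities:
the track-to-wound angle is a true angle in [0°, 180°] (0° = toward the
wound) and the filament angle θ is folded into [0°, 90°] (0° radial,
90° orthoradial).

## Synthetic-movie generator

The generator produces the study conditions under which the measurement
pipeline is validated. Its presets encode the measured epidermal dynamics
as ground-truth parameters, at 0.08 µm/px (the 100× spinning-disk
geometry, back-derived from a 21-px ≈ 1.68 µm wound ROI) and the native
frame intervals of each reporter:

| preset | motion model | speed (µm/s) | dt (s) | geometry |
|---|---|---|---|---|
| `eb1_unwounded` | straight transient comets, AP-biased | 0.26 ± 0.10 | 0.3 | 300×200×200 |
| `eb1_near_wound` | as above | 0.16 ± 0.06 | 0.3 | 300×200×200 |
| `rab11` | persistent directed runs | 1.31 ± 0.33 | 0.4 | 300×200×200 |
| `snf12_unwounded` | 25% movers, isotropic; rest static | 0.017 ± 0.005 | 0.2 | 1300×150×150 |
| `snf12_wounded` | 40% movers converging on the wound | 0.007 ± 0.004 | 0.2 | 2200×150×150 |
| `ring_eb1` | two-phase contracting annulus | v2 = 0.008, v1 = 10·v2 | 1.0 | 250×200×200 |

Movie lengths are set by what the measurement needs (the SNF-12 movies must
cover the 120 s / 420 s displacement-filter windows at 0.2 s/frame); sizes
keep a seed's full pipeline in seconds on one CPU.

Speeds are constant per object, drawn from a truncated normal with the
quoted mean and coefficient of variation — the between-track spread is
reproduced, within-track speed fluctuation is not modelled (the source
statistics are per-track means, which carry no information about it).
Comets nucleate by a Poisson process balancing an expected standing count
(20/frame) against an exponential lifetime (mean 30 frames) and are
rendered as pixel-integrated isotropic Gaussians (σ = 1 px, so the full
width ≈ 3 px blob the detector is tuned to); "amplitude" is the peak of the
continuous Gaussian and a spot's integrated energy is amplitude·2πσ²,
which the energy-conservation test uses. Vesicles/clusters follow a
two-state (run/pause) Markov chain with geometric dwell times tuned to a
duty cycle; pauses have exactly zero true displacement. The ring is an
annulus with Gaussian radial cross-section (FWHM 0.6 µm) whose radius
follows the continuous piecewise-linear r(t), clamped at zero. Filament
fields render anti-aliased line segments whose midpoint tangent follows the
field law (longitudinal / circumferential / orthoradial / radial / uniform)
plus Gaussian angular jitter.

Noise is applied as `Poisson(scale·bleach(t)·I)/scale + N(0, σ_read)`,
then a linear stage drift `(dy, dx)·t` (bilinear resampling, median fill)
and clipping at zero; dynamic presets use photon_scale 1 and σ_read 2 on
a background of 10 with amplitude 60, i.e. peak SNR ≈ 5–7. With all noise
parameters zero the operator is the identity, bit-exactly. Each generator
call uses a single seeded RNG; sub-streams derive via `SeedSequence.spawn`,
so (params, seed) reproduce movie and ground truth bit-exactly.

What the generator deliberately omits: 3-D optics (no axial PSF), motion
blur within a frame, autofluorescent scar texture, spatially varying or
correlated background, filament curvature, and comet nucleation coupled to
an underlying MT network. Passing the recovery tests therefore shows the
measurement chain is correct and unbiased under realistic shot noise and
density, not that it is robust to every real-acquisition artefact.

## Measurement pipeline choices

**Preprocessing.** Drift is estimated by subpixel phase cross-correlation
(upsampling ×20, plain cross-correlation normalisation, which proved far
more stable than phase normalisation on smooth low-texture frames) against
a `first`/`previous`/`mean` reference; correction is pure translation with
bilinear resampling and frame-median fill. The temporal median filter uses
a centred 31-frame window that *shrinks* at the movie ends (keeping early
post-wound frames usable) rather than reflecting; the window median is
subtracted per pixel and negatives are clamped by default (unclamped
output is marked as a residual movie). Default order is register →
median-subtract. `crop_substack` multiplies the frame interval by the
stride (stride 100 on a 0.2 s movie gives the 20 s cluster substack).

**Detection.** Scale-normalised LoG response at σ = d/(2√2) for blob
diameter d (default 3 px); 3×3 local maxima above threshold; subpixel
centres by 3×3 centre of mass of the min-subtracted response patch. The
historical absolute threshold ("900") is instrument-specific, so the
default auto-calibrates per frame as median + 8·MAD of the response, with
an absolute override for parity experiments.

**Linking.** Per frame pair, the matching that maximises the number of
links with length ≤ r_link and, among those, minimises total distance —
solved exactly as a linear assignment problem with unmatched cost r_link
(every admissible link saves 2·r_link − d > 0, so cardinality dominates).
Gap closing joins track ends to starts across ≤ g missing frames within
r_gap using the same matcher, shortest gaps first. Linking is deterministic
and order-independent; every detection ends up in exactly one track. The
comet regimes use the canonical r_link = 2 px, g = 1; for regimes whose
expected per-frame displacement exceeds that radius the pipeline configs
(`epiwound.pipelines`) set r_link ≈ 1.5× the expected displacement
(10 px for the 6.6 px/frame vesicle regime, 7 px for the 4.3 px/frame
cluster substack) — the radius must exceed the step while staying well
below the inter-particle spacing — and disable gap closing where a closed
gap could only be a cross-particle jump.

**Speeds.** The primary statistic is the mean step speed (gap-spanning
steps divided by actual elapsed time); net displacement over duration is
reported alongside because the cluster displacement filter is
net-displacement-based. Singleton tracks are flagged and excluded; the
recovery pipelines additionally require ≥ 3 detections per track so that a
speed is an average of at least two steps. Localisation jitter
(σ ≈ 0.15–0.2 px from the centre-of-mass refinement under shot noise)
inflates step lengths by E‖step‖ ≈ √(L² + 2σ²); at the slowest comet
regime (0.6 px/frame) this is a ≈ +5–8% bias, the dominant error term in
the speed-recovery tests, and it is why the recovered grand means sit
slightly above truth while remaining within the 10% acceptance band.

**Displacement filter.** A track passes when any pair of its positions
separated in time by at most the window (120 s pre-wound; 420 s for the
post-wound regime) lies ≥ 5 px apart — i.e. maximum net displacement over
any sub-window reaches the cutoff. Static and purely oscillating clusters
are removed exactly as intended.

**Ring dynamics.** The wound centroid is automated (intensity-weighted
centroid of above-Otsu pixels in a search ROI, ROI-centre fallback below
5 pixels); a fixed manual centre remains available through the CLI. Radial
profiles use contiguous 1-px annular bins from radius 0; every in-bounds
pixel contributes to exactly one bin, so profile mass equals image mass.
r_max takes the smallest radius on ties and flags plateaus. Kymographs are
per-frame column means over an AP stripe through the wound, each row
divided by its maximum (all-zero rows stay zero). The two-phase fit is a
*continuous* hinge regression r ≈ a + b·t + c·max(0, t − t_b), the break
t_b found by exhaustive search over interior sample times (first/last two
excluded), speeds |b| and |b + c|; continuity is the minimal assumption
consistent with a radius trace, and on noiseless piecewise input the fit
is exact. Its SSE can never exceed the single-line fit's (the hinge basis
nests the line).

**Huang threshold.** Implemented from the fuzzy-set formulation: 256-bin
histogram on the min–max-scaled ROI; for each candidate threshold the two
class means are computed, each grey level's membership is
μ = 1/(1 + |g − m_class|/C) with C the occupied grey-level range, and the
threshold minimises the histogram-weighted Shannon entropy
−μ ln μ − (1 − μ) ln(1 − μ). The implementation evaluates all candidates
with cumulative sums; the test suite checks exact argmin agreement with a
naive per-threshold oracle on random 8-bit images. "Area inside the actin
ring" is the connected below-threshold component containing the ROI centre
(the ring is bright, the wound interior dark), in an 80×80 px ROI by
default — the natural reading of an "80-px" square ROI.

**Orientation.** Gaussian-derivative gradients (σ_g = 1 px) and a Gaussian
tensor window (σ_w = 4 px); texture orientation is the eigenvector of the
*smaller* structure-tensor eigenvalue (the direction of least grey-level
change — for a bright ridge the large-eigenvalue eigenvector points across
it, a frequent source of convention confusion, so an `eigen="large"` parity
flag is kept); coherency (λ₁ − λ₂)/(λ₁ + λ₂), defined as 0 on zero-trace
pixels, gates validity at 0.2. θ folds the axial difference between local
orientation and the pixel→wound direction into [0°, 90°]. Sector radii
default to 1/4/8/12 µm (R1–R3) and are fully configurable, as no canonical
values exist. The primary sector statistic is the arithmetic mean of θ —
θ is a folded magnitude, not a circular variable — with the doubled-angle
axial circular mean and dispersion of the raw orientations reported
alongside. Before/after comparisons use a seeded two-sample permutation
test on the sector mean θ (pooled pixel shuffle, two-sided, add-one
p-value). Sector means on small sectors have limited precision regardless
of pixel count: pixels are correlated over the tensor window and along
filaments, so the innermost sector holds only ~10²  independent
orientations and its mean carries a few degrees of sampling spread; the
uniform-field check therefore pools sectors and averages seeds.

**Recruitment.** The thresholded trace sums the *raw* values of ROI pixels
strictly above mean + k·SD (k = 3) of the ROI pooled over all pre-wound
frames (a `prewound_range` restricts the pool); a zero pre-wound SD is
flagged and the strict inequality keeps a constant movie's trace at zero.
Summing raw values rather than background-subtracted excess follows the
integrated-density (RawIntDen) procedure literally; consequently adding a
constant offset shifts the threshold identically (the supra-threshold pixel
set is invariant) and shifts the trace by offset·count. The mean-intensity
trace is a plain ROI mean (18 µm² circle by default). Temporal colour
projections tint frame i with lut(i) and take the per-pixel, per-channel
maximum; a static scene thus takes the channel-wise max colour — a
documented convention, matching how such projections render static
structures as the LUT's brightest hue.

## Numerical and degenerate-input policy

Empty detection tables, empty sectors, all-zero kymograph rows, constant
ROIs and singleton tracks are all defined outcomes (empty result, NaN +
flag, zero row, explicit error, exclusion + count respectively) rather than
crashes; the specific choices are documented on each function. Ties break
deterministically: smallest radius for r_max, first histogram bin for the
Huang argmin, lowest index in assignment. All randomness flows through
explicit seeds; CLI runs with identical config + seed produce byte-identical
CSV/JSON.

## Validation scale

The test suite and the acceptance script run every recovery at the preset
conditions above — 3 seeds per speed target, 5 for the ring — completing in
a few minutes on one CPU. These sizes give the grand means a seed-to-seed
spread well inside the acceptance bands (≈1% for comets, ≈5% for the
small-n cluster regimes) while keeping the full suite fast.

## Known limitations

Registration is translation-only (no rotation/scaling) and loses exactness
at frame borders filled after large drifts (≤ 0.15 px error in testing).
The centre-of-mass subpixel localiser is mildly biased under noise, which
propagates into the documented positive speed bias. Z-drift across focal
planes is out of scope (inputs are single-plane movies), as are multi-
channel handling beyond single-channel splitting, OME-XML metadata, 3-D
PSFs and filament tracing.
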