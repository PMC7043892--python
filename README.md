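# epiwound

Quantification of wound-healing dynamics in time-lapse fluorescence movies
of the *C. elegans* epidermis.

Laser-wounding the large syncytial epidermal cell hyp7 triggers a stereotyped
sequence of subcellular events: microtubule plus-end-binding protein EB1
comets accumulate around the wound, an actin/EB1 ring forms and contracts in
two phases (a fast phase P1 followed by a ~10× slower phase P2), microtubules
reorganise into an orthoradial web around the wound, and signalling cargo
such as SNF-12 clusters and RAB-11 recycling endosomes traffic toward the
injury site. `epiwound` implements the complete image-quantification
methodology for this system as a reusable, tested pipeline:

* **comet tracking and directionality** — Laplacian-of-Gaussian spot
  detection (blob diameter 3 px), optimal-assignment frame-to-frame linking
  (2 px radius, 1-frame gap closing), per-track mean step speed
  `v̄ = ⟨‖Δx‖·p / Δt⟩` (pixel size `p`, frame interval `Δt`), the 5-px /
  120-s minimum-displacement filter for slow clusters, and angle histograms
  of track vectors referenced either to the anterior–posterior (AP) axis or
  to the wound centre;
* **wound-centred ring dynamics** — automated wound centroid, annular-mean
  radial profiles and the max-intensity radius r(t), per-row max-normalised
  AP-stripe kymographs, continuous two-segment piecewise-linear fits of r(t)
  whose absolute slopes are the P1/P2 closure velocities, and ring-interior
  area via Huang's fuzzy-entropy automatic threshold;
* **microtubule orientation** — structure-tensor local orientation with
  coherency, the wound-referenced angle θ ∈ [0°, 90°] (0° radial, 90°
  orthoradial), statistics over annular sectors R1–R3 and a permutation test
  for before/after comparisons;
* **recruitment densitometry** — thresholded integrated-density traces
  (threshold = pre-wound mean + 3 SD), mean-intensity ROI traces, and
  temporal colour-code projections;
* **preprocessing** — phase-correlation drift correction, temporal-median
  background subtraction (31-frame window), crop/substack extraction
  (e.g. the 20 s substack used for slow clusters);
* **a synthetic-movie generator** (`epiwound.synthgen`) that emulates the
  spinning-disk acquisitions with full ground truth — comets, run-and-pause
  vesicles, contracting rings, filament orientation fields, recruitment
  discs, Poisson/read noise, bleaching and stage drift — so every stage is
  validated as a parameter-recovery problem. Presets encode the measured
  dynamics (EB1 comets 0.26 ± 0.10 µm/s unwounded and 0.16 ± 0.06 µm/s near
  the wound; RAB-11 vesicles 1.31 ± 0.33 µm/s; SNF-12 clusters
  0.017 ± 0.005 µm/s pre-wound, 0.007 ± 0.004 µm/s directed post-wound;
  ring closure v2 = 0.008 µm/s with v1 = 10·v2).

## Worked example

Generate a synthetic unwounded EB1 movie (300 frames, 200×200 px,
0.3 s/frame, 0.08 µm/px, SNR ≈ 5), remove the static background, and track
the comets:

```sh
epiwound simulate --preset eb1_unwounded --seed 1 -o out/sim
epiwound preprocess out/sim/movie.tif -o out/pp --median-window 31
epiwound track out/pp/preprocessed.tif -o out/trk --diameter 3 --link 2 --gap 1
cat out/trk/track_summary.json
```

```json
{
 "mean_step_speed_um_s": 0.27773849387871175,
 "n_tracks": 4334,
 "n_tracks_with_speed": 266,
 "sd_step_speed_um_s": 0.11809542310009859
}
```

The grand mean step speed of the 266 multi-spot tracks, 0.278 µm/s, recovers
the generator's 0.26 µm/s comet speed within 7% (localisation jitter inflates
step speeds slightly; see `docs/methods.md`). The same chain on a
contracting-ring movie recovers the two closure phases:

```sh
epiwound simulate --preset ring_eb1 --seed 1 -o out/ringsim
epiwound ringdyn out/ringsim/movie.tif -o out/ring
cat out/ring/phase_fit.json
```

```json
{
 "r2_phase1": 0.9985533687717073,
 "r2_phase2": 0.9965836653421767,
 "sse": 0.2278755011441679,
 "t_break_s": 45.0,
 "v1_um_s": 0.07989450427867588,
 "v2_um_s": 0.007994002356021726
}
```

i.e. a fast contraction at 0.080 µm/s breaking at t = 45 s into a slow phase
at 0.0080 µm/s — the generator's v1 = 0.08, v2 = 0.008 µm/s, ratio 10.

The same operations are available as a library
(`epiwound.comets.detect_spots`, `epiwound.ringdyn.two_phase_fit`,
`epiwound.orientfield.theta_map`, ...); `epiwound.pipelines` bundles the
end-to-end recovery chains.

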