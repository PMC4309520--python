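# Methods

## The migration model

Cells in the agarose-spot assay are simulated as biased persistent random
walks in the plane, sampled every 10 min over a 14 h window (85 samples, the
cadence of an overnight brightfield timelapse). At each step the heading is
the persistence-weighted mix of the previous heading and the unit vector
toward the spot interior,

    h_t = angle( p·ĥ_{t−1} + (1−p)·b̂ ) + ε_t,   ε_t ~ N(0, σ²) (wrapped),

with persistence p = 0.7 and step length 0.6 µm/min × speed_scale ×
lognormal(σ = 0.2, unit mean). Cells are seeded 20–60 µm outside the spot
edge. Each cell is independently invasion-competent with probability
`migration_probability`; non-competent cells follow the same dynamics but
are mirrored back at the edge, modelling cells blocked at the agarose
interface. A cell is *migrated* when its track crossed the edge and its
final position is inside — the double condition excludes cells seeded under
the spot, which the generator never produces but real assays do.

**Treatment presets** are frozen constants: control invading fraction 0.5;
dynamin inhibition 0.4× control with speed 0.5×; AP2 (α-adaptin) knock-down
0.35× control; caveolin1 knock-down and non-silencing siRNA identical to
control. The multipliers are the effect sizes the pipeline is asked to
recover. Note that a single speed multiplier forces the percent decreases
of path length, net displacement and path-based average velocity to
coincide (~50% for the dynamin preset) — three subtly different printed
effects (45/46/50%) cannot all be matched exactly by one multiplier; all
three recoveries sit within the ±10-point acceptance band.

**Angular calibration.** The per-step heading noise σ = 9.35° was
calibrated once by Monte-Carlo so that the mean unsigned angle between a
control migrating cell's net displacement and the spot-edge perpendicular
is 2.80° under the default walk configuration (84 steps, p = 0.7); the
per-track dispersion that falls out is ≈ 2.1°. The calibration is packaged
as a constant; it is specific to the default step count and persistence,
and `GeneratorConfig.heading_noise_sd_deg` overrides it.

**Sample sizes.** Defaults are 50 cells per field and 36 fields per
condition (22 for the knock-down comparison). Fifty cells per 10×-objective
field keeps the binomial standard error of the migrated fraction near 1.7
percentage points, so a planted 60% decrease is recovered with an ensemble
sd of ~2.4 points.

## The TIRF scene model

Puncta are isotropic Gaussians (σ = 1.5 px at 0.1 µm/px — a typical TIRF
diffraction-limited spot) on a flat background (100 counts) with additive
Gaussian read noise (sd 10); SNR is defined as peak amplitude over noise sd
(default 10). The default frame interval is 2 s (the live-TIRF cadence is
not otherwise pinned down; it is exposed in the config). The cell footprint
is an ellipse with its long axis along the migration axis; the front band
faces the (off-field) spot.

Planted fates: *static* (fixed position and amplitude), *lateral*
(constant-velocity drift totalling 1–2.5 µm, above the 0.5 µm
classification threshold), *disappearing* (amplitude steps to zero at a
planted event frame — within ≤ 2 frames by construction, so the rapidity
criterion is satisfiable). Two designed negatives reuse the disappearing
rendering: *reappearing* spots return at the same position 3–8 frames
later, and *gradual* spots fade linearly over 15 frames. Global
photobleaching multiplies all pixels by exp(−rate·t) before noise.

Planted puncta keep a minimum mutual separation of 4 px (config). Closer
pairs are unresolvable at the diffraction limit, so per-spot ground truth
(which of the two disappeared?) would be ill-defined for any analysis,
manual or automatic. Event positions are drawn per region with
probabilities proportional to `front_bias`, so planted event *counts*
follow the configured ratio directly.

The second channel plants puncta co-positioned (±0.5 px jitter) with an
exact-count fraction of channel-one puncta, plus independent uniform
distractors (default 15 per cell, a chance-coincidence level of ~0.7% at
the 3 px scoring radius).

Focal adhesions are anisotropic Gaussians (σ 5 × 1.25 px, i.e. ~1 × 0.25 µm
half-axes at threshold) at 30× the noise sd — adhesion plaques are much
brighter than single pits, and the higher contrast keeps the
disassembly-trace noise floor below the measurement's 2%-of-plateau end
threshold. Disassembling adhesions hold a plateau, then decay linearly to
zero over 20–40 frames. For chance-overlap fields, the independent punctum
channel is rendered at 0.0272 puncta/µm², derived analytically as
−ln(0.93)/A_dil where A_dil = 2.67 µm² is the mean detected adhesion
footprint dilated by the default 2 px scoring radius — i.e. a designed 7%
Poisson chance of at least one punctum per adhesion.

All randomness flows from a single config seed through NumPy generators;
identical seeds reproduce stacks byte for byte. Per-condition seeds in the
pipeline derive from the run seed via CRC32 spawn keys (stable across
processes, unlike Python's salted `hash`).

## Measurement conventions and numerics

- Pixel coordinates are 0-based (row, col), origin top-left; `x` maps to
  columns. Calibrated outputs are µm (µm/h for velocities, counts/µm² for
  densities).
- *Average velocity* is path length over elapsed time. Displacement-based
  velocity is available (`mode="net"`); the path-based form is the default
  because total path length is reported alongside it.
- *Region partition*: "three equal lengths" means equal extent along the
  migration axis, not equal areas — the subsequent area normalisation is
  only meaningful if areas differ. The extent is that of the cell mask (a
  bounding-box variant was considered and rejected as it ties the bands to
  image orientation). Boundary points are assigned frontward; the axis
  comes from the spot geometry, not per-cell displacement, which the 2.80°
  calibration justifies.
- *Punctum detection*: scale-normalised LoG response, threshold = 5× the
  robust (MAD) response noise, local maxima ≥ 3 px apart, intensity-weighted
  sub-pixel centroid. At the 5σ threshold a blank 256² noise frame yields
  ≪ 1 spurious detection.
- *Linking*: greedy nearest neighbour, max step 3 px/frame, gaps up to 2
  frames bridged (allowed distance grows with the gap); ties resolved by
  distance then track id.
- *Fates*: lateral ≥ 0.5 µm net displacement; a track surviving to the last
  frame is static; a track ending early is disappearing if the intensity at
  its terminal position has fallen to ≤ 3 noise-sd above background over
  the next two frames, else censored.
- *Event criteria*: amplitude traces are sampled at the track position
  (3×3 mean, frame-median background subtracted) and smoothed with a
  3-frame moving average. Rapid: from the last frame at ≥ 90% of the
  pre-event plateau (75th percentile of the track's trace) to the first
  frame at the noise floor in ≤ 10 frames, counted inclusively from the
  plateau departure. No-reappearance: no detection within 3 px of the
  terminal position for 10 frames after the end. Not-photobleaching: the
  paper-side criterion is unquantified; it is operationalised as ≤ 10%
  decline of the cell-wide mean intensity across the event window
  (flag-tunable; the accepted-event set grows monotonically with this
  tolerance). Tracks ending within 10 frames of the stack end are censored
  — the reappearance window cannot be evaluated. Candidates must persist
  ≥ 3 frames: single-frame noise blips otherwise pass all three criteria
  vacuously.
- *Adhesion traces* integrate background-subtracted intensity over the
  union footprint of the linked object across every frame, so the decline
  can be followed below the detection threshold. Onset = last frame at
  ≥ 90% of the initial-window median plateau; end = first frame at or below
  the noise floor (2× the robust sd of trace increments, at least 2% of
  plateau). Constant traces are censored, not forced into a measurement.
- *Shifted control*: displacement magnitudes are drawn from 2–4 scoring
  radii ("moved slightly" is unquantified — close enough to preserve local
  density, far enough that the vacancy constraint can hold), directions
  uniform, re-drawn up to 50 times until the new circle contains no query
  punctum; unsatisfiable circles are skipped.
- *Statistics*: two-group comparisons use Mann–Whitney U (no test is
  prescribed for these skewed, small-n distributions; Welch's t by flag).
  Raw p-values are reported with a Holm-adjusted column alongside — no
  correction is silently applied. Comparisons are made against the control
  only, and pooled across cells by default (per-cell summaries available);
  a pooled-vs-per-cell choice is reported with both numbers where it
  matters.

## What the generator does and does not emulate

The synthetic scenes exercise the full measurement chain — rendering, noise,
detection, linking, censoring, chance coincidence — under known truth, so a
passing suite shows the estimators are unbiased and correctly calibrated
*for this scene model*. They do not emulate: non-uniform backgrounds or
illumination, punctum brightness heterogeneity and blinking, cell-shape
change or movement during a TIRF acquisition, sub-resolution punctum
clustering, 3D effects in the evanescent field, or motion more complex than
constant-velocity drift. Performance numbers (e.g. event-caller precision
and recall ≥ 0.9 at SNR 10) therefore bound what real data can give, and
thresholds may need retuning on real microscope stacks.

## Problem sizes

The packaged recovery runs use 36 fields × 2 conditions × 50 cells for the
dynamin comparison (22 fields for the knock-down), 14 rendered two-channel
cells × 50 circles for colocalisation, 30 cells × 16 adhesions for the
chance-overlap fraction, ~300 planted punctum tracks across four 512²×40
stacks for the event caller, and 100 migrating tracks for the angle
calibration — sizes chosen so each estimator's sampling error is
comfortably inside the tolerance it is checked against.
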