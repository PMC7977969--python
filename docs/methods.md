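# Methods

## Problem setting

A profile-view camera records a person eating; the recording is decimated to
6 fps (chewing tops out near 2 Hz, so 6 fps leaves headroom above the Nyquist
rate while cutting compute fivefold from a 30-fps source). Every quantity the
pipeline produces lives in the *retained-frame* index space of this decimated
stream; timestamps are always derived from the native-stream index so they
remain comparable to annotations made on the full-rate video. Decimation
keeps native frame 0 and then every k-th frame (k = native_fps / target_fps,
which must be an integer).

## Face ROI and gating

A detector is any callable mapping one frame to `(box, confidence)` or
nothing. Frames with confidence below `min_confidence` (default 0.8) are
dropped entirely; the retained stream therefore has gaps, and every
downstream series carries validity/gap flags instead of fabricated values.
Boxes that spill slightly outside the frame are clipped, not rejected,
because the chew counter needs temporal continuity more than it needs exact
box geometry. Face crops are converted to luma (ITU-R BT.601 weights — the
de-facto standard of mainstream image toolchains) and resized bilinearly to
150 rows × 120 columns by default (a taller-than-wide profile face; both
dimensions configurable).

## Affine optical flow

For each consecutive crop pair the brightness-constancy equation
`I_x u + I_y v + I_t = 0` is fitted with a velocity field linear in position
(six parameters). Numerical choices:

- Spatial gradients are central differences of the two-frame mean image;
  `I_t` is the plain difference; border pixels use one-sided differences.
- The pair is intensity-normalized **jointly** (one shared affine map of the
  pair's min/max onto [0, 1]); per-crop normalization would violate
  brightness constancy between the two frames.
- The fit is one global least squares over *all* crop pixels, giving one
  parameter set per pair — hence a single rotational value per pair, which is
  what the chew counter consumes. The expansion center is the crop center;
  the reported curl/divergence/shears are independent of that choice, the
  translations are not.
- Rank-deficient systems (texture-free crops, aperture problem) are flagged
  `indeterminate` and the pair is marked invalid, never zero-filled.

The 2×2 velocity-gradient matrix is reported in its standard first-order
decomposition: curl `r = a21 − a12` (a rigid rotation by ω per frame yields
`r = 2ω`), divergence `d_div = a11 + a22` (uniform scaling by s yields
`2(s−1)`), and shears `s1 = a11 − a22`, `s2 = a12 + a21`. Jaw grinding during
mastication is predominantly a rotation of the lower face, so `r` is the 1-D
chewing signal.

Accuracy depends on texture bandwidth relative to displacement: with
Gaussian-smoothed textures (σ ≈ 2.5 px) and motions up to 1 px translation,
0.02 rad rotation or 2% scaling, the median relative error of recovered
parameters is well under 10%; rougher textures raise the gradient-
discretization bias (this is the classical small-motion regime of windowed
least-squares flow — no pyramidal extension is provided).

## Bite counting

Per-frame bite probabilities (or hard labels) are smoothed with a centered
moving average of span 10. At the series edges the window is clipped and the
mean taken over available samples. The smoothed trace is binarized at 0.5
(tie counts as bite — the rule matters more than the choice and is
documented); each maximal run of ones is one bite event. A lone flipped
label reaches at most 1/span = 0.1 after smoothing and can never create an
event; an optional `min_event_frames` filter can additionally drop very
short events (off by default; gesture-induced false bites motivate it).

## Chew counting

Candidate segments span from the end of one bite event to the start of the
next, plus the span after the final bite (people chew their last bite); the
span before the first bite is discarded (chewing follows a bite). Each
segment is truncated to its first 52 s — the longest chewing sequence
observed in the study data this pipeline targets. Invalid flow samples
inside a segment are bridged by linear interpolation when the gap is ≤ 1 s,
otherwise the segment is split at the gap.

Each segment's short-time energy is the windowed sum of squared mean-removed
signal values (window 6 frames = 1 s, hop 1, partial final window allowed).
The dynamic threshold is `T = β · median(per-segment mean energies)` with
β = 0.5: the delegated threshold rule used by the original study is not
publicly specified, so this package adopts a median-based rule that is
meal-adaptive, robust to a minority of silent segments, and cheap to reason
about. Segments with mean energy below `T` contribute no chews.

Peaks: a sample is a peak when it exceeds its left neighbor, is at least its
right neighbor (a plateau therefore counts once, at its first index), and
has topographic prominence ≥ `drop_threshold` (default 0.5) — i.e. the
signal drops by at least that much on both sides before reaching a higher
sample. Prominence is computed with `scipy.signal.peak_prominences`; the
local-maximum rule itself is hand-rolled because library peak finders place
plateau peaks differently. By default the threshold applies to the signal in
*robust-amplitude units*: the segment signal is median-centered and divided
by the meal-level robust amplitude, defined as the median over segments of
half the 5th–95th percentile range. (A quartile-based range is too
aggressive here: a segment that is mostly rest has an interquartile range of
~0 even when it contains a strong chewing burst, which would collapse the
normalization.) Raw-unit mode is available via `normalize_amplitude=False`.

## Synthetic data

The generator scripts a meal as: lead-in 3 s; each bite lasts 2 s, is
followed by 1 s of food transport (chew-onset delay), a chewing sequence of
10–25 cycles at 1.5 Hz, and a 5-s rest tail. Twenty bites by default. These
defaults put segment durations (≈ 13–23 s) and per-meal totals (≈ 200–500
chews) in the range typical of laboratory meal recordings. The 1-s onset
delay also guarantees that the smoothing-induced widening of detected bite
events (at most span/2 = 5 frames) never clips the first chew cycle, so the
noiseless pipeline recovers counts exactly.

- **Signal level** (`signal_fixture`): the rotational trace is
  `2·jaw_amplitude·sin(2πft)` during chewing — exactly the curl a rigid jaw
  rotation of that angular velocity would induce — with one exact cycle per
  scripted chew when fps is an integer multiple of the chewing frequency
  (6 fps / 1.5 Hz = 4 samples per cycle, sampling each crest exactly). Bites
  add a large transient swing, mirroring the spike a hand/utensil occlusion
  produces in real flow traces. Labels are flipped i.i.d. with
  `label_flip_p`; Gaussian noise of `noise_sigma` rides on the trace.
- **Image level** (`render_meal`): a fixed Gaussian-smoothed random texture
  forms the face; its lower half rotates rigidly about a lateral hinge by
  the cumulative scripted jaw angle, resampled bilinearly from the base
  texture each frame (no compounding of interpolation error); a bright blob
  marks the jaw for localisation checks, and a bright occluder covers part
  of the lower face during bites.

All randomness flows from the script's single seed through named generators;
identical scripts render bit-identically. What the generator does **not**
emulate: talking, head translation and pose change, photometric drift,
multiple people, real facial appearance. Tests passing on these fixtures
therefore validate the counting logic and flow estimator under the modelled
jaw kinematics — they do not certify detector or classifier quality on real
video, which enters only through the interface contracts.

## Evaluation

Count accuracy is `100·(1 − |automatic − manual| / manual)`, reported to two
decimals; it is symmetric in the sign of the error and may go negative when
the error exceeds the reference (optional clipping at zero). This formula
reproduces, from the printed count columns, every per-subject accuracy cell
of the 28-subject reference table shipped with the test suite. Confusion
metrics (precision, sensitivity, F1) follow the usual definitions with
'bite' positive; zero denominators yield NaN rather than an exception so
degenerate folds can still be aggregated. Detector quality uses
intersection-over-union under half-open box conventions and average
precision computed by all-point interpolation: the precision curve is made
monotone non-increasing in recall and integrated exactly; mAP is the
arithmetic mean over classes.

## Problem sizes used in the shipped checks

Flow-recovery statistics use 100 seeded 100×90 textures (15-px borders
trimmed after warping to discard extrapolated pixels). Peak-counter
equivalence uses 1000 seeded random signals of mixed smooth/walk/plateau
character. End-to-end recovery uses the default 20-bite script: noiseless
once (exact recovery), and 50 seeds under 2% label flips with trace noise at
10% of the chewing amplitude (median errors reported). Rendered-meal checks
use shorter 2–3-bite scripts at 160×130 px. These sizes make the whole suite
convenient to run routinely while keeping every statistic stable across
seeds.

## Known limitations

- The flow estimator is small-motion, single-scale: displacements beyond
  ~1–2 px per frame or strong texture aliasing degrade it (no pyramids).
- The energy gate assumes chewing dominates segment energy; sustained
  talking or head motion between bites can pass the gate, as it does in real
  studies.
- Bite/chew counts after heavy detector dropout depend on the gap-bridging
  heuristic (1-s limit); meals with long occlusions will lose segments.
- MP4/AVI decoding requires an imageio backend with a video plugin;
  directories of extracted frames are the fully supported input path.
- The dynamic-threshold rule (β·median) is this package's documented choice;
  other published rules exist and can be swapped in via configuration of β
  or by gating segments externally.
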