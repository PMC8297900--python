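# Methods

## Pipeline overview

A session is one child completing doll-play story stems on camera. A
pose-estimation network reduces each frame to 2-D body keypoints with
detection confidences; this package starts from that keypoint stream.
The rating pipeline is:

1. per-frame kinematic features of the two wrists (the hands holding the
   dolls);
2. segmentation into non-overlapping 128-frame windows;
3. independent secure/insecure classification of each window;
4. a per-child majority vote over at most 500 windows;
5. Leave-One-Child-Out (LOCO) evaluation against the manual coding.

The wrists proxy the hands because the camera frames face and upper body;
whichever joints are tracked is configurable (`FeatureConfig.left_joint`
/ `right_joint`).

## Features

Six families per frame, all image-relative so that recordings of
different resolution are comparable:

| family | definition | units |
|---|---|---|
| position | (x/W, y/H) per hand | unitless in [0,1] |
| inter-hand distance | Euclidean distance of the normalized positions | unitless |
| speed | backward difference of position x frame rate | units/s |
| acceleration | abs. backward difference of speed x frame rate | units/s² |
| 1-D trajectory | x/W per hand (horizontal placing) | unitless |
| presence | per-frame detection flag; per-window proportion | — |

Conventions and degenerate cases:

- speed at frame 0 is 0; acceleration at frames 0 and 1 is 0 (the frame-0
  speed is padding, not a measurement);
- a keypoint with confidence below the missing threshold (default 0.1;
  exactly 0 always) is absent. Absent hands follow the `hold-last`
  policy: the kinematic channels keep the last seen position, so dropouts
  do not fabricate speed spikes; the presence flags and the
  `dist_valid` companion column carry the dropout information. The
  alternative `zero` policy zeroes the channels instead. The stretch
  before a hand's first detection is backfilled with its first seen
  position for the same reason;
- inter-hand distance is defined only when both hands are present; when
  invalid it holds the last defined value and `dist_valid` is 0;
- windows are `floor(T/128)` non-overlapping blocks from frame 0; the
  trailing remainder is discarded. At 30 fps a window spans ~4.27 s.
  The frame rate is read from the sequence metadata (default 30).

Translation of all keypoints leaves distance, speed and acceleration
unchanged; position and trajectory move with it. Zero motion gives
exactly zero speed and acceleration.

## Window classifier

Window labels are inherited from the child's manual coding (secure = B,
insecure = A/C/D); there is no window-level ground truth. Two backends
share the training interface, z-scored inputs (scaler fitted on the
training windows and stored with the model), optional inverse-frequency
class weighting (default on — field samples run roughly 70/30
secure/insecure), and JSON serialisation with a feature-schema hash that
prediction refuses to cross.

**recurrent-sequence** (reference): a single-layer gated recurrent unit
(GRU) over the 128-step feature sequence, hidden size 16, mean-pooled
hidden states, logistic output. Training is full backpropagation through
time with Adam (learning rate 0.02, mini-batches of 32, global-norm
gradient clip at 5), weighted binary cross-entropy. It is written in
numpy and seeded end to end: a fixed seed gives bit-identical models.
The analytic gradients are verified against finite differences in the
test suite. Depth, hidden size and schedule are this package's choices;
25 epochs is the preset used for protocol-scale runs (loss on the
synthetic task plateaus well before that), 60 the default for one-off
fits.

**summary-logistic** (baseline): logistic regression (scikit-learn,
lbfgs) on per-window summaries — mean and standard deviation of each
continuous channel plus the presence/validity proportions. Fully
deterministic and two orders of magnitude faster; it is the backend used
where determinism matters more than sequence fidelity.

**Majority vote**: the child is assigned the modal hard label over the
first `min(n, 500)` windows in temporal order. The 500-window cap bounds
the influence of very long sessions; set `max_windows_per_child=None`
for unlimited. Exact ties resolve to *insecure*: a screening instrument
should prefer sensitivity over specificity. Both the cap and the tie
rule are configurable. `vote_fraction` (share of counted windows voting
for the assigned label) is therefore always in [0.5, 1].

## Evaluation

LOCO: one fold per child; the held-out child's windows never enter
training. Per-fold training seeds are `seed + fold_index`, so a run is
reproducible without making every fold identically initialised. Metrics
are computed at the child level (after the vote — the level at which
ratings are used) and at the window level (diagnostic); the two can
differ, which is why both are always reported. Positive class for
precision/recall is insecure. Ratios with zero denominators are NaN with
a warning, never a silent 0.

A fold whose training set contains a single class (possible only in
minimal datasets, e.g. two children with one per class) cannot fit a
discriminative model; the fold predicts the training class as a constant
with a logged warning. A dataset whose children all share one class is
rejected outright.

## Agreement statistics

Confusion matrices are stored with a fixed category order — (B, A, C, D)
for four-way tables, matching the convention in which such tables are
printed, so published matrices transcribe directly. Percent agreement is
`100·trace/N` (full precision internally, nearest integer at the display
layer), discordance `N − trace`, and Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the row/column marginals
(κ reported to 2 d.p. at the display layer; NaN with a warning when
p_e = 1). Only Cohen's κ is provided — no weighted or multi-rater
variants. One printed-source quirk worth knowing: the four-way agreement
of the reference concordance table is 53/61 = 86.9%, which rounds to 87
although the source text prints 86; this module reports full precision
and nearest-integer display, and does not adopt truncation.

## Synthetic cohort generator

The generator exists because child videos cannot be shared; it emulates
the *kinematic signatures* the rater consumes, not doll play itself.
Each hand follows critically damped spring–damper dynamics (natural
frequency 6 rad/s, Euler-integrated at the frame rate) toward a
piecewise-constant target; targets switch at Poisson events
(`event_rate`/min), half of which start an approach during which both
targets contract toward their midpoint at `approach_rate`/s. Gaussian
acceleration noise (`jerk_sd`), observation jitter (`noise_sd`),
per-frame per-hand dropout, and a reflective boundary 5% inside the
image complete the model. The doll-placement region widens with the
resting inter-hand distance, so wide-separation play also ranges wider
across the image — giving the position and 1-D-trajectory families a
structural class difference rather than an incidental one.

Class presets (normalized units):

| parameter | secure | insecure | reads as |
|---|---|---|---|
| approach_rate (1/s) | 2.0 | 0.25 | fast vs reluctant proximity-seeking |
| event_rate (/min) | 8 | 24 | calm vs restless target switching |
| noise_sd | 0.004 | 0.015 | detection jitter |
| jerk_sd (units/s²) | 0.08 | 0.9 | smooth vs jerky motion |
| dropout left/right | .02/.02 | .03/.28 | both dolls vs one-doll-dominant |
| rest_distance | 0.15 | 0.45 | dolls together vs apart |

The insecure preset is a mixture family: A-labelled children get a wider
resting distance and stronger one-sided dropout, C-labelled more target
switching, D-labelled more jerk, all scaled by
`SyntheticCohortSpec.mixture_spread` (0 makes every insecure child share
exactly `insecure_params` — the configuration for strict null
experiments, where "identical class parameters" must mean identical
distributions). Cohorts assign `round(n·secure_fraction)` children to B
and split the rest A/C/D in equal thirds (remainder to C); child streams
are spawned from one seed sequence, so cohorts are reproducible and
children independent.

The default cohort — 40 children, 20/20, 768 frames (~25 s) per child at
30 fps on a 320×240 image, seed 11 — is the reference evaluation
condition; six windows per child keeps the majority vote meaningful
while LOCO with the recurrent backend stays in the minutes. Session
lengths are far shorter than real sessions; problem sizes throughout the
test suite (cohorts of 8–40 children) were chosen as the smallest that
give the statistical checks adequate power.

What passing tests on this generator do **not** show: that real doll
play separates this cleanly (the presets are deliberately
well-separated; real effect sizes are unknown here), that OpenPose noise
looks like Gaussian jitter plus Bernoulli dropout, or that the six
families carry independent signal in real data. What they do show: the
pipeline wiring is correct end to end, the protocol is leak-free, the
classifier can recover class-conditional kinematic structure when it
exists, and it finds nothing when there is none.

## Numerical choices

- Backward (not central) differences for speed: causal, and no look-ahead
  at the window boundary.
- Acceleration as |Δspeed|·fps — the magnitude of change of scalar
  speed, treating the features as physical measurements rather than
  signed vectors.
- Feature standardisation floors the standard deviation at 1e-8 to keep
  constant channels finite.
- Logistic/GRU probabilities compare to 0.5 with ≥ on the insecure side,
  consistent with the tie-to-insecure convention.
- κ and the metrics are plain closed forms; the test suite checks both
  against brute-force recomputation from regenerated label pairs (and κ
  against scikit-learn) to 1e-12.

## Known limitations

- Four-way (ABCD) and organised/disorganised *automatic* classification
  are out of scope — binary secure/insecure only, as is defensible at
  ~100-child sample sizes.
- No depth channel: inter-doll distance in 3-D is not modelled; the
  2-D inter-hand distance stands in.
- The simulator has no narrative structure (no story-stem timing, no
  crisis point) and no biomechanics; it is a statistical stand-in.
- The recurrent backend is a compact reference implementation, not a
  tuned architecture; on real-scale data a deeper model and a proper
  validation split for early stopping would be warranted.
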