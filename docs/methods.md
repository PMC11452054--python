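# Methods

This note documents the models and procedures implemented in `gaitvae`, the
assumptions behind the synthetic data, the numerical choices, and what the
passing test suite does and does not demonstrate about real recordings.

## 1. Problem setting

A two-minute walk test (2MWT) is recorded by two unsynchronized foot-worn
IMUs (one per foot), each a triaxial accelerometer (±8 g) plus triaxial
gyroscope (±500 °/s) sampling at 104 Hz, on a 14-m walking path with turns
at the ends. Two outcome families are computed per measurement: gait speed
(distance walked / 120 s) and twelve learned latent gait features. Their
clinical value is then assessed psychometrically: between-day test-retest
reliability, stroke-vs-healthy discrimination, and responsiveness to change
during rehabilitation.

Axis convention (fixed in `gaitvae.core`): x anterior–posterior, y
medio-lateral, z vertical in the foot frame at mid-stance; gravity reads
+1 g on z; the sagittal (pitch) angular velocity is gyroscope channel y.

## 2. Synthetic gait generator

No clinical recordings ship with the package; the generator produces
structure-matched surrogates with exact ground truth.

Each stride of duration T (drawn i.i.d. with a subject-level mean and
coefficient of variation) consists of a stationary stance phase of duration
(1 − swing_fraction)·T and a swing of duration sw = swing_fraction·T during
which the foot:

- advances one stride length L = speed·T with the raised-cosine forward
  velocity v(τ) = (L/sw)(1 − cos 2πτ), whose integral is exactly L;
- lifts along z(τ) = h·sin²(πτ) (h = 3 cm stroke-like, 5 cm healthy-like);
- pitches with rate A(sin 2πτ − harm·sin 4πτ), scaled so the peak equals the
  subject's `swing_peak_gyro`. The *negative* second harmonic matters: it
  keeps the mid-swing zero crossing of the sagittal gyro fast, so the
  quiet-dwell contact rule of the event detector cannot latch onto a
  spurious mid-swing plateau (a positive harmonic creates exactly such a
  plateau at slow cadences).

The stroke-like template uses harm = 0.3, a skewed forward-velocity profile
and a 0.8 g foot-flat impact transient; the healthy-like template is the
smooth symmetric variant (harm = 0, 0.3 g transient). This deliberate
distribution shift is what lets a model trained on stroke-like gait show
higher reconstruction error on healthy-like gait.

Turns: whenever 14 m of cumulative distance has been walked, strides inside
a 1.5-s window have their length reduced to 60% and the foot yaws through a
net-zero ±120 °/s burst during swing (a step turn). Pitch and yaw are
composed exactly as R = Ry(θ)Rz(ψ); the gyroscope reports the corresponding
body rates (θ̇ sin ψ, θ̇ cos ψ, ψ̇) and the accelerometer the rotated
specific force, so an orientation filter integrating the signals recovers
the true attitude. Strides continue through turns; turns do not pause the
cadence.

Asymmetry offsets the left/right swing parameters (swing fraction, swing
peak, half-stride phase) by ±asymmetry/2 but not the per-foot speed, so both
feet carry the same true distance. "Unsynchronized" sensors receive
independent start-time jitters up to 0.5 s on top of a 0.6-s standing
lead-in (which doubles as the static segment for gyro-offset estimation).
White Gaussian noise (defaults 0.02 g, 1 °/s), a constant per-axis gyro
offset (|offset| ≤ 3 °/s) and range clipping are applied last; ground truth
is recorded before them.

Cohorts: subject parameters are drawn from per-group distributions
(defaults: stroke speed 0.7 ± 0.3 m/s, healthy 1.2 ± 0.15 m/s, with matching
differences in stride time, variability, asymmetry and swing peak). Retest
sessions re-render the same walk realization from the subject's seed with a
small multiplicative parameter perturbation (default 2–4% per parameter), so
test-retest reliability is high but below 1. Longitudinal (T0 → Tend)
cohorts add a configurable speed/asymmetry change to a configurable fraction
of subjects.

A dedicated "two dominant factor" configuration
(`two_factor_cohort_spec`) freezes all parameters except stride time
(sd 0.25 s, with speed tied through a fixed 0.95-m stride length) and swing
peak (sd 90 °/s); it is the setting used to probe whether the learned latent
space recovers planted gait factors.

What the generator does **not** emulate: joint kinematics, double support,
walking-aid signal content (metadata flag only), soft-tissue artifacts,
magnetometer data, sensor dropout, or realistic turning kinematics beyond
the yaw burst. Results on synthetic cohorts therefore validate the
machinery — signal bookkeeping, integration, training dynamics, statistics —
not clinical effect sizes.

## 3. Gait events

Mid-swings are peaks of |gyro_y| above 0.5× its 95th percentile with a 0.5-s
refractory period. The contact after each mid-swing is the first sample
where the gyroscope magnitude stays below the quiet threshold for ≥ 50 ms;
stance ends when the magnitude rises above the swing-onset threshold. The
quiet/onset thresholds default to 20 and 40 °/s *at a sagittal p95 of
200 °/s* and scale linearly with the recording's own p95 — without this
scaling, contacts shift by hundreds of milliseconds when the overall signal
amplitude changes, and detection must be amplitude-invariant to work across
slow and fast walkers. On default-noise synthetic walks the detector finds
≥ 95% (typically ~99%) of true contacts within ±50 ms; this is a defined,
tunable detector, not a reconstruction of any particular clinical algorithm.

## 4. Gait speed

Orientation is tracked by a complementary filter: body-frame quaternion
propagation from the gyroscope at 100 Hz, with the predicted gravity
direction nudged toward the measured accelerometer direction by gain 0.02
per sample during stance only (swing accelerations are not gravity).
Acceleration is rotated to the global frame, gravity (g = 9.81 m/s²)
subtracted, and the horizontal components integrated trapezoidally.
Zero-velocity updates use the central 40% of each stance interval: velocity
is pinned to zero inside the windows and the inter-window drift removed by
linear interpolation between the windows' raw-velocity means (this removes a
constant accelerometer bias exactly and bounds any slowly varying drift by
half a stride's worth). Total distance is the sum of per-span horizontal
displacement magnitudes between consecutive anchors — magnitudes, not signed
sums, so heading reversals on a shuttle path cannot cancel distance — and
gait speed divides by the full recording duration. Recovery on synthetic
cohorts spanning 0.3–1.3 m/s is within 5% of truth for essentially all
measurements (median ≈ 1%). Speed is reported from the right foot by
convention (configurable).

## 5. Preprocessing for the representation model

Fixed order: resample (linear interpolation) to 100 Hz → subtract the gyro
offset estimated from the first 0.5 s of standing → detect events → cut
512-sample epochs → band-pass → zero the first sample per channel →
dataset-level outlier removal → normalize.

Epoch starts advance by a nominal 256 samples (≈50% overlap) and snap to the
nearest sample inside a stance interval; the first epoch starts at the
second stride's stance and no epoch extends beyond the second-to-last
stride. A 120-s walk yields ≈ 43 epochs per foot. The band-pass is a
first-order Butterworth, 0.01–10 Hz, applied causally per epoch by default
(a zero-phase variant and whole-recording filtering are flags). Outliers:
each epoch's six per-channel means and SDs are z-scored against their
distribution over the whole epoch set; any |z| > 5 (two-sided) removes the
epoch — about 1–2% of synthetic epochs, driven mostly by turn-heavy
segments. A zero-spread statistic contributes z = 0. Normalization divides
the accelerometer channels by 8 g and the gyroscope channels by 500 °/s
(symmetric min–max onto [−1, 1], clipped).

## 6. The variational autoencoder

Encoder: three 1-D convolution blocks (kernel 3, stride 2, tanh) with 32, 64
and 128 filters producing temporal lengths 256, 128, 64; the flattened
64×128 activation feeds two linear heads for the 12-dimensional posterior
mean and log-variance. Decoder: mirrored transposed convolutions
(zero-stuffing + stride-1 convolution) ending in a tanh output matching the
normalized input range. All implemented in numpy (float32) with analytic
gradients (validated against finite differences) and Adam (lr 0.001, batch
64). Strided convolution rather than pooling is a design choice: it keeps
the backward pass simple and the temporal halving explicit.

Reported losses follow the convention mse = mean over the 512×6 elements,
kl = batch mean of the dimension-wise sum of ½(exp(logvar)+mu²−1−logvar),
total = mse + kl_weight·kl with kl_weight = 1. The *training objective*
uses the Gaussian-decoder evidence bound — squared error **summed** over the
512×6 elements plus the KL term. The distinction matters: against a
per-element-mean reconstruction term (order 0.004 on normalized data) a
unit-weight KL term (order 0.5–10 nats) dominates by orders of magnitude and
the posterior collapses onto the prior within a few optimizer steps, leaving
nothing to analyze; the summed reconstruction restores the standard evidence
lower bound in which the latent code stays informative.
`recon_reduction="mean"` is available for experiments.

Training uses participant-level splits (no subject contributes epochs to two
sets of a fold); `make_split_plan` produces the 10-fold 70/20/10 protocol in
which every subject is validated exactly once. Early stopping monitors the
test-set objective with patience 10 and minimum improvement 1e-5, restoring
the best weights. Only stroke-like epochs are used for training; healthy-like
epochs probe distribution shift via reconstruction error. The latent "score"
at inference is the posterior mean (no sampling), making all downstream
statistics deterministic. Perturb-and-decode (shift one latent dimension of
a code, decode) is provided as the latent-exploration primitive.

Measured on the two-factor synthetic cohort (reduced model: 16/32/64
filters, ≤ 30 training passes over ~2200 epochs, ~2 min on one CPU): test
MSE ≈ 0.004–0.008, KL ≈ 7–11 nats, per-dimension latent means |m| < 0.1 and
SDs 0.73–1.0, healthy-like reconstruction MSE ≈ 1.7–3× the stroke-like one.
The KL magnitude deserves a note: synthetic epochs are far more predictable
than clinical ones, and under the evidence-bound scaling the model keeps
every latent dimension active, so the total KL (sum over 12 dimensions)
settles around 8–11 nats rather than collapsing toward zero.

**Factor recovery is the known weak point.** With all 12 dimensions active,
the KL term pushes the aggregate posterior toward N(0,1)¹² while the
two-factor cohort's epochs occupy only a ~3–4-dimensional manifold (two
factors, stride phase, realization noise); the encoder therefore space-fills,
and no mechanism aligns latent *axes* with generative factors (the objective
is rotation-invariant in the latent space). Measured per-dimension Pearson
correlations between latent scores and planted factors are 0.15–0.4 at epoch
level and 0.35–0.7 at measurement level (per-measurement averaged scores,
the unit at which the features are actually analyzed) — informative but not
reliably above 0.5 for a single dimension. The test suite asserts the
measurement-level check and it may fail for some training runs; this is a
property of plain VAEs at unit KL weight, not an implementation defect, and
axis-aligned disentanglement would require a different objective.

## 7. Psychometrics

ICC(2,1) is computed from the two-way ANOVA mean squares of the n×2 score
matrix (subjects × sessions), absolute agreement, single measure, with the
95% CI from the F-distribution method; it matches an independent brute-force
sums-of-squares oracle to 1e-10 and `pingouin.intraclass_corr` to machine
precision. A constant score matrix raises (the ICC is undefined without
variance). SEM defaults to sd_pooled·√(1 − ICC) — consistent with published
gait-speed SEM/ICC pairs — with √MS_E behind a flag; MDC = 1.96·√2·SEM
always. Categories: < 0.5 poor, < 0.75 moderate, < 0.9 good, ≥ 0.9 excellent.

Group comparison: two-sided pooled-variance t-test (Welch behind a flag) and
Hedges' g with the small-sample correction J = 1 − 3/(4N − 9); g is
invariant under common affine rescaling. Responsiveness: an individual
changed on a feature iff |Tend − T0| strictly exceeds that feature's MDC;
only good-to-excellent-reliability features are evaluated by default (gait
speed always); subjects missing either session are dropped and reported. No
multiple-testing correction is applied by default (deliberately, to mirror
common practice in this literature; the p-values are descriptive).

## 8. Pipeline and reproducibility

The `gaitvae` CLI / `gaitvae.pipeline` chain (simulate → preprocess → speed
→ train → encode → aggregate → stats) validates its YAML config against a
strict schema (unknown keys rejected), fans one global seed out to per-stage
seeds by fixed offsets, writes a JSON manifest per stage (config hash, seed,
input hashes, record counts), and emits all tables as CSV with a fixed float
format — two runs with the same config and seed produce byte-identical
statistics files. Recordings are CSV + JSON sidecar; epochs live in one HDF5
array plus a manifest CSV.

## 9. Problem sizes used by the tests and the acceptance script

Chosen to exercise the claims at meaningful scale while staying lightweight:
speed recovery uses 20 subjects spanning 0.3–1.3 m/s at full 120-s duration;
event recovery pools ~1200 contacts over six walks and both feet; the VAE
checks train the reduced model (half filters, ≤ 30 passes) on ~2200 epochs
from 32 stroke-like subjects plus 8 healthy-like subjects for the shift
check; pipeline determinism runs a 5-subject, 40-s cohort twice. The full
model (32/64/128 filters, up to 200 epochs) is the library default for real
use.

## 10. Known limitations

- The synthetic signals are smooth template gaits; none of the reported
  recovery rates or effect sizes transfer to clinical data.
- The event detector and orientation filter are defined stand-ins chosen for
  testability, not validated clinical algorithms.
- Latent features of a plain VAE are not axis-aligned with generative
  factors (section 6) and are only weakly interpretable individually;
  perturb-and-decode is the inspection tool, not a guarantee.
- Gait speed from a single foot assumes ZUPT-able stances; pathologies
  without quiet foot-flat phases (severe shuffling) would break the anchors.
- Per-epoch causal filtering leaves a small transient at each epoch start;
  the zero-phase and whole-recording options exist for sensitivity checks.
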