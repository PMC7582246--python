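# Methods

`gaitstgp` implements a complete bench for estimating spatiotemporal gait
parameters (STGPs) from wearable inertial sensors in knee-osteoarthritis (OA)
and total-knee-arthroplasty (TKA) populations: a gait simulator that stands in
for a motion-capture laboratory, the marker-based reference analysis, the IMU
preprocessing chain, a convolutional regression ensemble, and the sensor-
placement experiment with its nonparametric ranking statistics.

## The estimation problem

Each full stride (heel strike to ipsilateral heel strike) is described by 12
parameters: four spatial (step length, stride length, step width, toe-out
angle), six temporal (step, stride, stance, swing, single-support and
double-support time) and two general (cadence in steps/s, speed in cm/s).
Clinically these are measured with optical motion capture; the package's goal
is to predict them directly from raw, fixed-length windows of body-worn IMU
signals (3-axis free acceleration + 3-axis angular velocity at 40 Hz) without
orientation estimation or double integration, using one small 1-D CNN per
parameter.

## Gait simulator

No public OA/TKA gait dataset with paired marker and IMU recordings exists,
so every downstream stage is exercised against a parametric simulator whose
ground truth is exact by construction.

**Population model.** Defaults are per-cohort, per-pace means and SDs of the
12 parameters for OA and TKA cohorts at slow/normal/fast paces (units: cm, s,
deg, 1/s, cm/s). A subject draws a per-parameter z-offset once (applied at
every pace), with between-subject SD set to half the population SD; the
within-subject stride-to-stride SD is the remainder (`sqrt(3)/2` of the
population SD), so pooling many subjects recovers the configured variance.
The half/half split is an assumption (the descriptive tables the defaults
come from pool subjects) and is configurable via
`BETWEEN_SUBJECT_SD_FRACTION`.

**Free vs. derived parameters.** A kinematically consistent stride cannot
realize 12 independently drawn numbers: cadence is 2/stride-time by
definition, speed is stride-length/stride-time, a step is half a stride, and
support phases partition stance. The simulator therefore samples five free
quantities per stride — stride length, stride time, stance time, step width,
toe-out angle — and derives the rest from the realized footfall layout. The
published descriptive table is itself not exactly consistent at printed
precision (e.g. one cohort prints step time 0.5 s against stride time 0.9 s),
so the derived parameters track the identity-implied means, not the printed
cells; the distribution-fidelity test in `tests/test_synthetic.py` asserts
exactly this. Toe-out is sampled signed (toe-in occurs in these populations)
and recorded unsigned, so its realized mean is the folded-normal mean of the
configured distribution.

**Exact-recovery construction.** All event times are snapped to the 100 Hz
marker grid. Heel markers hold their footfall position through stance and
move to the next footfall during swing with zero endpoint velocity, so
positions read at event samples equal the footfall values exactly; heel
height is a cosine arch with its minimum exactly at each heel strike; the toe
clearance bump is positioned so the maximum upward toe velocity falls exactly
on the toe-off sample. Consequently the marker analysis recovers every truth
parameter to machine precision at zero noise — the closed loop validates the
analyzer's definitions, not a tolerance. The heel-height arch is stylized
(a real heel stays flat through mid-stance); only the event structure and
footfall geometry matter downstream.

**IMU synthesis.** Segment pitch angles (foot, shank, thigh) are
piecewise-smooth curves tied to the same events: a plantarflexion drop whose
rate minimum lies exactly at heel strike, a slow stance recovery, and a swing
dorsiflexion bump whose rise rate scales with stride length (rise time capped
at 0.18 s so slow short-stride gait still yields a detectable swing peak, and
the terminal-swing rate capped at 8 rad/s so the heel-strike dip is always the
deepest minimum between swing peaks). Gyroscope channels are analytic-grid
derivatives of these angles; free accelerations are second differences of
segment positions evaluated on a dense 400 Hz grid and decimated to the
native 40 Hz. Left-side medio-lateral channels are sign-mirrored so that the
left-reflection step of the pipeline maps left strides onto the right-side
convention. Additive white Gaussian noise (default SD 0.05 rad/s on gyros,
0.2 m/s^2 on accelerometers) models sensor noise; markers stay noise-free,
playing the ground-truth role of an optical system.

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: soft-tissue artifact, sensor mounting misalignment and
drift, foot-strike style variability, turning strides, double integration
drift, and any pathology-specific waveform shape beyond first-order parameter
shifts. Results on simulated data validate the pipeline's mechanics and
internal consistency, not clinical accuracy.

## Marker analysis

Heel strikes are prominence-filtered local minima of heel height (defaults:
0.5 cm prominence, 0.4 s minimum separation — below the fastest plausible
stride). Toe-off is the instant of maximal upward toe velocity inside each
stride; this rule is a documented substitute for an under-specified
convention and is validated only against the simulator. The progression axis
is re-estimated per trial from the pelvis displacement, making all spatial
parameters invariant to lab-frame translation and rotation about the
vertical. Single support is the contralateral swing time overlapping the
ipsilateral stance, double support the remainder of stance; ties in extremum
location break toward the earlier sample; strides with marker gaps or missing
contralateral context are dropped, never imputed.

## IMU pipeline

Streams are linearly up-sampled from 40 to 100 Hz (inclusive endpoints, grid
at exact multiples of 0.01 s). Strides are cut at the sagittal foot-gyro
swing peaks (threshold 3 rad/s): each window runs from the signal minimum
before one peak to the minimum before the next, which for walking is the
post-heel-strike deceleration dip. Left windows are mirrored about the
sagittal plane (negate ay, gx, gz across all sensor blocks, pelvis included,
i.e. a whole-body mirror). Channels are scaled into [-1, 1] by full-scale
sensor ranges (160 m/s^2, 34.9 rad/s = 2000 deg/s — typical for the sensor
family; out-of-range samples are clipped and counted). Windows are
zero-padded at the tail to 212 samples (2.12 s at 100 Hz; trailing padding
keeps stride onset at index 0 for the convolutions) and labeled with the
marker-derived parameters of the stride whose heel strike is nearest the
window start (tolerance 0.1 s; closer window wins duplicates, earlier wins
ties).

## Network and training

Per target parameter, a compact 1-D CNN: conv(32 filters, kernel 15) - ReLU -
maxpool 2 - conv(64, 9) - ReLU - maxpool 2 - flatten - dense 64 - ReLU -
dense 1 (linear). Filter counts and kernel sizes are package defaults chosen
to keep the receptive field within one stride and the parameter count of
order 1e5; they are configurable in `NetworkSpec`. The output layer is
linear: a rectified output cannot represent signed residuals. Loss is MSE,
optimized with Adam at learning rate 0.001, beta1 0.9, beta2 0.999; batch
size 32; default 300 epochs with best-validation-epoch checkpointing (which
makes long epoch budgets safe at any scale). Targets are standardized
internally during optimisation — the optimum is unchanged and Adam's step
size then suits every parameter's unit — and all reported losses and
predictions are in label units. Weight init is seeded He-normal; training is
bit-deterministic for a fixed seed. The padded window alone is the input;
valid length is not fed to the network.

## Experiment design

The 15 sensor combinations are all nonempty subsets of {feet, pelvis,
shanks, thighs} in canonical full-factorial order. Cross-validation is
subject-wise: each fold's test set is one OA, one unilateral-TKA and one
bilateral-TKA subject (drawn without replacement across folds), with the
remaining subjects' strides split 80/20 into train/validation per fold.
Metrics: ME = mean(pred - label), MAE = mean|pred - label|, and NAPE — the
absolute error divided by the mean labeled value of the (fold, target) test
cell, x100, pooled across folds. A leakage assertion inside the driver
guarantees no test subject's strides reach training or validation. DOE cells
are cached to CSV and skipped on rerun; failed cells are logged and excluded
from downstream ranking with a count.

## Ranking statistics

Per-parameter mean-NAPE ranks (average ranks on ties) are averaged within
spatial/temporal/general categories and overall. The Friedman test uses the
tie-corrected statistic; for tiny tie-free problems the p-value is computed
by exhaustive enumeration of within-block rank permutations, otherwise from
the chi-square reference with k-1 degrees of freedom. Dunn's post hoc
compares mean ranks pairwise with SE sqrt(k(k+1)/(6n)) and Bonferroni factor
C(15,2) = 105 (adjusted alpha 0.05/105 = 0.000476). Homogeneous subsets
follow the stepwise convention: sort by mean rank and extend each subset
while all within-subset pairs stay non-significant; subsets may overlap.
The blocking unit for the Friedman test is the per-(stride, parameter) NAPE
observation by default, with per-parameter means as the configurable
alternative; the choice is not dictated by the experiment design and both are
exposed.

Out-of-distribution screening uses the Jensen-Shannon divergence between a
test subject's per-parameter stride distribution and the pooled training
distribution: 30 equal-width histogram bins over the pooled range, 1e-9
additive smoothing, natural-log base (bounded by ln 2 ~ 0.693). Subjects
with fewer than 5 strides are flagged as insufficient data rather than
scored; the default flag threshold is 0.2 nats, comfortably above the
~0.05 nats a 200-stride in-distribution subject scores and far below the
near-ln 2 of a 5-SD shifted outlier.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale, as
a deliberate design point for a reproducible single-machine bench: the
closed-loop check uses ~240 strides across both cohorts and all paces; the
learning experiment uses 20 subjects x 3 paces x 5 strides/side (~650
segments), the feet combination, stride length + stride time, 2 folds and 60
epochs. Under those conditions held-out-subject NAPE lands around 4-5% for
stride length and 2-3% for stride time — the temporal target is predicted
more accurately than the spatial one, the same qualitative ordering a
full-scale run exhibits. Scaling up (15 combinations, 12 targets, 5 folds,
300 epochs) is a configuration change, not a code change.

## Known limitations

- Simulator realism is limited to event structure, footfall geometry and
  first-order parameter statistics (see above); waveform morphology is
  stylized.
- The toe-off marker rule and the stride-window boundary rule are documented
  package choices validated against the simulator, not against a published
  convention.
- Sensor frames are taken axis-aligned with anatomical axes at neutral
  stance; no orientation estimation is performed, so the simulated "free
  acceleration" is a lab-frame second derivative assigned to sensor axes.
- The homogeneous-subset procedure is a structural convention; its exact
  subsets depend on the blocking choice for the Friedman test.
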