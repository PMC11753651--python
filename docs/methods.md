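# Methods

This note documents the models, conventions and numerical choices behind
`gaitrel`, and what the synthetic data generator does and does not emulate.

## Coordinate and angle conventions

Laboratory axes are X = mediolateral, Y = anteroposterior, Z = vertical.
Every segment is an unconstrained 6-DoF rigid body: a pose is a 3×3 lab-frame
rotation plus a position in metres, sampled at a fixed frame rate (default
100 Hz). No joint-constraint model or anatomical calibration is applied.

Angles are Cardan angles in the fixed x-y-z sequence — rotation about x
(sagittal), then the rotated y (frontal), then the rotated z (transverse) —
reported in degrees, the clinical convention. The sequence places the
largest (sagittal) rotation first, which keeps the middle angle small and
the decomposition far from gimbal lock in normal gait; within 1° of ±90°
the decomposition degenerates, a warning is emitted and the residual
rotation is assigned by the zero-z convention.

Joint angles express the distal segment relative to the proximal
(`Rᵖᵀ·Rᵈ`). Segment angles are expressed relative to a progression frame
whose Y axis is the horizontal unit vector from the first to the last
pelvis position (an error is raised below 0.5 m of net displacement) and
whose Z axis is the lab vertical. For left-side joints and segments the
frontal and transverse components are negated so both limbs read the same
way under the right-hand rule; the pelvis is a midline segment and is never
negated. These conventions make all angle outputs exactly invariant to the
walkway direction (rotating an entire trial about the vertical axis changes
nothing), which is tested to 1e-9 degrees.

## Event detection

Heel strike (HS) and toe off (TO) are found from zero crossings of
anteroposterior velocities relative to the pelvis origin — the standard
kinematic substitute when force plates are absent. Two foot points are
used: the proximal point (the foot segment origin, heel end) for HS and the
distal point (one configurable foot length, default 0.25 m, along the
foot's long axis) for TO.

With the relative position taken as foot-minus-pelvis and the AP axis along
the progression direction, the heel's relative AP position is maximal at
heel strike and the toe's minimal at toe off. Hence the defaults: HS at the
*negative*-going zero crossing of the heel's relative AP velocity, TO at
the *positive*-going crossing of the toe's. Published descriptions of the
velocity-based method sometimes quote the opposite signs; those correspond
to taking the relative signal as pelvis-minus-foot, and
`EventConfig.hs_crossing` flips the convention for such pipelines. The two
conventions are mirror images; only the pairing of crossing direction to
event type changes.

Numerical details, each overridable in `EventConfig`:

* velocities are low-pass filtered with a zero-lag Butterworth at 6 Hz,
  effective order 4 (a half-order filter run forward and backward) — the
  field-standard gait filter; pure-tone signals keep their zero crossings
  exactly under a zero-phase filter;
* crossings are located to sub-frame precision by linear interpolation
  between the bracketing frames (frame-resolution timing is an option);
* same-type events closer than a 0.4 s refractory interval — well below any
  physiological stride time — are discarded, which suppresses doubled
  crossings caused by noise;
* events within 0.1 s of either end of the record are dropped, where
  finite-difference and filter edge effects live.

A gait cycle is the earliest pair of consecutive ipsilateral heel strikes
enclosing exactly one ipsilateral toe off and exactly one contralateral
heel strike; at most one cycle per side per trial is analyzed. Sides
without a valid cycle are omitted with a warning record, not an error.

## Spatiotemporal parameters

Per side and cycle: stance = HS→TO, swing = TO→next HS, stride = HS→HS,
step = contralateral HS → ipsilateral HS, double support = (first
contralateral TO after the starting HS − starting HS) + (ipsilateral TO −
contralateral HS); cadence is reported both as strides/min (60/stride) and
steps/min (60/step) under explicit column names. Spatial parameters project
heel positions into the progression frame: stride length and step length
are AP projections, stride width the absolute ML projection between the
ipsilateral heel at its HS and the contralateral heel at its HS. Using
projections rather than 3-D distances makes length and width an orthogonal
decomposition of the displacement and keeps all values invariant to
walkway direction. Speed = stride length / stride time, so
speed × stride time = stride length holds exactly; stance + swing = stride
is exact by construction. If the trial window clips the contralateral TO,
double support is reported missing rather than extrapolated. Bilateral
values are the mean of the two sides and are flagged missing if either
side is.

Relative velocities use central differences with second-order one-sided
differences at the two record ends (exact for affine and quadratic
positions); events never occur near the ends given the generator's
lead-in. Waveforms are normalized to 101 points over the cycle by linear
interpolation — exact for affine signals, no overshoot, idempotent on
already-normalized curves.

## Reliability statistics

**CMD.** The coefficient of multiple determination of W repeated curves of
length T compares the within-time-point variance of repetitions to the
total variance:

    CMD = 1 − [Σ_{w,t}(Y_wt − Ȳ_t)² / (T(W−1))] / [Σ_{w,t}(Y_wt − Ȳ)² / (WT−1)].

CMD ≤ 1 always, equals 1 only for identical repetitions, can be negative
when repetitions disagree more than the curve varies, and is invariant to
shifting or rescaling all values. Effect-size bands: > 0.04 small, > 0.25
medium, > 0.64 large (strict thresholds).

**ICC.** ICC(3,k) is the two-way mixed-effects *consistency* coefficient
for the average of k measurements, computed from the two-way ANOVA mean
squares; ICC(3,1) follows by the Spearman–Brown identity (held to 1e-12 and
cross-checked against `pingouin` in the tests). The 95 % CI uses the
F statistic BMS/EMS with (n−1, (n−1)(k−1)) df. Reliability bands: < 0.5
poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent (boundaries 0.5 and
0.75 open the higher band; excellent requires strictly more than 0.9).

**SEM / MDC.** SEM = SD_total · √(1 − ICC(3,1)), with SD_total taken over
all analyzed trials and ICC(3,1) from the same ANOVA as the reported
ICC(3,k). Using the single-measurement ICC is deliberate: SEM describes the
error of one measurement, and with SD·√(1−ICC(3,k)) the k-trial averaging
would be double-counted. MDC = 1.96·√2·SEM; the ratio MDC/SEM = 2.77186 is
asserted as an invariant on every reported pair.

**Aggregation layouts.** The within-session ICC stacks subject-session
units as rows (9 × 3 = 27) against the five sampled trials as columns,
yielding one value per parameter while using all data; the alternative
(one ICC per session, estimates averaged) is available as
`icc_layout="per_session_mean"`. The between-session ICC uses subjects as
rows and the three session means of the sampled trials as columns. CMD is
computed per subject per session per side across the sampled trials,
averaged over sessions and then over the two sides (the midline pelvis has
one curve per cycle window); between sessions, per subject across the three
session-mean curves. Per-subject CMDs are summarized by mean, sample SD and
a t-based CI95 (n−1 df). Grand means and SDs cover *all* collected trials
while ICC/SEM/MDC use only the sampled ones. Trials failing cycle assembly
are excluded and enumerated in the provenance block; the run aborts only
above a configurable failure fraction (default 10 %).

Degenerate inputs are handled explicitly: zero total variance defines
CMD = 1, zero between-row variance leaves the ICC undefined — both flagged
with a warning. Because "identical values" leaves float accumulation
residue of order machine-epsilon² in the sums of squares, degeneracy is
detected with a relative threshold (1e-20 × scale) rather than exact zero.

## The synthetic generator

The generator emulates the reference reliability design: 9 subjects × 3
sessions × 5 collected trials at 100 Hz, each trial one full gait cycle per
limb with a quarter-cycle lead-in and tail so velocities are defined at all
events. Defaults describe typical healthy-adult overground gait: cadence
53.5 strides/min, stride length 1.366 m (speed 1.218 m/s), stride width
0.172 m, stance fraction 0.665 (total double support ≈ 0.37 s/cycle).

The pelvis advances at the implied speed with sinusoidal vertical (25 mm)
and mediolateral (20 mm) oscillation; thigh and shank follow forward
kinematics driven by 3-harmonic Fourier joint-angle templates whose
amplitudes follow the clinical plane hierarchy (sagittal ≈ 40–50°
peak-to-peak, frontal ≈ 5–8°, transverse ≈ 3–6°). The left limb is the
sagittal-plane mirror of the right at half a cycle's phase offset, which is
exactly what the left-side negation convention assumes (verified as a
property test).

Ground contact is *programmed*, not physically simulated. The heel carries
a pure first-harmonic AP excursion (default 0.07 m) relative to the pelvis
whose maximum falls exactly at the programmed heel strike, and the foot
pitch follows a closed-form program — solved by first-harmonic phasor
algebra — that makes the toe's relative AP position another pure first
harmonic with its minimum exactly at the programmed toe off. Because both
signals are band-limited, the zero-lag filter leaves their zero crossings
in place and the detector recovers programmed events to well under one
frame on noiseless data; all programmed spatiotemporal truths
(stride = cadence⁻¹·60, step = stride/2, lengths from the periodic heel
track, width from the constant ML offsets) are exact closed forms.

Consequences a user should know:

* during stance the foot *glides* near the pelvis rather than sticking to
  the floor — no downstream quantity observes this, but the trajectories
  are not foot-flat realistic;
* the foot-pitch program is exaggerated relative to real gait (tens of
  degrees at contact) — it is the price of exact closed-form event truth;
* ankle sagittal/transverse truth curves derive from the chain
  (shankᵀ·foot with the pitch program) rather than free templates; the
  ankle's frontal component is free because rotation about the foot's long
  axis does not move the toe point;
* gait is bilaterally symmetric up to the sampled effects; there is no
  treadmill mode, no kinetics, and no keypoint/video level.

Hierarchical variance: subject, session and trial effects are zero-mean
normal draws added to the scalar template parameters and to the waveform
coefficients (an additive offset in degrees on the constant term and a
relative amplitude scale on the harmonics), one draw per label, with
per-trial RNG substreams derived from (seed, subject, session, trial) so
trial order never changes results. Default SDs (subject/session/trial):
cadence 3.2/0.9/0.5 strides/min, stride length 0.10/0.025/0.020 m, stride
width 0.022/0.005/0.006 m, stance fraction 0.010/0.004/0.004, angle offset
2.0/0.8/0.5°, amplitude scale 6/2.5/1.5 %. The subject-level SDs are sized
so that total SDs land near values reported for healthy adults (e.g. cycle
time ≈ 0.07 s, stride length ≈ 0.11 m); the session/trial splits are
plausible placeholders — real studies of this design do not report the
decomposition — so tests that pass on synthetic data certify the
*machinery* (recovery, invariances, statistical identities), not the
specific reliability magnitudes of any real capture system. Frame noise is
isotropic Gaussian on positions only (default SD 1.5 mm), leaving
orientations noise-free; this is the simplest model that perturbs both
events and angles.

## Interfaces

The canonical interchange format is a versioned JSON dataset schema
(`gaitrel-dataset/1`): frame rate and unit metadata plus per-trial,
per-segment rotation/position arrays and an optional ground-truth block;
readers fail fast with a JSON-pointer location and preserve unknown fields.
C3D import/export encodes each 6-DoF pose as four point channels (origin +
unit-axis tips, with mm→m conversion) and requires the optional `ezc3d`
dependency. Adapters for externally deposited files (normalized-waveform
JSON, spatiotemporal XLSX) are mapping-driven — a user-editable TOML/dict
names the source keys or columns — and feed the reliability stage directly,
bypassing event detection. Report tables render to CSV/XLSX/markdown with
3-decimal formatting and always include a provenance block (package
version, full configuration, per-trial failure log); re-rendering is
byte-identical.

## Known limitations

* The generator certifies pipeline correctness, not hardware realism: no
  soft-tissue artifact, no keypoint-model error structure, no pose dropout.
* Event detection assumes roughly straight overground walking (a single
  progression direction per trial).
* The within-session pooling convention (stacked subject-session rows) and
  the SD entering SEM are analysis choices; both alternatives are exposed
  in configuration because deposited studies rarely state theirs.
* ICC confidence intervals assume the balanced complete design the pipeline
  enforces; incomplete cells are dropped, not imputed.
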