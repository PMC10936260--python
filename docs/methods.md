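# Methods

`kicksense` quantifies the spontaneous kicking of supine infants from a
six-sensor lower-limb IMU suit (left/right × thigh/shin/foot, 3-axis
gyroscope in deg/s and 3-axis specific force in g, sampled at 100 Hz), and
turns the resulting kinematic features into normative feature-versus-age
models from which a per-feature developmental age can be estimated. This
note documents the model and procedure choices, the tunable parameters, the
synthetic-data generator, and the known limitations.

## Signal model and preprocessing

Each sensor's output is modeled as signal + constant per-axis bias (for the
accelerometer this includes gravity in the supine rest orientation) + slow
gyro drift + mechanical noise. A session begins with a stationary hold of
the legs; the per-axis mean over that window is the bias estimate and is
subtracted element-wise. Mechanical noise is removed with a 5-sample
running median (50 ms at 100 Hz — wide enough to reject single-sample
spikes, short enough not to blunt 100-ms kicks); at the series edges the
window shrinks rather than padding.

Gross activity per leg is the thresholded, 0.1-s-smoothed maximum of the
three per-sensor gyro magnitudes (default threshold 10 deg/s); events
shorter than 0.1 s are removed, then gaps shorter than 0.1 s are filled.
Taking the maximum over the leg's three sensors makes the gate robust to
single-sensor noise and to moments when one joint pauses while another
still moves.

Drift is cancelled with a zero-velocity update (ZVU): during detected rest
the angular rate is reset exactly to zero, and across each active run the
residual offset — linearly interpolated between the flanking rest means —
is subtracted. Two conservative-rest refinements matter in practice. First,
the activity mask is dilated by 0.25 s before zeroing, because the slow
head and tail of a movement sit below the activity threshold; zeroing them
erases real angle (up to ~1.3° on long, slow kicks). Dilated margins are
offset-corrected instead of zeroed. Second, rest-run means are computed
with a 0.1-s guard trimmed from each end so leaked movement tails do not
bias the offset estimate. The ZVU is idempotent.

## Joint kinematics

The suit has no pelvis sensor; with the infant supine the pelvis is treated
as stationary, so joint relative angular rates are: hip = thigh gyro, knee
= shin − thigh, ankle = foot − shin. Six degrees of freedom are tracked per
leg: hip flexion/abduction/rotation, knee flexion, ankle
flexion/inversion.

Joint axes are estimated per session by principal component analysis of the
active relative-rate sample cloud of each joint, ordering the principal
directions by explained variance (hip: flexion, abduction, rotation; knee:
flexion; ankle: flexion, inversion). Each axis is signed so the rotation
direction carrying the larger total excursion is positive; for motion that
returns to baseline the two directions balance, and the tie is broken by
rate skewness (sum of cubed projections), which makes the faster stroke —
flexion, in kicking — the positive direction. Per-DOF angular rate is the
projection of the joint relative rate onto its axis.

Each DOF rate series gets a per-sample phase label: +1 while rotating
positively, −1 negatively, with exact zeros carrying the preceding nonzero
sign to avoid single-sample fragmentation. A signed run is relabeled 0
(rest) if its angle change stays below 5° over every 1-s sliding window
(runs shorter than 1 s use their total change). The joint angle is reset to
0 at the start of each phase run; the magnitude of the angle at the run's
end is that run's excursion, collected into per-direction lists whose
maxima are the segment's excursion features.

Quadrature: durations and excursions use sample-as-interval semantics — a
run of n samples lasts n/fs seconds and its excursion is (Σ rate)/fs (left
Riemann sum). This keeps duration and excursion mutually consistent and
exact for constant-rate motion, so the rule boundaries (5° per 1 s, 11.5°)
behave exactly at threshold; for smooth physiological pulses it differs
from trapezoidal quadrature by O(1/n²).

## Activity, coordination and kick cycles

Per-leg binary activity vectors combine into an overall activity vector
(logical OR) and a coordination vector coded 0 rest / 1 unilateral left /
2 unilateral right / 3 bilateral. The predominant leg is the one with the
larger total active-sample count over the session (ties go right), decided
once per session.

A kick cycle is a full flexion followed by a full extension. Full flexion:
a maximal run where hip and knee phases are both +1, lasting at least
50 ms, in which the larger of the two within-run excursions strictly
exceeds 11.5°. Full extension: the next maximal run with both phases −1.
Intervening rest between the two is allowed; a new flexion onset of either
joint before the extension cancels the pending flexion. The ankle is not
required to move in phase; per-cycle flags record whether it did (phase
agreement on more than 50% of the window's samples), and the hip–ankle and
knee–ankle coordination metrics use only flagged windows.

## Segment features

Sessions are cut into consecutive non-overlapping 60-s segments starting
after the calibration hold; a trailing partial segment is discarded. Per
segment: activity/coordination frequencies (fractions of samples);
mean/maximum movement and rest durations (runs touching segment edges count
at observed length; absent runs give 0 — zero seconds of kicking is
meaningful); mean/peak foot specific-force magnitude of the predominant leg
over that leg's active samples (undefined with no active samples — 0 g is
not a meaningful rest value); per-DOF, per-direction maximum excursions of
the predominant leg; and inter-joint coordination: for each kick-cycle
flexion and extension window, joint angles re-zeroed at the window start,
zero-lag sample correlation per joint pair, averaged over windows
(undefined with no cycles; constant-angle windows skipped). "Undefined" is
NaN internally and an explicit `undef` token on disk.

## Normative modeling

Segments with activity fraction or rest fraction strictly greater than 0.9
are excluded as abnormal behavior before aggregation; session summaries are
per-feature medians over retained segments (undefined entries masked
per-feature). Features are screened against age at testing with Spearman's
rho on session medians (sessions treated as independent), two-sided p via
the t-approximation with n−2 degrees of freedom, significance at p < 0.05
per feature with no multiple-testing correction — each feature's model is
meant to be read individually. Features with fewer than four defined
sessions or constant values are not screenable.

Each significant feature gets a least-squares polynomial of feature versus
age. Quadratic is selected over linear only when it improves R²
(= 1 − SS_res/SS_tot) by more than 0.05, guarding against overfitting, with
one exception: a numerically exact quadratic fit (R² = 1 within 1e−9) is
always preferred, since noise cannot produce one. Age prediction inverts
the curve on a 0.1-week grid over the training age range — observed values
outside the model's range clamp to the nearest endpoint, and exact ties
(non-monotone quadratics) resolve to the mean of tied grid ages. A feature
flags potential delay when the session-median predicted age is strictly
below the infant's actual age.

## Synthetic kicking generator

The generator stands in for real infant recordings and defines the
conditions under which the pipeline is validated. Kicks arrive as bouts
from a Poisson process (default 10 bouts/min) with lognormal durations
(mean 2 s, shape 0.4, clipped to 0.4–6 s) and a minimum 0.4-s rest gap;
each bout is bilateral or unilateral (default 50/25/25%). Within a bout
each DOF realizes a two-stroke angle pulse rising to its programmed
excursion and returning to baseline with zero rate at the boundaries; the
flexion stroke occupies 40% of the window, so flexion is faster than
extension as in real kicking. The knee and ankle lag the hip by 10% and 18%
of the bout (proximal-to-distal sequencing); secondary DOFs (abduction,
rotation, inversion) occupy a random sub-window with a random sign. These
timing choices are physiological, make the joint axes identifiable to the
PCA (synchronous identical pulses would collapse the rate cloud onto a
single direction), and keep the leg's sensed rate magnitude above the
activity threshold through the mid-kick turnaround. Default excursions:
hip flexion 25°, knee flexion 20°, ankle flexion 12°, abduction 8°,
rotation 6°, inversion 5°, with 15% relative jitter — kick-defining
excursions sit comfortably above the 11.5° rule.

Sensor streams stack DOF rates down the kinematic chain on anatomically
aligned axes and add per-axis bias (σ 1 deg/s gyro, 0.05 g accel), a drift
ramp (0.5 deg/s per minute), and white noise (σ 0.5 deg/s, 0.02 g); the
foot accelerometer carries a tangential-acceleration proxy (second
derivative of the summed flexion angles scaled by a 0.1-m lever arm) on top
of gravity; a 5-s stationary hold is prepended. Everything is deterministic
for a fixed seed. The ground truth retains the event list, from which every
segment-level feature is computable without the sensor pipeline; the true
inter-joint correlations implied by the pulse timing are evaluated
numerically on a canonical grid (they are invariant to bout duration and
amplitude). Cohorts map per-session generating parameters (bout rate,
duration mean, amplitude scale, knee lag, ...) through user-supplied
functions of age.

What the generator does not emulate: orientation change of the sensors
during movement (gravity leakage into the corrected accelerometer),
soft-tissue artifact, sensor dropout, non-sinusoidal or multi-peaked kick
profiles, and truly coupled dynamics between legs. Passing tests therefore
demonstrate the correctness of the measurement pipeline under a controlled,
physiologically shaped signal model — not clinical validity on real infant
data.

## Validation problem sizes

The test suite validates end-to-end recovery on 3-minute sessions and an
8-session cohort (24 segments); per-run excursion recovery is checked
against the generator's known anatomical axes, isolating preprocessing +
phase labeling + integration, while PCA axis estimation is validated
separately (first principal axis within 2° for single-axis motion). The
100-replicate screening check runs on ground-truth event-level summaries
from the same generator, which exercises the bout process and the screen
without sensor synthesis. The type-I calibration of the screen uses 2000
null features over 31 sessions.

## Known limitations

* PCA joint axes carry a few degrees of cross-talk when sessions contain
  few bouts, because cross-DOF sample covariance only cancels across
  events; excursion features inherit up to ~1° of error from this at
  desk-scale session lengths. Longer recordings (the intended 20-minute
  collections) reduce it roughly as 1/√(number of bouts).
* Absolute anatomical angles are out of scope — angles are relative,
  re-zeroed at each movement onset, as the feature definitions require.
* Accelerometer bias correction removes gravity only in the rest
  orientation; during movement, orientation change reintroduces a gravity
  component into the magnitude. Both corrected and raw magnitudes are
  available; the default uses the bias-corrected signal.
* Age prediction clamps to the training age range; extrapolation beyond the
  normative cohort is deliberately not offered.
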