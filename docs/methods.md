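# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Frames and conventions

Quaternions are Hamilton, scalar-first, canonicalized to `w ≥ 0`. A DCM
`R_B/A` transforms coordinates from frame A to frame B (`v_B = R_B/A v_A`);
its rows are the B axes expressed in A. Five frames matter per leg side: the
sensor frame (the IMU's sense axes), the segment anatomical frame
(X̂ medial-lateral = FE axis, Ŷ anterior-posterior = AA axis, Ẑ
superior-inferior = IE axis), and the sensor's own world frame (vertical from
gravity, heading from that sensor's reference — independent per IMU and
subject to drift). Internal computation is in radians; every public
interface and file format uses degrees, since that is how joint kinematics
are reported.

The knee angles are the ordered Euler decomposition of `R_AT/AS`. The
default order is the serial mechanism order of the two-link analog — AA
first, IE second, FE third, so the middle (gimbal-critical) angle is IE —
with the ISB order (FE, IE, AA) selectable. Gimbal lock (|IE| within
numerical tolerance of 90°) zeroes the third angle, folds the remaining
rotation into the first, and flags the sample; the simulator's trajectories
keep IE within ±50°, so locked samples do not occur in the shipped
benchmark.

## Sensor-to-segment calibration

*Vertical axis.* The mean accelerometer vector over a still interval gives
the gravity direction; a mean magnitude deviating from 9.81 m/s² by more
than 5 % raises a not-still error. The mean vector is also stored as the
reference still `a₀` used by the stationary hinge criterion.

*Hinge axis.* During pure hinge motion the angular-rate components
perpendicular to the hinge axis have equal magnitude on both segments, so
both axes minimize

    Σ_i ( |ω_S(t_i) × n̂_S| − |ω_T(t_i) × n̂_T| )².

The two unit axes are parameterized by spherical coordinates (4 parameters)
and fitted with Levenberg-Marquardt (scipy `least_squares`, tolerances
1e-15, iteration cap 200), initialized at each sensor's principal rate
direction (dominant eigenvector of `ΣωωT`). Identifiability requires rate
content perpendicular to the hinge axis: if both links rotate *only* about
the hinge at proportional rates the cost is degenerate along a one-parameter
family (`|c_S| sin α_S ≡ |c_T| sin α_T`). The simulator therefore
superimposes a small two-axis assembly wobble on the calibration movement;
on real data the operator's hand tremor plays the same role. Guards: peak
rate below 30 °/s raises a poor-calibration error before solving, and a
residual RMS above 5 °/s after solving raises one too.

*Sign.* Rates alone cannot distinguish medial from lateral. The estimator
takes an approximate medial-direction hint per sensor (only its sign is
used; any hint within 90° of the true direction works — in practice, how the
sensor was strapped on). Without hints it makes the two axes mutually
consistent through the reported world orientations (valid while the heading
misalignment is below 90°) and takes the shank principal direction as
positive, which fixes the FE sign convention rather than the anatomical
medial direction.

*Frame assembly.* `Ŷ_A = Ẑ_est × X̂_A` normalized, then `Ẑ_A = X̂_A × Ŷ_A`,
which re-orthogonalizes the vertical estimate against the hinge axis; the
triad is orthonormal to machine precision by construction. Vertical and
hinge estimates closer than 10° raise a degenerate-geometry error.

## Hinge classification

Case 1a (stationary): windowed-mean accelerometer magnitudes of both sensors
within 0.02 g of gravity, and the two-sensor mean angle between the current
windowed-mean acceleration and `a₀` at most 3°. The magnitude condition is
evaluated per sensor on `|‖ā‖ − g|` (the stationarity intent, stated
frame-consistently); the directional content is carried entirely by the
angle condition. Case 1b (rotating): both windowed rate magnitudes at least
30 °/s and the two-sensor mean of the hinge-alignment cosine above 0.99.

Two readings were genuinely open and are resolved as follows. "Mean" is the
mean over the two sensors at each instant, not a trial average — that is
what produces per-sample Boolean traces. The alignment cosine uses the
*absolute* projection by default (`signed_projection` restores signed): with
an oscillating hinge the signed projection flips sign with the rotation
direction each half-cycle on both sensors simultaneously, which would
disqualify half of every flexion bout that is physically pure hinge motion.

All four thresholds plus the window length (default 0.1 s, centered mean;
one sample recovers the instantaneous criteria) are configuration-exposed,
because they are stringent mechanical-rig values that must be relaxed for
human subjects (joint laxity, soft tissue).

## Correction construction and interpolation

At every update sample the correction is built directly from the axis-angle
pair between the world-frame images of the two hinge axes and Rodrigues'
formula; the defining property `C u = v` holds to 1e-9 at every anchor and is
asserted as such. Numerical edge cases: `|u × v| < 1e-12` with positive dot
product yields the identity (continuity); antiparallel images (a ~180°
world-frame disagreement signals calibration failure, not drift) skip the
anchor with a warning in batch mode and raise in the single-sample API.

"Linear interpolation" across non-hinge gaps is realized as spherical-linear
interpolation of the correction quaternion — linear in the rotation angle for
coaxial anchors, and always a valid rotation, which elementwise matrix
interpolation is not. Before the first and after the last anchor the nearest
anchor is held: there is no basis for extrapolating drift. Anchors are kept
per sample within update intervals (no per-interval averaging); an optional
moving-average low-pass on the anchor rotation vectors exists but defaults
to off. Processing is offline (both sides of each gap available), matching
the post-hoc analysis setting.

A one-axis constraint cannot observe the component of world-frame error
*about* the hinge axis itself. With the vertical-axis drift that dominates
real filter estimates and a horizontal hinge axis, that unobservable
component is negligible; it grows when the hinge axis tilts toward the
drift axis, which is why anchors taken while the calibration wobble tilts
the rig contribute small (sub-degree here) residuals.

## The synthetic knee analog

The simulator emulates an encoder-instrumented two-link linkage exercised by
hand: a serial AA→IE→FE joint chain between a shank and a thigh link, an IMU
rigidly mounted on each at an arbitrary (seeded random) orientation, and a
scripted protocol per recording — 10 s still, 8 s hinge-calibration
flexion (ROM 70°, split between the links, with a 8°/6° two-axis assembly
wobble), 2 s still, the 10 s trial movement, 2 s closing still.

Joint trajectories are sinusoids under raised-cosine envelopes, chosen so
value and rate vanish at the phase boundaries and the extremes land exactly
on sample-grid points; the truth range of motion therefore equals the
configured amplitude exactly. Default amplitudes are the validation
envelopes of the mechanical rig this analog emulates: 161° (pure FE), 72.8°
(pure IE), 17.0° (pure AA) and 117°/98.4°/58.3° for combined movements —
deliberately far beyond a healthy human knee. Cycle counts per 8 s
trajectory hold are 4 (FE), 2 (IE), 1 (AA). The default sample rate is
128 Hz, typical of the sensor class.

Two phenomenological choices matter. First, during pure-FE trials and the
calibration movement the hinge angle is split half-and-half between the two
links (a hand-exercised rig swings both links); the rotating-hinge criterion
can only ever fire when both sensors move. During IE/AA/combined trials the
shank stays quasi-static, which gates Case 1b off mid-movement, as it
should: there the knee is not a hinge. Second, the whole assembly is held
at a constant 10° base tilt during the trial movement (ramped in and out
over 1 s). A hand-held trial is never conducted in the calibration pose,
and without the tilt a gravity-only accelerometer model would satisfy the
stationarity criteria during rotations about the vertical axis (gravity is
blind to them) and corrupt the correction with joint motion. Anchors during
the ramps are harmless: the joint is straight there, so the hinge constraint
genuinely holds.

Sensors: the gyro reports the exact analytic body rates of its link plus
white noise (manifold finite differencing is the fallback for externally
supplied orientation series); the accelerometer reports gravity in the
sensor frame plus white noise (a lever-arm option adds rotational specific
force; linear acceleration of hand transport is not modeled); the
orientation quaternion reports the true orientation composed with a
per-sensor heading error `ψ₀ + d·t` about the vertical (plus an optional
tilt-drift component), emulating independent drifting on-board filter
estimates. Everything is driven by one seeded generator; identical specs
regenerate bit-identical recordings.

What passing on this analog does **not** show about real data: soft-tissue
artifact, joint laxity, magnetometer interference structure, linear
acceleration transients, and non-ideal vendor-filter behavior are all outside
the model; the thresholds above are rig-grade, not human-grade.

## Validation metrics and benchmark

Per axis: ROM of the truth (max − min), RMS error, Pearson r, and the OLS
slope and intercept of estimate on truth (truth as abscissa), plus RMS as a
percentage of ROM. Axes without truth variance (unexercised in pure-rotation
trials) carry an undefined-correlation flag rather than a number. Pooling
concatenates samples across trials, so the pooled RMS of equal-length trials
is the quadratic mean of per-trial RMS values (asserted as an identity).

The benchmark runs ten recordings per movement type at 128 Hz with
per-trial draws of heading offset U(±30°), per-sensor drift U(±0.15 °/s),
gyro noise 0.5 °/s and accelerometer noise 0.02 g; each recording is
calibrated from its own alignment sequence (the true mounting axis is passed
as the sign hint only), estimated with and without the correction, and
metrics are pooled per movement type over the trial window (movement plus
closing still — the alignment sequence itself is excluded, matching a
per-trial-type report). Per-trial seeds derive from the benchmark seed via
`SeedSequence([seed, movement_index, trial_index])`. The problem size
(40 × ~32 s × 128 Hz ≈ 1.6 M samples in total) runs in a few seconds on one
CPU core; the built-in orientation filter is the only per-sample Python
loop and is not on the benchmark path.

## Known limitations

- The strapdown complementary filter is a minimal first-order integrator
  (trapezoidal rate sampling) intended for streams without vendor
  orientation estimates; it is not a substitute for a tuned Kalman filter.
- The correction assumes the hinge axes estimated at calibration stay fixed
  in their sensor frames (rigid mounting); mounting migration is not
  detected.
- Heading drift between anchors is assumed slow and smooth; a step change
  (e.g. a magnetic disturbance between stills) is interpolated through, not
  detected.
- Sign disambiguation of the medial direction ultimately rests on external
  knowledge (a hint or a <90° heading assumption); with neither, only the
  FE sign convention — not the anatomical direction — is pinned down.
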