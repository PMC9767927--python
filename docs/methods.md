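# Methods

## The kinematic model and its conventions

The rod is rigid; X points along the microtubule axis toward the plus
end, Z is vertical.  The center follows a helix of radius `h` (nm),
`helix(t) = (vt, h cos(pi/2 - w t), h sin(pi/2 - w t))`, which starts at
the top of the orbit and, for positive `omega_helix`, moves toward +Y
while advancing +X -- the left-handed orbit.  Left-handed pitches are
reported positive throughout.  The rod additionally rolls about X in
lockstep with the orbit and yaws about Z at half the orbital rate
(`omega_roll = omega_helix`, `|omega_yaw| = |omega_helix|/2`); the sign
of `omega_yaw` encodes counterclockwise (+) vs clockwise (-) yaw.  Both
the rotation-matrix form and the closed trigonometric forms of the pose
are implemented; a property test holds them equal on random draws.

Angles are radians internally and degrees at every user interface.  The
projected in-plane angle is computed as `atan2(Y_tip - Y_end, X_tip -
X_end) mod pi` rather than through the `arctan[cos * tan]` form, which
has tangent singularities; the two agree wherever the latter is defined.
A projection shorter than 1e-12 of the rod length (rod pointing along
Z) is flagged undefined rather than inverted.

Unwrapping folds the sawtooth `[0, 180)` series into a continuous trace
by shifting each sample by the multiple of 180 deg that minimises the
frame-to-frame jump; NaN samples are skipped and unwrapping resumes
from the last defined value.  A pattern is classified unidirectional
when the net unwrapped rotation over one helix period is within 10% of
+/-180 deg (the traces themselves give no sharper criterion), otherwise
oscillatory.  Note one genuinely counterintuitive property, verified
numerically: at phase angle 0 the apparent rotation of the projection
runs *opposite* to the yaw, because the roll flips the projection
halfway through the orbit.  A clockwise-yawing rod therefore shows a
counterclockwise pattern at phi = 0, a clockwise pattern at phi = 90 deg
and oscillatory patterns near 45 and 135 deg.

## Polarimetry

The two-channel model is evaluated exactly as written; the DOP is
`(I_b - I_u)/(I_b + I_u)` with an undefined flag at zero total.

Calibration fitting is joint nonlinear least squares over both channels.
Because the model is linear in `(I0, b)` once the phases are fixed, the
initial guess comes from a vectorised 3-degree grid over `(zeta, eta)`
with closed-form 2x2 normal-equation solves per node, followed by
Levenberg-Marquardt refinement; phases are folded to `[0, 180)` deg.
Uncertainties are the usual covariance estimate `(J^T J)^{-1} SSR/(n-p)`.
On a noiseless 19-angle sweep the reference parameters
(I0 = 127.5 counts, zeta = 99.3 deg, eta = 45.3 deg, b = 19.5 counts)
are recovered to <= 1e-6 relative error; with 3 counts of Gaussian
channel noise the displacer phase comes back within ~1 deg (Monte Carlo
in the test suite).

Angle inversion minimises the squared two-channel residual by a 0.5-deg
grid search plus bounded scalar refinement.  This was chosen over an
analytic inversion because with `b > 0` the DOP is not exactly
`cos 2(theta+zeta-eta)` and the residual route stays correct.  Within a
series, near-degenerate minima are broken by proximity to the previous
frame's angle; the first frame takes the global minimum.  A pair within
`1e-3 * I0` of `(b, b)` sits on the optical null `cos^2(theta+zeta)=0`,
where the objective is flat; such frames are flagged undefined (a few
per 180-deg period) and excluded downstream.

The DOP-vs-summed-intensity cloud is fit with the direct algebraic
ellipse fit (scikit-image's `EllipseModel`) on standardised coordinates,
since the two axes differ by orders of magnitude in scale.  With `b = 0`
the model curve is exactly an ellipse; with `b > 0` it is nearly so.
The reported `coverage` (occupied fraction of 36 parametric-phase bins)
separates full rotations (~1) from oscillatory arcs, and correlates with
the pattern classification on synthetic tracks.

## Spot tracking

Spots are axis-aligned elliptical Gaussians plus a constant offset, fit
by Levenberg-Marquardt from moment-based starts; the astigmatism axes
coincide with the camera axes, so no rotation term is needed.  Z is
linear in the width ratio, `z = 0.98 um * (S_Y/S_X - 1)` by default.
Channel intensity is reported as the integrated volume
`2 pi s_x s_y A` rather than the peak amplitude, which makes it robust
to defocus-induced width changes.  The moving average is a centered
boxcar (default 15 frames at 100 frames/s) with truncated windows at
the trace ends -- no padding, no phantom values.  `track_stack` assumes
a single particle per field: the bottom-channel spot is the brightest
pixel of the lower half-frame, the upper-channel spot sits a known
displacer offset above it, and frames where either fit fails are
flagged and never interpolated.

## Synthetic data

The generator is the study-conditions oracle: 100 frames/s, a particle
at 0.4-0.5 um/s on a ~0.7-um-pitch left-handed helix (orbit radius
35 nm: microtubule radius plus rod radius; it cancels from the angle
model and only matters for rendering), a 40 x 68 nm rod, and the
reference calibration above.  Noise is additive Gaussian: 3 counts per
channel (matching the scatter of the reference sweep) and 10 nm of
localization noise per axis by default; neither value is stated by the
source experiments, which report no noise magnitudes.  Shot noise,
EMCCD statistics, drift, Z-dependent polarization mixing and multiple
particles per field are deliberately out of scope, so passing tests
show correctness of the analysis chain under the stated model, not
robustness to every camera artifact.  Ground truth (exact per-frame
angle, positions, spot parameters) is always returned alongside the
noisy data, and the CLI writes it as a sidecar file.

## Trajectory quantification

Velocity is the least-squares slope of X vs t.  Cycle detection
mean-subtracts the smoothed series and places boundaries at successive
upward zero crossings (linearly interpolated), discarding partial
cycles at the ends; this books X displacement per cycle without
assuming a constant period.  The helix pitch uses the Y trajectory.
The polarization pitch defaults to boundaries at successive 180-deg
advances of the unwrapped angle: the roll modulation makes the DOP
trace cross its mean twice per period (a structural feature, not
noise), so zero-crossing detection on DOP would halve the pitch;
DOP- and sum-based detection remain available via the `signal`
argument.

The yaw direction is the sign of Pearson's r between the Y displacement
and the unwrapped, *linearly detrended* angle.  Detrending matters: the
raw unwrapped correlation flips sign with the phase angle (checked
numerically near phi = 60-120 deg), whereas the detrended correlation
has magnitude >= 0.58 with the correct sign at every phase --
positive for counterclockwise yaw, negative for clockwise.  The
direction is called only when |r| > 0.3 (no threshold is stated
anywhere; 0.3 cleanly separates the coupled motion from the no-yaw
control in the suite).  The supertwist correction
`1/P_meas = 1/P_motor + 1/P_MT` uses the tabulated lattice pitches
(-3.4, -24.8, +6.8 um for 12/13/14 protofilaments); for measured
pitches below 1 um the correction is bounded by 42% and usually far
smaller.  The binomial direction test doubles the smaller exact tail
(capped at 1); Welch's t test comes from scipy with Welch-Satterthwaite
degrees of freedom.

## Ratchet flux

Closed forms are implemented exactly as printed, including the gamma/4
prefactor on the erfc difference (flux = gamma/2 times the
barrier-crossing probability; the units question of that prefactor is
noted rather than "fixed").  The module's oracle integrates the
free-diffusion density over the crossing regions by adaptive quadrature
and agrees with the closed forms to 1e-10 across the parameter grid.
Offsets are restricted to d in [0, 1): beyond one lattice unit the
start position aliases to the neighbouring site.  The scan grid step is
0.005, which resolves the minimum at d = 0.5 unambiguously.

## Cargo Monte Carlo

Thirteen motors connect a rigid cargo to a 2D lattice (X unbounded,
unit spacing; Y lateral, 13 sites per filament circumference).  Per
unit-time tick: bound motors detach with probability 1/tau_on; detached
motors accumulate a Gaussian increment of SD sigma per axis and rebind
with probability 1/tau_off; at rebinding the excursion is tested
against the barriers (alpha_x forward vs 1-alpha_x backward;
1-alpha_y leftward vs alpha_y rightward) and the motor rebinds one site
over per crossed axis -- both axes may step (diagonal).  Exponential
waiting times are approximated by per-tick Bernoulli trials, matching
the units-of-time parameterisation.  Defaults: k = 1, tau_on = 40,
tau_off = 10, alpha_x = 0.12, alpha_y = 0.58, sigma = 0.11,
T_step = 0 or -24.

The genuinely open design choices, and what was chosen:

* **Excursion rule** (isolated in `_excursion`): the excursion is the
  accumulated diffusion *plus the motion of the motor's joint since
  detachment*.  A detached motor diffuses around its tether point, and
  the tether rides the cargo, so cargo displacement and torque-driven
  rotation feed into the barrier test -- the pathway by which rotation
  laterally displaces anterior and posterior motors by +/-d as in the
  flux theory.  Two rejected readings: pure diffusion (torque then
  cannot influence stepping at all) and joint-minus-bound-site (the
  spring strain at detachment leaks into the test and the cargo crawls
  even with sigma = 0).  With the chosen rule, sigma -> 0 gives exactly
  zero steps forever.
* **Initial binding**: motors start bound exactly under their joints
  (sites are continuous coordinates; the lattice enters through the
  step length and barrier offsets).  Nearest-site rounding would leave
  residual strain that sustains spurious stepping in the no-noise
  limit through binding-exchange pose jitter.
* **Joint geometry**: joints sit uniformly on a circle of radius 3.9
  lattice units in the cargo frame -- the rod radius (20 nm) over the
  5.1-nm lateral site spacing, i.e. the physical moment arm of surface
  motors.
* **Pose update**: the balance equations are solved exactly every tick.
  Eliminating the translation reduces the moment equation to
  `S sin(theta) + C cos(theta) = T_step N_step / k`, solved in closed
  form with the root nearest the previous orientation; force and
  moment residuals are at numerical round-off (<= 1e-9 asserted after
  every tick).  If the torque momentarily exceeds the maximum moment
  the bound springs can carry the tick is flagged unsolvable; at the
  default geometry this never occurs.  A `relaxation` parameter
  (default 1.0) optionally moves the pose only a fraction of the way
  to equilibrium per tick, modelling a viscously damped cargo, at the
  cost of nonzero per-tick residuals.
* **Torque application**: `T_step` enters the moment balance on the
  tick in which the steps occur and resets -- the literal reading of
  the printed balance.  Sustained and time-spread variants were
  explored and rejected (they over-rotate the cargo and destroy the
  lateral bias).

Measured behaviour at the printed defaults (all computed in the test
suite): the no-torque run shows no mean rotation and a net
forward:leftward step ratio of ~100:17; a documented bisection helper
(`calibrate_alpha_y`) re-tunes the off-axis asymmetry to recover the
100:13 calibration (equivalent, via
`pitch = net-forward-per-net-left x 13 sites x 8 nm`, to a 0.8-um
pitch), which is needed because the original parameter set was tuned
under a stepping rule whose pseudo-code is not available.  With
T_step = -24 the cargo rotation is systematically clockwise and the
median lateral displacement increases relative to T_step = 0 (the
torque-enhanced sideward transport the flux theory predicts).

**Known limitation**: the secular rotation under quasi-static balance
is slow -- roughly one revolution per ~200 lattice units of lateral
traversal rather than per 13.  The per-tick torque impulse relaxes
within the tick, so sustained rotation arises only through the slow
bias of the bound-site pattern.  The corresponding acceptance test is
expected to fail and says so in its docstring; a faster-rotating
variant (site-referenced excursions) was rejected because it reverses
the lateral-enhancement ordering, which is the mechanistically central
claim.  Problem sizes in the acceptance suite (300 runs x 4000 ticks
per torque arm, >= 1.2e6 motor-ticks for the ratio) were chosen so the
stochastic assertions have comfortable power.

## Mechanics

Pure closed forms: `K = pi d^4/32`; `theta_step = T L / (K G)` with G
converted at exactly 1000 pN/nm^2 per GPa; yaw per step
`180 deg x step/pitch`; lateral excursion `arm x tan(angle)` with the
arm between the rod radius (20 nm) and half-length (34 nm -- the
"at most" value); offsets normalised by the 5.1-nm site spacing.  The
rod surface is a closed right cylinder (lateral area plus two end
caps), which gives 1.1e4 nm^2 for the 40 x 68 nm rod -- a
spherocylinder would give 0.85e4 and was rejected for that reason.
Rounding (nearest degree, one significant figure) is opt-in, since the
headline numbers are conventionally reported rounded.

## File formats and reproducibility

Tracks are plain CSV with a fixed ten-column schema, validated on read
(strictly increasing frames, DOP consistent with the intensities to
1e-6); stacks are multi-page 16-bit grayscale TIFF; calibrations,
configs, reports and run manifests are JSON.  Every CLI command accepts
`--seed` and `--out`, derives all randomness from the single seed, and
writes a manifest (parameters, seed, versions) next to its output;
identical config and seed reproduce outputs byte for byte.
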