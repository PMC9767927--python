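# gnrtrack

Kinesin motor domains generate torque as well as forward force.  When a
team of weakly processive kinesins is rigidly coupled to a gold nanorod
(GNR) cargo, the cargo does not simply translocate along the microtubule:
it follows a left-handed helical orbit around the filament (pitch ~0.7 um
at ~0.4-0.5 um/s) while simultaneously rotating 180 degrees about its own
short (yaw) axis per orbit.  Dual-polarization dark-field microscopy
reads this out: the scattered light of the anisotropic rod is split into
two orthogonally polarized spots whose intensities oscillate in
antiphase as the rod turns.

`gnrtrack` implements the computational core of that analysis for people
working on single-particle polarization tracking and collective motor
transport: the forward kinematic model, the polarization observation
model and its inversion, spot localization, track quantification, the
Brownian-ratchet flux theory, and a multi-motor rigid-cargo Monte Carlo
-- all exercisable on synthetic data with known ground truth, so no
experimental recordings are required.

## The model

**Kinematics.** The rod pose is an extrinsic rotation sequence applied to
the initial rod axis $p_0(\varphi)$ plus a helical displacement:

$$R_X(\omega_{\mathrm{Roll}} t)\, R_Y(0)\, R_Z(\omega_{\mathrm{Yaw}} t)\, p_0(\varphi) + \mathrm{helix}(t, v, \omega_{\mathrm{Helix}})$$

with the coupling $\omega_{\mathrm{Helix}} = \omega_{\mathrm{Roll}} = \pm 2\,\omega_{\mathrm{Yaw}}$.
The measurable in-plane angle is
$\theta(t) = \arctan[\cos(\omega_{\mathrm{Roll}} t)\tan(\omega_{\mathrm{Yaw}} t + \varphi)]$,
folded to $[0^\circ, 180^\circ)$ because a rod is head-tail symmetric.
Depending on the phase angle $\varphi$, the apparent polarization
rotation is counterclockwise, clockwise or oscillatory even though the
yaw is strictly unidirectional.

**Observation.** The two displacer channels see

$$I_{\mathrm{bottom}} = I_0 \cos^2(\theta+\zeta)\cos^2(\theta+\zeta-\eta)+b,\qquad
I_{\mathrm{upper}} = I_0 \cos^2(\theta+\zeta)\cos^2(\theta+\zeta-\eta+\pi/2)+b.$$

`polarimetry.CalibrationModel` fits $(I_0, \zeta, \eta, b)$ from a
polarizer sweep; `estimate_angle_series` inverts intensity pairs back to
$\theta$ with temporal-continuity tie-breaks.  The degree of
polarization is $(I_b - I_u)/(I_b + I_u)$.

**Ratchet theory.**  A motor whose diffusion starts at lateral offset
$\pm d$ in a two-state ratchet with asymmetry $\alpha$ and drag $\gamma$
has closed-form flux
$J_{\pm d} = \tfrac{\gamma}{4}\{\mathrm{erfc}[\tfrac{\alpha \mp d}{2}\sqrt{\gamma}] - \mathrm{erfc}[\tfrac{1-\alpha \pm d}{2}\sqrt{\gamma}]\}$;
`ratchet_flux` evaluates these and the net flux $J_{-d}+J_0+J_{+d}$,
whose minimum at $d=0.5$ and branch dominance $|J_{-d}| \gg |J_{+d}|$
explain why a slight rotation-induced offset biases sideward stepping.

**Cargo Monte Carlo.**  `cargo_sim` couples 13 motors to a rigid cargo
through springs; motors stochastically detach, diffuse and rebind across
asymmetric barriers, and the cargo pose satisfies the force and moment
balance $\sum_i k\,\vec d_i = 0$, $\sum_i k\,\vec d_i \times \vec l_i = T_{\mathrm{step}} N_{\mathrm{step}}$
exactly each tick.

## Worked example

Simulate a noisy track of the coupled motion and re-analyze it:

```
$ gnrtrack simulate-track --out track.csv --seed 7 --duration 6.0
$ gnrtrack analyze-track --track track.csv --out report.json --seed 0
Track quantification
--------------------------------------------
velocity               0.500 +/- 0.000 um/s
helix pitch            0.698 +/- 0.010 um (n=3)
polarization pitch     0.709 +/- 0.019 um (n=3)
Pearson r (Y vs angle) -0.825 -> cw
```

The generator advanced the particle at 0.5 um/s on a 0.7-um-pitch
left-handed helix with clockwise yaw at half the orbital rate.  The
analysis recovers the velocity, finds the helix pitch (X displacement
per Y oscillation) and the polarization pitch (X displacement per
180-degree angle period) equal within noise -- the signature of the
"one yaw half-turn per orbit" coupling -- and calls the yaw direction
clockwise from the negative Pearson correlation between the Y
displacement and the detrended angle trace.

The same from Python:

```python
from gnrtrack import synthetic_data as sd
from gnrtrack.trajectory_analysis import TrackModel

gt = sd.GroundTruth(model=sd.default_motion_model(), duration=6.0, seed=7)
_, noisy = sd.gen_track(gt)
print(TrackModel(noisy).fit().summary())
```

Other entry points: `gnrtrack calibrate` (fit the two-channel
calibration), `gnrtrack simulate-images` / `track_stack` (render and
re-localize dual-spot image stacks with astigmatic Z),
`gnrtrack ratchet-scan` (flux-vs-offset table; its minimum prints at
d = 0.500), `gnrtrack cargo-sim` (the Monte Carlo) and
`gnrtrack mechanics` (torsion and coating arithmetic, e.g. a twist of
0.0332 rad ~ 2 degrees per step at 170 pN nm).

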