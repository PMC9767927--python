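"""Rigid-body kinematics of a rod yawing while rolling around a helical track.

A nanorod crawling along a microtubule is modelled as a rigid rod whose
center follows a helix of radius ``h`` around the filament (X) axis while
the rod simultaneously rolls about X (synchronised with the orbit) and
yaws about the vertical Z axis.  The dark-field polarization signal only
reports the rod's orientation projected into the X-Y sample plane, folded
to [0, 180) because a rod is head-tail symmetric.

Conventions
-----------
* X points along the microtubule axis toward the plus end, Z is vertical.
* Angles are radians internally; degrees appear only at user interfaces.
* Positive ``omega_helix`` is the left-handed orbit: at the top of the
  orbit the center moves toward +Y while advancing +X.
* The physiological coupling is ``omega_roll = omega_helix`` and
  ``|omega_yaw| = |omega_helix| / 2`` (a 180 deg yaw per orbit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HelixParams",
    "YawRollParams",
    "RodGeometry",
    "RodPose",
    "rot_x",
    "rot_y",
    "rot_z",
    "helix_center",
    "rod_pose",
    "projected_angle",
    "unwrap_angles",
    "classify_pattern",
]


@dataclass(frozen=True)
class HelixParams:
    """Helical center trajectory: X advances at ``v`` while (Y, Z) orbit.

    v : translational velocity along X (um/s)
    omega_helix : signed angular velocity in the Y-Z plane (rad/s);
        positive is the left-handed orbit
    h : orbit radius (nm)
    """

    v: float
    omega_helix: float
    h: float = 35.0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("helix radius h must be >= 0")

    @property
    def pitch_um(self) -> float:
        """Forward displacement per orbit, 2*pi*v/omega (um, signed)."""
        return 2.0 * np.pi * self.v / self.omega_helix


@dataclass(frozen=True)
class YawRollParams:
    """Rotation of the rod about its own axes.

    omega_roll : angular velocity about X (rad/s)
    omega_yaw : signed angular velocity about Z (rad/s); sign encodes
        counterclockwise (+) vs clockwise (-) yaw in the sample plane
    phi : initial phase angle in [0, pi) -- the rod orientation relative
        to the microtubule axis when the rod is at the top of its orbit
    """

    omega_roll: float
    omega_yaw: float
    phi: float = 0.0

    @classmethod
    def coupled(cls, omega_helix: float, yaw_sign: int = -1, phi: float = 0.0) -> "YawRollParams":
        """The coupled motion: roll locked to the orbit, yaw at half rate."""
        return cls(
            omega_roll=omega_helix,
            omega_yaw=yaw_sign * abs(omega_helix) / 2.0,
            phi=phi,
        )


@dataclass(frozen=True)
class RodGeometry:
    """Nanorod dimensions (nm).  ``r`` is the half-length of the long axis."""

    diameter: float = 40.0
    length: float = 68.0

    def __post_init__(self) -> None:
        if not (self.length >= self.diameter > 0):
            raise ValueError("require length >= diameter > 0")

    @property
    def r(self) -> float:
        return self.length / 2.0


@dataclass(frozen=True)
class RodPose:
    """Tip, center and end positions (nm) of the rod at one instant."""

    tip: np.ndarray
    center: np.ndarray
    end: np.ndarray


def rot_x(angle: float | np.ndarray) -> np.ndarray:
    """Elemental rotation about X (roll).  Orthonormal, det +1."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle: float | np.ndarray) -> np.ndarray:
    """Elemental rotation about Y (pitch)."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle: float | np.ndarray) -> np.ndarray:
    """Elemental rotation about Z (yaw)."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def helix_center(t: np.ndarray | float, hp: HelixParams) -> np.ndarray:
    """Center trajectory: (v*t, h*cos(pi/2 - w*t), h*sin(pi/2 - w*t)).

    Starts at the top of the orbit (0, 0, h).  Returns shape (..., 3),
    with X in the same length unit as ``hp.h`` per unit of ``v*t`` --
    callers are expected to keep v in nm/s when h is in nm (the helpers
    in :mod:`gnrtrack.synthetic_data` do this bookkeeping).
    """
    t = np.asarray(t, dtype=float)
    phase = np.pi / 2.0 - hp.omega_helix * t
    return np.stack(
        [hp.v * t, hp.h * np.cos(phase), hp.h * np.sin(phase)], axis=-1
    )


def rod_pose(
    t: float | np.ndarray,
    hp: HelixParams,
    yr: YawRollParams,
    geom: RodGeometry = RodGeometry(),
) -> RodPose:
    """Closed-form tip/center/end of the rolling, yawing rod.

    tip(t)  = ( r*cos(wy*t + phi) + v*t,
                r*cos(wr*t)*sin(wy*t + phi) + Y_helix,
                r*sin(wr*t)*sin(wy*t + phi) + Z_helix )
    end(t) mirrors the tip about the center; center(t) is the helix alone,
    independent of the yaw/roll parameters.
    """
    t = np.asarray(t, dtype=float)
    r = geom.r
    yaw = yr.omega_yaw * t + yr.phi
    roll = yr.omega_roll * t
    center = helix_center(t, hp)
    arm = np.stack(
        [
            r * np.cos(yaw),
            r * np.cos(roll) * np.sin(yaw),
            r * np.sin(roll) * np.sin(yaw),
        ],
        axis=-1,
    )
    return RodPose(tip=center + arm, center=center, end=center - arm)


def rod_pose_matrix(
    t: float,
    hp: HelixParams,
    yr: YawRollParams,
    geom: RodGeometry = RodGeometry(),
) -> RodPose:
    """Same pose via the explicit matrix product R_X R_Y(0) R_Z p0 + helix.

    Kept separate from :func:`rod_pose` as an algebraic cross-check of the
    closed forms (extrinsic Z-then-Y-then-X rotation of the initial rod).
    """
    p0_tip = geom.r * np.array([np.cos(yr.phi), np.sin(yr.phi), 0.0])
    p0_end = geom.r * np.array(
        [np.cos(yr.phi + np.pi), np.sin(yr.phi + np.pi), 0.0]
    )
    rot = rot_x(yr.omega_roll * t) @ rot_y(0.0) @ rot_z(yr.omega_yaw * t)
    center = helix_center(t, hp)
    return RodPose(tip=rot @ p0_tip + center, center=center, end=rot @ p0_end + center)


def projected_angle(
    t: float | np.ndarray, yr: YawRollParams, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane rod orientation, folded to [0, pi).

    Computed as atan2(Y_tip - Y_end, X_tip - X_end) mod pi, which equals
    arctan[cos(w_roll t) * tan(w_yaw t + phi)] wherever the tangent form
    is defined, but has no singularities.

    Returns ``(angle, defined)``; ``defined`` is False where the rod
    points along Z so that the projection degenerates to a point.
    """
    t = np.asarray(t, dtype=float)
    yaw = yr.omega_yaw * t + yr.phi
    dx = np.cos(yaw)
    dy = np.cos(yr.omega_roll * t) * np.sin(yaw)
    norm = np.hypot(dx, dy)
    defined = norm > eps
    ang = np.where(defined, np.arctan2(dy, dx) % np.pi, np.nan)
    return ang, defined


def unwrap_angles(angles: np.ndarray, period: float = np.pi) -> np.ndarray:
    """Unwrap a head-tail symmetric angle series (period pi by default).

    Successive samples are shifted by multiples of the period to minimise
    frame-to-frame jumps, turning the sawtooth [0, pi) series into a
    continuous trace.  NaNs (undefined angles) stay NaN and unwrapping
    resumes from the last defined sample.
    """
    angles = np.asarray(angles, dtype=float)
    out = np.empty_like(angles)
    prev = np.nan
    for i, a in enumerate(angles):
        if np.isnan(a):
            out[i] = np.nan
            continue
        if np.isnan(prev):
            out[i] = a
        else:
            k = np.round((prev - a) / period)
            out[i] = a + k * period
        prev = out[i]
    return out


def classify_pattern(
    phi: float,
    yaw_sign: int = -1,
    *,
    omega_helix: float = 2.0 * np.pi,
    n_samples: int = 4096,
    unidirectional_tol: float = 0.10,
) -> str:
    """Classify the in-plane polarization-rotation pattern over one orbit.

    Simulates the coupled motion (|omega_yaw| = omega_helix/2) for one
    helix period, unwraps the projected angle and measures the net
    rotation.  A pattern is "counterclockwise"/"clockwise" if the net
    unwrapped rotation is within ``unidirectional_tol`` of +/-180 deg;
    otherwise "oscillatory".

    With the default clockwise yaw (``yaw_sign=-1``) the apparent pattern
    is counterclockwise at phi=0, oscillatory at phi=45 and 135 deg, and
    clockwise at phi=90 deg: the projected rotation at phi=0 runs
    *opposite* to the yaw because the roll flips the projection halfway
    through the orbit.

    Parameters
    ----------
    phi : initial phase angle (radians, in [0, pi))
    yaw_sign : +1 counterclockwise yaw, -1 clockwise yaw
    """
    if not (0.0 <= phi < np.pi):
        raise ValueError("phi must lie in [0, pi)")
    if yaw_sign not in (-1, 1):
        raise ValueError("yaw_sign must be +1 or -1")
    period = 2.0 * np.pi / abs(omega_helix)
    t = np.linspace(0.0, period, n_samples)
    yr = YawRollParams.coupled(abs(omega_helix), yaw_sign=yaw_sign, phi=phi)
    ang, defined = projected_angle(t, yr)
    unwrapped = unwrap_angles(ang)
    good = ~np.isnan(unwrapped)
    net = unwrapped[good][-1] - unwrapped[good][0]
    if abs(abs(net) - np.pi) <= unidirectional_tol * np.pi:
        return "counterclockwise" if net > 0 else "clockwise"
    return "oscillatory"
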