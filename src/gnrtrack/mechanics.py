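"""Order-of-magnitude torsional and coating mechanics of the motor-rod system.

Closed forms connecting the per-step torque of a kinesin motor to the
observed rotation of its nanorod cargo:

* torsional twist per step of the motor "shaft" (a protein cylinder),
  theta_step = T_step * L / (K G) with polar moment K = pi d^4 / 32;
* the yaw angle per 8-nm step implied by a 180-deg rotation per helix
  pitch;
* the lateral excursion of surface motors caused by that yaw, and its
  value in lattice units of the 5.1-nm protofilament spacing;
* how many motors fit on the rod surface and how many are engaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import RodGeometry

__all__ = [
    "TorsionParams",
    "CoatingParams",
    "polar_moment",
    "twist_angle",
    "yaw_per_step",
    "lateral_excursion",
    "normalized_offset",
    "surface_capacity",
    "engaged_motors",
]

#: 1 GPa expressed in pN/nm^2.
GPA_TO_PN_PER_NM2 = 1000.0


@dataclass(frozen=True)
class TorsionParams:
    """Torsion of the motor linker approximated as a protein cylinder.

    t_step : torque per step (pN nm); 170 for kinesin-1
    length : cylinder length L (nm)
    diameter : cylinder diameter d (nm)
    g_modulus : modulus of rigidity G (GPa); ~1 GPa for globular protein
    """

    t_step: float = 170.0
    length: float = 12.0
    diameter: float = 5.0
    g_modulus: float = 1.0

    def __post_init__(self) -> None:
        if min(self.t_step, self.length, self.diameter, self.g_modulus) <= 0:
            raise ValueError("all torsion parameters must be > 0")


@dataclass(frozen=True)
class CoatingParams:
    """Motor coating of the rod surface.

    footprint : occupied area per motor (nm^2)
    accessible_fraction : fraction of coated motors able to reach the
        microtubule at any instant
    duty_ratio : fraction of the cycle a motor is bound and pulling
    """

    rod: RodGeometry = field(default_factory=RodGeometry)
    footprint: float = 100.0
    accessible_fraction: float = 0.25
    duty_ratio: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.accessible_fraction <= 1 and 0 < self.duty_ratio <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.footprint <= 0:
            raise ValueError("footprint must be > 0")


def polar_moment(diameter: float) -> float:
    """Polar moment of inertia K = pi d^4 / 32 of a cylinder (nm^4)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return np.pi * diameter**4 / 32.0


def twist_angle(p: TorsionParams = TorsionParams(), degrees: bool = False) -> float:
    """Twist per step theta_step = T_step L / (K G).

    G is converted from GPa to pN/nm^2 (factor exactly 1000).  Defaults
    give ~0.033 rad ~ 2 deg.
    """
    k = polar_moment(p.diameter)
    theta = p.t_step * p.length / (k * p.g_modulus * GPA_TO_PN_PER_NM2)
    return float(np.rad2deg(theta)) if degrees else float(theta)


def yaw_per_step(pitch_nm: float = 700.0, step_nm: float = 8.0) -> float:
    """Yaw angle (deg) per forward step: 180 * step / pitch.

    A 180-deg rotation per 700-nm helix pitch gives ~2 deg per 8-nm
    tubulin dimer.
    """
    if pitch_nm <= 0:
        raise ValueError("pitch must be > 0")
    return 180.0 * step_nm / pitch_nm


def lateral_excursion(moment_arm_nm: float, angle_deg: float) -> float:
    """Lateral displacement arm * tan(angle) of a surface motor (nm).

    The arm ranges from the rod radius (20 nm) to the half-length
    (34 nm); the "at most" excursion uses 34 nm.
    """
    if moment_arm_nm <= 0:
        raise ValueError("moment arm must be > 0")
    return float(moment_arm_nm * np.tan(np.deg2rad(angle_deg)))


def normalized_offset(displacement_nm: float, site_spacing_nm: float = 5.1) -> float:
    """Displacement in lattice units of the lateral binding-site spacing."""
    if site_spacing_nm <= 0:
        raise ValueError("site spacing must be > 0")
    return displacement_nm / site_spacing_nm


def _round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    mag = np.floor(np.log10(abs(x)))
    return float(round(x, -int(mag) + sig - 1))


def surface_capacity(cp: CoatingParams = CoatingParams(), rounded: bool = False) -> float:
    """Motor capacity of the rod: closed-cylinder area / footprint.

    The rod surface is modelled as a right cylinder with two flat end
    caps, area = pi d L + 2 pi (d/2)^2 (~1.1e4 nm^2 for the 40 x 68 nm
    rod), which over a 100-nm^2 footprint is ~110 motors, "about 100" at
    one significant figure (``rounded=True``).
    """
    d, length = cp.rod.diameter, cp.rod.length
    area = np.pi * d * length + 2.0 * np.pi * (d / 2.0) ** 2
    cap = area / cp.footprint
    return _round_sig(cap, 1) if rounded else float(cap)


def engaged_motors(cp: CoatingParams = CoatingParams(), capacity: float | None = None) -> float:
    """Expected force-generating motors: capacity x accessible x duty.

    With ~100 attached motors, one quarter accessible and a 20% duty
    ratio, about 5 motors pull at any one time.
    """
    if capacity is None:
        capacity = surface_capacity(cp, rounded=True)
    return float(capacity * cp.accessible_fraction * cp.duty_ratio)
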