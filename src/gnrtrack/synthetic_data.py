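"""Ground-truthed synthetic data: calibration sweeps, tracks, image stacks.

Everything the analysis pipeline consumes can be generated here with
known ground truth, emulating the study conditions: a particle advancing
at ~0.4-0.5 um/s along X while orbiting the microtubule with ~0.7 um
pitch, yawing 180 deg per orbit, observed at 100 frames/s as two
orthogonally polarized Gaussian spots.

The noise model is additive Gaussian per channel and per axis; the
magnitudes are generator knobs (the measured recordings' noise levels
are not part of the model).  Defaults: 3 counts of intensity noise
(matching the scatter of the reference calibration sweep) and 10 nm of
localization noise per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import polarimetry as pol

__all__ = [
    "NoiseSpec",
    "MotionModel",
    "GroundTruth",
    "REFERENCE_CALIBRATION",
    "default_motion_model",
    "gen_calibration_sweep",
    "gen_track",
    "gen_image_stack",
]

#: Calibration of the reference polarizer sweep (counts / degrees).
REFERENCE_CALIBRATION = pol.PolarCalibration(
    I0=127.5,
    zeta=float(np.deg2rad(99.3)),
    eta=float(np.deg2rad(45.3)),
    b=19.5,
)

TRACK_COLUMNS = [
    "frame", "t", "x_um", "y_um", "z_um",
    "i_bottom", "i_upper", "dop", "angle_deg", "angle_defined",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise magnitudes.

    intensity_sd : counts per channel
    localization_sd : nm, isotropic per axis
    background : counts added to both channels (on top of the model's b)
    """

    intensity_sd: float = 3.0
    localization_sd: float = 10.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.intensity_sd, self.localization_sd, self.background) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class MotionModel:
    """Helix + yaw/roll + rod geometry bundle.

    ``geom=None`` models a point particle (zero-length rod): positions
    are generated but the in-plane angle is undefined.
    """

    helix: kin.HelixParams
    yawroll: kin.YawRollParams
    geom: kin.RodGeometry | None = field(default_factory=kin.RodGeometry)


def default_motion_model(
    v: float = 0.5,
    pitch_um: float = 0.7,
    yaw_sign: int = -1,
    phi: float = 0.0,
    h_nm: float = 35.0,
) -> MotionModel:
    """The coupled biaxial motion: omega_roll = omega_helix = 2|omega_yaw|.

    v in um/s, pitch in um (positive = left-handed).  Defaults give the
    ~0.5 um/s, 0.7-um-pitch motion typical of the nanorod assay.
    """
    omega = 2.0 * np.pi * v / pitch_um
    return MotionModel(
        helix=kin.HelixParams(v=v, omega_helix=omega, h=h_nm),
        yawroll=kin.YawRollParams.coupled(omega, yaw_sign=yaw_sign, phi=phi),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Generator configuration: motion, calibration, sampling, seed."""

    model: MotionModel
    calibration: pol.PolarCalibration = REFERENCE_CALIBRATION
    frame_rate: float = 100.0
    duration: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be > 0")


def gen_calibration_sweep(
    cal: pol.PolarCalibration,
    angle_step_deg: float = 10.0,
    noise: NoiseSpec = NoiseSpec.none(),
    seed: int = 0,
) -> pd.DataFrame:
    """Polarizer sweep 0..180 deg inclusive at ``angle_step_deg`` intervals.

    Returns a table of (angle_deg, i_bottom, i_upper); with the default
    10-deg step that is 19 rows.  Intensities follow the two-channel
    model plus additive Gaussian noise.
    """
    if not (0.0 < angle_step_deg <= 90.0):
        raise ValueError("angle_step must lie in (0, 90] degrees")
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 180.0 + 1e-9, angle_step_deg)
    bottom, upper = pol.intensity_pair(np.deg2rad(angles), cal)
    bottom = bottom + noise.background + rng.normal(0, noise.intensity_sd, len(angles)) if noise.intensity_sd or noise.background else bottom
    upper = upper + noise.background + rng.normal(0, noise.intensity_sd, len(angles)) if noise.intensity_sd or noise.background else upper
    return pd.DataFrame({"angle_deg": angles, "i_bottom": bottom, "i_upper": upper})


def _track_frame(gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(gt.duration * gt.frame_rate))
    frames = np.arange(n)
    return frames, frames / gt.frame_rate


def gen_track(
    gt: GroundTruth, noise: NoiseSpec = NoiseSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (true, noisy) pair of per-frame track tables.

    Positions are the helical center trajectory plus localization noise;
    intensities are the two-channel polarization model evaluated at the
    projected rod angle plus intensity noise.  The true table carries the
    exact per-frame angle; the noisy table's angle column is re-estimated
    from the noisy intensities by residual inversion, exactly as the
    analysis of a measured track would.
    """
    rng = np.random.default_rng(gt.seed)
    frames, t = _track_frame(gt)
    mm = gt.model
    center = kin.helix_center(t, replace(mm.helix, v=0.0))  # orbit only, nm
    x_um = mm.helix.v * t
    y_um = center[:, 1] / 1000.0
    z_um = center[:, 2] / 1000.0

    if mm.geom is not None and mm.geom.r > 0:
        ang, defined = kin.projected_angle(t, mm.yawroll)
    else:
        ang = np.full(len(t), np.nan)
        defined = np.zeros(len(t), dtype=bool)
    safe = np.where(np.isnan(ang), 0.0, ang)
    i_b, i_u = pol.intensity_pair(safe, gt.calibration)
    i_b = np.where(defined, i_b, gt.calibration.b)
    i_u = np.where(defined, i_u, gt.calibration.b)

    true = pd.DataFrame({
        "frame": frames, "t": t,
        "x_um": x_um, "y_um": y_um, "z_um": z_um,
        "i_bottom": i_b, "i_upper": i_u,
        "dop": pol.dop((i_b, i_u)),
        "angle_deg": np.rad2deg(ang),
        "angle_defined": defined.astype(int),
    })

    loc_sd_um = noise.localization_sd / 1000.0
    nb = i_b + noise.background + rng.normal(0, noise.intensity_sd, len(t)) if noise.intensity_sd else i_b + noise.background
    nu = i_u + noise.background + rng.normal(0, noise.intensity_sd, len(t)) if noise.intensity_sd else i_u + noise.background
    est_ang, est_def = pol.estimate_angle_series(nb, nu, gt.calibration)
    noisy = pd.DataFrame({
        "frame": frames, "t": t,
        "x_um": x_um + rng.normal(0, loc_sd_um, len(t)) if loc_sd_um else x_um,
        "y_um": y_um + rng.normal(0, loc_sd_um, len(t)) if loc_sd_um else y_um,
        "z_um": z_um + rng.normal(0, loc_sd_um, len(t)) if loc_sd_um else z_um,
        "i_bottom": nb, "i_upper": nu,
        "dop": pol.dop((nb, nu)),
        "angle_deg": np.rad2deg(est_ang),
        "angle_defined": est_def.astype(int),
    })
    return true, noisy


def gen_image_stack(
    track: pd.DataFrame,
    psf_sd_nm: float = 130.0,
    displacer_offset_nm: float = 1260.0,
    astig_slope_um: float = 0.98,
    noise: NoiseSpec = NoiseSpec.none(),
    pixel_size_nm: float = 42.0,
    seed: int = 0,
    margin_px: int = 12,
) -> tuple[np.ndarray, dict]:
    """Render a track as a dual-spot dark-field image stack.

    Each frame holds two axis-aligned Gaussian spots: the bottom channel
    at the particle position and the upper channel ``displacer_offset_nm``
    above it along the camera Y axis.  Spot amplitudes are the channel
    intensities; the width ratio S_Y/S_X encodes Z through
    ``ratio = 1 + z_um / astig_slope_um``.

    Returns ``(stack, ground_truth)`` where the stack is float counts of
    shape (frames, ny, nx) and the ground truth dict carries the per-frame
    spot parameters (positions in px, widths, amplitudes and integrated
    intensities) plus the geometry needed to invert the rendering.

    A warning is raised if the two spots approach within 2*psf_sd (fit
    degeneracy).
    """
    import warnings

    rng = np.random.default_rng(seed)
    px = pixel_size_nm
    sx_px = psf_sd_nm / px
    off_px = displacer_offset_nm / px
    if off_px < 2.0 * sx_px:
        warnings.warn("displacer offset < 2*psf_sd: overlapping spots, fit degeneracy")

    x_px = track["x_um"].to_numpy() * 1000.0 / px
    y_px = track["y_um"].to_numpy() * 1000.0 / px
    z_um = track["z_um"].to_numpy()
    i_b = track["i_bottom"].to_numpy()
    i_u = track["i_upper"].to_numpy()

    ratio = 1.0 + z_um / astig_slope_um
    sy_px = sx_px * ratio

    # camera layout: upper-channel spot at smaller row index
    x0 = margin_px - x_px.min()
    row_b0 = margin_px + off_px - (y_px.min())
    nx = int(np.ceil(x_px.max() - x_px.min())) + 2 * margin_px + 1
    ny = int(np.ceil(y_px.max() - y_px.min() + off_px)) + 2 * margin_px + 1

    n = len(x_px)
    stack = np.zeros((n, ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    rows_b = row_b0 + y_px
    rows_u = rows_b - off_px
    cols = x0 + x_px
    for i in range(n):
        for amp, row in ((i_b[i], rows_b[i]), (i_u[i], rows_u[i])):
            stack[i] += amp * np.exp(
                -((xx - cols[i]) ** 2) / (2 * sx_px**2)
                - ((yy - row) ** 2) / (2 * sy_px[i] ** 2)
            )
        if noise.background:
            stack[i] += noise.background
        if noise.intensity_sd:
            stack[i] += rng.normal(0, noise.intensity_sd, (ny, nx))

    truth = {
        "col_px": cols,
        "row_bottom_px": rows_b,
        "row_upper_px": rows_u,
        "s_x_px": np.full(n, sx_px),
        "s_y_px": sy_px,
        "amp_bottom": i_b,
        "amp_upper": i_u,
        "integrated_bottom": 2 * np.pi * sx_px * sy_px * i_b,
        "integrated_upper": 2 * np.pi * sx_px * sy_px * i_u,
        "displacer_offset_px": off_px,
        "pixel_size_nm": px,
        "origin_col_px": x0,
        "origin_row_bottom_px": row_b0,
        "z_um": z_um,
    }
    return stack, truth
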