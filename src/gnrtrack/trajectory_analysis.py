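"""Track quantification: velocity, pitches, correlations, yaw direction.

A track is a per-frame table (see ``gnrtrack.io.TRACK_COLUMNS``) of the
particle position, the two channel intensities, the DOP and the
estimated in-plane angle.  This module measures:

* forward velocity (linear fit of X vs t),
* the helix pitch (X displacement per oscillation cycle of Y) and the
  polarization pitch (X displacement per 180-deg period of the
  polarization signal),
* the supertwist correction of the measured pitch against the
  microtubule lattice twist (1/P_measured = 1/P_motor + 1/P_mt),
* lagged cross-correlations between Y and the polarization signals,
* the yaw direction from the sign of Pearson's r between Y and the
  (detrended, unwrapped) angle,
* the binomial direction test and Welch's t test used for population
  comparisons.

``TrackModel(track).fit()`` bundles these into a results object with a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import unwrap_angles
from .spot_tracking import moving_average

__all__ = [
    "PitchMeasurement",
    "SUPERTWIST_PITCH_UM",
    "fit_velocity",
    "detect_cycles",
    "helix_pitch",
    "polarization_pitch",
    "correct_pitch",
    "cross_correlation",
    "yaw_direction",
    "binomial_direction_test",
    "welch_test",
    "TrackModel",
    "TrackResults",
]

#: Supertwist pitch (um) of the microtubule lattice by protofilament
#: number; positive = left-handed.
SUPERTWIST_PITCH_UM = {12: -3.4, 13: -24.8, 14: 6.8}


@dataclass(frozen=True)
class PitchMeasurement:
    """Per-cycle X displacements and their summary statistics (um)."""

    cycles: list  # (start_t, end_t, x_displacement_um)
    mean: float
    sd: float
    n: int

    @classmethod
    def from_cycles(cls, cycles: list) -> "PitchMeasurement":
        if not cycles:
            return cls([], np.nan, np.nan, 0)
        dx = np.array([c[2] for c in cycles])
        return cls(list(cycles), float(dx.mean()), float(dx.std(ddof=1)) if len(dx) > 1 else 0.0, len(dx))


def fit_velocity(track: pd.DataFrame) -> tuple[float, float]:
    """Forward velocity from a linear fit of X vs t.

    Returns (v, stderr) in um/s.  Requires >= 10 frames.
    """
    t = track["t"].to_numpy()
    x = track["x_um"].to_numpy()
    good = np.isfinite(x)
    if good.sum() < 10:
        raise ValueError("need >= 10 frames with finite X to fit a velocity")
    res = stats.linregress(t[good], x[good])
    return float(res.slope), float(res.stderr)


def detect_cycles(series, t, smooth_window: int = 15) -> list[tuple[float, float]]:
    """Oscillation cycles from same-sign zero crossings.

    The series is boxcar-smoothed, mean-subtracted, and cycle boundaries
    are placed at successive *upward* zero crossings.  Partial cycles at
    the ends are discarded; fewer than one full cycle gives ``[]``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(series, dtype=float)
    good = np.isfinite(y)
    t, y = t[good], y[good]
    if len(y) < 3:
        return []
    if smooth_window > 1 and smooth_window <= len(y):
        y = moving_average(y, smooth_window)
    y = y - y.mean()
    up = np.flatnonzero((y[:-1] < 0) & (y[1:] >= 0))
    if len(up) < 2:
        return []
    # linear interpolation of each crossing time
    tc = t[up] + (0.0 - y[up]) / (y[up + 1] - y[up]) * (t[up + 1] - t[up])
    return [(tc[i], tc[i + 1]) for i in range(len(tc) - 1)]


def _pitch_from_boundaries(track: pd.DataFrame, boundaries) -> PitchMeasurement:
    t = track["t"].to_numpy()
    x = track["x_um"].to_numpy()
    cycles = []
    for t0, t1 in boundaries:
        x0 = np.interp(t0, t, x)
        x1 = np.interp(t1, t, x)
        cycles.append((float(t0), float(t1), float(x1 - x0)))
    return PitchMeasurement.from_cycles(cycles)


def helix_pitch(track: pd.DataFrame, smooth_window: int = 15) -> PitchMeasurement:
    """X displacement per oscillation cycle of the Y trajectory (um)."""
    bounds = detect_cycles(track["y_um"], track["t"], smooth_window)
    return _pitch_from_boundaries(track, bounds)


def polarization_pitch(
    track: pd.DataFrame, signal: str = "angle", smooth_window: int = 15
) -> PitchMeasurement:
    """X displacement per period of the polarization signal (um).

    One polarization period corresponds to a 180-deg rotation of the rod
    angle.  The default ``signal="angle"`` places cycle boundaries at
    successive 180-deg advances of the unwrapped angle trace, which is
    robust to the non-uniform phase of the angle within a period (the
    roll modulation makes the DOP trace cross its mean more than once
    per period).  ``signal="dop"``/"sum" instead apply zero-crossing
    cycle detection to those observables.
    """
    if signal in ("dop", "sum"):
        y = (
            track["dop"]
            if signal == "dop"
            else track["i_bottom"] + track["i_upper"]
        )
        bounds = detect_cycles(y, track["t"], smooth_window)
    elif signal == "angle":
        ang = np.rad2deg(unwrap_angles(np.deg2rad(track["angle_deg"].to_numpy()), np.pi))
        t = track["t"].to_numpy()
        good = np.isfinite(ang)
        ang, t = ang[good], t[good]
        if len(ang) < 2:
            return PitchMeasurement.from_cycles([])
        direction = np.sign(ang[-1] - ang[0]) or 1.0
        rel = (ang - ang[0]) * direction
        n_cycles = int(np.floor(rel.max() / 180.0))
        # first time each 180-deg level is crossed, linearly interpolated;
        # the stretch before the first crossing is a partial cycle and is
        # discarded, as are trailing partials
        bounds_t = []
        for k in range(1, n_cycles + 1):
            idx = int(np.argmax(rel >= k * 180.0))
            frac = (k * 180.0 - rel[idx - 1]) / (rel[idx] - rel[idx - 1])
            bounds_t.append(t[idx - 1] + frac * (t[idx] - t[idx - 1]))
        bounds = list(zip(bounds_t[:-1], bounds_t[1:]))
    else:
        raise ValueError("signal must be 'angle', 'dop' or 'sum'")
    return _pitch_from_boundaries(track, bounds)


def correct_pitch(p_measured: float, p_mt: float | None) -> float:
    """Remove the microtubule supertwist from a measured pitch (um).

    1/P_measured = 1/P_motor + 1/P_mt, so
    P_motor = 1 / (1/P_measured - 1/P_mt).  ``p_mt=None`` (or +/-inf)
    models the idealised straight 13.00-protofilament lattice and returns
    the measured pitch unchanged.  Pitches are signed; positive =
    left-handed.
    """
    if p_measured == 0:
        raise ValueError("p_measured must be nonzero")
    if p_mt is None or not np.isfinite(p_mt):
        return p_measured
    if p_mt == 0 or p_measured == p_mt:
        raise ValueError("require p_mt != 0 and p_measured != p_mt")
    return 1.0 / (1.0 / p_measured - 1.0 / p_mt)


def cross_correlation(a, b, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson-normalized cross-correlation on overlapping segments.

    Returns ``(lags, ccf)`` for lags -max_lag..+max_lag; positive lag
    means ``b`` shifted later relative to ``a``.  Constant input yields
    NaNs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: len(a) - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag]
        good = np.isfinite(x) & np.isfinite(y)
        if good.sum() < 3:
            continue
        x, y = x[good], y[good]
        if x.std() == 0 or y.std() == 0:
            continue
        ccf[i] = np.corrcoef(x, y)[0, 1]
    return lags, ccf


def yaw_direction(
    track: pd.DataFrame, r_min: float = 0.3
) -> tuple[float, str]:
    """Yaw direction from Pearson's r between Y and the angle trace.

    The estimated angle is unwrapped (period 180 deg) and linearly
    detrended before correlating with the Y displacement, which makes
    the sign of r a robust readout of the yaw sense at any phase angle:
    r > r_min: counterclockwise, r < -r_min: clockwise, otherwise
    undetermined.
    """
    ang = unwrap_angles(np.deg2rad(track["angle_deg"].to_numpy()), np.pi)
    y = track["y_um"].to_numpy()
    t = track["t"].to_numpy()
    good = np.isfinite(ang) & np.isfinite(y)
    if good.sum() < 10:
        return np.nan, "undetermined"
    ang, y, t = ang[good], y[good], t[good]
    coef = np.polyfit(t, ang, 1)
    det = ang - np.polyval(coef, t)
    if det.std() == 0 or y.std() == 0:
        return np.nan, "undetermined"
    r = float(np.corrcoef(y, det)[0, 1])
    if r > r_min:
        return r, "ccw"
    if r < -r_min:
        return r, "cw"
    return r, "undetermined"


def binomial_direction_test(n_cw: int, n_total: int) -> float:
    """Exact two-sided binomial test against p = 0.5.

    The p value is twice the smaller tail probability, capped at 1 --
    e.g. 8 clockwise of 13 gives p ~ 0.58.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_cw <= n_total):
        raise ValueError("need 0 <= n_cw <= n_total")
    lower = stats.binom.cdf(n_cw, n_total, 0.5)
    upper = stats.binom.sf(n_cw - 1, n_total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def welch_test(sample_a, sample_b) -> tuple[float, float]:
    """Welch's two-tailed t test (unequal variances).

    Returns (t, p).  Requires n >= 2 per sample and nonzero variance in
    at least one sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------


class TrackModel:
    """Quantification model for one track table.

    Parameters
    ----------
    track : per-frame table with the canonical track columns
    smooth_window : boxcar window (frames) used before cycle detection
    r_min : |r| threshold for calling a yaw direction
    """

    def __init__(self, track: pd.DataFrame, smooth_window: int = 15, r_min: float = 0.3):
        self.track = track.reset_index(drop=True)
        self.smooth_window = smooth_window
        self.r_min = r_min

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TrackModel":
        from .io import read_track

        return cls(read_track(path), **kwargs)

    def fit(self) -> "TrackResults":
        v, v_se = fit_velocity(self.track)
        hp = helix_pitch(self.track, self.smooth_window)
        pp = polarization_pitch(self.track, smooth_window=self.smooth_window)
        r, direction = yaw_direction(self.track, self.r_min)
        return TrackResults(
            model=self,
            velocity=v,
            velocity_se=v_se,
            helix_pitch=hp,
            polarization_pitch=pp,
            pearson_r=r,
            direction=direction,
        )


@dataclass
class TrackResults:
    """Per-track estimates produced by :meth:`TrackModel.fit`."""

    model: TrackModel
    velocity: float
    velocity_se: float
    helix_pitch: PitchMeasurement
    polarization_pitch: PitchMeasurement
    pearson_r: float
    direction: str

    @property
    def pitch_ratio(self) -> float:
        """Polarization pitch / helix pitch (1 for the coupled motion)."""
        return self.polarization_pitch.mean / self.helix_pitch.mean

    def to_dict(self) -> dict:
        return {
            "velocity_um_s": self.velocity,
            "velocity_se_um_s": self.velocity_se,
            "helix_pitch_um": self.helix_pitch.mean,
            "helix_pitch_sd_um": self.helix_pitch.sd,
            "helix_pitch_n": self.helix_pitch.n,
            "helix_cycles": self.helix_pitch.cycles,
            "polarization_pitch_um": self.polarization_pitch.mean,
            "polarization_pitch_sd_um": self.polarization_pitch.sd,
            "polarization_pitch_n": self.polarization_pitch.n,
            "polarization_cycles": self.polarization_pitch.cycles,
            "pearson_r": self.pearson_r,
            "yaw_direction": self.direction,
        }

    def summary(self) -> str:
        lines = [
            "Track quantification",
            "-" * 44,
            f"velocity            {self.velocity:8.3f} +/- {self.velocity_se:.3f} um/s",
            f"helix pitch         {self.helix_pitch.mean:8.3f} +/- {self.helix_pitch.sd:.3f} um (n={self.helix_pitch.n})",
            f"polarization pitch  {self.polarization_pitch.mean:8.3f} +/- {self.polarization_pitch.sd:.3f} um (n={self.polarization_pitch.n})",
            f"Pearson r (Y vs angle) {self.pearson_r:+.3f} -> {self.direction}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """X/Y displacements and the angle trace against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model.track
        ax.plot(tr["t"], tr["x_um"], label="X (um)", color="tab:red")
        ax.plot(tr["t"], tr["y_um"], label="Y (um)", color="black")
        ax2 = ax.twinx()
        ax2.plot(tr["t"], tr["angle_deg"], ".", ms=2, color="tab:blue", label="angle (deg)")
        ax.set_xlabel("t (s)")
        ax.set_ylabel("displacement (um)")
        ax2.set_ylabel("angle (deg)")
        ax.legend(loc="upper left")
        return ax
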