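"""Spot localization for dual-polarization dark-field image stacks.

Each particle appears as two displaced spots (the two beam-displacer
channels).  Spots are fit with axis-aligned elliptical 2D Gaussians;
the astigmatic width ratio S_Y/S_X encodes the Z position through a
linear calibration (0.98 um per unit of width ratio by default, the
cylindrical-lens calibration obtained by stepping the objective in
50-nm intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SpotFit",
    "ZCalibration",
    "fit_gaussian_2d",
    "z_from_astigmatism",
    "moving_average",
    "track_stack",
]


@dataclass(frozen=True)
class SpotFit:
    """Axis-aligned elliptical Gaussian fit of one spot.

    x, y : subpixel center (px, in patch coordinates unless offset)
    s_x, s_y : Gaussian SDs along X and Y (px)
    amplitude : peak amplitude above offset (counts)
    offset : constant background (counts)
    converged : False on non-convergence or a fit escaping the patch
    """

    x: float
    y: float
    s_x: float
    s_y: float
    amplitude: float
    offset: float
    converged: bool

    @property
    def integrated(self) -> float:
        """Integrated Gaussian volume 2*pi*s_x*s_y*amplitude (counts)."""
        return 2.0 * np.pi * self.s_x * self.s_y * self.amplitude

    @property
    def width_ratio(self) -> float:
        return self.s_y / self.s_x


@dataclass(frozen=True)
class ZCalibration:
    """Linear map from astigmatic width ratio to Z (um per unit ratio)."""

    factor: float = 0.98
    ratio_at_focus: float = 1.0

    def __post_init__(self) -> None:
        if self.factor == 0:
            raise ValueError("calibration factor must be nonzero")


def _gauss2d(coords, amp, x0, y0, sx, sy, off):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2) / (2 * sx**2) - ((y - y0) ** 2) / (2 * sy**2))
        + off
    )


def fit_gaussian_2d(patch: np.ndarray, initial_guess=None) -> SpotFit:
    """Nonlinear least-squares elliptical Gaussian fit of a single spot.

    ``patch`` must be at least 7x7 px and contain one dominant spot.
    ``initial_guess`` may supply (amp, x0, y0, sx, sy, off); otherwise a
    moment-based guess is used.  A flat or non-converging patch returns
    ``converged=False`` (parameters are then the failed guess).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 7:
        raise ValueError("patch must be 2D and at least 7x7 px")
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    if initial_guess is None:
        off0 = float(np.percentile(patch, 10))
        amp0 = float(patch.max() - off0)
        if amp0 <= 0 or patch.std() < 1e-12:
            return SpotFit(nx / 2, ny / 2, 1.0, 1.0, 0.0, float(patch.mean()), False)
        w = np.clip(patch - off0, 0, None)
        x0 = float((w * xx).sum() / w.sum())
        y0 = float((w * yy).sum() / w.sum())
        sx0 = max(float(np.sqrt((w * (xx - x0) ** 2).sum() / w.sum())), 0.5)
        sy0 = max(float(np.sqrt((w * (yy - y0) ** 2).sum() / w.sum())), 0.5)
        p0 = (amp0, x0, y0, sx0, sy0, off0)
    else:
        p0 = tuple(initial_guess)
    try:
        import warnings

        with warnings.catch_warnings():
            # noiseless patches make the covariance singular; harmless here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss2d,
                (xx.ravel(), yy.ravel()),
                patch.ravel(),
                p0=p0,
                maxfev=5000,
            )
    except RuntimeError:
        return SpotFit(p0[1], p0[2], p0[3], p0[4], p0[0], p0[5], False)
    amp, x0, y0, sx, sy, off = popt
    sx, sy = abs(sx), abs(sy)
    inside = 0 <= x0 <= nx - 1 and 0 <= y0 <= ny - 1
    ok = inside and amp > 0 and sx > 0 and sy > 0
    return SpotFit(float(x0), float(y0), float(sx), float(sy), float(amp), float(off), bool(ok))


def z_from_astigmatism(s_x: float, s_y: float, zcal: ZCalibration = ZCalibration()) -> float:
    """Z position (um) from the astigmatic width ratio S_Y/S_X."""
    if s_x <= 0:
        raise ValueError("s_x must be > 0")
    return zcal.factor * (s_y / s_x - zcal.ratio_at_focus)


def moving_average(series, window: int = 15) -> np.ndarray:
    """Centered boxcar smoothing with truncated windows at the ends.

    ``window`` must be odd; window=1 is the identity.  The output has the
    same length as the input; near the ends the effective window shrinks
    so no phantom values are introduced.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(series):
        raise ValueError("window longer than series")
    return (
        pd.Series(series)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _patch_around(frame: np.ndarray, cy: int, cx: int, half: int):
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    if y0 < 0 or x0 < 0 or y1 > frame.shape[0] or x1 > frame.shape[1]:
        return None, None
    return frame[y0:y1, x0:x1], (y0, x0)


def track_stack(
    stack: np.ndarray,
    displacer_offset_px: float,
    zcal: ZCalibration = ZCalibration(),
    pixel_size_nm: float = 42.0,
    frame_rate: float = 100.0,
    patch_half: int = 7,
) -> pd.DataFrame:
    """Localize the two displaced spots per frame and build a track table.

    The bottom-channel spot is searched in the lower half of each frame
    and the upper-channel spot ``displacer_offset_px`` above it (smaller
    row index).  X/Y are the mean of the two spot positions after
    removing the offset; Z comes from the mean astigmatic width ratio;
    intensities are integrated Gaussian volumes per channel.

    Frames where either fit fails are flagged (``ok=0``) and left NaN --
    no interpolation is applied.  A single particle per field of view is
    assumed.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, y, x)")
    n_frames, ny, nx = stack.shape
    split = int(round(ny / 2))
    rows = []
    for i in range(n_frames):
        frame = stack[i].astype(float)
        rec = {"frame": i, "t": i / frame_rate}
        fits = []
        for chan, region in (("bottom", frame[split:]), ("upper", frame[:split])):
            cy, cx = np.unravel_index(np.argmax(region), region.shape)
            cy += split if chan == "bottom" else 0
            patch, origin = _patch_around(frame, cy, cx, patch_half)
            if patch is None:
                fits.append(None)
                continue
            fit = fit_gaussian_2d(patch)
            if not fit.converged:
                fits.append(None)
                continue
            fits.append(
                SpotFit(
                    fit.x + origin[1],
                    fit.y + origin[0],
                    fit.s_x,
                    fit.s_y,
                    fit.amplitude,
                    fit.offset,
                    True,
                )
            )
        bottom, upper = fits
        if bottom is None or upper is None:
            rec.update(
                x_um=np.nan, y_um=np.nan, z_um=np.nan,
                i_bottom=np.nan, i_upper=np.nan, ok=0,
            )
        else:
            x_px = (bottom.x + upper.x) / 2.0
            # remove the displacer separation: upper sits offset rows above
            y_px = (bottom.y + (upper.y + displacer_offset_px)) / 2.0
            ratio = (bottom.width_ratio + upper.width_ratio) / 2.0
            rec.update(
                x_um=x_px * pixel_size_nm / 1000.0,
                y_um=y_px * pixel_size_nm / 1000.0,
                z_um=zcal.factor * (ratio - zcal.ratio_at_focus),
                i_bottom=bottom.integrated,
                i_upper=upper.integrated,
                ok=1,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
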