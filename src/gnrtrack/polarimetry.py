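"""Two-channel polarization intensity model, calibration and inversion.

A polarizing beam displacer splits the scattered light of a nanorod into
two orthogonally polarized spots.  Their intensities as functions of the
in-plane rod orientation theta are

    I_bottom = I0 * cos^2(theta + zeta) * cos^2(theta + zeta - eta) + b
    I_upper  = I0 * cos^2(theta + zeta) * cos^2(theta + zeta - eta + pi/2) + b

where I0 is the amplitude, zeta the polarization phase of the incident
beam, eta the beam-displacer phase and b the background.  The degree of
polarization DOP = (I_bottom - I_upper) / (I_bottom + I_upper).

This module fits the calibration (I0, zeta, eta, b) from a polarizer
sweep, inverts observed intensity pairs back to rod angles, and fits the
DOP-vs-summed-intensity ellipse that signals continuous rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "PolarCalibration",
    "IntensityPair",
    "intensity_pair",
    "dop",
    "fit_calibration",
    "CalibrationModel",
    "CalibrationResults",
    "estimate_angle",
    "estimate_angle_series",
    "fit_dop_ellipse",
    "EllipseFit",
]


@dataclass(frozen=True)
class PolarCalibration:
    """Parameters of the two-channel intensity model.

    I0 : amplitude (counts), > 0
    zeta : incident-beam polarization phase (rad)
    eta : beam-displacer phase (rad)
    b : background intensity (counts), >= 0
    """

    I0: float
    zeta: float
    eta: float
    b: float

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")
        if self.b < 0:
            raise ValueError("background b must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "I0": self.I0,
                    "zeta_deg": float(np.rad2deg(self.zeta)),
                    "eta_deg": float(np.rad2deg(self.eta)),
                    "b": self.b,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PolarCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            I0=d["I0"],
            zeta=float(np.deg2rad(d["zeta_deg"])),
            eta=float(np.deg2rad(d["eta_deg"])),
            b=d["b"],
        )


@dataclass(frozen=True)
class IntensityPair:
    """Raw model intensities of the two displacer channels (counts)."""

    i_bottom: float
    i_upper: float

    @property
    def total(self) -> float:
        return self.i_bottom + self.i_upper


def _channels(theta: np.ndarray, I0: float, zeta: float, eta: float, b: float):
    u = theta + zeta
    envelope = np.cos(u) ** 2
    bottom = I0 * envelope * np.cos(u - eta) ** 2 + b
    upper = I0 * envelope * np.cos(u - eta + np.pi / 2.0) ** 2 + b
    return bottom, upper


def intensity_pair(theta, cal: PolarCalibration):
    """Evaluate both channel intensities at rod orientation ``theta`` (rad).

    Scalar input returns an :class:`IntensityPair`; array input returns a
    pair of arrays.
    """
    theta_arr = np.asarray(theta, dtype=float)
    bottom, upper = _channels(theta_arr, cal.I0, cal.zeta, cal.eta, cal.b)
    if theta_arr.ndim == 0:
        return IntensityPair(float(bottom), float(upper))
    return bottom, upper


def dop(pair) -> float:
    """Degree of polarization (i_bottom - i_upper)/(i_bottom + i_upper).

    Accepts an :class:`IntensityPair` or a (bottom, upper) array pair.
    Returns NaN where the total intensity is not positive.
    """
    if isinstance(pair, IntensityPair):
        bottom, upper = pair.i_bottom, pair.i_upper
    else:
        bottom, upper = pair
    bottom = np.asarray(bottom, dtype=float)
    upper = np.asarray(upper, dtype=float)
    total = bottom + upper
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, (bottom - upper) / total, np.nan)
    return float(out) if out.ndim == 0 else out


class CalibrationModel:
    """Joint nonlinear least-squares of both channels of a polarizer sweep.

    Parameters
    ----------
    angles_deg : polarizer (rod-equivalent) angles in degrees
    i_bottom, i_upper : measured channel intensities (counts)

    The model is fit statsmodels-style: ``CalibrationModel(...).fit()``
    returns a :class:`CalibrationResults` with parameter estimates and
    covariance-based uncertainties.
    """

    def __init__(self, angles_deg, i_bottom, i_upper):
        self.angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
        self.i_bottom = np.asarray(i_bottom, dtype=float)
        self.i_upper = np.asarray(i_upper, dtype=float)
        if not (len(self.angles) == len(self.i_bottom) == len(self.i_upper)):
            raise ValueError("angle and intensity columns must have equal length")
        distinct = np.unique(np.round(self.angles, 9))
        if len(distinct) < 8 or np.ptp(distinct) < np.deg2rad(90.0) - 1e-9:
            raise ValueError(
                "calibration sweep needs >= 8 distinct angles spanning >= 90 deg"
            )

    # -- internal -----------------------------------------------------
    def _residual(self, params: np.ndarray) -> np.ndarray:
        I0, zeta, eta, b = params
        bottom, upper = _channels(self.angles, I0, zeta, eta, b)
        return np.concatenate([bottom - self.i_bottom, upper - self.i_upper])

    def _grid_start(self) -> np.ndarray:
        """Coarse (zeta, eta) grid with per-node linear solve for (I0, b).

        For fixed phases the model is linear in (I0, b), so each grid
        node reduces to a closed-form 2x2 normal-equation solve; the
        whole grid is evaluated vectorised.
        """
        y = np.concatenate([self.i_bottom, self.i_upper])
        grid = np.deg2rad(np.arange(0.0, 180.0, 3.0))
        u = self.angles[None, :] + grid[:, None]            # (Z, N)
        env = np.cos(u) ** 2
        cb = np.cos(u[:, None, :] - grid[None, :, None]) ** 2   # (Z, E, N)
        shape = np.concatenate(
            [env[:, None, :] * cb, env[:, None, :] * (1.0 - cb)], axis=2
        )                                                       # (Z, E, 2N)
        n = shape.shape[2]
        s11 = np.einsum("zen,zen->ze", shape, shape)
        s1 = shape.sum(axis=2)
        sy = shape @ y
        ysum = y.sum()
        det = s11 * n - s1**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        i0 = (sy * n - s1 * ysum) / det
        b = (s11 * ysum - s1 * sy) / det
        ssr = (
            np.einsum("ze,ze->ze", i0, i0) * s11
            + 2 * i0 * b * s1
            + b**2 * n
            - 2 * i0 * sy
            - 2 * b * ysum
            + y @ y
        )
        ssr = np.where(np.isfinite(ssr) & (i0 > 0), ssr, np.inf)
        iz, ie = np.unravel_index(np.argmin(ssr), ssr.shape)
        return np.array([i0[iz, ie], grid[iz], grid[ie], b[iz, ie]])

    def fit(self) -> "CalibrationResults":
        x0 = self._grid_start()
        x0[0] = max(x0[0], 1e-6)
        x0[3] = max(x0[3], 0.0)
        sol = optimize.least_squares(self._residual, x0, method="lm", xtol=1e-15, ftol=1e-15)
        if not sol.success:
            raise RuntimeError(
                "calibration fit did not converge; residual norm "
                f"{np.linalg.norm(sol.fun):.3g}"
            )
        params = sol.x.copy()
        # canonicalise: fold phases into [0, pi), keep I0 positive
        params[1] %= np.pi
        params[2] %= np.pi
        n, p = len(sol.fun), 4
        ssr = float(sol.fun @ sol.fun)
        jac = sol.jac
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * (ssr / max(n - p, 1))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return CalibrationResults(self, params, cov, ssr)


@dataclass
class CalibrationResults:
    """Fitted calibration with uncertainties from the fit covariance."""

    model: CalibrationModel
    params: np.ndarray
    cov: np.ndarray
    ssr: float

    @property
    def calibration(self) -> PolarCalibration:
        I0, zeta, eta, b = self.params
        return PolarCalibration(I0=I0, zeta=zeta, eta=eta, b=max(b, 0.0))

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (I0, zeta, eta, b); phases in radians."""
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> str:
        names = ["I0 (counts)", "zeta (deg)", "eta (deg)", "b (counts)"]
        vals = self.params.copy()
        errs = self.bse.copy()
        vals[1:3] = np.rad2deg(vals[1:3])
        errs[1:3] = np.rad2deg(errs[1:3])
        lines = ["Polarization calibration fit", "-" * 38]
        for name, v, e in zip(names, vals, errs):
            lines.append(f"{name:<14s} {v:10.4f} +/- {e:.4f}")
        lines.append(f"{'SSR':<14s} {self.ssr:10.4g}")
        return "\n".join(lines)


def fit_calibration(angles_deg, i_bottom, i_upper) -> CalibrationResults:
    """Functional wrapper around :class:`CalibrationModel`."""
    return CalibrationModel(angles_deg, i_bottom, i_upper).fit()


# ---------------------------------------------------------------------
# angle inversion
# ---------------------------------------------------------------------

_GRID_DEG = 0.5
_GRID = np.deg2rad(np.arange(0.0, 180.0, _GRID_DEG))


def _pair_residual(theta, bottom_obs, upper_obs, cal: PolarCalibration):
    bottom, upper = _channels(np.asarray(theta, dtype=float), cal.I0, cal.zeta, cal.eta, cal.b)
    return (bottom - bottom_obs) ** 2 + (upper - upper_obs) ** 2


def estimate_angle(
    pair,
    cal: PolarCalibration,
    prev_angle: float | None = None,
    undef_rel_tol: float = 1e-3,
) -> tuple[float, float, bool]:
    """Invert one intensity pair to a rod angle in [0, pi).

    Grid search at 0.5 deg followed by bounded local refinement of the
    squared two-channel residual.  When both channels sit at background
    (the rod crosses the optical null cos^2(theta+zeta)=0) the objective
    is flat and the angle is flagged undefined.

    Returns ``(theta, residual, defined)``.  ``prev_angle`` breaks ties
    between near-degenerate minima by temporal continuity.
    """
    if isinstance(pair, IntensityPair):
        bottom, upper = pair.i_bottom, pair.i_upper
    else:
        bottom, upper = pair
    if (bottom - cal.b) + (upper - cal.b) < undef_rel_tol * cal.I0:
        return np.nan, np.nan, False
    res = _pair_residual(_GRID, bottom, upper, cal)
    thresh = res.min() + 1e-9 * cal.I0**2 + 1e-3 * res.min()
    candidates = _GRID[res <= thresh]
    if prev_angle is not None and len(candidates) > 1:
        # distance on the half-circle
        d = np.abs((candidates - prev_angle + np.pi / 2) % np.pi - np.pi / 2)
        start = candidates[np.argmin(d)]
    else:
        start = _GRID[np.argmin(res)]
    step = np.deg2rad(_GRID_DEG)
    sol = optimize.minimize_scalar(
        _pair_residual,
        bounds=(start - step, start + step),
        args=(bottom, upper, cal),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(sol.x % np.pi), float(sol.fun), True


def estimate_angle_series(
    i_bottom, i_upper, cal: PolarCalibration, undef_rel_tol: float = 1e-3
):
    """Invert an intensity time series with temporal-continuity tie-breaks.

    Returns ``(angles, defined)`` with angles in radians on [0, pi),
    NaN where undefined.
    """
    i_bottom = np.asarray(i_bottom, dtype=float)
    i_upper = np.asarray(i_upper, dtype=float)
    n = len(i_bottom)
    angles = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    prev = None
    for i in range(n):
        theta, _, ok = estimate_angle(
            (i_bottom[i], i_upper[i]), cal, prev_angle=prev, undef_rel_tol=undef_rel_tol
        )
        angles[i] = theta
        defined[i] = ok
        if ok:
            prev = theta
    return angles, defined


# ---------------------------------------------------------------------
# DOP-vs-sum ellipse
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseFit:
    """Direct least-squares ellipse through the (sum, DOP) cloud.

    center, axes : ellipse center and semi-axes in (sum, DOP) units
    tilt : orientation of the major axis (rad)
    rms_residual : RMS algebraic distance of the points from the ellipse
    coverage : fraction of the parametric circle [0, 2pi) visited by the
        data (36-bin occupancy); ~1 means the polarization rotates through
        full cycles, low values mean an arc (oscillatory rotation).
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    tilt: float
    rms_residual: float
    coverage: float


def fit_dop_ellipse(total, dop_series) -> EllipseFit:
    """Fit an ellipse to DOP vs summed intensity (continuous rotation test).

    Uses the direct conic fit of scikit-image's EllipseModel on
    standardised coordinates (the two axes have very different scales).
    Raises ``ValueError`` on degenerate input.
    """
    from skimage.measure import EllipseModel

    x = np.asarray(total, dtype=float)
    y = np.asarray(dop_series, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < 20:
        raise ValueError("need >= 20 finite points for the ellipse fit")
    sx = np.std(x)
    sy = np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (collinear) points")
    pts = np.stack([(x - x.mean()) / sx, (y - y.mean()) / sy], axis=1)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed (degenerate points?)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed (degenerate points?)")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError("ellipse fit failed (degenerate points?)")
    resid = model.residuals(pts)
    # parametric phase of each point on the fitted ellipse
    ct, st = np.cos(theta), np.sin(theta)
    dx, dy = pts[:, 0] - xc, pts[:, 1] - yc
    phase = np.arctan2((-dx * st + dy * ct) / b, (dx * ct + dy * st) / a)
    bins = np.unique(((phase + np.pi) / (2 * np.pi) * 36).astype(int) % 36)
    coverage = len(bins) / 36.0
    return EllipseFit(
        center=(float(xc * sx + x.mean()), float(yc * sy + y.mean())),
        axes=(float(a), float(b)),
        tilt=float(theta),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        coverage=coverage,
    )
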