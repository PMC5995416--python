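"""DMT contact-mechanics fitting and modulus aggregation.

Each PeakForce force curve records force versus indentation depth.  The
adhesive Derjaguin-Muller-Toporov (DMT) model relates them through

    F(delta) = F_adh + (4/3) * E_r * sqrt(R) * delta^(3/2)

with tip radius ``R``, adhesion force ``F_adh`` and reduced modulus ``E_r``.
For a rigid tip the sample modulus is ``E = E_r * (1 - nu^2)``.  Moduli are
kept in MPa, lengths in nm, forces in nN; in those units the DMT prefactor
carries a factor 1e-3 (MPa * nm^2 = 1e-3 nN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ForceCurve",
    "DMTFit",
    "CalibrationResult",
    "MapSummary",
    "dmt_force",
    "fit_dmt",
    "calibrate",
    "apply_calibration",
    "summarize_map",
]

# (4/3) * E[MPa] * sqrt(R[nm]) * delta[nm]^1.5 gives force in units of 1e-3 nN
_DMT_UNIT = 1e-3


@dataclass
class ForceCurve:
    """A single force-indentation record.

    depth_nm is non-decreasing indentation depth (0 = contact point);
    force_nN the measured force at each depth.
    """

    depth_nm: np.ndarray
    force_nN: np.ndarray
    curve_id: str = ""
    pixel_coord: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.depth_nm = np.asarray(self.depth_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.depth_nm.shape != self.force_nN.shape or self.depth_nm.ndim != 1:
            raise ValueError("depth and force must be 1-D arrays of equal length")
        if self.depth_nm.size < 8:
            raise ValueError("force curve needs at least 8 points")
        if np.any(np.diff(self.depth_nm) < 0):
            raise ValueError("depths must be non-decreasing")


@dataclass
class DMTFit:
    """Result of fitting the DMT model to one curve."""

    E_r_MPa: float
    E_MPa: float
    F_adh_nN: float
    R_nm: float
    nu: float
    r_squared: float
    fit_window: tuple[float, float]
    n_points: int
    curve_id: str = ""


@dataclass
class CalibrationResult:
    """Multiplicative modulus calibration against a reference sample."""

    scale_factor: float
    E_ref_known_MPa: float
    E_ref_measured_MPa: float
    n_curves: int


@dataclass
class MapSummary:
    """Per-image modulus summary over the successful fits of a force-volume map."""

    mean_MPa: float
    sd_MPa: float
    n_success: int
    n_failed: int


def dmt_force(
    depth_nm: np.ndarray, E_r_MPa: float, R_nm: float, F_adh_nN: float = 0.0
) -> np.ndarray:
    """Evaluate the DMT force law (nN) at the given depths (nm)."""
    depth_nm = np.asarray(depth_nm, dtype=float)
    return F_adh_nN + (4.0 / 3.0) * E_r_MPa * np.sqrt(R_nm) * depth_nm**1.5 * _DMT_UNIT


def fit_dmt(
    curve: ForceCurve,
    R_nm: float = 8.0,
    nu: float = 0.0,
    fit_window: tuple[float, float] = (0.1, 0.9),
) -> DMTFit:
    """Fit the DMT model to one force curve.

    The adhesion force is taken as the minimum recorded force (the pull-off /
    contact point), and ``F - F_adh`` is regressed on ``delta^(3/2)`` through
    the origin over the window of forces between ``fit_window[0]`` and
    ``fit_window[1]`` of the peak force above adhesion.

    Raises
    ------
    ValueError
        If fewer than 5 points fall in the window ("insufficient contact
        data") or the fitted slope is non-positive ("non-physical fit").
    """
    if R_nm <= 0:
        raise ValueError("tip radius must be positive")
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("fit window fractions must satisfy 0 <= lo < hi <= 1")

    f_adh = float(np.min(curve.force_nN))
    rel = curve.force_nN - f_adh
    peak = float(np.max(rel))
    if peak <= 0:
        raise ValueError("insufficient contact data: no force above adhesion")
    in_win = (rel >= lo * peak) & (rel <= hi * peak) & (curve.depth_nm > 0)
    if int(np.count_nonzero(in_win)) < 5:
        raise ValueError("insufficient contact data: fewer than 5 points in fit window")

    x = curve.depth_nm[in_win] ** 1.5
    y = rel[in_win]
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise ValueError("non-physical fit: non-positive modulus")
    e_r = slope / ((4.0 / 3.0) * np.sqrt(R_nm) * _DMT_UNIT)

    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))

    return DMTFit(
        E_r_MPa=e_r,
        E_MPa=e_r * (1.0 - nu**2),
        F_adh_nN=f_adh,
        R_nm=R_nm,
        nu=nu,
        r_squared=r2,
        fit_window=(lo, hi),
        n_points=int(np.count_nonzero(in_win)),
        curve_id=curve.curve_id,
    )


def calibrate(
    fits_on_reference: Sequence[DMTFit], E_ref_known_MPa: float
) -> CalibrationResult:
    """Derive a multiplicative modulus scale factor from reference-sample fits.

    scale_factor = E_ref_known / median(fitted E on the reference); applying it
    to subsequent sample fits removes any systematic gain error.
    """
    if len(fits_on_reference) < 10:
        raise ValueError("calibration requires at least 10 successful reference fits")
    measured = float(np.median([f.E_MPa for f in fits_on_reference]))
    if measured <= 0:
        raise ValueError("median reference modulus is non-positive")
    return CalibrationResult(
        scale_factor=E_ref_known_MPa / measured,
        E_ref_known_MPa=E_ref_known_MPa,
        E_ref_measured_MPa=measured,
        n_curves=len(fits_on_reference),
    )


def apply_calibration(fit: DMTFit, calibration: CalibrationResult) -> DMTFit:
    """Return a copy of a fit with moduli rescaled by the calibration factor."""
    s = calibration.scale_factor
    return DMTFit(
        E_r_MPa=fit.E_r_MPa * s,
        E_MPa=fit.E_MPa * s,
        F_adh_nN=fit.F_adh_nN,
        R_nm=fit.R_nm,
        nu=fit.nu,
        r_squared=fit.r_squared,
        fit_window=fit.fit_window,
        n_points=fit.n_points,
        curve_id=fit.curve_id,
    )


def summarize_map(fits: Sequence[DMTFit | None]) -> MapSummary:
    """Mean and SD of sample modulus over the successful fits of one map.

    ``None`` entries stand for failed fits and are counted but excluded.
    """
    values = np.array([f.E_MPa for f in fits if f is not None], dtype=float)
    n_failed = sum(1 for f in fits if f is None)
    if values.size == 0:
        raise ValueError("empty map: all fits failed")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return MapSummary(
        mean_MPa=float(values.mean()),
        sd_MPa=sd,
        n_success=int(values.size),
        n_failed=int(n_failed),
    )
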