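"""Compactibility of powder compacts: porosity, tensile strength, and
Ryshkewitch-Duckworth profiles.

A compact's tensile strength falls roughly exponentially with its porosity.
The Ryshkewitch-Duckworth (R-D) relation

    sigma(eps) = sigma0 * exp(-k * eps)

captures this with two material constants: ``sigma0``, the extrapolated
tensile strength of a fully dense (zero-porosity) compact in MPa, and ``k``,
a dimensionless bonding-capacity constant. This module converts raw tablet
measurements into (porosity, strength) points and fits/evaluates R-D
profiles.

Unit conventions are fixed: weight in g, diameter and thickness in mm,
failure force in N, true density in g/cm^3; tensile strengths come out in
MPa (N/mm^2). Conversions between mm^3 and cm^3 are internal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import (
    ExtrapolationWarning,
    FitFailureError,
    InconsistentMeasurementWarning,
    InsufficientDataError,
    InvalidMeasurementError,
)

__all__ = [
    "TabletMeasurement",
    "CompactPoint",
    "CompactibilityProfile",
    "tablet_porosity",
    "diametral_tensile_strength",
    "measurement_to_point",
    "fit_rd",
    "predict_rd",
]


@dataclass(frozen=True)
class TabletMeasurement:
    """One tablet's raw dimensions, weight, true density and failure force.

    Parameters
    ----------
    weight : float
        Tablet weight W in g.
    diameter : float
        Tablet diameter D in mm.
    thickness : float
        Tablet thickness t in mm.
    failure_force : float
        Diametral crushing force F in N.
    true_density : float
        Skeletal (pycnometric) density rho of the powder in g/cm^3.
    """

    weight: float
    diameter: float
    thickness: float
    failure_force: float
    true_density: float

    def __post_init__(self):
        for name in ("weight", "diameter", "thickness", "failure_force",
                     "true_density"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise InvalidMeasurementError(
                    f"{name} must be finite and strictly positive, got {value!r}"
                )


@dataclass(frozen=True)
class CompactPoint:
    """A (porosity, tensile strength) observation for one compact."""

    porosity: float
    tensile_strength: float

    def __post_init__(self):
        if not 0.0 <= self.porosity < 1.0:
            raise InvalidMeasurementError(
                f"porosity must lie in [0, 1), got {self.porosity!r}"
            )
        if self.tensile_strength < 0:
            raise InvalidMeasurementError(
                f"tensile_strength must be >= 0, got {self.tensile_strength!r}"
            )


@dataclass(frozen=True)
class CompactibilityProfile:
    """Fitted (or directly supplied) R-D parameters for one material.

    ``fitted_porosity_range`` is the closed porosity interval actually
    covered by the fit data; ``None`` when the parameters were supplied
    directly rather than fitted. ``n_points`` / ``rss`` / ``n_excluded``
    document the fit: number of points used, residual sum of squares in
    linear strength space, and number of zero-strength points excluded.
    """

    material_id: str
    sigma0: float
    k: float
    fitted_porosity_range: tuple[float, float] | None = None
    n_points: int | None = None
    rss: float | None = None
    n_excluded: int = 0
    residuals: tuple[float, ...] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise InvalidMeasurementError(f"sigma0 must be > 0, got {self.sigma0!r}")
        if self.k <= 0:
            raise InvalidMeasurementError(f"k must be > 0, got {self.k!r}")

    def predict(self, porosity: float) -> float:
        """Tensile strength in MPa at the given porosity (see predict_rd)."""
        return predict_rd(self, porosity)


def tablet_porosity(m: TabletMeasurement) -> float:
    """Porosity of a tablet from its weight, dimensions and true density.

    eps = 1 - 4 W / (pi D^2 t rho), with W in g, D and t in mm, rho in
    g/cm^3; the envelope volume pi D^2 t / 4 (mm^3) is converted to cm^3 so
    mass and volume units cancel.

    A non-positive result (solid fraction > 1) indicates mutually
    inconsistent inputs; it is returned as-is but flagged with
    :class:`InconsistentMeasurementWarning`.
    """
    envelope_cm3 = math.pi * m.diameter**2 * m.thickness / 4.0 / 1000.0
    solid_fraction = m.weight / (m.true_density * envelope_cm3)
    eps = 1.0 - solid_fraction
    if eps <= 0.0:
        warnings.warn(
            f"computed porosity {eps:.4g} <= 0 (solid fraction > 1); "
            "weight, dimensions and true density are inconsistent",
            InconsistentMeasurementWarning,
            stacklevel=2,
        )
    return eps


def diametral_tensile_strength(m: TabletMeasurement) -> float:
    """Diametral-compression tensile strength sigma = 2F / (pi D t) in MPa.

    With F in N and D, t in mm the result is directly N/mm^2 = MPa.
    """
    return 2.0 * m.failure_force / (math.pi * m.diameter * m.thickness)


def measurement_to_point(m: TabletMeasurement) -> CompactPoint:
    """Convert a raw tablet measurement to a (porosity, strength) point."""
    return CompactPoint(tablet_porosity(m), diametral_tensile_strength(m))


def _rd_model(eps, sigma0, k):
    return sigma0 * np.exp(-k * eps)


def fit_rd(points: Sequence[CompactPoint], material_id: str = "") -> CompactibilityProfile:
    """Fit the R-D equation to (porosity, strength) points.

    The fit minimizes the sum of squared residuals in *linear* strength
    space (log-space ordinary least squares is used only to initialize),
    which avoids the log-transform's overweighting of low-strength points.
    Points with zero tensile strength — compacts that failed to form — are
    excluded from the fit and counted in ``n_excluded``.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 points with positive strength.
    FitFailureError
        The nonlinear fit did not converge; the error carries the
        log-linear fallback profile in ``.fallback``.
    """
    usable = [p for p in points if p.tensile_strength > 0]
    n_excluded = len(points) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 points with positive strength to fit, got {len(usable)}"
        )
    eps = np.array([p.porosity for p in usable], dtype=float)
    sig = np.array([p.tensile_strength for p in usable], dtype=float)
    if np.ptp(eps) == 0.0:
        raise InsufficientDataError(
            "all points share one porosity; k is not identifiable"
        )

    # log-space OLS initializer: ln sigma = ln sigma0 - k * eps
    slope, intercept = np.polyfit(eps, np.log(sig), 1)
    sigma0_init = float(np.exp(intercept))
    k_init = float(max(-slope, 1e-12))

    def _fallback():
        return CompactibilityProfile(
            material_id=material_id,
            sigma0=sigma0_init,
            k=k_init,
            fitted_porosity_range=(float(eps.min()), float(eps.max())),
            n_points=len(usable),
            rss=float(np.sum((sig - _rd_model(eps, sigma0_init, k_init)) ** 2)),
            n_excluded=n_excluded,
        )

    try:
        popt, _ = curve_fit(
            _rd_model, eps, sig, p0=(sigma0_init, k_init),
            bounds=([1e-300, 1e-300], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"R-D fit failed to converge for {material_id!r}: {exc}",
            fallback=_fallback(),
        ) from exc

    sigma0, k = float(popt[0]), float(popt[1])
    resid = sig - _rd_model(eps, sigma0, k)
    return CompactibilityProfile(
        material_id=material_id,
        sigma0=sigma0,
        k=k,
        fitted_porosity_range=(float(eps.min()), float(eps.max())),
        n_points=len(usable),
        rss=float(np.sum(resid**2)),
        n_excluded=n_excluded,
        residuals=tuple(float(r) for r in resid),
    )


def predict_rd(profile: CompactibilityProfile, porosity: float) -> float:
    """Evaluate sigma0 * exp(-k * eps) at the given porosity.

    Emits :class:`ExtrapolationWarning` when the porosity lies outside the
    profile's fitted range (when that range is known); the R-D form itself
    remains well defined on all of [0, 1).
    """
    if not 0.0 <= porosity < 1.0:
        raise InvalidMeasurementError(
            f"porosity must lie in [0, 1), got {porosity!r}"
        )
    rng = profile.fitted_porosity_range
    if rng is not None and not (rng[0] <= porosity <= rng[1]):
        warnings.warn(
            f"porosity {porosity:.4g} outside fitted range "
            f"[{rng[0]:.4g}, {rng[1]:.4g}] for {profile.material_id!r}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return profile.sigma0 * math.exp(-profile.k * porosity)
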