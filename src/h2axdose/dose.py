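"""Inverse regression: from an observed yield to a dose estimate with SE.

Given a linear calibration curve E(y) = A + B x, the dose corresponding to
an observed yield y* is x* = (y* - A)/B. Its uncertainty is propagated by
the delta method in the MULTIBIODOSE simplification, which keeps the three
variance terms and drops the parameter covariances:

    SE^2(x*) = SE^2(A)/B^2 + (y* - A)^2 SE^2(B)/B^4 + phi y* / (n* B^2)

The last summand is the quasi-Poisson sampling variance of the customer's
yield (phi times the Poisson variance of a mean of n* counts). Negative
dose estimates are reported as-is: they are consistent with an unexposed
sample and clipping them would bias averages of estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .curves import CONSENSUS_PHI, CalibrationCurve
from .errors import (
    InputError,
    NonInvertibleCurveError,
    UnsupportedInversionError,
    WarningCode,
)

__all__ = [
    "CustomerSample",
    "DoseEstimate",
    "estimate_dose",
    "dose_standard_error",
    "variance_decomposition",
    "resolve_phi",
]


@dataclass(frozen=True)
class CustomerSample:
    """Yield observed on a potentially exposed individual.

    ``yield_y_star`` is the mean focus count per cell over ``n_star`` scored
    cells; for triage n* is typically 50 (manual) to 200 cells.
    """

    yield_y_star: float
    n_star: int
    total_count: Optional[int] = None
    time_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.yield_y_star) or self.yield_y_star < 0:
            raise InputError(f"yield must be a finite non-negative real, got {self.yield_y_star}")
        if int(self.n_star) != self.n_star or self.n_star < 1:
            raise InputError(f"n_star must be a positive integer, got {self.n_star}")

    @classmethod
    def from_counts(
        cls, total_count: int, n_star: int, time_label: Optional[str] = None
    ) -> "CustomerSample":
        return cls(
            yield_y_star=total_count / n_star,
            n_star=n_star,
            total_count=total_count,
            time_label=time_label,
        )


@dataclass
class DoseEstimate:
    """Point estimate of dose with its delta-method uncertainty budget."""

    x_star: float
    se_x_star: float
    var_components: dict
    curve_provenance: str = "unvalidated_calibration"
    warnings: List[WarningCode] = field(default_factory=list)
    phi_used: Optional[float] = None

    @property
    def ci95(self) -> tuple:
        return (self.x_star - 1.96 * self.se_x_star, self.x_star + 1.96 * self.se_x_star)

    def interval(self, multiplier: float = 1.96) -> tuple:
        return (self.x_star - multiplier * self.se_x_star,
                self.x_star + multiplier * self.se_x_star)

    def __str__(self) -> str:
        lo, hi = self.ci95
        warn = f"  warnings: {', '.join(map(str, self.warnings))}" if self.warnings else ""
        return (
            f"dose = {self.x_star:.2f} Gy, SE = {self.se_x_star:.2f} Gy, "
            f"95% CI [{lo:.2f}, {hi:.2f}] ({self.curve_provenance}){warn}"
        )


def resolve_phi(
    phi: Optional[float], curve: CalibrationCurve
) -> tuple[float, List[WarningCode]]:
    """Resolution order: explicit argument > curve's fitted phi > consensus 60."""
    if phi is not None:
        if phi <= 0:
            raise InputError(f"phi must be positive, got {phi}")
        return float(phi), []
    if curve.phi is not None:
        return float(curve.phi), []
    return CONSENSUS_PHI, [WarningCode.DEFAULT_PHI]


def _check_invertible(curve: CalibrationCurve) -> None:
    if not curve.is_linear:
        raise UnsupportedInversionError(
            "dose estimation inverts linear curves only; quadratic curves are "
            "supported for fitting and variance decomposition"
        )
    if curve.slope == 0:
        raise NonInvertibleCurveError("curve slope is zero; yield carries no dose information")


def estimate_dose(curve: CalibrationCurve, sample: CustomerSample) -> float:
    """x* = (y* - A)/B. May be negative; never truncated."""
    _check_invertible(curve)
    return (sample.yield_y_star - curve.intercept) / curve.slope


def dose_standard_error(
    curve: CalibrationCurve,
    sample: CustomerSample,
    phi: Optional[float] = None,
    annotate_below_zero: bool = False,
) -> DoseEstimate:
    """Point estimate plus MBD delta-method SE and its additive components.

    Missing curve SEs enter as 0 with a MISSING_SE warning; a missing
    dispersion falls back to the consensus 60 with a DEFAULT_PHI warning.
    """
    _check_invertible(curve)
    phi_val, warnings = resolve_phi(phi, curve)
    se_a, se_b, _, missing = curve.resolved_ses()
    if missing:
        warnings = warnings + [WarningCode.MISSING_SE]

    a, b, y, n = curve.intercept, curve.slope, sample.yield_y_star, sample.n_star
    x_star = (y - a) / b
    comp = {
        "intercept": se_a**2 / b**2,
        "slope": (y - a) ** 2 * se_b**2 / b**4,
        "sampling": phi_val * y / (n * b**2),
    }
    se = float(np.sqrt(sum(comp.values())))
    if annotate_below_zero and x_star < 0:
        warnings = warnings + [WarningCode.BELOW_ZERO]
    provenance = (
        "reference_curve" if curve.source == "reference_derived" else "unvalidated_calibration"
    )
    return DoseEstimate(
        x_star=float(x_star),
        se_x_star=se,
        var_components=comp,
        curve_provenance=provenance,
        warnings=warnings,
        phi_used=phi_val,
    )


# ---------------------------------------------------------------------------
# quadratic inversion (decomposition support only)
# ---------------------------------------------------------------------------

def _invert_quadratic(a: float, b: float, c: float, y: float) -> float:
    """Root of C x^2 + B x + (A - y) = 0; the smaller positive root for a
    saturating curve (C < 0), else the standard increasing branch."""
    disc = b**2 - 4 * c * (a - y)
    if disc < 0:
        raise NonInvertibleCurveError(
            f"yield {y} is beyond the curve's maximum; no real dose solves the curve"
        )
    sq = float(np.sqrt(disc))
    roots = np.array([(-b - sq) / (2 * c), (-b + sq) / (2 * c)])
    pos = roots[roots >= 0]
    if pos.size == 0:
        return float(roots.max())
    return float(pos.min())


def _components_at(
    curve: CalibrationCurve, y: float, n_star: int, phi: float
) -> tuple[float, dict]:
    se_a, se_b, se_c, _ = curve.resolved_ses()
    a, b = curve.intercept, curve.slope
    if curve.is_linear:
        x = (y - a) / b
        dxda, dxdb, dxdy = -1.0 / b, -x / b, 1.0 / b
        comp = {
            "intercept": dxda**2 * se_a**2,
            "slope": dxdb**2 * se_b**2,
            "sampling": dxdy**2 * phi * y / n_star,
        }
        return x, comp
    c = curve.quad
    x = _invert_quadratic(a, b, c, y)
    slope_at_x = b + 2 * c * x  # dy/dx; implicit differentiation divides by it
    if slope_at_x == 0:
        raise NonInvertibleCurveError("curve is flat at the inverted dose")
    comp = {
        "intercept": (1.0 / slope_at_x) ** 2 * se_a**2,
        "slope": (x / slope_at_x) ** 2 * se_b**2,
        "quad": (x**2 / slope_at_x) ** 2 * (se_c or 0.0) ** 2,
        "sampling": (1.0 / slope_at_x) ** 2 * phi * y / n_star,
    }
    return x, comp


def variance_decomposition(
    curve: CalibrationCurve,
    yield_grid: Sequence[float],
    n_star: int,
    phi: Optional[float] = None,
) -> pd.DataFrame:
    """Per-yield additive variance components of the dose estimate.

    One row per grid yield with the delta-method contributions of the curve
    parameters and of the sampling variance; the components sum to the total
    variance. For quadratic curves the partial derivatives come from
    implicit differentiation of A + Bx + Cx^2 = y.
    """
    yields = list(yield_grid)
    if not yields:
        raise InputError("yield grid must be non-empty")
    if curve.is_linear:
        _check_invertible(curve)
    phi_val, _ = resolve_phi(phi, curve)
    rows = []
    for y in yields:
        if y < 0:
            raise InputError(f"yields must be non-negative, got {y}")
        x, comp = _components_at(curve, float(y), n_star, phi_val)
        total = sum(comp.values())
        row = {"yield": y, "x_star": x}
        row.update({f"var_{k}": v for k, v in comp.items()})
        row["var_total"] = total
        row["se"] = float(np.sqrt(total))
        rows.append(row)
    return pd.DataFrame(rows)
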