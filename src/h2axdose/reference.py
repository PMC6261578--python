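"""Curve validation via reference samples, and the two-point reference curve.

A calibration curve quantifies random variation around itself but not
systematic bias (different scorer, staining, shipment...). Reference
samples - a negative control at 0 Gy and a positive control irradiated at a
known dose (typically 1.5 Gy), scored under the customer's conditions - are
compared with quasi-Poisson prediction intervals around the curve:

    A + B x  +/-  q_crit * sqrt(phi (A + B x) / n')

The negative control gets the more lenient q = 3 (a small background
mismatch should not discard an established curve), the positive control the
stricter q = 2 (a slope bias has severe consequences). There is one decision
for the curve as a whole: it is discarded if either control falls outside
its interval, and then replaced by the straight line through the two
reference points, whose parameter SEs follow from the same quasi-Poisson
variance reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .curves import CalibrationCurve
from .data import pooled_yield
from .dose import resolve_phi
from .errors import DegenerateFitError, InputError, WarningCode

__all__ = [
    "ReferenceSet",
    "ValidationResult",
    "pool_reference_samples",
    "prediction_interval",
    "validate_curve",
    "build_reference_curve",
    "reference_sample_ratio",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Negative (0 Gy) and positive (xr Gy) control yields with cell counts."""

    y0: float
    n0: int
    yr: float
    nr: int
    xr: float = 1.5

    def __post_init__(self) -> None:
        if self.y0 < 0 or self.yr < 0:
            raise InputError("reference yields must be non-negative")
        if self.n0 < 1 or self.nr < 1:
            raise InputError("reference cell counts must be >= 1")
        if self.xr <= 0:
            raise InputError(f"positive-control dose must be > 0 Gy, got {self.xr}")

    @classmethod
    def from_samples(
        cls,
        negatives: Iterable[Tuple[float, int]],
        positives: Iterable[Tuple[float, int]],
        xr: float = 1.5,
    ) -> "ReferenceSet":
        """Pool replicate controls (yield, n_cells) at each reference dose.

        Negative controls may be pooled across time labels: at 0 Gy the
        time-after-exposure tag is meaningless.
        """
        y0, n0 = pool_reference_samples(negatives)
        yr, nr = pool_reference_samples(positives)
        return cls(y0=y0, n0=n0, yr=yr, nr=nr, xr=xr)


def pool_reference_samples(samples: Iterable[Tuple[float, int]]) -> Tuple[float, int]:
    """Pool (yield, n_cells) replicates at a common dose into one sample."""
    return pooled_yield(samples)


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of checking a curve against a reference set.

    Two intervals are checked but a single decision is made: ``accept`` iff
    both controls fall inside (endpoints count as inside).
    """

    pi_negative: Tuple[float, float]
    pi_positive: Tuple[float, float]
    inside_negative: bool
    inside_positive: bool
    decision: str  # "accept" | "discard"
    q_crit_used: Tuple[float, float]

    @property
    def accepted(self) -> bool:
        return self.decision == "accept"

    def __str__(self) -> str:
        def seg(name, pi, inside):
            lo, hi = pi
            return f"{name} PI [{lo:.3f}, {hi:.3f}] -> {'inside' if inside else 'OUTSIDE'}"

        return (
            f"{seg('negative', self.pi_negative, self.inside_negative)}; "
            f"{seg('positive', self.pi_positive, self.inside_positive)}; "
            f"decision: {self.decision}"
        )


def prediction_interval(
    curve: CalibrationCurve,
    dose: float,
    n_prime: int,
    phi: Optional[float] = None,
    q_crit: float = 2.0,
) -> Tuple[float, float]:
    """Approximate prediction interval for a yield of n' cells at a dose."""
    if n_prime < 1:
        raise InputError("n_prime must be >= 1")
    if q_crit < 0:
        raise InputError("q_crit must be non-negative")
    phi_val, _ = resolve_phi(phi, curve)
    mu = curve.mean_yield(dose)
    if mu <= 0:
        raise DegenerateFitError(
            f"fitted mean {mu:.4f} at dose {dose} Gy is not positive; "
            "no prediction interval exists"
        )
    half = q_crit * float(np.sqrt(phi_val * mu / n_prime))
    return (mu - half, mu + half)


def validate_curve(
    curve: CalibrationCurve,
    ref: ReferenceSet,
    phi: Optional[float] = None,
    q_neg: float = 3.0,
    q_pos: float = 2.0,
) -> ValidationResult:
    """Check both controls against their prediction intervals."""
    pi_neg = prediction_interval(curve, 0.0, ref.n0, phi, q_neg)
    pi_pos = prediction_interval(curve, ref.xr, ref.nr, phi, q_pos)
    inside_neg = pi_neg[0] <= ref.y0 <= pi_neg[1]
    inside_pos = pi_pos[0] <= ref.yr <= pi_pos[1]
    return ValidationResult(
        pi_negative=pi_neg,
        pi_positive=pi_pos,
        inside_negative=bool(inside_neg),
        inside_positive=bool(inside_pos),
        decision="accept" if inside_neg and inside_pos else "discard",
        q_crit_used=(q_neg, q_pos),
    )


def build_reference_curve(
    ref: ReferenceSet, phi: float = 60.0
) -> Tuple[CalibrationCurve, List[WarningCode]]:
    """Two-point curve through (0, y0) and (xr, yr) with quasi-Poisson SEs.

    A-tilde = y0 with SE sqrt(phi y0 / n0); B-tilde = (yr - y0)/xr with
    SE (1/xr) sqrt(phi (y0/n0 + yr/nr)). The dispersion is never estimated
    from the two reference points; it comes from the curve or consensus.
    """
    if phi <= 0:
        raise InputError(f"phi must be positive, got {phi}")
    slope = (ref.yr - ref.y0) / ref.xr
    warnings: List[WarningCode] = []
    if slope == 0:
        warnings.append(WarningCode.ZERO_SLOPE_REFERENCE)
    curve = CalibrationCurve(
        intercept=ref.y0,
        slope=slope,
        se_intercept=float(np.sqrt(phi * ref.y0 / ref.n0)),
        se_slope=float(np.sqrt(phi * (ref.y0 / ref.n0 + ref.yr / ref.nr)) / ref.xr),
        phi=phi,
        source="reference_derived",
    )
    return curve, warnings


def reference_sample_ratio(curve: CalibrationCurve, ref: ReferenceSet) -> float:
    """(A + B xr) / yr, a bias diagnostic only.

    Reference yields falling below the curve can indicate shipment-related
    focus loss in the calibration data; the ratio quantifies it but the
    workflow never applies it to dose estimates automatically.
    """
    if ref.yr <= 0:
        raise InputError("reference sample ratio undefined for yr = 0")
    return float(curve.mean_yield(ref.xr) / ref.yr)
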