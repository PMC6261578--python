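"""The calibration-curve object shared by fitting, validation and estimation.

A calibration curve is the portable summary of a dose-response experiment:
the identity-link regression parameters ``A`` (background yield, foci/cell)
and ``B`` (yield increase per Gy), their dispersion-corrected standard
errors, and the dispersion index ``phi`` of the focus counts around the
curve. Curves may come from a fit, be typed in by a user, or be derived from
a two-point reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InputError

__all__ = ["CalibrationCurve"]

CONSENSUS_PHI = 60.0
"""Consensus worst-case dispersion of manually scored focus counts."""

_SOURCES = ("fitted", "user_supplied", "reference_derived")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear (or quadratic) identity-link dose-response curve.

    E(y) = A + B x (+ C x^2) with y in foci/cell and x in Gy.

    ``se_*`` are the dispersion-corrected standard errors; ``None`` means
    "not supplied" (distinct from zero, which is an exact statement). The
    dispersion ``phi`` is the variance/mean ratio of the underlying counts;
    ``None`` means unknown, in which case downstream consumers substitute
    the consensus value 60 with a warning.
    """

    intercept: float
    slope: float
    quad: Optional[float] = None
    se_intercept: Optional[float] = None
    se_slope: Optional[float] = None
    se_quad: Optional[float] = None
    phi: Optional[float] = None
    time_label: Optional[str] = None
    fit_df: Optional[int] = None
    source: str = "user_supplied"
    poisson_se: Optional[tuple] = field(default=None, compare=False)
    """Uncorrected (Poisson) SEs of the parameters, kept as fit diagnostics."""

    def __post_init__(self) -> None:
        for name in ("se_intercept", "se_slope", "se_quad"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be non-negative, got {v}")
        if self.phi is not None and self.phi <= 0:
            raise InputError(f"phi must be positive, got {self.phi}")
        if self.source not in _SOURCES:
            raise InputError(f"source must be one of {_SOURCES}, got {self.source!r}")

    # ------------------------------------------------------------------
    @property
    def model_form(self) -> str:
        return "linear" if self.quad is None else "quadratic"

    @property
    def is_linear(self) -> bool:
        return self.quad is None

    def mean_yield(self, dose):
        """Expected yield (foci/cell) at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        mu = self.intercept + self.slope * dose
        if self.quad is not None:
            mu = mu + self.quad * dose**2
        return mu if mu.ndim else float(mu)

    def with_(self, **changes) -> "CalibrationCurve":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def resolved_ses(self) -> tuple[float, float, Optional[float], bool]:
        """(se_A, se_B, se_C, any_missing) with missing SEs taken as 0."""
        missing = self.se_intercept is None or self.se_slope is None
        se_a = self.se_intercept if self.se_intercept is not None else 0.0
        se_b = self.se_slope if self.se_slope is not None else 0.0
        se_c: Optional[float] = None
        if self.quad is not None:
            missing = missing or self.se_quad is None
            se_c = self.se_quad if self.se_quad is not None else 0.0
        return se_a, se_b, se_c, missing

    def __str__(self) -> str:
        def fmt(v, se):
            base = f"{v:.3f}"
            return base + (f" ({se:.3f})" if se is not None else "")

        parts = [
            f"A={fmt(self.intercept, self.se_intercept)}",
            f"B={fmt(self.slope, self.se_slope)}",
        ]
        if self.quad is not None:
            parts.append(f"C={fmt(self.quad, self.se_quad)}")
        if self.phi is not None:
            parts.append(f"phi={self.phi:.1f}")
        tag = f"[{self.time_label}] " if self.time_label else ""
        return f"CalibrationCurve({tag}{', '.join(parts)}; {self.source})"
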