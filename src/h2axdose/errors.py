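"""Exceptions and machine-readable warning codes."""

from __future__ import annotations

import enum


class InputError(ValueError):
    """Invalid or inconsistent user input (bad counts, missing columns, ...)."""


class ConvergenceError(RuntimeError):
    """The iterative curve fit did not converge within the iteration cap."""


class DegenerateFitError(RuntimeError):
    """The fitted curve has a non-positive mean at a design dose."""


class NonInvertibleCurveError(ValueError):
    """The curve cannot be inverted at an observed yield (zero slope)."""


class UnsupportedInversionError(ValueError):
    """Dose estimation was requested from a curve form that is not inverted
    in the main workflow (quadratic curves)."""


class WarningCode(str, enum.Enum):
    """Codes attached to estimates and resolved curves.

    Every silent default substitution in the workflow emits exactly one of
    these, so downstream reports can surface them to the user.
    """

    MISSING_SE = "MISSING_SE"          # curve SEs absent; taken as 0
    DEFAULT_PHI = "DEFAULT_PHI"        # dispersion absent; consensus 60 used
    NO_REFERENCE = "NO_REFERENCE"      # curve used without reference validation
    DATA_OVERRIDES_CURVE = "DATA_OVERRIDES_CURVE"  # both data and curve given
    ZERO_SLOPE_REFERENCE = "ZERO_SLOPE_REFERENCE"  # reference curve not invertible
    BELOW_ZERO = "BELOW_ZERO"          # dose estimate < 0 Gy (unexposed-consistent)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
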