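"""Decision logic tying calibration, validation and estimation together.

The resolution of "which curve do we trust" mirrors the applet workflow:

1. if calibration data are supplied, fit them (data win over a typed-in
   curve, because a fitted curve carries SEs and a dispersion);
2. if reference samples are supplied, validate the curve: accept -> use it
   (provenance ``validated_calibration``); discard -> replace it by the
   two-point reference curve (``reference_curve``);
3. if no reference samples exist, the curve is used uncontested with a
   NO_REFERENCE warning (``unvalidated_calibration``).

Missing SEs are taken as 0 and a missing dispersion as the consensus 60,
each with its own warning code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .calibration import fit_calibration
from .curves import CONSENSUS_PHI, CalibrationCurve
from .data import CalibrationDataset
from .dose import CustomerSample, DoseEstimate, dose_standard_error
from .errors import InputError, WarningCode
from .reference import ReferenceSet, ValidationResult, build_reference_curve, validate_curve

__all__ = ["WorkflowConfig", "ResolvedCurve", "resolve_curve", "run_dose_estimation"]

logger = logging.getLogger("h2axdose.workflow")


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunable constants of the estimation workflow."""

    phi_default: float = CONSENSUS_PHI
    q_neg: float = 3.0
    q_pos: float = 2.0
    ci_multiplier: float = 1.96

    def __post_init__(self) -> None:
        if min(self.phi_default, self.ci_multiplier) <= 0 or min(self.q_neg, self.q_pos) < 0:
            raise InputError("workflow config values must be positive")


@dataclass
class ResolvedCurve:
    """A curve chosen by the workflow, with provenance and warnings."""

    curve: CalibrationCurve
    provenance: str  # validated_calibration | reference_curve | unvalidated_calibration
    warnings: List[WarningCode] = field(default_factory=list)
    validation: Optional[ValidationResult] = None
    phi: float = CONSENSUS_PHI


def resolve_curve(
    curve: Optional[CalibrationCurve] = None,
    calibration_data: Optional[CalibrationDataset] = None,
    ref: Optional[ReferenceSet] = None,
    config: WorkflowConfig = WorkflowConfig(),
    time_label: Optional[str] = None,
) -> ResolvedCurve:
    """Choose the curve to use for dose estimation (see module docstring)."""
    warnings: List[WarningCode] = []
    if curve is None and calibration_data is None:
        raise InputError("supply a calibration curve or calibration data")
    if calibration_data is not None:
        if curve is not None:
            warnings.append(WarningCode.DATA_OVERRIDES_CURVE)
            logger.info("both curve and data supplied; refitting from data")
        curve = fit_calibration(calibration_data, "linear", time_label=time_label)

    if curve.phi is None:
        phi = config.phi_default
        warnings.append(WarningCode.DEFAULT_PHI)
        logger.info("no dispersion on curve; consensus default %.0f used", phi)
    else:
        phi = curve.phi
    if curve.resolved_ses()[3]:
        warnings.append(WarningCode.MISSING_SE)
        logger.info("curve has missing SEs; they enter the delta method as 0")

    if ref is None:
        warnings.append(WarningCode.NO_REFERENCE)
        logger.info("no reference samples; curve used uncontested")
        return ResolvedCurve(curve, "unvalidated_calibration", warnings, None, phi)

    result = validate_curve(curve, ref, phi=phi, q_neg=config.q_neg, q_pos=config.q_pos)
    logger.info("validation: %s", result)
    if result.accepted:
        return ResolvedCurve(curve, "validated_calibration", warnings, result, phi)
    ref_curve, ref_warnings = build_reference_curve(ref, phi=phi)
    logger.info("curve discarded; reference curve %s", ref_curve)
    return ResolvedCurve(ref_curve, "reference_curve", warnings + ref_warnings, result, phi)


def _estimate_with(
    resolved: ResolvedCurve, sample: CustomerSample, config: WorkflowConfig
) -> DoseEstimate:
    est = dose_standard_error(
        resolved.curve, sample, phi=resolved.phi, annotate_below_zero=True
    )
    est.curve_provenance = resolved.provenance
    # curve-level warnings propagate; drop duplicates while keeping order
    seen = []
    for w in resolved.warnings + est.warnings:
        if w not in seen:
            seen.append(w)
    est.warnings = seen
    return est


def run_dose_estimation(
    samples: Sequence[CustomerSample],
    curve: Optional[CalibrationCurve] = None,
    curves: Optional[Dict[str, CalibrationCurve]] = None,
    calibration_data: Optional[CalibrationDataset] = None,
    ref: Optional[ReferenceSet] = None,
    refs: Optional[Dict[str, ReferenceSet]] = None,
    config: WorkflowConfig = WorkflowConfig(),
) -> List[DoseEstimate]:
    """Resolve the curve(s) once, then estimate a dose per customer sample.

    Either a single ``curve`` (optionally validated against ``ref``) or a
    dict of per-time-label ``curves`` (validated against per-label ``refs``)
    may be given; in the latter case each sample's ``time_label`` selects
    its curve, and a label with no matching curve is an error.
    """
    if not samples:
        raise InputError("no customer samples supplied")
    if curves is not None:
        resolved = {
            lab: resolve_curve(
                c,
                calibration_data,
                (refs or {}).get(lab, ref),
                config,
                time_label=lab if calibration_data is not None else None,
            )
            for lab, c in curves.items()
        }
        out = []
        for s in samples:
            if s.time_label is None or s.time_label not in resolved:
                raise InputError(
                    f"sample time label {s.time_label!r} has no matching curve "
                    f"(available: {sorted(resolved)})"
                )
            out.append(_estimate_with(resolved[s.time_label], s, config))
        return out
    one = resolve_curve(curve, calibration_data, ref, config)
    return [_estimate_with(one, s, config) for s in samples]
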