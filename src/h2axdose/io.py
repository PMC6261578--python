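"""Readers and writers: calibration tables, curve documents, reports.

Calibration data travel as delimiter-separated text with header columns
``dose_gy, time, n_cells, focus_count`` (optional ``donor``, ``scorer``);
yields are always recomputed from counts and cells, never trusted from a
yield column. Curves and estimation reports are flat JSON documents with a
versioned schema field; numbers are serialized at full precision and only
rounded for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from .curves import CalibrationCurve
from .data import CalibrationDataset
from .dose import CustomerSample, DoseEstimate
from .errors import InputError, WarningCode
from .workflow import WorkflowConfig

__all__ = [
    "read_calibration_table",
    "write_calibration_table",
    "read_curve",
    "write_curve",
    "curve_to_dict",
    "curve_from_dict",
    "EstimationReport",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1

#: Column mapping for whitespace-separated legacy ``.dat`` exports whose
#: headers differ from ours (dose / time / ncells / count).
DAT_DIALECT = {"dose": "dose_gy", "ncells": "n_cells", "count": "focus_count"}


# ---------------------------------------------------------------------------
# calibration tables
# ---------------------------------------------------------------------------

def read_calibration_table(
    path: Union[str, Path],
    sep: Optional[str] = None,
    columns: Optional[Dict[str, str]] = None,
) -> CalibrationDataset:
    """Read a calibration table (CSV/TSV or whitespace-separated .dat).

    ``columns`` maps file headers to the canonical names, e.g.
    ``{"dose": "dose_gy"}``; pass :data:`DAT_DIALECT` for the common legacy
    layout. The delimiter is sniffed from the extension when not given
    (.dat -> whitespace, otherwise comma/tab).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if sep is None:
        sep = r"\s+" if path.suffix == ".dat" else None  # None lets pandas sniff , / \t
    df = pd.read_csv(path, sep=sep, engine="python")
    if columns:
        df = df.rename(columns=columns)
    return CalibrationDataset.from_dataframe(df)


def write_calibration_table(data: CalibrationDataset, path: Union[str, Path]) -> None:
    df = data.to_dataframe().drop(columns=["donor", "scorer"], errors="ignore")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curve documents
# ---------------------------------------------------------------------------

def curve_to_dict(curve: CalibrationCurve) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model_form": curve.model_form,
        "time_label": curve.time_label,
        "A": curve.intercept,
        "B": curve.slope,
        "C": curve.quad,
        "se_A": curve.se_intercept,
        "se_B": curve.se_slope,
        "se_C": curve.se_quad,
        "phi": curve.phi,
        "df": curve.fit_df,
        "source": curve.source,
    }


def curve_from_dict(doc: dict) -> tuple[CalibrationCurve, List[WarningCode]]:
    """Rebuild a curve; absent SEs / dispersion yield warning codes."""
    try:
        curve = CalibrationCurve(
            intercept=float(doc["A"]),
            slope=float(doc["B"]),
            quad=None if doc.get("C") is None else float(doc["C"]),
            se_intercept=None if doc.get("se_A") is None else float(doc["se_A"]),
            se_slope=None if doc.get("se_B") is None else float(doc["se_B"]),
            se_quad=None if doc.get("se_C") is None else float(doc["se_C"]),
            phi=None if doc.get("phi") is None else float(doc["phi"]),
            time_label=doc.get("time_label"),
            fit_df=doc.get("df"),
            source=doc.get("source", "user_supplied"),
        )
    except KeyError as exc:
        raise InputError(f"curve document missing required field {exc}") from exc
    warnings = []
    if curve.resolved_ses()[3]:
        warnings.append(WarningCode.MISSING_SE)
    if curve.phi is None:
        warnings.append(WarningCode.DEFAULT_PHI)
    return curve, warnings


def write_curve(curve: CalibrationCurve, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(curve_to_dict(curve), indent=2) + "\n")


def read_curve(path: Union[str, Path]) -> tuple[CalibrationCurve, List[WarningCode]]:
    return curve_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# estimation reports
# ---------------------------------------------------------------------------

@dataclass
class EstimationReport:
    """Serializable record of one estimation run."""

    samples: List[CustomerSample]
    estimates: List[DoseEstimate]
    config: WorkflowConfig = field(default_factory=WorkflowConfig)
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.estimates):
            raise InputError("one estimate per sample required")
        if self.timestamp is None:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def to_dict(self) -> dict:
        m = self.config.ci_multiplier
        return {
            "schema_version": SCHEMA_VERSION,
            "timestamp": self.timestamp,
            "config": {
                "phi_default": self.config.phi_default,
                "q_neg": self.config.q_neg,
                "q_pos": self.config.q_pos,
                "ci_multiplier": m,
            },
            "records": [
                {
                    "yield": s.yield_y_star,
                    "n_star": s.n_star,
                    "time_label": s.time_label,
                    "x_star": e.x_star,
                    "se_x_star": e.se_x_star,
                    "ci": list(e.interval(m)),
                    "var_components": e.var_components,
                    "phi_used": e.phi_used,
                    "curve_provenance": e.curve_provenance,
                    "warnings": [str(w) for w in e.warnings],
                }
                for s, e in zip(self.samples, self.estimates)
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EstimationReport":
        samples, estimates = [], []
        for rec in doc["records"]:
            samples.append(
                CustomerSample(
                    yield_y_star=rec["yield"],
                    n_star=rec["n_star"],
                    time_label=rec.get("time_label"),
                )
            )
            estimates.append(
                DoseEstimate(
                    x_star=rec["x_star"],
                    se_x_star=rec["se_x_star"],
                    var_components=rec["var_components"],
                    curve_provenance=rec["curve_provenance"],
                    warnings=[WarningCode(w) for w in rec["warnings"]],
                    phi_used=rec.get("phi_used"),
                )
            )
        cfg = doc.get("config", {})
        return cls(
            samples=samples,
            estimates=estimates,
            config=WorkflowConfig(**cfg) if cfg else WorkflowConfig(),
            timestamp=doc.get("timestamp"),
        )

    def to_text(self) -> str:
        """Human-readable rendering (2-decimal display; storage is full precision)."""
        m = self.config.ci_multiplier
        lines = [f"Dose estimation report ({self.timestamp})", "-" * 64]
        for s, e in zip(self.samples, self.estimates):
            lo, hi = e.interval(m)
            lab = f" [{s.time_label}]" if s.time_label else ""
            lines.append(
                f"y* = {s.yield_y_star:.2f} foci/cell over {s.n_star} cells{lab}: "
                f"x* = {e.x_star:.2f} Gy, SE = {e.se_x_star:.2f} Gy, "
                f"{m:.2f}-SE interval [{lo:.2f}, {hi:.2f}]"
            )
            lines.append(f"    curve: {e.curve_provenance}"
                         + (f"; warnings: {', '.join(map(str, e.warnings))}"
                            if e.warnings else ""))
        return "\n".join(lines)


def write_report(report: EstimationReport, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_report(path: Union[str, Path]) -> EstimationReport:
    return EstimationReport.from_dict(json.loads(Path(path).read_text()))
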