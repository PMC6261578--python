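"""Containers for scored focus-count samples.

The atomic observation of a calibration experiment is one blood sample of
``n_cells`` cells scored for gamma-H2AX foci after ex-vivo irradiation at a
known dose: the recorded datum is the *total* focus count over those cells,
and the quantity modelled downstream is the yield (foci per cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["FocusSample", "CalibrationDataset"]


@dataclass(frozen=True)
class FocusSample:
    """One scored sample: total focus count over ``n_cells`` cells at a dose.

    Parameters
    ----------
    dose_gy : float
        Absorbed dose in Gy; must be >= 0.
    time_label : str
        Time-after-exposure tag, e.g. ``"1h"`` or ``"24h"``.
    n_cells : int
        Number of cells scored (>= 1).
    total_count : int
        Total number of foci counted over all cells (>= 0).
    donor_id, scorer_id : str, optional
        Provenance tags used by the donor-effect deviance test and for
        book-keeping; not used by the curve fit itself.
    """

    dose_gy: float
    time_label: str
    n_cells: int
    total_count: int
    donor_id: Optional[str] = None
    scorer_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose_gy) or self.dose_gy < 0:
            raise InputError(f"dose_gy must be a finite non-negative real, got {self.dose_gy}")
        if int(self.n_cells) != self.n_cells or self.n_cells < 1:
            raise InputError(f"n_cells must be a positive integer, got {self.n_cells}")
        if int(self.total_count) != self.total_count or self.total_count < 0:
            raise InputError(
                f"total_count must be a non-negative integer, got {self.total_count}"
            )

    @property
    def yield_per_cell(self) -> float:
        """Observed yield y = Y / n (foci per cell)."""
        return self.total_count / self.n_cells


@dataclass
class CalibrationDataset:
    """Ordered collection of :class:`FocusSample` forming a calibration set."""

    samples: Sequence[FocusSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CalibrationDataset":
        """Build from a frame with columns dose_gy, time, n_cells, focus_count
        and optional donor / scorer columns."""
        required = {"dose_gy", "time", "n_cells", "focus_count"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"missing required columns: {sorted(missing)}")
        samples = []
        for idx, row in df.iterrows():
            try:
                samples.append(
                    FocusSample(
                        dose_gy=float(row["dose_gy"]),
                        time_label=str(row["time"]),
                        n_cells=int(row["n_cells"]),
                        total_count=int(row["focus_count"]),
                        donor_id=None if "donor" not in df.columns or pd.isna(row["donor"])
                        else str(row["donor"]),
                        scorer_id=None if "scorer" not in df.columns or pd.isna(row["scorer"])
                        else str(row["scorer"]),
                    )
                )
            except (InputError, ValueError) as exc:
                raise InputError(f"row {idx}: {exc}") from exc
        return cls(samples)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_gy": [s.dose_gy for s in self.samples],
                "time": [s.time_label for s in self.samples],
                "n_cells": [s.n_cells for s in self.samples],
                "focus_count": [s.total_count for s in self.samples],
                "donor": [s.donor_id for s in self.samples],
                "scorer": [s.scorer_id for s in self.samples],
            }
        )

    # -- protocol ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[FocusSample]:
        return iter(self.samples)

    # -- derived quantities ------------------------------------------------
    @property
    def n_obs(self) -> int:
        """N = sum of replicates over dose levels."""
        return len(self.samples)

    @property
    def doses(self) -> np.ndarray:
        return np.array([s.dose_gy for s in self.samples], dtype=float)

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([s.n_cells for s in self.samples], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.total_count for s in self.samples], dtype=float)

    @property
    def yields(self) -> np.ndarray:
        return self.counts / self.n_cells

    @property
    def time_labels(self) -> np.ndarray:
        return np.array([s.time_label for s in self.samples], dtype=object)

    @property
    def donor_ids(self) -> np.ndarray:
        return np.array([s.donor_id for s in self.samples], dtype=object)

    def distinct_doses(self, time_label: Optional[str] = None) -> np.ndarray:
        sub = self.subset(time_label) if time_label is not None else self
        return np.unique(sub.doses)

    def subset(self, time_label: str) -> "CalibrationDataset":
        return CalibrationDataset([s for s in self.samples if s.time_label == time_label])

    def require_fit_feasible(self, n_params: int, time_strata: bool = False) -> None:
        """Validate the dataset invariants required before a fit.

        Requires N > n_params (so the dispersion denominator N - p is
        positive) and at least two distinct dose values per fitted stratum.
        """
        if self.n_obs <= n_params:
            raise InputError(
                f"need more observations ({self.n_obs}) than parameters ({n_params})"
            )
        labels = np.unique(self.time_labels) if time_strata else [None]
        for lab in labels:
            sub = self.subset(lab) if lab is not None else self
            if len(np.unique(sub.doses)) < 2:
                where = f" in stratum {lab!r}" if lab is not None else ""
                raise InputError(f"need at least 2 distinct dose values{where}")


def pooled_yield(samples: Iterable[tuple[float, int]]) -> tuple[float, int]:
    """Pool (yield, n_cells) pairs taken at a common dose.

    Total counts are added and divided by the pooled number of cells, so the
    result is again a single (yield, n_cells) pair.
    """
    samples = list(samples)
    if not samples:
        raise InputError("cannot pool an empty list of samples")
    total = sum(y * n for y, n in samples)
    cells = sum(n for _, n in samples)
    if cells < 1:
        raise InputError("pooled cell count must be >= 1")
    return total / cells, cells
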