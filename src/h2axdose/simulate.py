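"""Synthetic overdispersed focus-count data.

The estimation framework assumes only the first two moments of the counts:
E(Y) = n (A + B x) and Var(Y) = phi E(Y). The generator realises that
mean-variance law with a negative-binomial family (size = mean/(phi - 1)),
which matches Var = phi * mean exactly for phi > 1 and degrades to Poisson
at phi = 1. The negative binomial is a modelling choice of this package -
any count family with the right two moments would serve the same role.

The bundled default scenario reproduces a typical two-time-point manual
scoring experiment: 339 samples of 500 cells at design doses 0-4 Gy scored
1 h and 24 h after exposure, background yield 0.150 foci/cell, slopes
12.518 (1 h) and 1.956 (24 h) foci/cell/Gy, dispersion 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curves import CalibrationCurve
from .data import CalibrationDataset, FocusSample
from .dose import CustomerSample
from .errors import InputError

__all__ = [
    "DesignPoint",
    "SimulationScenario",
    "simulate_dataset",
    "simulate_customer",
    "default_design",
    "default_scenario",
]


@dataclass(frozen=True)
class DesignPoint:
    """One cell of the calibration design: replicates at a (dose, time)."""

    dose_gy: float
    time_label: str
    n_cells: int
    n_replicates: int


# replicate layout of a realistic two-time manual-scoring experiment
_DESIGN_1H: Tuple[Tuple[float, int], ...] = (
    (0.0, 56), (0.05, 16), (0.1, 16), (0.25, 16), (0.5, 55), (1.0, 28),
)
_DESIGN_24H: Tuple[Tuple[float, int], ...] = (
    (0.0, 22), (0.05, 16), (0.1, 16), (0.25, 16), (0.5, 19), (1.0, 27), (4.0, 36),
)


def default_design(n_cells: int = 500) -> List[DesignPoint]:
    """The bundled 339-sample two-time calibration design."""
    pts = [DesignPoint(d, "1h", n_cells, r) for d, r in _DESIGN_1H]
    pts += [DesignPoint(d, "24h", n_cells, r) for d, r in _DESIGN_24H]
    return pts


@dataclass
class SimulationScenario:
    """Generating truth for a synthetic calibration experiment.

    ``slopes`` maps each time label to its dose-response slope; all labels
    share the intercept (the background yield does not depend on a time
    after an exposure that never happened). ``donor_ids`` are assigned
    round-robin over samples and ``donor_multipliers`` scale the mean per
    donor (for donor-effect power studies; no donor effect by default).
    """

    true_intercept: float = 0.150
    slopes: Dict[str, float] = field(default_factory=lambda: {"1h": 12.518, "24h": 1.956})
    phi: float = 60.0
    design: List[DesignPoint] = field(default_factory=default_design)
    seed: int = 0
    family: str = "quasipoisson_nb"
    donor_ids: Optional[Sequence[str]] = None
    donor_multipliers: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.phi < 1:
            raise InputError(f"phi must be >= 1, got {self.phi}")
        if self.family not in ("quasipoisson_nb", "poisson"):
            raise InputError(f"unknown family {self.family!r}")
        for pt in self.design:
            if pt.time_label not in self.slopes:
                raise InputError(f"no slope for time label {pt.time_label!r}")
            mu = self.true_intercept + self.slopes[pt.time_label] * pt.dose_gy
            if mu <= 0:
                raise InputError(f"non-positive mean yield {mu:.3f} at {pt}")


def default_scenario(seed: int = 0, phi: float = 60.0) -> SimulationScenario:
    return SimulationScenario(seed=seed, phi=phi)


def _draw_counts(rng: np.random.Generator, mean, phi: float, size=None) -> np.ndarray:
    """Counts with the quasi-Poisson mean-variance law Var = phi * mean."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise InputError("count means must be positive")
    if phi == 1.0:
        return rng.poisson(mean, size=size)
    nb_size = mean / (phi - 1.0)
    return rng.negative_binomial(nb_size, 1.0 / phi, size=size)


def simulate_dataset(scenario: SimulationScenario) -> CalibrationDataset:
    """Draw one calibration dataset; reproducible under the scenario seed.

    Each design row uses its own substream spawned from the scenario seed,
    so appending rows never perturbs earlier rows.
    """
    phi = scenario.phi if scenario.family == "quasipoisson_nb" else 1.0
    streams = np.random.SeedSequence(scenario.seed).spawn(len(scenario.design))
    samples: List[FocusSample] = []
    k = 0
    for pt, ss in zip(scenario.design, streams):
        rng = np.random.default_rng(ss)
        mu = scenario.true_intercept + scenario.slopes[pt.time_label] * pt.dose_gy
        for _ in range(pt.n_replicates):
            donor = None
            mult = 1.0
            if scenario.donor_ids is not None:
                donor = scenario.donor_ids[k % len(scenario.donor_ids)]
                if scenario.donor_multipliers:
                    mult = scenario.donor_multipliers.get(donor, 1.0)
            count = int(_draw_counts(rng, pt.n_cells * mu * mult, phi))
            samples.append(
                FocusSample(
                    dose_gy=pt.dose_gy,
                    time_label=pt.time_label,
                    n_cells=pt.n_cells,
                    total_count=count,
                    donor_id=donor,
                )
            )
            k += 1
    return CalibrationDataset(samples)


def simulate_customer(
    true_dose: float,
    curve: CalibrationCurve,
    n_star: int,
    phi: float = 60.0,
    seed: int = 0,
) -> CustomerSample:
    """One overdispersed customer yield drawn from the curve at a true dose."""
    mu = curve.mean_yield(true_dose)
    if mu <= 0:
        raise InputError(f"curve mean {mu:.4f} at dose {true_dose} Gy is not positive")
    rng = np.random.default_rng(seed)
    count = int(_draw_counts(rng, n_star * mu, max(phi, 1.0)))
    return CustomerSample.from_counts(count, n_star, time_label=curve.time_label)
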