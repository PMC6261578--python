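"""Shared fixtures: the published two-time calibration curves and the
worked-example reference samples used throughout the suite."""

from pathlib import Path

import pytest

from h2axdose import CalibrationCurve, ReferenceSet, pool_reference_samples

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def curve_1h() -> CalibrationCurve:
    """Joint-model 1 h curve: A = 0.150 (0.013), B = 12.518 (0.158), phi 60."""
    return CalibrationCurve(
        intercept=0.150, slope=12.518, se_intercept=0.013, se_slope=0.158,
        phi=60.0, time_label="1h", source="fitted",
    )


@pytest.fixture
def curve_24h() -> CalibrationCurve:
    """Joint-model 24 h curve: A = 0.150 (0.013), B = 1.956 (0.037), phi 60."""
    return CalibrationCurve(
        intercept=0.150, slope=1.956, se_intercept=0.013, se_slope=0.037,
        phi=60.0, time_label="24h", source="fitted",
    )


@pytest.fixture
def pooled_y0() -> tuple:
    """0 Gy controls 68/200 and 117/200 pooled across time labels."""
    return pool_reference_samples([(68 / 200, 200), (117 / 200, 200)])


@pytest.fixture
def reference_1h(pooled_y0) -> ReferenceSet:
    y0, n0 = pooled_y0
    return ReferenceSet(y0=y0, n0=n0, yr=5.02, nr=200, xr=1.5)


@pytest.fixture
def reference_24h(pooled_y0) -> ReferenceSet:
    y0, n0 = pooled_y0
    return ReferenceSet(y0=y0, n0=n0, yr=2.92, nr=200, xr=1.5)


@pytest.fixture
def case_study_path() -> Path:
    return DATA_DIR / "case_study_samples.csv"
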