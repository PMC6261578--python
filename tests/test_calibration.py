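"""Calibration-curve fitting, dispersion estimation and the donor test."""

import numpy as np
import pytest
import statsmodels.api as sm

from h2axdose import (
    CalibrationDataset,
    FocusCalibrationModel,
    FocusSample,
    InputError,
    correct_standard_errors,
    default_scenario,
    donor_effect_test,
    estimate_dispersion,
    fit_calibration,
    fit_joint_model,
    simulate_dataset,
)


def _exact_line_dataset(a=0.1, b=2.0, doses=(0.0, 1.0, 2.0), n=100, reps=2,
                        label="1h"):
    samples = [
        FocusSample(x, label, n, int(round(n * (a + b * x))))
        for x in doses
        for _ in range(reps)
    ]
    return CalibrationDataset(samples)


class TestLinearFit:
    def test_perfect_line_recovered_exactly(self):
        """Zero-residual data solve the score equations at the generating line."""
        curve = fit_calibration(_exact_line_dataset(), "linear")
        assert curve.intercept == pytest.approx(0.1, abs=1e-10)
        assert curve.slope == pytest.approx(2.0, abs=1e-10)

    def test_matches_statsmodels_identity_poisson(self):
        """Dual-route check: our scoring equals statsmodels GLM on counts."""
        ds = simulate_dataset(default_scenario(seed=42))
        fit = FocusCalibrationModel(ds.subset("24h")).fit("linear")
        X = np.column_stack([
            ds.subset("24h").n_cells,
            ds.subset("24h").n_cells * ds.subset("24h").doses,
        ])
        ref = sm.GLM(
            ds.subset("24h").counts, X,
            family=sm.families.Poisson(sm.families.links.Identity()),
        ).fit(start_params=fit.params)
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-7)
        np.testing.assert_allclose(fit.poisson_bse, ref.bse, rtol=1e-6)

    def test_quadratic_fit_recovers_curved_truth(self):
        ds = CalibrationDataset([
            FocusSample(x, "24h", 500, int(round(500 * (0.2 + 2.0 * x - 0.1 * x**2))))
            for x in (0.0, 0.5, 1.0, 2.0, 4.0)
            for _ in range(3)
        ])
        curve = fit_calibration(ds, "quadratic")
        assert curve.model_form == "quadratic"
        assert curve.intercept == pytest.approx(0.2, abs=5e-3)
        assert curve.quad == pytest.approx(-0.1, abs=5e-3)

    def test_quadratic_needs_three_doses(self):
        with pytest.raises(InputError):
            fit_calibration(_exact_line_dataset(doses=(0.0, 1.0)), "quadratic")

    def test_mixed_time_labels_require_choice(self):
        ds = simulate_dataset(default_scenario(seed=3))
        with pytest.raises(InputError, match="time label"):
            fit_calibration(ds, "linear")
        curve = fit_calibration(ds, "linear", time_label="1h")
        assert curve.time_label == "1h"


class TestGridOracle:
    @staticmethod
    def _loglik(ds, a, b):
        m = ds.n_cells * (a + b * ds.doses)
        if np.any(m <= 0):
            return -np.inf
        return float(np.sum(ds.counts * np.log(m) - m))

    def test_tiny_fit_matches_brute_force_maximizer(self):
        """On a tiny dataset the fit equals a refined grid search of the
        identity-link Poisson log-likelihood to within grid resolution."""
        ds = CalibrationDataset([
            FocusSample(0.0, "1h", 5, 1),
            FocusSample(1.0, "1h", 5, 6),
            FocusSample(2.0, "1h", 5, 8),
        ])
        curve = fit_calibration(ds, "linear")
        a_lo, a_hi, b_lo, b_hi = 0.01, 1.0, 0.01, 2.0
        best = None
        for _ in range(4):  # coarse-to-fine refinement down to ~1e-4
            aa = np.linspace(a_lo, a_hi, 61)
            bb = np.linspace(b_lo, b_hi, 61)
            vals = [(self._loglik(ds, a, b), a, b) for a in aa for b in bb]
            best = max(vals)
            da, db = aa[1] - aa[0], bb[1] - bb[0]
            a_lo, a_hi = best[1] - da, best[1] + da
            b_lo, b_hi = best[2] - db, best[2] + db
        assert curve.intercept == pytest.approx(best[1], abs=1e-4)
        assert curve.slope == pytest.approx(best[2], abs=1e-4)


class TestDispersion:
    def test_perfect_fit_gives_zero(self):
        ds = _exact_line_dataset()
        assert estimate_dispersion(ds, 0.1 + 2.0 * ds.doses, 2) == pytest.approx(0.0)

    def test_hand_computed_toy_value(self):
        """Direct evaluation: (12-10)^2/10 + (30-32)^2/32 over N - p = 1 df."""
        ds = CalibrationDataset([
            FocusSample(0.0, "1h", 10, 12),
            FocusSample(1.0, "1h", 10, 30),
        ])
        phi = estimate_dispersion(ds, np.array([1.0, 3.2]), n_params=1)
        assert phi == pytest.approx((2**2 / 10 + 2**2 / 32) / 1)

    def test_equals_scaled_mean_pearson_residual_square(self):
        """phi-hat = mean of squared Pearson residuals times N/(N-p)."""
        ds = simulate_dataset(default_scenario(seed=9))
        fit = FocusCalibrationModel(ds).fit_joint()
        mu = fit.raw.fitted
        pearson_sq = (ds.counts - mu) ** 2 / mu
        expected = pearson_sq.mean() * ds.n_obs / (ds.n_obs - 3)
        assert fit.phi == pytest.approx(expected, rel=1e-12)

    def test_undefined_when_too_few_observations(self):
        ds = CalibrationDataset([
            FocusSample(0.0, "1h", 10, 2), FocusSample(1.0, "1h", 10, 5),
        ])
        with pytest.raises(InputError):
            estimate_dispersion(ds, np.array([0.2, 0.5]), n_params=2)


class TestCorrectedStandardErrors:
    @pytest.mark.parametrize(
        "se, phi, expected",
        [(0.1, 60.0, 0.1 * np.sqrt(60)), (0.0, 17.0, 0.0), (0.25, 1.0, 0.25)],
    )
    def test_sqrt_phi_scaling(self, se, phi, expected):
        assert correct_standard_errors(se, phi) == pytest.approx(expected)

    def test_negative_se_rejected(self):
        with pytest.raises(InputError):
            correct_standard_errors([-0.1], 60.0)

    def test_ratio_is_sqrt_phi_for_every_parameter(self):
        ds = simulate_dataset(default_scenario(seed=21))
        fit = FocusCalibrationModel(ds.subset("1h")).fit("linear")
        np.testing.assert_allclose(
            fit.bse / fit.poisson_bse, np.sqrt(fit.phi), rtol=1e-12
        )


class TestJointModel:
    def test_exact_common_intercept_identities(self):
        """Two strata lying on exact lines with common intercept: a, b2 exact;
        the derived per-time curves obey A = a, B = b1 (+ b2)."""
        ds = CalibrationDataset(
            list(_exact_line_dataset(a=0.2, b=10.0, n=500, label="1h"))
            + list(_exact_line_dataset(a=0.2, b=2.0, n=500, label="24h"))
        )
        jm = fit_joint_model(ds)
        assert jm.a == pytest.approx(0.2, abs=1e-8)
        assert jm.b2 == pytest.approx(2.0 - 10.0, abs=1e-7)
        curves = jm.curves()
        assert curves["1h"].intercept == curves["24h"].intercept == pytest.approx(jm.a)
        assert curves["24h"].slope == pytest.approx(jm.b1 + jm.b2)

    def test_single_time_label_rejected(self):
        with pytest.raises(InputError):
            fit_joint_model(_exact_line_dataset())

    def test_intercept_recovery_over_replicates(self):
        """Mean of the fitted shared intercept over 200 synthetic experiments
        is within Monte-Carlo error of the generating value 0.150."""
        a_hats = [
            fit_joint_model(simulate_dataset(default_scenario(seed=60000 + i))).a
            for i in range(200)
        ]
        mc_se = np.std(a_hats) / np.sqrt(len(a_hats))
        assert np.mean(a_hats) == pytest.approx(0.150, abs=4 * mc_se)

    def test_separate_slopes_bracket_interaction(self):
        """Per-stratum slope difference approximates b2 within combined SEs."""
        ds = simulate_dataset(default_scenario(seed=77))
        jm = fit_joint_model(ds)
        f1 = FocusCalibrationModel(ds.subset("1h")).fit("linear")
        f2 = FocusCalibrationModel(ds.subset("24h")).fit("linear")
        diff = f2.curve.slope - f1.curve.slope
        tol = 3 * np.hypot(f1.curve.se_slope, f2.curve.se_slope)
        assert abs(diff - jm.b2) < tol

    def test_parameter_recovery_matches_reported_ses(self):
        """Empirical SD of the joint estimates over 500 replicates at phi=60
        agrees with the dispersion-corrected SEs (0.013, 0.158) within 15%."""
        a_hats, b_hats = [], []
        for i in range(500):
            jm = fit_joint_model(simulate_dataset(default_scenario(seed=50000 + i)))
            a_hats.append(jm.a)
            b_hats.append(jm.b1)
        assert np.std(a_hats) == pytest.approx(0.013, rel=0.15)
        assert np.std(b_hats) == pytest.approx(0.158, rel=0.15)


class TestDonorEffect:
    donors = tuple(f"D{i}" for i in range(8))

    def _dataset(self, seed, multipliers=None):
        sc = default_scenario(seed=seed)
        sc.donor_ids = list(self.donors)
        sc.donor_multipliers = multipliers
        return simulate_dataset(sc)

    def test_sequential_deviance_table_structure(self):
        tab = donor_effect_test(self._dataset(11))
        frame = tab.to_frame()
        resid = frame["residual_deviance"].to_numpy()
        assert np.all(np.diff(resid) <= 0)
        expl = frame["deviance_explained"].to_numpy()[1:]
        np.testing.assert_allclose(expl, -np.diff(resid), rtol=1e-10)
        assert tab.df == len(self.donors) - 1

    def test_no_injected_effect_is_not_significant(self):
        tab = donor_effect_test(self._dataset(11))
        assert tab.p_value > 0.05

    def test_power_against_injected_donor_effect(self):
        """Donor-specific mean multipliers 0.7-1.3 are detected (p < 0.05)
        in at least 95% of 200 replicates."""
        mults = dict(zip(self.donors, np.linspace(0.7, 1.3, len(self.donors))))
        hits = sum(
            donor_effect_test(self._dataset(20000 + i, mults)).p_value < 0.05
            for i in range(200)
        )
        assert hits / 200 >= 0.95

    def test_single_level_factor_rejected(self):
        ds = _exact_line_dataset()
        with pytest.raises(InputError, match="single level"):
            donor_effect_test(ds, factors=("dose", "time"))
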