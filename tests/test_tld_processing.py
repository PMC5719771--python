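"""TLD reading-to-dose chain: characterization, session factors, reading
correction, calibration fit, and dose recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungpdd.synthetic_data import SyntheticStudyParams, generate_tld_study
from lungpdd.tld_processing import (
    BatchCharacterization,
    CalibrationCurve,
    SessionControl,
    characterize_batch,
    correct_reading,
    fit_calibration,
    process_study,
    reading_to_dose,
    session_factor,
)

# the study's fitted calibration curve, used as a fixture throughout:
# Dw [cGy] = 0.0009 * TLcorr + 1.4243
CAL = CalibrationCurve(a=0.0009, b=1.4243, residual_sd=0.0,
                       cov=np.zeros((2, 2)))


class TestCharacterizeBatch:
    def test_identical_dosimeters(self):
        zeros = {f"d{i}": [100.0] for i in range(4)}
        refs = {f"d{i}": [1100.0] for i in range(4)}
        char = characterize_batch(zeros, refs)
        assert char.tl0 == 100.0
        assert all(s == pytest.approx(1.0) for s in char.sensitivity.values())

    def test_sensitivities_from_net_signals(self):
        zeros = {"a": [0.0], "b": [0.0]}
        refs = {"a": [90.0], "b": [110.0]}
        char = characterize_batch(zeros, refs)
        assert char.sensitivity["a"] == pytest.approx(0.9)
        assert char.sensitivity["b"] == pytest.approx(1.1)

    def test_zero_net_signal_names_dosimeter(self):
        zeros = {"a": [100.0], "b": [100.0]}
        refs = {"a": [1100.0], "b": [100.0]}
        with pytest.raises(ValueError, match="b"):
            characterize_batch(zeros, refs)

    def test_recovers_known_sensitivities(self):
        params = SyntheticStudyParams(seed=3)
        table, truth = generate_tld_study({5.0: 80.0}, params)
        result = process_study(table)
        s_est = result["characterization"].sensitivity
        s_true = truth["sensitivity"]
        err = [abs(s_est[i] / s_true[i] - 1.0) for i in s_est]
        # read noise is 1%; each sensitivity comes from one zero + one
        # reference reading, so a ~2-sigma band is 3%
        assert np.median(err) < 0.02
        assert max(err) < 0.06


class TestSessionFactor:
    def _char(self, n=8):
        ids = [f"c{i}" for i in range(n)]
        return BatchCharacterization(
            tl0=100.0, sensitivity={i: 1.0 for i in ids}, zero_sd=0.0,
            ldl_reader_units=0.0), ids

    def test_reference_session_has_unit_factor(self):
        char, ids = self._char()
        readings = {i: 1100.0 for i in ids}
        sc = session_factor(readings, char, "ref")
        assert sc.tlref == pytest.approx(1000.0)
        assert sc.fcm["ref"] == 1.0

    def test_scaled_net_readings_give_scaled_factor(self):
        char, ids = self._char()
        sc = session_factor({i: 1100.0 for i in ids}, char, "ref")
        scaled = {i: 100.0 + 1000.0 * 1.05 for i in ids}
        sc = session_factor(scaled, char, "m1", ref=sc)
        assert sc.fcm["m1"] == pytest.approx(1.05)

    def test_injected_drift_recovered(self):
        params = SyntheticStudyParams(seed=11, session_drift_sd=0.0)
        # fix drift by hand: rebuild a session with drift 0.97
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(8)]
        char = BatchCharacterization(
            tl0=100.0, sensitivity={i: 1.0 for i in ids}, zero_sd=0.0,
            ldl_reader_units=0.0)
        ref = session_factor({i: 100.0 + 1e5 for i in ids}, char, "ref")
        noisy = {i: 100.0 + 0.97 * 1e5 * (1 + rng.normal(0, 0.01))
                 for i in ids}
        sc = session_factor(noisy, char, "m", ref=ref)
        assert sc.fcm["m"] == pytest.approx(0.97, abs=0.01)

    def test_wrong_control_count(self):
        char, ids = self._char()
        with pytest.raises(ValueError):
            session_factor({i: 1100.0 for i in ids[:5]}, char, "ref")


class TestCorrectReading:
    def _setup(self, tl0=0.0, si=1.0, fcm=1.0):
        # pad with two chips keeping the batch-mean-1 invariant
        pad = (3.0 - si) / 2.0
        char = BatchCharacterization(
            tl0=tl0, sensitivity={"d": si, "e": pad, "f": pad}, zero_sd=0.0,
            ldl_reader_units=0.0)
        sc = SessionControl(tlref=1.0, fcm={"s": fcm}, fcm_rel_se={"s": 0.0})
        return char, sc

    def test_identity(self):
        char, sc = self._setup()
        assert correct_reading(123.4, char, sc, "s", "d") == 123.4

    def test_arithmetic(self):
        char, sc = self._setup(tl0=100.0, si=2.0, fcm=0.5)
        assert correct_reading(1100.0, char, sc, "s", "d") == pytest.approx(1000.0)

    def test_negative_net_reading_propagates(self):
        char, sc = self._setup(tl0=100.0)
        assert correct_reading(50.0, char, sc, "s", "d") == pytest.approx(-50.0)

    @given(k=st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_session_gain_invariance(self, k):
        """Scaling every net signal of a session by k > 0 is absorbed exactly
        by the session control factor, leaving corrected readings unchanged."""
        ids = [f"c{i}" for i in range(8)]
        char = BatchCharacterization(
            tl0=100.0, sensitivity={**{i: 1.0 for i in ids}, "m": 1.0},
            zero_sd=0.0, ldl_reader_units=0.0)
        ref = session_factor({i: 100.0 + 1000.0 for i in ids}, char, "ref")
        base = correct_reading(100.0 + 500.0, char, ref, "ref", "m")
        scaled_controls = {i: 100.0 + k * 1000.0 for i in ids}
        sc = session_factor(scaled_controls, char, "s", ref=ref)
        got = correct_reading(100.0 + k * 500.0, char, sc, "s", "m")
        assert got == pytest.approx(base, rel=1e-12)


class TestCalibration:
    def test_exact_line_recovered(self):
        groups = {d: [(d - 2.0) / 0.001] * 8 for d in (25.0, 50.0, 100.0)}
        cal = fit_calibration(groups)
        assert cal.a == pytest.approx(0.001, rel=1e-9)
        assert cal.b == pytest.approx(2.0, rel=1e-9)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_prediction_at_zero_reading_is_intercept(self):
        assert CAL.dose(0.0) == pytest.approx(1.4243)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            fit_calibration({50.0: [1.0, 2.0]})

    def test_noisy_groups_recovered_across_seeds(self):
        """With 1% read noise and 8 replicates per level, the fitted slope
        stays within ~1% and the intercept within ~0.5 cGy for the large
        majority of repetitions (noise-propagated tolerances)."""
        a_true, b_true = 0.0009, 1.4243
        aerr, berr = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            groups = {}
            for d in (25.0, 50.0, 100.0):
                latent = (d - b_true) / a_true
                groups[d] = list(latent * (1 + rng.normal(0, 0.01, 8)))
            cal = fit_calibration(groups)
            aerr.append(abs(cal.a / a_true - 1.0))
            berr.append(abs(cal.b - b_true))
        assert np.median(aerr) < 0.01
        assert np.percentile(aerr, 95) < 0.02
        assert np.median(berr) < 0.3
        assert np.percentile(berr, 95) < 1.0


class TestReadingToDose:
    def test_intercept_at_zero_mean_reading(self):
        est = reading_to_dose([0.0, 0.0], CAL)
        assert est.dose_cgy == pytest.approx(1.4243, abs=1e-12)

    def test_inverse_arithmetic_of_calibration(self):
        est = reading_to_dose([109_530.8, 109_530.8], CAL)
        assert est.dose_cgy == pytest.approx(100.0, abs=0.01)

    def test_uncertainty_combines_components(self):
        cal = CalibrationCurve(a=0.001, b=0.0, residual_sd=0.5,
                               cov=np.array([[1e-12, 0.0], [0.0, 0.25]]))
        est = reading_to_dose([99_000.0, 101_000.0], cal, fcm_rel_se=0.005)
        u_rep = 0.001 * np.std([99_000.0, 101_000.0], ddof=1) / np.sqrt(2)
        u_fcm = 0.001 * 100_000.0 * 0.005
        u_fit = np.sqrt(1e-12 * 100_000.0**2 + 0.25)
        assert est.u_cgy == pytest.approx(
            np.hypot(np.hypot(u_rep, u_fcm), u_fit), rel=1e-9)

    def test_below_ldl_flagged(self):
        char = BatchCharacterization(
            tl0=100.0, sensitivity={"a": 1.0, "b": 1.0}, zero_sd=10.0,
            ldl_reader_units=30.0)
        est = reading_to_dose([5.0, 8.0], CAL, char=char)
        assert est.below_ldl


class TestEndToEnd:
    def test_recovery_within_two_percent(self):
        depths = {float(d): 100.0 * np.exp(-0.05 * d) for d in range(1, 27)}
        params = SyntheticStudyParams(seed=42)
        table, truth = generate_tld_study(depths, params)
        result = process_study(table)
        errs = [abs(result["doses"][d].dose_cgy / depths[d] - 1.0)
                for d in depths]
        frac_ok = np.mean([e < 0.02 for e in errs])
        assert frac_ok >= 0.95

    def test_calibration_self_consistency(self):
        """Predicting the calibration doses from their own mean readings
        reproduces them within a few residual sd."""
        params = SyntheticStudyParams(seed=9)
        table, _ = generate_tld_study({5.0: 70.0}, params)
        result = process_study(table)
        cal = result["calibration"]
        for d in (25.0, 50.0, 100.0):
            latent = (d - 1.4243) / 0.0009
            assert cal.dose(latent) == pytest.approx(
                d, abs=max(3 * cal.residual_sd, 0.02 * d) + 1e-9)

    def test_total_uncertainty_below_five_percent(self):
        depths = {float(d): 100.0 * np.exp(-0.04 * d) for d in range(1, 27)}
        table, _ = generate_tld_study(depths, SyntheticStudyParams(seed=2))
        result = process_study(table)
        assert max(e.rel_u for e in result["doses"].values()) < 0.05
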