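"""Mass-balance model: closed forms, linearity, calibration round trips."""
import math

import numpy as np
import pytest

from poptk import (
    BiomarkerMeasurement,
    BreastfeedingSchedule,
    CompoundParams,
    DyadProfile,
    calibrate_intake,
    recover_half_life,
    simulate_adult,
    simulate_dyad,
    simulate_from_biomarker,
    simulate_mother,
    window_average,
)
from poptk.kinetics import CalibrationError


class TestSimulateDyad:
    def test_zero_intake_is_zero_everywhere(self, dyad, pcb153):
        s = simulate_dyad(dyad, pcb153, 0.0)
        assert np.all(s.child_conc == 0) and np.all(s.mother_conc == 0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 2.0, 10.0])
    def test_linearity_in_dose(self, dyad, pcb153, alpha):
        base = simulate_dyad(dyad, pcb153, 100.0)
        scaled = simulate_dyad(dyad, pcb153, 100.0 * alpha)
        np.testing.assert_allclose(
            scaled.child_conc, alpha * base.child_conc, rtol=1e-9, atol=1e-12
        )
        np.testing.assert_allclose(
            scaled.mother_conc, alpha * base.mother_conc, rtol=1e-9, atol=1e-12
        )

    def test_newborn_in_equilibrium_with_mother(self, dyad, pcb153):
        s = simulate_dyad(dyad, pcb153, 100.0)
        assert s.child_conc[0] == pytest.approx(s.mother_conc[0], rel=1e-12)

    def test_mass_balance_audit(self, dyad, pcb153):
        s = simulate_dyad(dyad, pcb153, 100.0)
        assert s.mass_balance_error() < 1e-3
        # milk transfer is monotone and appears in the audit fields
        assert np.all(np.diff(s.cum_transferred_ng) >= 0)

    def test_no_breastfeeding_matches_growth_diluted_decay(self, dyad_no_bf, pcb153):
        s = simulate_dyad(dyad_no_bf, pcb153, 100.0)
        k = pcb153.k_el
        analytic = (
            s.child_conc[0]
            * np.exp(-k * s.times)
            * s.child_lipid_kg[0]
            / s.child_lipid_kg
        )
        np.testing.assert_allclose(s.child_conc, analytic, rtol=5e-3)

    def test_longer_exclusive_feeding_raises_six_month_level(
        self, maternal, child, pcb153
    ):
        levels = []
        for excl in (0.0, 0.1, 0.25, 0.5):
            p = DyadProfile(
                maternal, child, BreastfeedingSchedule(exclusive_duration=excl)
            )
            levels.append(simulate_dyad(p, pcb153, 100.0).child_at(0.5))
        assert np.all(np.diff(levels) >= 0)

    def test_step_halving_convergence(self, dyad, pcb153):
        coarse = simulate_dyad(dyad, pcb153, 100.0, step_days=1.0)
        fine = simulate_dyad(dyad, pcb153, 100.0, step_days=0.5)
        at = np.linspace(0.01, 3.7, 50)
        np.testing.assert_allclose(
            coarse.child_at(at), fine.child_at(at), rtol=1e-3
        )

    def test_invalid_arguments_rejected(self, dyad, pcb153):
        with pytest.raises(ValueError):
            simulate_dyad(dyad, pcb153, -1.0)
        with pytest.raises(ValueError):
            simulate_dyad(dyad, pcb153, 10.0, horizon=0.0)


class TestMaternalDecay:
    @pytest.mark.parametrize("name,half_life", [("PCB-153", 14.4), ("HCB", 6.0)])
    def test_half_life_recovered_after_intake_cessation(self, name, half_life):
        recovered = recover_half_life(CompoundParams(name, half_life))
        assert recovered == pytest.approx(half_life, rel=5e-3)

    def test_accumulation_approaches_steady_state(self, pcb153):
        times, conc = simulate_adult(pcb153, 100.0, 80.0, lipid_kg=20.0)
        steady = 100.0 * 365.25 / pcb153.k_el / (1000.0 * 20.0)
        assert conc[-1] < steady
        assert conc[-1] == pytest.approx(steady * -math.expm1(-pcb153.k_el * 80.0), rel=1e-4)

    def test_mother_series_covers_lifetime(self, dyad, pcb153):
        s = simulate_mother(dyad, pcb153, 50.0)
        t_del = dyad.maternal.age_at_delivery
        assert s.times[0] == 0.0
        assert s.times[-1] == pytest.approx(t_del + 45.0 / 12.0)
        # doubling intake doubles the whole profile
        s2 = simulate_mother(dyad, pcb153, 100.0)
        np.testing.assert_allclose(s2.mother_conc, 2 * s.mother_conc, rtol=1e-12)


class TestCalibration:
    @pytest.mark.parametrize("matrix", ["maternal_blood", "cord_blood", "breast_milk"])
    def test_round_trip_recovers_generating_intake(self, dyad, pcb153, matrix):
        truth = 123.4
        s = simulate_dyad(dyad, pcb153, truth)
        if matrix == "breast_milk":
            meas = BiomarkerMeasurement(
                matrix=matrix, concentration=1.6 * s.mother_at(1 / 12),
                time=1 / 12, milk_basis_factor=1.6,
            )
        else:
            meas = BiomarkerMeasurement(matrix=matrix, concentration=s.mother_conc[0])
        est = calibrate_intake(dyad, pcb153, meas)
        assert est.daily_intake == pytest.approx(truth, rel=1e-3)

    def test_zero_measurement_gives_zero_intake(self, dyad, pcb153):
        meas = BiomarkerMeasurement(matrix="maternal_blood", concentration=0.0)
        assert calibrate_intake(dyad, pcb153, meas).daily_intake == 0.0

    def test_cord_and_maternal_blood_equivalent_at_delivery(self, dyad, pcb153):
        m1 = BiomarkerMeasurement(matrix="maternal_blood", concentration=104.0)
        m2 = BiomarkerMeasurement(matrix="cord_blood", concentration=104.0)
        i1 = calibrate_intake(dyad, pcb153, m1).daily_intake
        i2 = calibrate_intake(dyad, pcb153, m2).daily_intake
        assert i1 == pytest.approx(i2, rel=1e-12)

    def test_simulation_reproduces_the_measurement(self, dyad, pcb153):
        meas = BiomarkerMeasurement(
            matrix="breast_milk", concentration=118.0, time=1 / 12
        )
        series = simulate_from_biomarker(dyad, pcb153, meas)
        assert series.mother_at(1 / 12) == pytest.approx(118.0, rel=1e-6)

    def test_proportionality_between_matrices(self, dyad, pcb153):
        a = simulate_from_biomarker(
            dyad, pcb153,
            BiomarkerMeasurement(matrix="maternal_blood", concentration=100.0),
        )
        b = simulate_from_biomarker(
            dyad, pcb153,
            BiomarkerMeasurement(matrix="breast_milk", concentration=50.0, time=1 / 12),
        )
        ratio = b.child_conc[1:] / a.child_conc[1:]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_measurement_validation(self):
        with pytest.raises(ValueError):
            BiomarkerMeasurement(matrix="plasma", concentration=1.0)
        with pytest.raises(ValueError):
            BiomarkerMeasurement(matrix="maternal_blood", concentration=-1.0)
        with pytest.raises(ValueError):
            BiomarkerMeasurement(matrix="maternal_blood", concentration=1.0, time=0.5)
        with pytest.raises(ValueError):
            BiomarkerMeasurement(matrix="breast_milk", concentration=1.0, time=-0.1)


class TestWindowAverage:
    def test_constant_series(self, dyad_no_bf):
        slow = CompoundParams("inert", 1e9)  # effectively no elimination
        s = simulate_dyad(dyad_no_bf, slow, 0.0)
        s.child_conc = np.full_like(s.times, 7.5)
        assert window_average(s, 0.2, 1.7) == pytest.approx(7.5)

    def test_exponential_decay_analytic_mean(self, dyad_no_bf, pcb153):
        s = simulate_dyad(dyad_no_bf, pcb153, 100.0)
        k = pcb153.k_el
        c0 = s.child_conc[0]
        # strip growth dilution to leave a pure exponential
        s.child_conc = c0 * np.exp(-k * s.times)
        t0, t1 = 0.5, 2.0
        expected = c0 / (k * (t1 - t0)) * (math.exp(-k * t0) - math.exp(-k * t1))
        assert window_average(s, t0, t1) == pytest.approx(expected, rel=1e-6)

    def test_full_horizon_equals_overall_mean(self, dyad, pcb153):
        s = simulate_dyad(dyad, pcb153, 100.0)
        full = window_average(s, 0.0, float(s.times[-1]))
        manual = np.trapezoid(s.child_conc, s.times) / (s.times[-1] - s.times[0])
        assert full == pytest.approx(manual, rel=1e-9)

    def test_bad_windows_rejected(self, dyad, pcb153):
        s = simulate_dyad(dyad, pcb153, 100.0)
        for t0, t1 in [(-0.1, 1.0), (1.0, 1.0), (1.0, 99.0)]:
            with pytest.raises(ValueError):
                window_average(s, t0, t1)
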