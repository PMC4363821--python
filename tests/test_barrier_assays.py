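"""Electrophysiology and tracer-flux computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from paracellkit.barrier_assays import (
    DEFAULT_FILTER_AREA_CM2,
    EphysMeasurement,
    IonicSolution,
    TracerAssay,
    bath_concentration,
    compute_ter,
    ephys_pipeline,
    fit_standard_curve,
    ghk_dilution_potential,
    invert_dilution_potential,
    kimizuka_koketsu,
    nernst_limits_mV,
    tracer_permeability,
)
from paracellkit.constants import FARADAY, R_GAS, T_BODY_K
from paracellkit.errors import (
    DegenerateDesignError,
    InvalidMeasurementError,
    OutOfRangeError,
)


class TestTER:
    def test_blank_subtraction_and_area_normalisation(self):
        assert compute_ter(200.0, 100.0, 1.12) == pytest.approx(112.0)

    def test_zero_allowed_when_raw_equals_blank(self):
        assert compute_ter(100.0, 100.0, 1.12) == 0.0

    def test_raw_below_blank_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            compute_ter(90.0, 100.0, 1.12)

    @pytest.mark.parametrize("bad", [(0.0, 100, 1.12), (100, -1, 1.12), (100, 50, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(OutOfRangeError):
            compute_ter(*bad)


class TestSolutions:
    def test_full_chloride_accounting(self, solution_a, solution_b):
        # Cl = NaCl + KCl + 2*CaCl2 + 2*MgCl2
        assert solution_a.cl_mM == pytest.approx(149.0)
        assert solution_b.cl_mM == pytest.approx(79.0)

    def test_nacl_only_accounting(self):
        assert IonicSolution.solution_a(cl_accounting="nacl_only").cl_mM == 140.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(OutOfRangeError):
            IonicSolution(na_mM=-1, k_mM=5, cl_mM=10, ca_mM=1, mg_mM=1)


class TestGHKDilutionPotential:
    def test_nonselective_monolayer_sees_zero_potential(self, solution_a, solution_b):
        # Na gradient (140-70) equals Cl gradient (149-79): terms balance at eta=1
        assert ghk_dilution_potential(1.0, solution_a, solution_b) == pytest.approx(0.0, abs=1e-12)

    def test_cation_selective_control_value(self, solution_a, solution_b):
        v = ghk_dilution_potential(18.21, solution_a, solution_b)
        assert v == pytest.approx(16.39, abs=0.05)
        assert v > 0  # positive under the apical-minus-basolateral convention

    def test_large_eta_converges_to_sodium_nernst_limit(self, solution_a, solution_b):
        v_cl, v_na = nernst_limits_mV(solution_a, solution_b)
        assert v_na == pytest.approx(
            1000 * R_GAS * T_BODY_K / FARADAY * math.log(140 / 70), rel=1e-12
        )
        assert ghk_dilution_potential(1e6, solution_a, solution_b) == pytest.approx(v_na, abs=1e-2)

    def test_strictly_increasing_in_eta(self, solution_a, solution_b):
        etas = np.logspace(-2, 3, 200)
        vs = [ghk_dilution_potential(e, solution_a, solution_b) for e in etas]
        assert np.all(np.diff(vs) > 0)
        v_cl, v_na = nernst_limits_mV(solution_a, solution_b)
        assert v_cl < min(vs) and max(vs) < v_na

    def test_invalid_eta_rejected(self, solution_a, solution_b):
        with pytest.raises(OutOfRangeError):
            ghk_dilution_potential(0.0, solution_a, solution_b)


class TestInversion:
    def test_zero_potential_gives_unit_eta(self, solution_a, solution_b):
        assert invert_dilution_potential(0.0, solution_a, solution_b) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(eta=st.floats(min_value=0.05, max_value=100.0))
    def test_round_trip(self, eta, solution_a, solution_b):
        v = ghk_dilution_potential(eta, solution_a, solution_b)
        assert invert_dilution_potential(v, solution_a, solution_b) == pytest.approx(
            eta, rel=1e-9
        )

    def test_closed_form_matches_numerical_root_finder(self, solution_a, solution_b):
        """Inversion agrees with a brute-force zero crossing of the forward model."""
        v_cl, v_na = nernst_limits_mV(solution_a, solution_b)
        for v in np.linspace(v_cl + 0.5, v_na - 0.5, 25):
            eta_closed = invert_dilution_potential(v, solution_a, solution_b)
            eta_root = brentq(
                lambda e: ghk_dilution_potential(e, solution_a, solution_b) - v,
                1e-6,
                1e9,
                xtol=1e-12,
                rtol=1e-14,
            )
            assert eta_closed == pytest.approx(eta_root, rel=1e-6)

    def test_potential_beyond_nernst_limit_rejected(self, solution_a, solution_b):
        with pytest.raises(OutOfRangeError, match="Na"):
            invert_dilution_potential(25.0, solution_a, solution_b)
        with pytest.raises(OutOfRangeError):
            invert_dilution_potential(-20.0, solution_a, solution_b)


class TestKimizukaKoketsu:
    def test_symmetric_split_when_eta_is_one(self):
        p_na, p_cl = kimizuka_koketsu(500.0, 1.0, 1.4e-4)
        assert p_na == pytest.approx(p_cl)

    def test_eta_recovered_from_ratio(self):
        p_na, p_cl = kimizuka_koketsu(61.6, 18.21, 1.4e-4)
        assert p_na / p_cl == pytest.approx(18.21, rel=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        ter=st.floats(min_value=10.0, max_value=10000.0),
        eta=st.floats(min_value=0.05, max_value=100.0),
    )
    def test_conductance_consistency(self, ter, eta):
        """Reconstructed symmetric-bath GHK slope conductance equals 1/TER."""
        c = 1.4e-4
        p_na, p_cl = kimizuka_koketsu(ter, eta, c)
        g = (FARADAY**2 / (R_GAS * T_BODY_K)) * c * (p_na + p_cl)
        assert g == pytest.approx(1.0 / ter, rel=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(OutOfRangeError):
            kimizuka_koketsu(-1.0, 1.0, 1.4e-4)


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve([(0, 0), (1, 10), (2, 20)])
        assert (curve.slope, curve.intercept, curve.r_squared) == pytest.approx((10, 0, 1))

    def test_two_point_line(self):
        curve = fit_standard_curve([(0, 1), (2, 5)])
        assert (curve.slope, curve.intercept) == pytest.approx((2, 1))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 3.0 * x + 0.7 + rng.normal(0, 0.5, 5)
        curve = fit_standard_curve(list(zip(x, y)))
        # hand-rolled normal equations
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_standard_curve([(1.0, 2.0), (1.0, 3.0)])

    def test_inverse_mapping(self):
        curve = fit_standard_curve([(0, 1), (2, 5)])
        assert curve.concentration(curve.fluorescence(1.3)) == pytest.approx(1.3)


def _assay(sample_fluor, volume=1.0, duration=3600.0, area=1.12, c0=2e-7):
    # ground-truth curve: fluorescence = 10 + 1e10 * concentration
    curve = [(0.0, 10.0), (1e-9, 20.0), (2e-9, 30.0)]
    return TracerAssay(curve, sample_fluor, volume, duration, area, c0)


class TestTracerPermeability:
    def test_unit_analysis_worked_example(self):
        # Q = 1e-9 mol over 3600 s, A = 1.12 cm2, C0 = 2e-7 mol/cm3
        q = 1e-9
        assay = _assay(10.0 + 1e10 * q)  # volume 1 cm3 -> conc = Q
        res = tracer_permeability(assay)
        assert res.p_cm_s == pytest.approx((q / 3600.0) / (1.12 * 2e-7), rel=1e-9)
        assert res.p_cm_s == pytest.approx(1.24e-6, rel=0.01)

    def test_zero_accumulation_gives_zero(self):
        assert tracer_permeability(_assay(10.0)).p_cm_s == 0.0

    def test_below_curve_clamped_with_flag(self):
        with pytest.warns(UserWarning):
            res = tracer_permeability(_assay(5.0))
        assert res.p_cm_s == 0.0 and res.below_curve

    def test_scaling_laws(self):
        base = tracer_permeability(_assay(30.0)).p_cm_s
        assert tracer_permeability(_assay(30.0, c0=4e-7)).p_cm_s == pytest.approx(base / 2)
        assert tracer_permeability(_assay(30.0, area=2.24)).p_cm_s == pytest.approx(base / 2)
        # linear in accumulated Q (fluorescence above intercept)
        double_q = tracer_permeability(_assay(50.0)).p_cm_s
        assert double_q == pytest.approx(2 * base)


def _record(raw, v, condition="c", day=6, area=DEFAULT_FILTER_AREA_CM2, rep=""):
    return EphysMeasurement(
        raw_resistance_ohm=raw,
        blank_resistance_ohm=100.0,
        filter_area_cm2=area,
        dilution_potential_mV=v,
        apical=IonicSolution.solution_a(),
        basolateral=IonicSolution.solution_b(),
        condition=condition,
        day=day,
        replicate_id=rep,
    )


class TestEphysPipeline:
    def test_single_record_chain(self, solution_a, solution_b):
        v = ghk_dilution_potential(5.0, solution_a, solution_b)
        results, summaries = ephys_pipeline([_record(200.0, v)])
        (res,) = results
        assert res.eta == pytest.approx(5.0, rel=1e-9)
        assert res.ter_ohm_cm2 == pytest.approx(100.0 * DEFAULT_FILTER_AREA_CM2)
        sem = {s.quantity: s for s in summaries}
        assert sem["TER"].n == 1 and sem["TER"].sem == 0.0 and sem["TER"].degenerate_n

    def test_bath_concentration_modes(self):
        rec = _record(200.0, 5.0)
        assert bath_concentration(rec, "apical") == pytest.approx(1.4e-4)
        lm = (140.0 - 70.0) / math.log(140.0 / 70.0) * 1e-6
        assert bath_concentration(rec, "logmean") == pytest.approx(lm)
        assert bath_concentration(rec, "override", 1e-4) == 1e-4

    def test_mixed_areas_warn(self, solution_a, solution_b):
        v = ghk_dilution_potential(2.0, solution_a, solution_b)
        with pytest.warns(UserWarning, match="mixed filter areas"):
            ephys_pipeline([_record(200.0, v, area=1.12, rep="a"),
                            _record(200.0, v, area=4.67, rep="b")])

    def test_pooled_averaging_matches_per_record_when_noiseless(self, solution_a, solution_b):
        v = ghk_dilution_potential(3.0, solution_a, solution_b)
        recs = [_record(250.0, v, rep=str(i)) for i in range(3)]
        _, per = ephys_pipeline(recs, averaging="per_record")
        _, pooled = ephys_pipeline(recs, averaging="pooled")
        per_means = {s.quantity: s.mean for s in per}
        pooled_means = {s.quantity: s.mean for s in pooled}
        for q in ("TER", "eta", "p_na", "p_cl"):
            assert pooled_means[q] == pytest.approx(per_means[q], rel=1e-12)
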