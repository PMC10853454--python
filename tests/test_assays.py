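"""Shedding ratios, FRET normalization, dose-response fits and qPCR."""

import numpy as np
import pytest

import shedmap as sm
from shedmap.assays import PlateMeasurement, Well
from shedmap.simulate import (
    simulate_dose_response,
    simulate_fret_trace,
    simulate_plate,
)


def plate_from(rows, background=100.0):
    wells = [Well(c, comp, f) for c, comp, f in rows]
    return PlateMeasurement(wells, {"supernatant": background, "cell": background})


class TestSheddingRatio:
    def test_stated_arithmetic(self):
        plate = plate_from(
            [("ctrl", "supernatant", 200.0), ("ctrl", "cell", 200.0),
             ("x", "supernatant", 300.0), ("x", "cell", 200.0)]
        )
        results = {r.condition: r for r in sm.shedding_ratio(plate, "ctrl")}
        assert results["x"].ratio == pytest.approx(2.0)
        assert results["x"].normalized_ratio == pytest.approx(2.0)

    def test_control_normalizes_to_exactly_one(self):
        plate = plate_from(
            [("ctrl", "supernatant", 450.0), ("ctrl", "cell", 800.0),
             ("x", "supernatant", 900.0), ("x", "cell", 400.0)]
        )
        results = {r.condition: r for r in sm.shedding_ratio(plate, "ctrl")}
        assert results["ctrl"].normalized_ratio == 1.0

    def test_gain_invariance(self):
        base, truth = simulate_plate({"ctrl": 0.1, "hi": 0.5}, "ctrl", seed=1)
        scaled, _ = simulate_plate({"ctrl": 0.1, "hi": 0.5}, "ctrl", gain=10.0, seed=1)
        r1 = {r.condition: r.normalized_ratio for r in sm.shedding_ratio(base, "ctrl")}
        r2 = {r.condition: r.normalized_ratio for r in sm.shedding_ratio(scaled, "ctrl")}
        for cond in r1:
            assert r1[cond] == pytest.approx(r2[cond], rel=1e-12)

    def test_recovers_generator_truth(self):
        plate, truth = simulate_plate(
            {"ctrl": 0.2, "shed": 0.6}, "ctrl", n_wells=4, seed=3
        )
        results = {r.condition: r for r in sm.shedding_ratio(plate, "ctrl")}
        for cond, expected in truth["normalized_ratio"].items():
            assert results[cond].normalized_ratio == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_cell_compartment_rejected(self):
        plate = plate_from(
            [("ctrl", "supernatant", 200.0), ("ctrl", "cell", 50.0)]
        )  # background 100 > 50
        with pytest.raises(ValueError):
            sm.shedding_ratio(plate, "ctrl")


class TestFretNormalize:
    def test_anchors_map_to_exactly_0_and_100(self):
        trace, truth = simulate_fret_trace(seed=0)
        norm = sm.fret_normalize(trace)
        baseline = norm[trace.ligand_index - 10 : trace.ligand_index]
        assert baseline.mean() == pytest.approx(0.0, abs=1e-12)
        assert norm[-10:].mean() == pytest.approx(100.0, abs=1e-12)

    def test_round_trip_with_bleed_through(self):
        """Correction inverts the generator's channel encoding exactly."""
        trace, truth = simulate_fret_trace(bleed_through=0.3, background=80.0, seed=2)
        norm = sm.fret_normalize(trace)
        np.testing.assert_allclose(norm, truth["normalized_percent"], atol=1e-6)

    def test_affine_example(self):
        # baseline ratio 1.0, plateau 2.0 -> a point at 1.7 reads 70%
        trace, _ = simulate_fret_trace(
            baseline_ratio=1.0, plateau_ratio=2.0, response_fraction=0.7, seed=0
        )
        norm = sm.fret_normalize(trace)
        mid = norm[trace.ligand_index + 5]
        assert mid == pytest.approx(70.0, abs=1e-9)

    def test_degenerate_plateau_rejected(self):
        trace, _ = simulate_fret_trace(
            baseline_ratio=2.0, plateau_ratio=2.0, response_fraction=0.5, seed=0
        )
        with pytest.raises(ValueError):
            sm.fret_normalize(trace)


class TestDoseResponse:
    def test_exact_recovery_on_noise_free_data(self):
        conc, resp = simulate_dose_response(0.0, 100.0, -8.0)
        fit = sm.fit_dose_response(conc, resp)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-6)
        assert fit.log_ec50 == pytest.approx(-8.0, abs=1e-6)

    def test_constant_response_flagged_degenerate(self):
        conc = np.logspace(-10, -6, 6)
        fit = sm.fit_dose_response(conc, np.full(6, 42.0))
        assert fit.degenerate

    def test_offset_equivariance(self):
        """Adding a constant shifts bottom/top, leaves logEC50 unchanged."""
        conc, resp = simulate_dose_response(5.0, 80.0, -7.5, noise_sd=2.0, seed=6)
        fit = sm.fit_dose_response(conc, resp)
        shifted = sm.fit_dose_response(conc, resp + 37.0)
        assert shifted.bottom == pytest.approx(fit.bottom + 37.0, abs=1e-4)
        assert shifted.top == pytest.approx(fit.top + 37.0, abs=1e-4)
        assert shifted.log_ec50 == pytest.approx(fit.log_ec50, abs=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            sm.fit_dose_response([1e-9, 1e-8, 1e-7], [1.0, 2.0, 3.0])


class TestESSFTest:
    def test_identical_curves_do_not_reject(self):
        conc, resp = simulate_dose_response(0.0, 100.0, -8.0, noise_sd=4.0, seed=9)
        _, _, test = sm.compare_dose_response(conc, resp, conc, resp, share="top")
        assert test.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert test.p_value == pytest.approx(1.0, abs=1e-6)

    def test_response_unit_invariance(self):
        c1, r1 = simulate_dose_response(0.0, 100.0, -8.0, noise_sd=4.0, seed=1)
        c2, r2 = simulate_dose_response(0.0, 70.0, -8.0, noise_sd=4.0, seed=2)
        _, _, t_raw = sm.compare_dose_response(c1, r1, c2, r2, share="top")
        _, _, t_scaled = sm.compare_dose_response(c1, 1000 * r1, c2, 1000 * r2, share="top")
        assert t_raw.f_statistic == pytest.approx(t_scaled.f_statistic, rel=1e-5)
        assert t_raw.p_value == pytest.approx(t_scaled.p_value, rel=1e-4)

    def test_power_at_five_sd_top_difference(self):
        """Tops 5 residual-SDs apart are detected at p < 0.001."""
        hits = 0
        n = 50
        for i in range(n):
            c1, r1 = simulate_dose_response(
                0.0, 100.0, -8.0, n_replicates=3, noise_sd=5.0, seed=3 * i
            )
            c2, r2 = simulate_dose_response(
                0.0, 125.0, -8.0, n_replicates=3, noise_sd=5.0, seed=3 * i + 1
            )
            _, _, t = sm.compare_dose_response(c1, r1, c2, r2, share="top")
            hits += t.p_value < 0.001
        assert hits >= 0.95 * n

    def test_nested_f_formula(self):
        test = sm.ess_f_test(ss_shared=120.0, df_shared=11, ss_separate=100.0,
                             df_separate=10)
        assert test.f_statistic == pytest.approx((20.0 / 1) / (100.0 / 10))
        assert test.df1 == 1 and test.df2 == 10


class TestQpcrEfficiency:
    def test_perfect_doubling(self):
        assert sm.qpcr_efficiency(-1.0 / np.log10(2.0)) == pytest.approx(100.0)

    def test_slope_minus_one(self):
        assert sm.qpcr_efficiency(-1.0) == pytest.approx(900.0)

    def test_steep_slope_limit(self):
        assert sm.qpcr_efficiency(-1e9) == pytest.approx(0.0, abs=1e-6)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            sm.qpcr_efficiency(0.0)
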