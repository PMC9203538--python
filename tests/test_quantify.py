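"""Gating, GMFI statistics, MESF calibration and the transfer metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synaptoquant.io import AntibodyPanel, EventTable
from synaptoquant.quantify import (
    CalibrationCurve,
    GateConfig,
    Geometry,
    correct_gmfi,
    density,
    fit_mesf,
    gate_singlets,
    gmfi,
    molecules_per_event,
    nst_percent,
    quantify_coculture,
    tmax_percent,
)
from synaptoquant.simulate import SimulationDesign, simulate_coculture

positive = st.floats(1e-3, 1e6, allow_nan=False)


class TestGmfi:
    def test_two_point_geometric_mean(self):
        assert gmfi([10, 1000]) == pytest.approx(100.0)

    def test_constant_vector_identity(self):
        assert gmfi([7.5, 7.5, 7.5]) == pytest.approx(7.5)

    def test_lognormal_sample_converges(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(np.log(500), 0.3, 10_000))
        assert gmfi(x) == pytest.approx(500.0, rel=0.02)

    def test_nonpositive_events_excluded_and_counted(self):
        value, excluded = gmfi([10.0, 1000.0, 0.0, -5.0], return_excluded=True)
        assert value == pytest.approx(100.0) and excluded == 2

    def test_no_positive_events_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            gmfi([0.0, -1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(positive, min_size=1, max_size=30))
    def test_matches_brute_force_log_mean(self, xs):
        """Oracle equivalence: gmfi equals exp(mean(log x)) computed directly."""
        brute = float(np.exp(sum(np.log(v) for v in xs) / len(xs)))
        assert gmfi(xs) == pytest.approx(brute, rel=1e-12)


class TestCorrectGmfi:
    @pytest.mark.parametrize("sample,control,expected,raw", [
        (500.0, 100.0, 400.0, 400.0),
        (80.0, 100.0, 0.0, -20.0),    # floored, raw difference kept
        (123.0, 0.0, 123.0, 123.0),   # null control
    ])
    def test_subtraction_with_floor(self, sample, control, expected, raw):
        cg, r = correct_gmfi(sample, control)
        assert cg == expected and r == raw

    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            correct_gmfi(-1.0, 0.0)
        with pytest.raises(ValueError):
            correct_gmfi(np.nan, 0.0)


class TestTransferMetrics:
    def test_nst_worked_examples(self):
        assert nst_percent(200, 600) == pytest.approx(25.0)
        assert nst_percent(5.0, 5.0) == pytest.approx(50.0)
        assert nst_percent(0.0, 42.0) == 0.0

    def test_nst_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            nst_percent(0.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(positive, positive)
    def test_nst_complementarity_and_scale_invariance(self, a, b):
        assert nst_percent(a, b) + nst_percent(b, a) == pytest.approx(100.0)
        assert nst_percent(3.7 * a, 3.7 * b) == pytest.approx(nst_percent(a, b))

    def test_tmax_examples(self):
        assert tmax_percent(50, 200) == pytest.approx(25.0)
        assert tmax_percent(200, 200) == pytest.approx(100.0)

    def test_tmax_monotone_in_series(self):
        series = [10.0, 40.0, 90.0, 200.0]
        out = [tmax_percent(v, max(series)) for v in series]
        assert out == sorted(out) and out[-1] == 100.0

    def test_tmax_requires_positive_reference(self):
        with pytest.raises(ValueError):
            tmax_percent(10.0, 0.0)

    def test_density_examples(self):
        geom = Geometry()
        assert geom.bead_surface_area_um2 == pytest.approx(78.54, abs=0.005)
        assert density(7854, geom.bead_surface_area_um2) == pytest.approx(100.0, rel=1e-3)
        assert density(82, geom.patch_area_um2) == pytest.approx(100.0)
        assert density(0, 1.0) == 0.0
        with pytest.raises(ValueError):
            density(-1, 1.0)


class TestCalibration:
    def test_exact_points_recover_slope_and_intercept(self):
        mesf = np.array([1e3, 1e4, 1e5, 1e6])
        curve = CalibrationCurve.from_points(mesf, 0.5 * mesf)
        assert curve.slope == pytest.approx(0.5)
        assert curve.intercept == 0.0
        assert curve.r_squared == pytest.approx(1.0)

    def test_free_intercept_mode_recovers_affine_line(self):
        mesf = np.array([1e3, 1e4, 1e5, 1e6])
        curve = CalibrationCurve.from_points(mesf, 0.5 * mesf + 20, through_origin=False)
        assert curve.slope == pytest.approx(0.5)
        assert curve.intercept == pytest.approx(20.0)

    def test_simulated_ladder_slope_within_2pct_of_gain(self, mesf_ladder, mesf_levels):
        curve = fit_mesf(mesf_ladder, mesf_levels)
        assert curve.slope == pytest.approx(0.5, rel=0.02)
        assert curve.r_squared > 0.999

    def test_single_level_refused(self, mesf_ladder):
        with pytest.raises(ValueError, match="two positive"):
            fit_mesf(mesf_ladder, [1e4])

    def test_negative_slope_is_calibration_failure(self):
        with pytest.raises(ValueError, match="calibration failure"):
            CalibrationCurve.from_points([1.0, 2.0], [10.0, 5.0], through_origin=False)

    def test_molecule_arithmetic(self):
        curve = CalibrationCurve(slope=0.5, intercept=0.0, r_squared=1.0,
                                 levels=(1e3, 1e6))
        assert molecules_per_event(5000.0, curve, f_over_p=2.0) == pytest.approx(5000.0)
        assert molecules_per_event(0.0, curve, f_over_p=2.0) == 0.0

    def test_below_intercept_floors_to_zero_with_warning(self):
        curve = CalibrationCurve(slope=0.5, intercept=10.0, r_squared=1.0,
                                 levels=(1e3, 1e6))
        with pytest.warns(UserWarning, match="extrapolat"):
            assert molecules_per_event(5.0, curve, 2.0) == 0.0


class TestGating:
    def test_label_recovery_without_doublets(self):
        """Well-separated modes: >=99% of simulator labels recovered."""
        design = SimulationDesign(doses=[0.0, 1000.0], n_events_per_population=5000,
                                  doublet_fraction=0.0, seed=13)
        events, _ = simulate_coculture(design)
        sel = (events.data.acquisition == "TH:dose=1000").to_numpy()
        block = events.subset(sel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gate = gate_singlets(block, GateConfig(min_events=1))
        agree = (gate.classes.to_numpy() == block.labels.to_numpy()).mean()
        assert agree >= 0.99

    def test_doublets_detected(self):
        design = SimulationDesign(doses=[0.0, 1000.0], n_events_per_population=5000,
                                  doublet_fraction=0.05, seed=14)
        events, _ = simulate_coculture(design)
        block = events.subset((events.data.acquisition == "CTL:dose=1000").to_numpy())
        gate = gate_singlets(block, GateConfig(min_events=1))
        truth = block.labels.to_numpy()
        found = gate.classes.to_numpy()
        doublet_recall = (found[truth == "doublet"] == "doublet").mean()
        assert doublet_recall > 0.9

    def test_all_debris_input_warns(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"LIPID": rng.lognormal(1, 0.3, 200),
                             "FSC": rng.lognormal(5, 0.3, 200),  # ~150, below floor
                             "SSC": rng.lognormal(5, 0.3, 200)})
        t = EventTable(data, ["LIPID"], ["FSC", "SSC"])
        with pytest.warns(UserWarning, match="debris"):
            gate = gate_singlets(t, GateConfig(min_events=1))
        assert (gate.classes == "debris").all()

    def test_manual_thresholds_reproduce_partition(self, small_coculture):
        events, _ = small_coculture
        block = events.subset((events.data.acquisition == "TH:dose=1000").to_numpy())
        config = GateConfig(lipid_threshold=500.0, doublet_fsc=25_000.0, min_events=1)
        a = gate_singlets(block, config)
        b = gate_singlets(block, config)
        assert (a.classes == b.classes).all()

    def test_acquisition_floor_warning(self, small_coculture):
        events, _ = small_coculture
        block = events.subset((events.data.acquisition == "TH:dose=1000").to_numpy())
        with pytest.warns(UserWarning, match="floor"):
            gate_singlets(block, GateConfig(min_events=50_000))


@pytest.fixture(scope="module")
def quantified(small_coculture, mesf_ladder, mesf_levels):
    events, truth = small_coculture
    curve = fit_mesf(mesf_ladder, mesf_levels)
    panel = AntibodyPanel()
    panel.add("CD40L", "AF647", 2.0)
    records = quantify_coculture(events, panel, curve,
                                 gate_config=GateConfig(min_events=1))
    return records, truth


class TestPipeline:
    def test_molecule_recovery_within_5pct(self, quantified):
        records, truth = quantified
        merged = records.merge(truth.conditions, on=["marker", "population", "dose"])
        at_dose = merged[merged.dose > 0]
        rel = (at_dose.molecules_per_BSLB - at_dose.molecules_bslb).abs() / at_dose.molecules_bslb
        assert rel.max() < 0.05

    def test_nst_recovery_within_2pp(self, quantified):
        records, truth = quantified
        merged = records.merge(truth.conditions, on=["marker", "population", "dose"],
                               suffixes=("_est", "_true"))
        err = (merged.nst_percent_est - merged.nst_percent_true).abs()
        assert err.max() < 2.0

    def test_tmax_is_100_at_series_maximum(self, quantified):
        records, _ = quantified
        for _, series in records.groupby(["marker", "population"]):
            assert series.tmax_percent.max() == pytest.approx(100.0)
            assert (series.tmax_percent <= 100.0 + 1e-9).all()

    def test_tmax_reference_must_be_declared(self, small_coculture, mesf_ladder,
                                             mesf_levels):
        events, _ = small_coculture
        curve = fit_mesf(mesf_ladder, mesf_levels)
        panel = AntibodyPanel()
        panel.add("CD40L", "AF647", 2.0)
        with pytest.raises(ValueError, match="declared"):
            quantify_coculture(events, panel, curve, tmax_reference=None)

    def test_noiseless_simulation_reproduces_truth_exactly(self):
        """The molecule map is the affine inverse of the generator's signal model."""
        design = SimulationDesign(doses=[0.0, 250.0, 1000.0],
                                  n_events_per_population=300, cv=1e-12,
                                  doublet_fraction=0.0, seed=21)
        events, truth = simulate_coculture(design)
        curve = CalibrationCurve(slope=design.gain, intercept=0.0, r_squared=1.0,
                                 levels=(1e3, 1e6))
        panel = AntibodyPanel()
        panel.add("CD40L", "AF647", design.markers["CD40L"].f_over_p)
        records = quantify_coculture(events, panel, curve,
                                     gate_config=GateConfig(min_events=1))
        merged = records.merge(truth.conditions, on=["marker", "population", "dose"])
        np.testing.assert_allclose(merged.molecules_per_BSLB, merged.molecules_bslb,
                                   rtol=1e-6, atol=1e-6)
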