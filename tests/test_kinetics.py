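"""Kinetic model fits: round trips, breakpoint search, model selection."""
import numpy as np
import pytest

from nanosorb import (
    KineticDataset,
    fit_elovich,
    fit_fractional_power,
    fit_intraparticle,
    fit_pseudo_first,
    fit_pseudo_second,
    pseudo_second_qt,
    select_kinetic_model,
)
from nanosorb.kinetics import fit_kinetic
from nanosorb.synthetic import gen_kinetics, intraparticle_qt

# sub-minute points are needed to sample the first diffusion stage of the
# published two-line parameter set, whose kink sits near t = 0.057 min
IPD_TIME_GRID = [0.01, 0.02, 0.03, 0.04, 0.05,
                 1, 3, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90]


class TestPseudoFirst:
    def test_noise_free_roundtrip_is_exact(self, kinetic_params, sampling_times):
        p = kinetic_params["pseudo_first"]
        data, _ = gen_kinetics("pseudo_first", p, sampling_times, 0.0)
        fit = fit_pseudo_first(data, qe_exp=p["qe"])
        assert fit.parameters["qe"] == pytest.approx(p["qe"], rel=1e-8)
        assert fit.parameters["k1"] == pytest.approx(p["k1"], rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_zero_uptake_gives_zero_rate(self, sampling_times):
        data = KineticDataset(t=tuple(sampling_times), qt=(0.0,) * sampling_times.size)
        fit = fit_pseudo_first(data, qe_exp=100.0)
        assert fit.parameters["k1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.parameters["qe"] == pytest.approx(100.0, rel=1e-12)

    def test_noisy_fit_equals_transformed_ols_oracle(self, kinetic_params, sampling_times):
        p = kinetic_params["pseudo_first"]
        data, _ = gen_kinetics("pseudo_first", p, sampling_times, 0.01, seed=13)
        fit = fit_pseudo_first(data, qe_exp=p["qe"] * 1.05)
        t, qt = data.t_array, data.qt_array
        y = np.log10(p["qe"] * 1.05 - qt)
        sxx = ((t - t.mean()) ** 2).sum()
        slope = ((t - t.mean()) * (y - y.mean())).sum() / sxx
        inter = y.mean() - slope * t.mean()
        assert fit.parameters["k1"] == pytest.approx(-np.log(10) * slope, rel=1e-12)
        assert fit.parameters["qe"] == pytest.approx(10**inter, rel=1e-12)

    def test_points_at_or_above_plateau_are_excluded(self, sampling_times):
        qt = 100.0 * (1 - np.exp(-0.05 * sampling_times))
        qt[-1] = 100.0  # at the plateau: log undefined
        data = KineticDataset(t=tuple(sampling_times), qt=tuple(qt))
        fit = fit_pseudo_first(data, qe_exp=100.0)
        assert fit.diagnostics["n_excluded"] == 1

    def test_requires_plateau_value(self, sampling_times):
        data = KineticDataset(t=(1.0, 2.0, 3.0), qt=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="qe_exp"):
            fit_pseudo_first(data)


class TestPseudoSecond:
    def test_noise_free_roundtrip_is_exact(self, kinetic_params, sampling_times):
        p = kinetic_params["pseudo_second"]
        data, _ = gen_kinetics("pseudo_second", p, sampling_times, 0.0)
        fit = fit_pseudo_second(data)
        assert fit.parameters["qe"] == pytest.approx(p["qe"], rel=1e-8)
        assert fit.parameters["k2"] == pytest.approx(p["k2"], rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_predictor_at_ten_minutes(self, kinetic_params):
        p = kinetic_params["pseudo_second"]
        # oracle: direct evaluation of qe^2 k2 t / (1 + qe k2 t)
        oracle = p["qe"] ** 2 * p["k2"] * 10.0 / (1.0 + p["qe"] * p["k2"] * 10.0)
        assert pseudo_second_qt(10.0, p["qe"], p["k2"]) == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(2965.4, abs=0.05)

    def test_three_point_slope_matches_hand_ols(self):
        t = np.array([1.0, 2.0, 4.0])
        qt = np.array([10.0, 18.0, 30.0])
        fit = fit_pseudo_second(KineticDataset(t=tuple(t), qt=tuple(qt)))
        y = t / qt
        sxx = ((t - t.mean()) ** 2).sum()
        slope = ((t - t.mean()) * (y - y.mean())).sum() / sxx
        assert 1.0 / fit.parameters["qe"] == pytest.approx(slope, rel=1e-12)

    def test_predictor_is_monotone_and_asymptotes_to_plateau(self, kinetic_params):
        p = kinetic_params["pseudo_second"]
        t = np.geomspace(1e-3, 1e6, 400)
        qt = pseudo_second_qt(t, p["qe"], p["k2"])
        assert np.all(np.diff(qt) > 0)
        assert qt[-1] == pytest.approx(p["qe"], rel=1e-3)
        assert np.all(qt < p["qe"])

    def test_zero_capacity_rejected(self):
        data = KineticDataset(t=(1.0, 2.0, 3.0), qt=(0.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="row 0"):
            fit_pseudo_second(data)


class TestIntraparticle:
    def test_two_segment_roundtrip_with_exact_breakpoint(self, kinetic_params):
        p = kinetic_params["intraparticle"]
        data, _ = gen_kinetics("intraparticle", p, IPD_TIME_GRID, 0.0)
        fit = fit_intraparticle(data, n_segments=2)
        for key in ("k1", "C1", "k2", "C2"):
            assert fit.parameters[key] == pytest.approx(p[key], rel=1e-8)
        # the kink sits at sqrt(t*) = (C2-C1)/(k1-k2); the fitted breakpoint
        # is the last sample time on the first line
        s_star = (p["C2"] - p["C1"]) / (p["k1"] - p["k2"])
        expected_bp = max(t for t in IPD_TIME_GRID if np.sqrt(t) <= s_star)
        assert fit.diagnostics["breakpoint_times"] == [pytest.approx(expected_bp)]

    def test_single_segment_recovers_plain_line(self, sampling_times):
        qt = 50.0 * np.sqrt(sampling_times) + 7.0
        data = KineticDataset(t=tuple(sampling_times), qt=tuple(qt))
        fit = fit_intraparticle(data, n_segments=1)
        assert fit.parameters["k1"] == pytest.approx(50.0, rel=1e-10)
        assert fit.parameters["C1"] == pytest.approx(7.0, rel=1e-10)

    def test_breakpoint_search_equals_full_enumeration(self, sampling_times):
        rng = np.random.default_rng(21)
        qt = intraparticle_qt(sampling_times, 900.0, 50.0, 80.0, 2500.0)
        qt = qt * np.exp(rng.normal(0, 0.02, qt.size))
        data = KineticDataset(t=tuple(sampling_times), qt=tuple(qt))
        fit = fit_intraparticle(data, n_segments=2)

        # independent enumeration over every admissible split
        s = np.sqrt(sampling_times)
        def sse_line(x, y):
            sxx = ((x - x.mean()) ** 2).sum()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
            inter = y.mean() - slope * x.mean()
            r = y - slope * x - inter
            return float(r @ r)
        best = min(
            (sse_line(s[:j], qt[:j]) + sse_line(s[j:], qt[j:]), sampling_times[j - 1])
            for j in range(3, sampling_times.size - 2)
        )
        assert fit.diagnostics["total_sse"] == pytest.approx(best[0], rel=1e-9)
        assert fit.diagnostics["breakpoint_times"][0] == pytest.approx(best[1])

    def test_two_segments_never_fit_worse_than_one(self, sampling_times):
        rng = np.random.default_rng(4)
        qt = 200.0 * np.sqrt(sampling_times) + 30.0 + rng.normal(0, 20.0, sampling_times.size)
        qt = np.abs(qt)
        data = KineticDataset(t=tuple(sampling_times), qt=tuple(qt))
        one = fit_intraparticle(data, n_segments=1)
        two = fit_intraparticle(data, n_segments=2)
        assert two.diagnostics["total_sse"] <= one.diagnostics["total_sse"] + 1e-9

    def test_too_few_points_for_requested_segments(self):
        data = KineticDataset(t=(1.0, 2.0, 3.0, 4.0, 5.0), qt=(1.0, 2.0, 3.0, 4.0, 5.0))
        with pytest.raises(ValueError, match="segment"):
            fit_intraparticle(data, n_segments=2)


class TestFractionalPowerAndElovich:
    def test_fractional_power_roundtrip(self, kinetic_params, sampling_times):
        p = kinetic_params["fractional_power"]
        data, _ = gen_kinetics("fractional_power", p, sampling_times, 0.0)
        fit = fit_fractional_power(data)
        assert fit.parameters["v"] == pytest.approx(p["v"], rel=1e-8)
        assert fit.parameters["KFP"] == pytest.approx(p["KFP"], rel=1e-8)
        assert fit.diagnostics["v_below_unity"]

    def test_constant_capacity_gives_zero_exponent(self, sampling_times):
        data = KineticDataset(t=tuple(sampling_times), qt=(55.0,) * sampling_times.size)
        fit = fit_fractional_power(data)
        assert fit.parameters["v"] == pytest.approx(0.0, abs=1e-12)

    def test_elovich_roundtrip_on_simplified_form(self, kinetic_params, sampling_times):
        p = kinetic_params["elovich"]
        data, _ = gen_kinetics("elovich_simplified", p, sampling_times, 0.0)
        fit = fit_elovich(data)
        assert fit.parameters["alpha"] == pytest.approx(p["alpha"], rel=1e-8)
        assert fit.parameters["beta"] == pytest.approx(p["beta"], rel=1e-8)
        assert fit.valid

    def test_elovich_three_point_slope_matches_hand_ols(self):
        t = np.array([1.0, 3.0, 9.0])
        qt = np.array([5.0, 9.0, 12.0])
        fit = fit_elovich(KineticDataset(t=tuple(t), qt=tuple(qt)))
        x = np.log(t)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (qt - qt.mean())).sum() / sxx
        assert 1.0 / fit.parameters["beta"] == pytest.approx(slope, rel=1e-12)
        assert fit.parameters["beta"] > 0  # qt increases with ln t

    def test_every_model_exact_on_own_noise_free_data(self, kinetic_params, sampling_times):
        cases = {
            "pseudo_first": ("pseudo_first", kinetic_params["pseudo_first"]),
            "pseudo_second": ("pseudo_second", kinetic_params["pseudo_second"]),
            "fractional_power": ("fractional_power", kinetic_params["fractional_power"]),
            "elovich": ("elovich_simplified", kinetic_params["elovich"]),
        }
        for fit_model, (gen_model, p) in cases.items():
            data, _ = gen_kinetics(gen_model, p, sampling_times, 0.0)
            fit = fit_kinetic(data, fit_model, qe_exp=p.get("qe"))
            for key, val in p.items():
                assert fit.parameters[key] == pytest.approx(val, rel=1e-6), fit_model
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestSelection:
    def test_pseudo_second_data_ranks_pseudo_second_first_unflagged(
        self, kinetic_params, sampling_times
    ):
        p = kinetic_params["pseudo_second"]
        data, _ = gen_kinetics("pseudo_second", p, sampling_times, 0.0)
        fits = [
            fit_kinetic(data, m, qe_exp=p["qe"])
            for m in ("pseudo_first", "pseudo_second", "fractional_power", "elovich")
        ]
        report = select_kinetic_model(fits, qe_exp=p["qe"])
        assert report[0].model_name == "pseudo_second"
        assert not report[0].rejected

    def test_pseudo_first_rejected_when_capacity_disagrees(
        self, kinetic_params, sampling_times
    ):
        # fitted plateau 2290 vs experimental 3900: a 41% deviation
        p = kinetic_params["pseudo_first"]
        data, _ = gen_kinetics("pseudo_first", p, sampling_times, 0.0)
        fit = fit_pseudo_first(data, qe_exp=p["qe"])
        [entry] = select_kinetic_model([fit], qe_exp=3900.0)
        assert entry.qe_relative_deviation == pytest.approx(
            abs(2290.0 - 3900.0) / 3900.0, rel=1e-4)
        assert entry.rejected

    def test_empty_fit_list_gives_empty_report(self):
        assert select_kinetic_model([], qe_exp=3900.0) == []
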