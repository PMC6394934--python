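import numpy as np
import pytest
from hypothesis import given, strategies as st

from pupyscreen import simulate as sim
from pupyscreen.quant import (
    InjectionError,
    calibrate_from_series,
    carryover_check,
    fit_calibration,
    integrate_peak,
    quantify,
    quantify_sample,
)


def _gauss_trace(height=1e6, sigma=0.05, rt=5.0, noise_sd=0.0, seed=0, analyte="X"):
    times = np.arange(0.0, 10.0, 0.005)
    y = height * np.exp(-0.5 * ((times - rt) / sigma) ** 2)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, times.size)
    return sim.ChromatogramTrace(
        sample_label="t", analyte=analyte, channel_role="quantifier",
        esi_mode="positive", times=times, intensities=np.clip(y, 0, None),
    )


class TestIntegratePeak:
    def test_noiseless_gaussian_area(self):
        peak = integrate_peak(_gauss_trace(height=1e6, sigma=0.05), 5.0)
        assert peak.found
        assert peak.area == pytest.approx(1e6 * 0.05 * np.sqrt(2 * np.pi), rel=5e-3)

    def test_noiseless_gaussian_fwhm(self):
        peak = integrate_peak(_gauss_trace(sigma=0.05), 5.0)
        assert peak.width_at_half_height == pytest.approx(2.3548 * 0.05, rel=0.01)

    def test_flat_zero_not_found(self):
        peak = integrate_peak(_gauss_trace(height=0.0), 5.0)
        assert not peak.found
        assert peak.area == 0.0

    def test_empty_trace_rejected(self):
        tr = sim.ChromatogramTrace("t", "X", "quantifier", "positive",
                                   np.array([]), np.array([]))
        with pytest.raises(ValueError):
            integrate_peak(tr, 5.0)

    def test_window_outside_range_rejected(self):
        with pytest.raises(ValueError):
            integrate_peak(_gauss_trace(), 50.0)

    def test_small_peak_under_noise_not_found(self):
        peak = integrate_peak(_gauss_trace(height=100.0, noise_sd=200.0, seed=3), 5.0)
        assert not peak.found

    def test_snr_scales_with_height(self):
        p1 = integrate_peak(_gauss_trace(height=1e5, noise_sd=100.0, seed=4), 5.0)
        p2 = integrate_peak(_gauss_trace(height=2e5, noise_sd=100.0, seed=4), 5.0)
        assert p2.snr == pytest.approx(2 * p1.snr, rel=0.05)

    def test_retention_time_recovered(self):
        peak = integrate_peak(_gauss_trace(rt=4.321), 4.3)
        assert peak.retention_time == pytest.approx(4.321, abs=0.003)


class TestFitCalibration:
    def test_perfect_proportionality(self):
        levels = [(c, 0.04 * c) for c in (1, 2, 4, 8, 16)]
        fit = fit_calibration(levels)
        assert fit.slope == pytest.approx(0.04)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_printed_series_with_two_percent_noise(self):
        rng = np.random.default_rng(7)
        levels = [
            (c, 0.04 * c * (1 + 0.02 * rng.standard_normal()))
            for c in sim.CALIBRATOR_NOMINALS_UM
        ]
        fit = fit_calibration(levels)
        assert fit.r_squared > 0.99

    def test_blank_level_excluded(self):
        levels = [(0.0, 123.0)] + [(c, 0.04 * c) for c in (1, 2, 4)]
        fit = fit_calibration(levels)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.level_range_used == (1.0, 4.0)

    def test_saturation_lowers_r_squared(self):
        linear = [(c, 0.04 * c) for c in (1, 2, 4, 8, 16, 32, 64, 128, 256)]
        saturated = [(c, r) for c, r in linear[:-1]] + [(256.0, 0.6 * 0.04 * 256)]
        assert fit_calibration(saturated).r_squared < fit_calibration(linear).r_squared

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 0.1), (2.0, 0.2)])

    def test_identical_responses(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 0.5), (2.0, 0.5), (4.0, 0.5)])

    def test_weighting_option(self):
        rng = np.random.default_rng(0)
        levels = [(c, 0.04 * c * (1 + 0.05 * rng.standard_normal())) for c in
                  (1, 2, 4, 8, 16, 32, 64, 128, 256)]
        fit = fit_calibration(levels, weighting="1/x")
        assert fit.weighting == "1/x"
        assert fit.slope == pytest.approx(0.04, rel=0.1)

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_r_squared_affine_invariant(self, scale, shift):
        rng = np.random.default_rng(12)
        base = [(c, 0.04 * c + 0.01 * rng.standard_normal()) for c in
                (1.0, 2.0, 4.0, 8.0, 16.0)]
        rescaled = [(c, scale * r + shift) for c, r in base]
        assert fit_calibration(rescaled).r_squared == pytest.approx(
            fit_calibration(base).r_squared, rel=1e-9
        )


class TestQuantify:
    def _fit(self):
        return fit_calibration([(c, 0.04 * c) for c in (1, 2, 4, 8, 16)])

    def _peak(self, area, found=True):
        from pupyscreen.quant import PeakResult

        return PeakResult(
            analyte="X", channel_role="quantifier", retention_time=5.0,
            height=area / 0.125, area=area, width_at_half_height=0.118,
            noise_sd=1.0, snr=100.0, found=found,
        )

    def test_inversion(self):
        fit = self._fit()
        readout = quantify(self._peak(0.04 * 16 * 100), self._peak(100.0), fit)
        assert readout.value_um == pytest.approx(16.0)

    def test_missing_analyte_below_lod(self):
        readout = quantify(self._peak(0, found=False), self._peak(100.0), self._fit())
        assert readout.value_um == 0.0
        assert readout.below_lod

    def test_missing_is_raises(self):
        with pytest.raises(InjectionError):
            quantify(self._peak(10.0), self._peak(0, found=False), self._fit())

    def test_ratio_invariance_under_intensity_scaling(self, registry):
        series = sim.generate_calibrator_series(registry, analytes=["SAICAr"])
        fits = calibrate_from_series(series, registry)
        design = sim.RunDesign("s", {"SAICAr": 16.0})
        traces = sim.generate_chromatogram(design, registry)
        doubled = [
            sim.ChromatogramTrace(
                tr.sample_label, tr.analyte, tr.channel_role, tr.esi_mode,
                tr.times, 2.0 * tr.intensities,
            )
            for tr in traces
        ]
        r1 = quantify_sample(traces, registry, fits)[0]["readout_uM"]
        r2 = quantify_sample(doubled, registry, fits)[0]["readout_uM"]
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestRoundTrip:
    def test_cal06_round_trip(self, registry):
        series = sim.generate_calibrator_series(registry, analytes=["Uracil"])
        fits = calibrate_from_series(series, registry)
        design = sim.RunDesign("Cal06-check", {"Uracil": 16.0})
        traces = sim.generate_chromatogram(design, registry)
        rec = quantify_sample(traces, registry, fits)[0]
        assert rec["readout_uM"] == pytest.approx(16.0, abs=0.2)

    def test_round_trip_across_range(self, registry):
        # noiseless round trip within 1% for c in [1, 256]
        series = sim.generate_calibrator_series(registry, analytes=["SAICAr"])
        fits = calibrate_from_series(series, registry)
        for conc in (1.0, 4.0, 16.0, 64.0, 256.0):
            traces = sim.generate_chromatogram(
                sim.RunDesign("rt", {"SAICAr": conc}), registry
            )
            rec = quantify_sample(traces, registry, fits)[0]
            assert rec["readout_uM"] == pytest.approx(conc, rel=0.01)

    def test_round_trip_every_analyte(self, registry):
        series = sim.generate_calibrator_series(registry)
        fits = calibrate_from_series(series, registry)
        assert set(fits) == set(registry.measured_analytes)
        design = sim.RunDesign(
            "all16", {a: 16.0 for a in registry.measured_analytes}
        )
        traces = sim.generate_chromatogram(design, registry)
        for rec in quantify_sample(traces, registry, fits):
            assert rec["readout_uM"] == pytest.approx(16.0, rel=0.01), rec["analyte"]


class TestCarryover:
    def test_generated_blank_passes(self, registry):
        design = sim.RunDesign(
            "blank", {a: 0.0 for a in registry.measured_analytes},
            noise_sd=100.0, seed=2,
        )
        traces = sim.generate_chromatogram(design, registry)
        results = carryover_check(traces, registry)
        assert len(results) == 26
        assert all(results.values())

    def test_spiked_blank_fails_for_uracil(self, registry):
        design = sim.RunDesign(
            "blank", {a: 0.0 for a in registry.measured_analytes},
            noise_sd=100.0, seed=2,
        )
        traces = sim.generate_chromatogram(design, registry)
        rt = registry.analytes["Uracil"].retention_time
        for tr in traces:
            if tr.analyte == "Uracil" and tr.channel_role == "quantifier":
                tr.intensities = tr.intensities + 1000.0 * np.exp(
                    -0.5 * ((tr.times - rt) / 0.05) ** 2
                )
        results = carryover_check(traces, registry)
        assert not results["Uracil"]
        assert all(v for a, v in results.items() if a != "Uracil")

    def test_empty_panel_vacuous_pass(self, registry):
        assert carryover_check([], registry) == {}
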