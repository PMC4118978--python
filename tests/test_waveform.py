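"""Feature extraction: onset detection, peak-to-peak, rectified area."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blinkreflex.cohort import RenderConfig, _render_trace
from blinkreflex.records import ResponseMeasure
from blinkreflex.waveform import (
    EmgTrace,
    MeasurementConfig,
    SearchWindow,
    detect_onset,
    measure_trial,
    peak_to_peak,
    rectified_area,
)

FS = 5000.0


def make_trace(samples, side="right", site="supraorbital_right", t0=125):
    return EmgTrace(np.asarray(samples, float), FS, t0, side, site)


def flat_trace(n=926, value=0.0, **kw):
    return make_trace(np.full(n, value), **kw)


def noise_trace(rng, sd=1.5, n=926, **kw):
    return make_trace(rng.normal(0, sd, n), **kw)


def burst_trace(rng, latency_ms, component="R2", area=3000.0, amplitude=None, sd=1.5):
    """Render a single-component trace through the waveform synthesiser."""
    m = ResponseMeasure(
        component,
        "right",
        "right" if component != "R2c" else "left",
        latency_ms,
        area,
        amplitude,
        present=True,
        trial=1,
    )
    cfg = RenderConfig(noise_sd=sd)
    return _render_trace(
        [m], m.rec_side, "supraorbital_right", cfg, rng
    )


class TestPeakToPeak:
    def test_constant_zero_signal(self):
        assert peak_to_peak(flat_trace(), SearchWindow("R2", 25, 87)) == 0.0

    def test_two_extremes(self):
        samples = np.zeros(926)
        samples[300] = 50.0
        samples[320] = -30.0
        assert peak_to_peak(make_trace(samples), SearchWindow("R2", 25, 87)) == 80.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        trace = noise_trace(rng, sd=20)
        window = SearchWindow("R2", 25, 87)
        i0, i1 = trace.index_at(25), trace.index_at(87)
        brute = max(trace.samples[i0 : i1 + 1]) - min(trace.samples[i0 : i1 + 1])
        assert peak_to_peak(trace, window) == pytest.approx(brute)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_to_peak(flat_trace(), SearchWindow("R2", 200, 300))


class TestRectifiedArea:
    def test_constant_positive(self):
        trace = flat_trace(value=1.0)
        assert rectified_area(trace, SearchWindow("R2", 30, 40)) == pytest.approx(
            10.0
        )

    def test_constant_negative_is_rectified(self):
        trace = flat_trace(value=-2.0)
        assert rectified_area(trace, SearchWindow("R2", 30, 35)) == pytest.approx(
            10.0
        )

    def test_matches_oversampled_riemann_sum(self):
        rng = np.random.default_rng(1)
        # smooth band-limited signal so 10x oversampling converges
        t = np.arange(926) / FS
        samples = 50 * np.sin(2 * np.pi * 80 * t) + 20 * np.cos(2 * np.pi * 33 * t)
        trace = make_trace(samples)
        window = SearchWindow("R2", 25, 87)
        t10 = np.arange(926 * 10) / (FS * 10)
        dense = np.abs(
            50 * np.sin(2 * np.pi * 80 * t10) + 20 * np.cos(2 * np.pi * 33 * t10)
        )
        lo = int(round((trace.t0_index / FS + 0.025) * FS * 10))
        hi = int(round((trace.t0_index / FS + 0.087) * FS * 10))
        riemann = dense[lo:hi].sum() * (1000.0 / (FS * 10))
        assert rectified_area(trace, window) == pytest.approx(riemann, rel=1e-3)

    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 100))
    def test_scale_equivariant_and_additive(self, scale, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(0, 5, 926)
        t_full = SearchWindow("R2", 25, 87)
        t_a = SearchWindow("R2", 25, 50)
        t_b = SearchWindow("R2", 50, 87)
        trace = make_trace(samples)
        scaled = make_trace(samples * scale)
        a_full = rectified_area(trace, t_full)
        assert a_full >= 0
        assert rectified_area(scaled, t_full) == pytest.approx(
            scale * a_full, rel=1e-9
        )
        assert rectified_area(trace, t_a) + rectified_area(
            trace, t_b
        ) == pytest.approx(a_full, rel=1e-9)


class TestDetectOnset:
    def test_flat_noise_has_no_onset(self):
        rng = np.random.default_rng(2)
        assert detect_onset(noise_trace(rng), SearchWindow("R2", 25, 87)) is None

    def test_burst_at_34ms_snr10_detected_within_1ms(self):
        # tolerance swept over 100 seeded noise realisations at SNR 10
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sd = 1.5
            n = 926
            samples = rng.normal(0, sd, n)
            t = np.arange(n) / FS
            onset = 125 / FS + 0.034
            ramp = 0.001
            dur = 0.035
            tau = t - onset
            env = np.clip(tau / ramp, 0, 1) * np.clip((dur - tau) / ramp, 0, 1)
            env = np.minimum(env, 1.0) * (tau >= 0) * (tau <= dur)
            samples += 10 * sd * env * np.cos(2 * np.pi * 120 * tau)
            trace = make_trace(samples)
            lat = detect_onset(trace, SearchWindow("R2", 25, 87))
            assert lat is not None
            errors.append(lat - 34.0)
        assert max(abs(e) for e in errors) <= 1.0

    def test_r1_burst_at_12p5ms(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trace = burst_trace(rng, 12.5, "R1", area=0.0, amplitude=160.0)
            lat = detect_onset(trace, SearchWindow("R1", 8, 18))
            assert lat == pytest.approx(12.5, abs=0.6)

    def test_translation_equivariance(self):
        """Shifting the burst shifts the latency by the same amount."""
        rng = np.random.default_rng(3)
        sd = 1.5
        noise = rng.normal(0, sd, 926)
        lats = []
        for shift_ms in (0.0, 6.0):
            samples = noise.copy()
            t = np.arange(926) / FS
            tau = t - (125 / FS + (40.0 + shift_ms) / 1000)
            env = (tau >= 0) * (tau <= 0.030)
            samples += 40 * env * np.cos(2 * np.pi * 120 * tau)
            lats.append(detect_onset(make_trace(samples), SearchWindow("R2", 25, 87)))
        assert lats[1] - lats[0] == pytest.approx(6.0, abs=0.2001)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(flat_trace(n=400), SearchWindow("SBR", 35, 110))


class TestMeasureTrial:
    def _healthy_traces(self, rng):
        cfg = RenderConfig()
        ipsi = [
            ResponseMeasure("R1", "right", "right", 10.5, 410.0, 165.0, trial=1),
            ResponseMeasure("R2", "right", "right", 33.0, 4500.0, None, trial=1),
        ]
        contra = [
            ResponseMeasure("R2c", "right", "left", 34.0, 3600.0, None, trial=1)
        ]
        return {
            "right": _render_trace(ipsi, "right", "supraorbital_right", cfg, rng),
            "left": _render_trace(contra, "left", "supraorbital_right", cfg, rng),
        }

    def test_supraorbital_trial_yields_three_present_measures(self):
        rng = np.random.default_rng(4)
        measures = measure_trial(self._healthy_traces(rng), "supraorbital_right")
        assert {m.component for m in measures} == {"R1", "R2", "R2c"}
        assert all(m.present for m in measures)
        by_comp = {m.component: m for m in measures}
        assert by_comp["R1"].rec_side == "right"
        assert by_comp["R2c"].rec_side == "left"

    def test_absent_contralateral_response_scored_zero_area(self):
        rng = np.random.default_rng(5)
        traces = self._healthy_traces(rng)
        traces["left"] = noise_trace(rng, side="left")
        measures = measure_trial(traces, "supraorbital_right")
        r2c = next(m for m in measures if m.component == "R2c")
        assert not r2c.present
        assert r2c.latency_ms is None
        assert r2c.area_uVms == 0.0

    def test_missing_contralateral_trace_is_an_error(self):
        rng = np.random.default_rng(6)
        traces = self._healthy_traces(rng)
        del traces["left"]
        with pytest.raises(ValueError, match="both OOc sides"):
            measure_trial(traces, "supraorbital_right")

    def test_mirrored_traces_give_side_swapped_measures(self):
        rng = np.random.default_rng(7)
        traces = self._healthy_traces(rng)
        mirrored = {
            "left": EmgTrace(
                traces["right"].samples, FS, 125, "left", "supraorbital_left"
            ),
            "right": EmgTrace(
                traces["left"].samples, FS, 125, "right", "supraorbital_left"
            ),
        }
        orig = measure_trial(traces, "supraorbital_right")
        mirr = measure_trial(mirrored, "supraorbital_left")
        orig_by = {m.component: m for m in orig}
        mirr_by = {m.component: m for m in mirr}
        for comp in ("R1", "R2", "R2c"):
            assert mirr_by[comp].rec_side != orig_by[comp].rec_side
            assert mirr_by[comp].latency_ms == pytest.approx(
                orig_by[comp].latency_ms
            )
            assert mirr_by[comp].area_uVms == pytest.approx(
                orig_by[comp].area_uVms
            )

    def test_median_trial_yields_sbr_only(self):
        rng = np.random.default_rng(8)
        cfg = RenderConfig()
        sbr = [ResponseMeasure("SBR", "left", "left", 55.0, 1700.0, None, trial=1)]
        traces = {"left": _render_trace(sbr, "left", "median_left", cfg, rng)}
        measures = measure_trial(traces, "median_left")
        assert len(measures) == 1
        assert measures[0].component == "SBR"
        assert measures[0].present
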