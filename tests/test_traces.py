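"""Trace normalization, EMD detrending, binarization and response metrics."""

import numpy as np
import pytest

from isletmap.traces import (
    BinaryRaster,
    FluorescenceTraceSet,
    NormalizedTraceSet,
    StimEpoch,
    binarize_activity,
    detrend_denoise,
    normalize_traces,
    response_metrics,
)

FR = 20.0


def _nts(values, epochs=()):
    return NormalizedTraceSet(values=np.atleast_2d(values), frame_rate_hz=FR, epochs=list(epochs))


class TestNormalization:
    def test_constant_trace_maps_to_one(self):
        raw = FluorescenceTraceSet(values=np.full((1, 200), 3.7), frame_rate_hz=FR)
        out = normalize_traces(raw, "f_over_fmin")
        assert np.allclose(out.values, 1.0)

    def test_ratiometric_quotient(self):
        raw = FluorescenceTraceSet(values=np.full((2, 50), 2.0), frame_rate_hz=FR)
        out = normalize_traces(raw, "fura_340_385", channel_b=np.full((2, 50), 1.0))
        assert np.allclose(out.values, 2.0)

    def test_plateau_normalized_against_baseline_fmin(self):
        """Baseline 1.0 then plateau 2.4; F_min from the baseline epoch."""
        vals = np.concatenate([np.full(100, 1.0), np.full(100, 2.4)])
        raw = FluorescenceTraceSet(
            values=vals[None, :],
            frame_rate_hz=FR,
            epochs=[StimEpoch("baseline", 0.0, 5.0), StimEpoch("glucose", 5.0, 10.0, 0.5)],
        )
        out = normalize_traces(raw, "f_over_fmin")
        assert out.f_min[0] == pytest.approx(1.0)
        assert out.values[0, -1] == pytest.approx(2.4)

    def test_nonpositive_fmin_names_offending_cell(self):
        vals = np.vstack([np.full(50, 1.0), np.full(50, -0.5)])
        raw = FluorescenceTraceSet(values=vals, frame_rate_hz=FR)
        with pytest.raises(ValueError, match="cell001"):
            normalize_traces(raw, "f_over_fmin")

    def test_zero_denominator_rejected(self):
        raw = FluorescenceTraceSet(values=np.ones((1, 50)), frame_rate_hz=FR)
        with pytest.raises(ValueError, match="zero denominator"):
            normalize_traces(raw, "fura_340_385", channel_b=np.zeros((1, 50)))


class TestDetrendDenoise:
    def test_clean_burst_train_preserved(self):
        t = np.arange(0, 120, 1 / FR)
        x = np.zeros_like(t)
        for k in range(10):
            x[120 + k * 230 : 170 + k * 230] = 1.0
        out = detrend_denoise(_nts(x)).values[0]
        assert np.corrcoef(out, x)[0, 1] > 0.95

    def test_ramp_only_input_removed(self):
        ramp = np.linspace(0.0, 1.0, 2400)
        out = detrend_denoise(_nts(ramp)).values[0]
        assert np.max(np.abs(out)) < 0.05  # < 5% of the ramp range

    def test_zero_trace_passes_through(self):
        out = detrend_denoise(_nts(np.zeros(500))).values
        assert np.allclose(out, 0.0)

    def test_idempotent_in_noiseless_limit(self):
        t = np.arange(0, 120, 1 / FR)
        x = np.sin(2 * np.pi * t / 15.0)
        once = detrend_denoise(_nts(x))
        twice = detrend_denoise(once)
        delta = np.abs(twice.values - once.values).max()
        assert delta < 0.01 * np.ptp(once.values)


class TestBinarization:
    def test_flat_trace_all_off(self):
        ras = binarize_activity(_nts(np.full(100, 2.0)))
        assert not ras.states.any()

    def test_square_wave_duty_cycle_exact(self):
        x = np.zeros(1000)
        x[:300] = 1.0  # 30% duty
        ras = binarize_activity(_nts(x), threshold_fraction=0.20)
        assert ras.on_fraction()[0] == 0.30

    @pytest.mark.parametrize("duty", [0.1, 0.25, 0.45])
    @pytest.mark.parametrize("thr", [0.05, 0.5, 0.95])
    def test_duty_cycle_exact_for_any_interior_threshold(self, duty, thr):
        """ON fraction equals duty for noiseless square waves (duty < 50%)."""
        n = 1000
        x = np.zeros(n)
        x[: int(duty * n)] = 1.0
        ras = binarize_activity(_nts(x), threshold_fraction=thr)
        assert ras.on_fraction()[0] == pytest.approx(duty)

    def test_zero_threshold_marks_everything_above_min(self):
        x = np.zeros(1000)
        x[:300] = 1.0
        ras = binarize_activity(_nts(x), threshold_fraction=0.0)
        assert np.array_equal(ras.states[0], (x > x.min()).astype(np.uint8))

    def test_entries_strictly_binary(self, rng):
        ras = binarize_activity(_nts(rng.standard_normal(400)))
        assert set(np.unique(ras.states)) <= {0, 1}


class TestResponseMetrics:
    EPOCHS = [StimEpoch("baseline", 0.0, 30.0), StimEpoch("glucose", 30.0, 90.0, 0.5)]

    def test_amplitude_is_mean_difference(self):
        vals = np.concatenate([np.full(600, 1.0), np.full(1200, 2.0)])
        nts = _nts(vals, self.EPOCHS)
        ras = BinaryRaster(states=np.zeros((1, 1800), int), frame_rate_hz=FR)
        m = response_metrics(nts, ras, self.EPOCHS)
        assert m.amplitude[0] == pytest.approx(1.0)

    def test_pulse_duration_and_frequency_hand_count(self):
        """Three 2-s ON runs in a 60-s stimulus: duration 2 s, 0.05 Hz."""
        states = np.zeros((1, 1800), int)
        for start in (700, 900, 1100):
            states[0, start : start + 40] = 1  # 40 frames = 2 s
        nts = _nts(np.zeros(1800), self.EPOCHS)
        ras = BinaryRaster(states=states, frame_rate_hz=FR)
        m = response_metrics(nts, ras, self.EPOCHS)
        assert m.pulse_duration_s[0] == pytest.approx(2.0)
        assert m.oscillation_frequency_hz[0] == pytest.approx(0.05)

    def test_noise_only_rarely_responsive(self):
        """With stimulus statistically identical to baseline, >= 95% of cells
        are called non-responsive across seeds."""
        flags = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            vals = 1.0 + 0.1 * r.standard_normal((40, 1800))
            nts = _nts(vals, self.EPOCHS)
            ras = BinaryRaster(states=np.zeros_like(vals, int), frame_rate_hz=FR)
            m = response_metrics(nts, ras, self.EPOCHS)
            flags.append(m.responsive)
        assert np.mean(np.concatenate(flags)) < 0.05

    def test_missing_epoch_is_configuration_error(self):
        nts = _nts(np.zeros(100), [StimEpoch("baseline", 0.0, 5.0)])
        ras = BinaryRaster(states=np.zeros((1, 100), int), frame_rate_hz=FR)
        with pytest.raises(ValueError, match="glucose"):
            response_metrics(nts, ras)


class TestContainers:
    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            StimEpoch("espresso", 0, 10)
        with pytest.raises(ValueError):
            StimEpoch("baseline", 10, 5)
        with pytest.raises(ValueError, match="overlap"):
            FluorescenceTraceSet(
                values=np.zeros((1, 100)),
                frame_rate_hz=FR,
                epochs=[StimEpoch("baseline", 0, 10), StimEpoch("glucose", 5, 20)],
            )

    def test_trace_csv_round_trip(self, tmp_path, small_islet):
        path = tmp_path / "traces.csv"
        small_islet.traces.to_csv(path)
        back = FluorescenceTraceSet.from_csv(path)
        assert back.frame_rate_hz == pytest.approx(FR, rel=1e-6)
        np.testing.assert_allclose(back.values, small_islet.traces.values, rtol=1e-6)
        np.testing.assert_allclose(back.coords, small_islet.traces.coords, rtol=1e-6)

    def test_raster_rejects_non_binary(self):
        with pytest.raises(ValueError):
            BinaryRaster(states=np.array([[0, 1, 2]]), frame_rate_hz=FR)
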