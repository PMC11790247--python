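"""Current-clamp synthesis and AP/passive feature extraction."""

import numpy as np
import pytest

from aismorph import ephys_features as ef
from aismorph import synthetic
from aismorph.errors import FeatureFailure
from aismorph.synthetic import (EphysTraceSpec, MembraneModel, StepProtocol,
                                generate_ephys_traces)


@pytest.fixture(scope="module")
def sweepset():
    return generate_ephys_traces(EphysTraceSpec(), seed=0)


def insert_template_train(times_ms, total_ms=500.0, rate_khz=20.0,
                          rest=-65.0, thr=-45.0, amp=85.0, hw=1.0):
    """Hand-built sweep: AP templates at known onsets, each preceded by a
    slow (sub-criterion) depolarizing ramp from rest to threshold."""
    dt = 1.0 / rate_khz
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, rest)
    dur = synthetic.ap_template_duration_ms(hw)
    ramp_ms = 5.0  # (thr - rest)/ramp = 4 mV/ms, below the 20 mV/ms criterion
    for t0 in times_ms:
        ramp = (t >= t0 - ramp_ms) & (t < t0)
        v[ramp] = rest + (thr - rest) * (t[ramp] - (t0 - ramp_ms)) / ramp_ms
        sel = (t >= t0) & (t < t0 + dur)
        v[sel] = synthetic._ap_template_values(t[sel] - t0, thr, amp, hw)
    return ef.Sweep(100.0, t, v)


class TestDetectAPs:
    def test_subthreshold_sweep_empty(self, sweepset):
        sub = [s for s in sweepset.sweeps if s.current_pa == 100.0][0]
        assert ef.detect_aps(sub).peak_times_ms.size == 0

    def test_template_train_detected_at_known_times(self):
        times = [60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 420.0]
        sweep = insert_template_train(times)
        det = ef.detect_aps(sweep)
        assert det.peak_indices.size == 7
        # peak occurs half a half-width after template onset
        expected = np.asarray(times) + 0.5
        assert np.max(np.abs(det.peak_times_ms - expected)) <= sweep.dt_ms

    def test_truncated_ap_excluded_and_flagged(self):
        sweep = insert_template_train([499.2])  # rise cut off by sweep end
        det = ef.detect_aps(sweep)
        assert det.peak_indices.size == 0
        assert det.excluded_truncated == 1
        assert "truncated-ap-excluded" in det.flags


class TestAPFeatures:
    def test_amplitude_and_threshold_with_quantization_bound(self):
        sweep = insert_template_train([100.0])
        det = ef.detect_aps(sweep)
        f = ef.ap_features(sweep, int(det.peak_indices[0]))
        # worst-case quantization: the voltage climbed within one sample
        one_sample_rise = 85.0 * np.sin(np.pi * sweep.dt_ms / 1.0)
        assert abs(f.amplitude - 85.0) <= one_sample_rise
        assert abs(f.threshold - (-45.0)) <= one_sample_rise
        assert f.threshold + f.amplitude == pytest.approx(
            sweep.voltage_mv[det.peak_indices[0]])

    def test_half_width_within_one_sample(self):
        sweep = insert_template_train([100.0])
        det = ef.detect_aps(sweep)
        f = ef.ap_features(sweep, int(det.peak_indices[0]))
        assert abs(f.half_width - 1.0) <= sweep.dt_ms

    def test_generator_roundtrip_half_width(self, sweepset):
        spiking = [s for s in sweepset.sweeps if s.current_pa >= 150.0][0]
        det = ef.detect_aps(spiking)
        idx = ef.first_ap_for_waveform(spiking, det, sweepset.step_onset_ms)
        assert idx is not None
        f = ef.ap_features(spiking, idx)
        assert abs(f.half_width - 1.0) <= spiking.dt_ms
        assert f.max_rise > 100.0

    def test_flat_sweep_fails(self):
        t = np.arange(0.0, 100.0, 0.05)
        sweep = ef.Sweep(0.0, t, np.full_like(t, -65.0))
        with pytest.raises(FeatureFailure):
            ef.ap_features(sweep, 1000)

    def test_dc_offset_shifts_threshold_only(self):
        sweep = insert_template_train([100.0])
        det = ef.detect_aps(sweep)
        f0 = ef.ap_features(sweep, int(det.peak_indices[0]))
        shifted = ef.Sweep(sweep.current_pa, sweep.time_ms,
                           sweep.voltage_mv + 7.0)
        det2 = ef.detect_aps(shifted)
        f1 = ef.ap_features(shifted, int(det2.peak_indices[0]))
        assert f1.threshold == pytest.approx(f0.threshold + 7.0)
        assert f1.amplitude == pytest.approx(f0.amplitude)
        assert f1.half_width == pytest.approx(f0.half_width)
        assert f1.max_rise == pytest.approx(f0.max_rise)


class TestRheobaseAndFI:
    def test_rheobase_quantized_to_first_spiking_step(self, sweepset):
        rheo, flags = ef.rheobase(sweepset)
        # model rheobase 133 pA -> first 25 pA step strictly above is 150
        assert rheo == 150.0
        assert flags == ()

    def test_rheobase_not_reached(self):
        spec = EphysTraceSpec(model=MembraneModel(threshold_mv=0.0))
        sweeps = generate_ephys_traces(spec, seed=0)
        rheo, flags = ef.rheobase(sweeps)
        assert np.isnan(rheo)
        assert "not-reached" in flags

    def test_rheobase_at_minimum_tested_flagged(self):
        proto = StepProtocol(step_start_pa=200.0, step_stop_pa=300.0)
        sweeps = generate_ephys_traces(EphysTraceSpec(protocol=proto), seed=0)
        rheo, flags = ef.rheobase(sweeps)
        assert rheo == 200.0
        assert "at-minimum-tested" in flags

    def test_rheobase_nondecreasing_in_model_threshold(self):
        rheos = []
        for thr in (-50.0, -45.0, -40.0):
            spec = EphysTraceSpec(model=MembraneModel(threshold_mv=thr))
            rheo, _ = ef.rheobase(generate_ephys_traces(spec, seed=0))
            rheos.append(rheo)
        assert rheos == sorted(rheos)

    def test_latency_decreases_with_current(self, sweepset):
        latencies = []
        for s in sweepset.sweeps:
            det = ef.detect_aps(s)
            if det.peak_times_ms.size:
                latencies.append(det.peak_times_ms[0])
        assert len(latencies) > 3
        assert all(b < a for a, b in zip(latencies, latencies[1:]))

    def test_fi_slope_matches_finite_difference(self, sweepset):
        table, slope = ef.fi_curve_max_slope(sweepset)
        rates = table["rate_hz"].to_numpy()
        di = np.diff(table["current_pa"].to_numpy())
        assert slope == pytest.approx(np.max(np.diff(rates) / di))
        assert slope > 0

    def test_all_zero_rates_slope_zero(self):
        spec = EphysTraceSpec(model=MembraneModel(threshold_mv=0.0))
        _, slope = ef.fi_curve_max_slope(generate_ephys_traces(spec, seed=0))
        assert slope == 0.0

    def test_single_sweep_slope_undefined(self):
        proto = StepProtocol(step_start_pa=-100.0, step_stop_pa=-100.0)
        sweeps = generate_ephys_traces(EphysTraceSpec(protocol=proto), seed=0)
        with pytest.raises(ValueError):
            ef.fi_curve_max_slope(sweeps)


class TestPassive:
    def test_ohms_law_exact(self, sweepset):
        p = ef.passive_properties(sweepset)
        assert p.rmp == pytest.approx(-65.0, abs=1e-6)
        assert p.input_resistance == pytest.approx(150.0, rel=1e-4)

    def test_subthreshold_steady_state_deflection(self, sweepset):
        s = [x for x in sweepset.sweeps if x.current_pa == -100.0][0]
        late = s.voltage_mv[(s.time_ms > 500) & (s.time_ms < 600)]
        assert late.mean() == pytest.approx(-80.0, abs=0.01)

    def test_zero_deflection_flagged(self):
        t = np.arange(0.0, 700.0, 0.05)
        flat = ef.Sweep(-100.0, t, np.full_like(t, -65.0))
        ss = ef.SweepSet([flat], 100.0, 500.0, 20.0)
        p = ef.passive_properties(ss)
        assert "implausible-rin" in p.flags

    def test_noisy_rin_unbiased_within_two_percent(self):
        proto = StepProtocol(step_start_pa=-100.0, step_stop_pa=-100.0,
                             step_duration_ms=200.0)
        rins = []
        for seed in range(100):
            spec = EphysTraceSpec(protocol=proto,
                                  model=MembraneModel(noise_sd_mv=0.5))
            sweeps = generate_ephys_traces(spec, seed=seed)
            rins.append(ef.passive_properties(sweeps).input_resistance)
        assert abs(np.mean(rins) - 150.0) / 150.0 < 0.02


class TestSpecValidation:
    def test_sample_rate_floor(self):
        with pytest.raises(ValueError):
            EphysTraceSpec(sample_rate_khz=5.0,
                           model=MembraneModel(ap_halfwidth_ms=1.0))

    def test_increment_positive(self):
        with pytest.raises(ValueError):
            StepProtocol(step_increment_pa=0.0)
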