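"""Synthetic-cohort generator: kernel, shock law, current measurement,
and cohort-level guarantees."""

import dataclasses

import numpy as np
import pytest

from mbplast.preprocess import compute_dff
from mbplast.synthdata import (
    SyntheticConfig,
    cs_exposure_count,
    current_from_voltage,
    generate_cohort,
    response_kernel,
    shock_amplitude,
)


class TestResponseKernel:
    def test_causal(self):
        assert response_kernel(-1.0, 0.2, 2.0) == 0.0
        t = np.linspace(-5, 0, 100, endpoint=False)
        assert np.all(response_kernel(t, 0.2, 2.0) == 0.0)

    def test_peak_normalized_to_one(self):
        for rise, decay in ((0.2, 2.0), (0.5, 4.0)):
            t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
            assert response_kernel(t_peak, rise, decay) == \
                pytest.approx(1.0, abs=1e-12)
            t = np.arange(0, 30, 1e-3)
            sampled = response_kernel(t, rise, decay)
            assert sampled.max() <= 1.0 + 1e-12
            assert sampled.max() == pytest.approx(1.0, abs=1e-6)

    def test_integral_matches_quadrature_oracle(self):
        # trapezoidal quadrature of the peak-normalized kernel at 1 ms
        # resolution, rise 0.2 s / decay 2.0 s, frozen before the build
        t = np.arange(0, 60, 1e-3)
        integral = np.trapezoid(response_kernel(t, 0.2, 2.0), t)
        assert integral == pytest.approx(2.58310, abs=2e-4)

    def test_decay_must_exceed_rise(self):
        with pytest.raises(ValueError, match="decay"):
            response_kernel(1.0, 2.0, 0.2)


class TestShockAmplitude:
    def test_tenfold_current_adds_one_slope(self):
        lo = shock_amplitude(50.0, 0.715, 0.1)
        hi = shock_amplitude(500.0, 0.715, 0.1)
        assert hi - lo == pytest.approx(0.715)

    def test_zero_slope_returns_intercept(self):
        for current in (1.0, 10.0, 1e4):
            assert shock_amplitude(current, 0.0, 0.42) == 0.42

    def test_direct_evaluation(self):
        assert shock_amplitude(100.0, 0.3, 0.1) == pytest.approx(0.7)

    def test_floored_at_zero_and_rejects_nonpositive_current(self):
        assert shock_amplitude(1.0, 0.3, -0.5) == 0.0
        with pytest.raises(ValueError, match="current"):
            shock_amplitude(0.0, 0.3, 0.1)


class TestCurrentFromVoltage:
    def test_parallel_combination_oracle(self):
        # Ohm's law on 29 MΩ ∥ 150 kΩ ≈ 1.4923e5 Ω, frozen value
        current = current_from_voltage(1.0, 29e6, 150e3)
        assert current == pytest.approx(6.701149425e-6, rel=1e-6)

    def test_zero_voltage_and_linearity(self):
        assert current_from_voltage(0.0, 29e6, 150e3) == 0.0
        one = current_from_voltage(1.0, 29e6, 150e3)
        assert current_from_voltage(2.0, 29e6, 150e3) == pytest.approx(2 * one)

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError, match="resistances"):
            current_from_voltage(1.0, -1.0, 150e3)


class TestGenerateCohort:
    def test_seed_determinism_bitwise(self, protocols, noiseless_config):
        pair = (protocols["paired"], protocols["unpaired"])
        cfg = dataclasses.replace(noiseless_config, noise_sd=0.05, seed=3)
        a = generate_cohort(pair, cfg, 2)
        b = generate_cohort(pair, cfg, 2)
        assert [f.fly_id for f in a] == [f.fly_id for f in b]
        for fa, fb in zip(a, b):
            assert fa.traces.keys() == fb.traces.keys()
            for key in fa.traces:
                np.testing.assert_array_equal(fa.traces[key], fb.traces[key])

    def test_null_signal_gives_pure_bleached_baseline(self, protocols):
        cfg = SyntheticConfig(noise_sd=0.0, fly_amplitude_cv=0.0,
                              odor_amplitudes={}, shock_params={},
                              bleach_rate=0.02, seed=0)
        fly = generate_cohort((protocols["paired"], protocols["unpaired"]),
                              cfg, 1)[0]
        for (_, _, trial), trace in fly.traces.items():
            expected = 100.0 * 0.98 ** (trial - 1)
            np.testing.assert_allclose(trace, expected, rtol=1e-12)

    def test_trace_length_and_trial_coverage(self, noiseless_cohort,
                                             protocols):
        for fly in noiseless_cohort:
            recorded = {t for t, _ in __import__("mbplast").recorded_stimuli(
                protocols[fly.group])}
            trials_seen = {trial for (_, _, trial) in fly.traces}
            assert trials_seen == recorded
            for trace in fly.traces.values():
                assert trace.shape == (225,)

    def test_noiseless_dff_reproduces_amplitude_times_waveform(
            self, protocols, noiseless_config):
        """With zero noise, ΔF/F₀ of the trial-2 BUT trace equals the
        configured amplitude times the unit evoked waveform."""
        from mbplast.synthdata import _unit_waveform

        pair = (protocols["paired"], protocols["unpaired"])
        fly = generate_cohort(pair, noiseless_config, 1)[0]
        proto = protocols[fly.group]
        trial = proto.trial(2)
        event = trial.recorded_events()[0]
        comp = "γ2"
        amp = noiseless_config.odor_amplitudes[(fly.genotype, comp, "BUT")]
        wave = _unit_waveform(event, trial.onset, 225, 5.0,
                              noiseless_config.kernel_rise,
                              noiseless_config.kernel_decay)
        dff = compute_dff(fly.traces[("left", comp, 2)])
        np.testing.assert_allclose(dff, amp * wave, atol=1e-9)

    def test_us_trace_monotone_in_current(self, protocols, noiseless_config):
        """Noiseless US response amplitude never decreases with current
        when the slope is positive."""
        pair = (protocols["paired"], protocols["unpaired"])
        amps = []
        for log_current in (1.5, 2.0, 2.5, 3.0):
            cfg = dataclasses.replace(noiseless_config,
                                      current_log_mean=log_current)
            fly = generate_cohort(pair, cfg, 1)[0]
            dff = compute_dff(fly.traces[("left", "γ1", 4)])
            amps.append(dff.max())
        assert all(b >= a for a, b in zip(amps, amps[1:]))

    def test_mismatched_protocols_rejected(self, protocols, noiseless_config):
        with pytest.raises(ValueError, match="paired and one"):
            generate_cohort((protocols["paired"], protocols["paired"]),
                            noiseless_config, 1)

    def test_paired_plasticity_injected_from_onset_trials(
            self, protocols, noiseless_config):
        pair = (protocols["paired"], protocols["unpaired"])
        flies = generate_cohort(pair, noiseless_config, 1)
        by_id = {f.fly_id: f for f in flies}
        dan_p = by_id["DAN_paired_000"]
        dan_u = by_id["DAN_unpaired_000"]
        # the trial-4 CS precedes the plasticity onset (trial 5): with
        # run-down disabled it matches the trial-2 CS until shock onset
        np.testing.assert_allclose(
            compute_dff(dan_p.traces[("left", "γ2", 4)])[:70],
            compute_dff(dan_p.traces[("left", "γ2", 2)])[:70], atol=1e-9)
        # trial 10 CS carries the paired-only gain
        p10 = compute_dff(dan_p.traces[("left", "γ2", 10)]).max()
        u10 = compute_dff(dan_u.traces[("left", "γ2", 10)]).max()
        assert p10 == pytest.approx(noiseless_config.dan_gain * u10, rel=1e-6)
        # KC depression confined to β'-lobe/junction
        kc_p = by_id["KC_paired_000"]
        kc_u = by_id["KC_unpaired_000"]
        b10p = compute_dff(kc_p.traces[("left", "β'2", 10)]).max()
        b10u = compute_dff(kc_u.traces[("left", "β'2", 10)]).max()
        assert b10p == pytest.approx(noiseless_config.kc_depression * b10u,
                                     rel=1e-6)
        g10p = compute_dff(kc_p.traces[("left", "γ2", 10)]).max()
        g10u = compute_dff(kc_u.traces[("left", "γ2", 10)]).max()
        assert g10p == pytest.approx(g10u, rel=1e-6)


def test_cs_exposure_count_follows_but_presentations():
    # BUT appears in trials 2, 4-9, 10, 13
    assert cs_exposure_count(2) == 0
    assert cs_exposure_count(4) == 1
    assert cs_exposure_count(5) == 2
    assert cs_exposure_count(10) == 7
    assert cs_exposure_count(13) == 8
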