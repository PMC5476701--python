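"""Response strengths, trace differences, rank-sum barcodes and
associative-effect contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbplast.protocol import StimulusKind
from mbplast.quantify import (
    QuantifyError,
    associative_effect,
    common_trials,
    framewise_pbarcode,
    response_strength,
    stimulus_window_mean,
    trace_difference,
)


def _event(protocol, trial_idx, kind):
    trial = protocol.trial(trial_idx)
    return trial, next(e for e in trial.events if e.kind is kind)


class TestStimulusWindowMean:
    def test_flat_trace_is_zero(self, paired_protocol):
        trial, ev = _event(paired_protocol, 2, StimulusKind.CS_BUT)
        assert stimulus_window_mean(np.full(225, 0.3), ev, trial) == \
            pytest.approx(0.0, abs=1e-12)

    def test_step_spanning_odor_window(self, paired_protocol):
        trial, ev = _event(paired_protocol, 2, StimulusKind.CS_BUT)
        trace = np.zeros(225)
        trace[25:75] = 0.8  # odorant window: frames 25-74 (5-15 s at 5 Hz)
        assert stimulus_window_mean(trace, ev, trial) == pytest.approx(0.8)

    def test_shock_train_frame_set_oracle(self, paired_protocol):
        """Four pulses of heights 0.2/0.4/0.4/0.2, zero between pulses
        and a zero pre-onset frame, must average to 0.3. The included
        frame sets were enumerated by hand from the 1.5 s on / 1.5 s
        off train starting at 20 s: [100-107], [115-122], [130-137],
        [145-152]."""
        trial, ev = _event(paired_protocol, 4, StimulusKind.SHOCK_US)
        trace = np.zeros(225)
        heights = (0.2, 0.4, 0.4, 0.2)
        for h, start in zip(heights, (100, 115, 130, 145)):
            trace[start:start + 8] = h
        assert stimulus_window_mean(trace, ev, trial) == pytest.approx(0.3)

    def test_baseline_relative_to_pre_onset_frame(self, paired_protocol):
        trial, ev = _event(paired_protocol, 2, StimulusKind.CS_BUT)
        trace = np.full(225, 0.1)
        trace[25:75] = 0.6
        assert stimulus_window_mean(trace, ev, trial) == pytest.approx(0.5)

    def test_window_outside_trace_rejected(self, paired_protocol):
        trial, ev = _event(paired_protocol, 2, StimulusKind.CS_BUT)
        with pytest.raises(QuantifyError, match="outside trace"):
            stimulus_window_mean(np.zeros(50), ev, trial)


class TestResponseStrength:
    def test_reference_trials_exactly_zero(self, noiseless_strengths):
        refs = noiseless_strengths[
            noiseless_strengths.trial == noiseless_strengths.reference_trial]
        assert (refs.strength == 0.0).all()
        # every stimulus class carries reference rows
        assert set(refs.stimulus) == {"CS", "MCH", "US"}

    def test_identical_response_gives_zero_strength(
            self, noiseless_strengths):
        """With run-down, bleaching and plasticity disabled, the
        trial-4 CS response equals the trial-2 reference (strength 0;
        the paired gain only starts at trial 5)."""
        cs4 = noiseless_strengths[
            (noiseless_strengths.stimulus == "CS")
            & (noiseless_strengths.trial == 4)]
        assert not cs4.empty
        assert cs4.strength.abs().max() < 1e-9

    def test_noiseless_gain_recovery_closed_form(
            self, noiseless_strengths, noiseless_config):
        """Injected 1.5x DAN CS gain from trial 5: the noiseless
        strength equals 0.5x the trial-2 window mean."""
        dan = noiseless_strengths[
            (noiseless_strengths.genotype == "DAN")
            & (noiseless_strengths.group == "paired")
            & (noiseless_strengths.stimulus == "CS")
            & (noiseless_strengths.compartment == "γ2")]
        wm2 = dan.loc[dan.trial == 2, "window_mean"].iloc[0]
        s5 = dan.loc[dan.trial == 5, "strength"].iloc[0]
        assert s5 == pytest.approx(
            (noiseless_config.dan_gain - 1.0) * wm2, abs=1e-9)

    def test_missing_reference_rejected(self, noiseless_trace_sets,
                                        paired_protocol):
        ts = dataclasses.replace(
            noiseless_trace_sets[0],
            traces={k: v for k, v in noiseless_trace_sets[0].traces.items()
                    if k[1] != 2})
        with pytest.raises(QuantifyError, match="reference trial 2"):
            response_strength(ts, paired_protocol)


class TestTraceDifference:
    def test_identical_traces_zero(self):
        t = np.linspace(0, 1, 225)
        np.testing.assert_array_equal(trace_difference(t, t), 0.0)

    def test_zero_pre_returns_post(self):
        post = np.linspace(0, 1, 225)
        np.testing.assert_array_equal(
            trace_difference(post, np.zeros(225)), post)

    def test_constant_offset(self):
        pre = np.linspace(0, 1, 225)
        np.testing.assert_allclose(
            trace_difference(pre + 0.3, pre), 0.3, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(QuantifyError, match="mismatch"):
            trace_difference(np.zeros(10), np.zeros(11))


class TestFramewiseBarcode:
    def test_identical_groups_all_ns(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 10))
        out = framewise_pbarcode(data, data.copy())
        assert (out.band == "ns").all()
        assert (out.p == 1.0).all()

    def test_exact_permutation_oracle(self):
        """5-vs-5 fully separated samples: the exhaustive permutation
        two-sided rank-sum p is 2/C(10,5) = 2/252 ≈ 0.0079."""
        paired = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        unpaired = np.array([[10.0], [20.0], [30.0], [40.0], [50.0]])
        out = framewise_pbarcode(paired, unpaired)
        assert out.p.iloc[0] == pytest.approx(2 / 252, rel=1e-9)
        assert out.band.iloc[0] == "p<0.01"

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 4))
        b = rng.normal(1.0, size=(7, 4))
        p1 = framewise_pbarcode(a, b).p
        p2 = framewise_pbarcode(np.exp(a), np.exp(b)).p
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(QuantifyError, match="2 flies"):
            framewise_pbarcode(np.zeros((1, 5)), np.zeros((3, 5)))


class TestAssociativeEffect:
    def test_identical_groups_zero_effect(self, noiseless_strengths):
        table = noiseless_strengths.copy()
        # overwrite group labels so both groups hold the same data
        half = table.copy()
        half["group"] = "paired"
        other = table.copy()
        other["group"] = "unpaired"
        other["fly_id"] = other.fly_id + "_u"
        eff = associative_effect(pd.concat([half, other]))
        assert eff.effect.abs().max() < 1e-12

    def test_antisymmetric_under_group_swap(self, noisy_strengths):
        eff = associative_effect(noisy_strengths)
        swapped = noisy_strengths.copy()
        swapped["group"] = swapped.group.map(
            {"paired": "unpaired", "unpaired": "paired"})
        eff_swapped = associative_effect(swapped)
        merged = eff.merge(eff_swapped, on=["genotype", "compartment"])
        np.testing.assert_allclose(merged.effect_x, -merged.effect_y,
                                   atol=1e-12)

    def test_noiseless_dan_gain_sign_pattern(self, noiseless_strengths):
        """The paired-minus-unpaired post-training CS effect is positive
        exactly where the DAN gain was injected, and negative exactly
        where the KC depression was injected."""
        eff = associative_effect(noiseless_strengths)
        dan = eff[eff.genotype == "DAN"].set_index("compartment").effect
        kc = eff[eff.genotype == "KC"].set_index("compartment").effect
        from mbplast.synthdata import (DAN_PLASTICITY_COMPARTMENTS,
                                       KC_DEPRESSION_COMPARTMENTS)
        for comp in dan.index:
            if comp in DAN_PLASTICITY_COMPARTMENTS:
                assert dan[comp] > 1e-6, comp
            else:
                assert abs(dan[comp]) < 1e-9, comp
        for comp in kc.index:
            if comp in KC_DEPRESSION_COMPARTMENTS:
                assert kc[comp] < -1e-6, comp
            else:
                assert abs(kc[comp]) < 1e-9, comp

    def test_missing_group_rejected(self, noiseless_strengths):
        only_paired = noiseless_strengths[
            noiseless_strengths.group == "paired"]
        with pytest.raises(QuantifyError, match="both groups"):
            associative_effect(only_paired)


def test_common_trials_excludes_unpaired_gaps(noiseless_strengths):
    """Trials whose CS was not recorded in the unpaired group are
    excluded from group contrasts."""
    trials = common_trials(noiseless_strengths[
        noiseless_strengths.genotype == "DAN"], "CS")
    unpaired_cs = set(noiseless_strengths[
        (noiseless_strengths.group == "unpaired")
        & (noiseless_strengths.stimulus == "CS")].trial)
    assert set(trials) <= unpaired_cs
    assert {2, 10, 13} <= set(trials)
    # exactly three training CS trials are shared
    assert sum(1 for t in trials if 4 <= t <= 9) == 3
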