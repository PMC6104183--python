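"""Pitch-jump detection and call-type assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usvkit import (
    ClassifierConfig,
    PitchJump,
    SpectrogramFrames,
    SyllableSpec,
    classify_call,
    compute_spectrogram,
    detect_jumps,
    peak_frequency,
    synth_syllable,
)

from conftest import make_syllable

CFG = ClassifierConfig()
HOP = 1.0  # ms


def trace(*segments):
    """Constant-pitch segments, e.g. trace((5, 75e3), (5, 69e3))."""
    return np.concatenate([np.full(n, hz) for n, hz in segments])


class TestDetectJumps:
    def test_constant_trace_no_jumps(self):
        assert detect_jumps(trace((20, 70e3)), CFG, HOP) == []

    def test_down_step_6khz_detected(self):
        jumps = detect_jumps(trace((10, 75e3), (10, 69e3)), CFG, HOP)
        assert len(jumps) == 1
        assert jumps[0].direction == "down"
        assert jumps[0].magnitude_hz == pytest.approx(6000.0)

    def test_up_step_5khz_not_qualifying(self):
        assert detect_jumps(trace((10, 70e3), (10, 75e3)), CFG, HOP) == []

    def test_up_step_8khz_detected(self):
        jumps = detect_jumps(trace((10, 70e3), (10, 78e3)), CFG, HOP)
        assert len(jumps) == 1
        assert jumps[0].direction == "up"

    def test_exact_thresholds_not_qualifying(self):
        assert detect_jumps(trace((10, 70e3), (10, 66e3)), CFG, HOP) == []
        assert detect_jumps(trace((10, 70e3), (10, 77e3)), CFG, HOP) == []

    def test_smeared_transition_counts_once(self):
        # two consecutive -6 kHz steps collapse into one 12 kHz jump
        t = trace((8, 80e3), (1, 74e3), (8, 68e3))
        jumps = detect_jumps(t, CFG, HOP)
        assert len(jumps) == 1
        assert jumps[0].magnitude_hz == pytest.approx(12_000.0)

    def test_median_smoothing_suppresses_single_frame_outlier(self):
        t = trace((5, 70e3), (1, 90e3), (5, 70e3))
        assert detect_jumps(t, CFG, HOP) == []

    def test_two_well_separated_jumps_both_detected(self):
        t = trace((8, 90e3), (8, 80e3), (8, 70e3))
        jumps = detect_jumps(t, CFG, HOP)
        assert [j.direction for j in jumps] == ["down", "down"]

    def test_pre_post_durations_partition_syllable(self):
        t = trace((10, 75e3), (30, 69e3))
        (jump,) = detect_jumps(t, CFG, HOP)
        assert jump.pre_duration_ms + jump.post_duration_ms == pytest.approx(40 * HOP)


def _call(duration_ms, jumps):
    syl = make_syllable(0.0, duration_ms / 1e3, n_frames=max(int(duration_ms), 2))
    return classify_call(syl, jumps, CFG)


def _jump(direction, pre_ms, post_ms, magnitude=6000.0):
    return PitchJump(
        frame_index=int(pre_ms) - 1, direction=direction,
        magnitude_hz=magnitude, pre_duration_ms=pre_ms, post_duration_ms=post_ms,
    )


class TestClassifyCall:
    @pytest.mark.parametrize(
        "duration_ms, jumps, expected",
        [
            (20.0, [], "NS"),
            (25.0, [], "NL"),  # boundary: exactly 25 ms is long
            (40.0, [], "NL"),
            (40.0, [_jump("down", 30, 10)], "JS"),       # ratio 1/3
            (40.0, [_jump("down", 20, 20)], "JN"),       # ratio 1
            (40.0, [_jump("down", 10, 30)], "JL"),       # ratio 3
            (35.0, [_jump("down", 25, 10)], "JN"),       # ratio exactly 0.4
            (30.0, [_jump("down", 10, 20)], "JN"),       # ratio exactly 2
            (20.0, [_jump("up", 10, 10, 8000.0)], "JU"),
            (30.0, [_jump("down", 10, 10), _jump("down", 20, 10)], "MJ"),
            (30.0, [_jump("up", 10, 20, 8000.0), _jump("down", 20, 10)], "MJ"),
        ],
    )
    def test_rule_table(self, duration_ms, jumps, expected):
        assert _call(duration_ms, jumps).call_type == expected

    def test_ratio_reported_only_for_single_down_jump(self):
        call = _call(40.0, [_jump("down", 10, 30)])
        assert call.ratio == pytest.approx(3.0)
        assert _call(20.0, []).ratio is None
        assert _call(20.0, [_jump("up", 10, 10, 8000.0)]).ratio is None

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_partition_matches_brute_force_rules(self, n_jumps, seed):
        """Decision-table agreement with an independent restatement of
        the classification rules."""
        rng = np.random.default_rng(seed)
        duration = float(rng.choice([10.0, 24.0, 25.0, 26.0, 60.0]))
        jumps = []
        for _ in range(n_jumps):
            direction = rng.choice(["down", "up"])
            pre = float(rng.choice([5.0, 10.0, duration / 3.4, duration / 2]))
            jumps.append(
                _jump(direction, pre, duration - pre,
                      6000.0 if direction == "down" else 8000.0)
            )
        got = _call(duration, jumps).call_type

        # independent brute-force restatement
        if len(jumps) > 1:
            expected = "MJ"
        elif len(jumps) == 1 and jumps[0].direction == "up":
            expected = "JU"
        elif len(jumps) == 1:
            r = jumps[0].post_duration_ms / jumps[0].pre_duration_ms
            expected = "JS" if r < 0.4 else ("JN" if r <= 2.0 else "JL")
        else:
            expected = "NS" if duration < 25.0 else "NL"
        assert got == expected


class TestPeakFrequency:
    def _manual_spec(self, power):
        power = np.asarray(power, dtype=float)
        return SpectrogramFrames(
            power=power,
            frame_times_s=np.arange(power.shape[0]) * 1e-3,
            freq_bins_hz=np.linspace(0, 125_000, power.shape[1]),
            window_ms=2.048, hop_ms=1.0, sample_rate_hz=250_000.0,
        )

    def test_pure_tone_peak_close_to_tone(self):
        spec = SyllableSpec("NL", 0.0, (30.0,), (70e3,))
        sg = compute_spectrogram(synth_syllable(spec, 250_000.0))
        syl = make_syllable(0.0, 0.03, n_frames=sg.n_frames, start_frame=0)
        pf = peak_frequency(syl, sg, 25_000, 120_000)
        assert abs(pf - 70e3) <= 250_000 / 512

    def test_louder_second_segment_wins(self):
        s1 = synth_syllable(SyllableSpec("NS", 0.0, (10.0,), (75e3,), amplitude=0.4), 250_000.0)
        s2 = synth_syllable(SyllableSpec("NL", 0.0, (30.0,), (69e3,), amplitude=0.8), 250_000.0)
        combined = np.concatenate([s1.samples, s2.samples])
        from usvkit import Waveform

        sg = compute_spectrogram(Waveform(combined, 250_000.0))
        syl = make_syllable(0.0, 0.04, n_frames=sg.n_frames)
        assert abs(peak_frequency(syl, sg, 25_000, 120_000) - 69e3) < 1e3

    def test_two_equal_cells_tie_breaks_low_frequency(self):
        power = np.zeros((3, 257))
        power[0, 180] = 1.0
        power[2, 120] = 1.0
        sg = self._manual_spec(power)
        syl = make_syllable(0.0, 0.003, n_frames=3)
        assert peak_frequency(syl, sg, 25_000, 120_000) == np.linspace(0, 125_000, 257)[120]

    def test_zero_power_syllable_raises(self):
        sg = self._manual_spec(np.zeros((3, 257)))
        syl = make_syllable(0.0, 0.003, n_frames=3)
        with pytest.raises(ValueError, match="power"):
            peak_frequency(syl, sg, 25_000, 120_000)
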