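"""Pitch-jump detection and the seven-type call taxonomy.

Each detected syllable is labelled by the temporal shape of its pitch
trace (dominant frequency over frames):

1. two or more qualifying jumps        -> MJ
2. exactly one upward jump (> 7 kHz)   -> JU
3. exactly one downward jump (> 4 kHz) -> JS / JN / JL by the duration
   ratio ``post / pre`` (< 0.4, [0.4, 2], > 2)
4. no jump                             -> NS (< 25 ms) or NL (>= 25 ms)

A qualifying jump is a step between consecutive median-smoothed pitch
samples below -4 kHz (down) or above +7 kHz (up); both thresholds are
strict, so a step of exactly -4.0 kHz or +7.0 kHz does not qualify.
Consecutive qualifying steps of the same sign within two frames collapse
into one jump so that a transition smeared over adjacent frames is not
double counted.  The classifier is total and deterministic: every
syllable receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .segment import Syllable
from .spectro import SpectrogramFrames

__all__ = ["ClassifierConfig", "PitchJump", "ClassifiedCall", "detect_jumps",
           "classify_call", "peak_frequency", "classify_syllables"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds of the call-type rule table."""

    down_jump_hz: float = 4_000.0
    up_jump_hz: float = 7_000.0
    duration_split_ms: float = 25.0
    ratio_low: float = 0.4
    ratio_high: float = 2.0
    pitch_median_window_frames: int = 3

    def __post_init__(self) -> None:
        if min(self.down_jump_hz, self.up_jump_hz, self.duration_split_ms) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.ratio_low < self.ratio_high:
            raise ValueError("ratio_low must be below ratio_high")
        if self.pitch_median_window_frames < 1 or self.pitch_median_window_frames % 2 == 0:
            raise ValueError("median window must be a positive odd frame count")


@dataclass(frozen=True)
class PitchJump:
    """One qualifying pitch step inside a syllable.

    ``frame_index`` is the index (into the syllable's trace) of the last
    frame before the step; the trace up to and including it lasts
    ``pre_duration_ms``, the remainder ``post_duration_ms``.
    """

    frame_index: int
    direction: str  # "up" | "down"
    magnitude_hz: float
    pre_duration_ms: float
    post_duration_ms: float


@dataclass(frozen=True)
class ClassifiedCall:
    """A syllable with its assigned call type."""

    syllable: Syllable
    call_type: str
    jumps: tuple[PitchJump, ...]
    ratio: float | None
    peak_frequency_hz: float | None = None

    @property
    def duration_ms(self) -> float:
        return self.syllable.duration_ms


def _smooth_pitch(trace: np.ndarray, window: int) -> tuple[np.ndarray, bool]:
    """Median-smooth a pitch trace; short traces pass through, flagged."""
    if len(trace) < window:
        return trace, False
    return medfilt(trace, kernel_size=window), True


def detect_jumps(
    pitch_trace_hz: np.ndarray,
    cfg: ClassifierConfig,
    hop_ms: float,
) -> list[PitchJump]:
    """Qualifying pitch jumps of a trace, in time order.

    Steps are differences of consecutive median-smoothed samples; a step
    must exceed 4 kHz downward or 7 kHz upward (both strict).  Same-sign
    qualifying steps within two frames of each other collapse into one
    jump whose magnitude is the total pitch change across the group.
    """
    trace = np.asarray(pitch_trace_hz, dtype=np.float64)
    if len(trace) < 2:
        return []
    smoothed, _ = _smooth_pitch(trace, cfg.pitch_median_window_frames)
    diffs = np.diff(smoothed)
    sign = np.zeros(len(diffs), dtype=np.int8)
    sign[diffs < -cfg.down_jump_hz] = -1
    sign[diffs > cfg.up_jump_hz] = 1
    idx = np.flatnonzero(sign)
    n = len(trace)
    jumps: list[PitchJump] = []
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and sign[idx[j + 1]] == sign[idx[i]] and idx[j + 1] - idx[j] <= 2:
            j += 1
        first, last = int(idx[i]), int(idx[j])
        magnitude = abs(float(smoothed[last + 1] - smoothed[first]))
        pre_frames = first + 1
        jumps.append(
            PitchJump(
                frame_index=first,
                direction="down" if sign[first] < 0 else "up",
                magnitude_hz=magnitude,
                pre_duration_ms=pre_frames * hop_ms,
                post_duration_ms=(n - pre_frames) * hop_ms,
            )
        )
        i = j + 1
    return jumps


def classify_call(
    syllable: Syllable,
    jumps: list[PitchJump],
    cfg: ClassifierConfig | None = None,
) -> ClassifiedCall:
    """Assign exactly one of the seven call types.

    Decision order: multiple jumps -> MJ; one upward jump -> JU; one
    downward jump -> JS/JN/JL by the post/pre duration ratio (boundary
    values 0.4 and 2.0 both fall to JN); no jump -> NS below 25 ms,
    NL at or above it.
    """
    cfg = cfg or ClassifierConfig()
    ratio: float | None = None
    if len(jumps) >= 2:
        call_type = "MJ"
    elif len(jumps) == 1 and jumps[0].direction == "up":
        call_type = "JU"
    elif len(jumps) == 1:
        ratio = jumps[0].post_duration_ms / jumps[0].pre_duration_ms
        if ratio < cfg.ratio_low:
            call_type = "JS"
        elif ratio <= cfg.ratio_high:
            call_type = "JN"
        else:
            call_type = "JL"
    else:
        call_type = "NS" if syllable.duration_ms < cfg.duration_split_ms else "NL"
    return ClassifiedCall(
        syllable=syllable, call_type=call_type, jumps=tuple(jumps), ratio=ratio
    )


def peak_frequency(
    syllable: Syllable,
    spec: SpectrogramFrames,
    band_low_hz: float,
    band_high_hz: float,
) -> float:
    """Frequency of the single most powerful spectrogram cell of a call.

    The search is restricted to the analysis band and the syllable's
    frames; among equally powerful cells the lowest frequency wins.

    Raises
    ------
    ValueError
        If the syllable's frames carry no in-band power.
    """
    in_band = (spec.freq_bins_hz >= band_low_hz) & (spec.freq_bins_hz <= band_high_hz)
    block = spec.power[syllable.start_frame : syllable.stop_frame][:, in_band]
    if block.size == 0 or block.max() <= 0:
        raise ValueError("syllable has no in-band power")
    freqs = spec.freq_bins_hz[in_band]
    peak = block.max()
    cols = np.flatnonzero((block == peak).any(axis=0))
    return float(freqs[cols[0]])


def classify_syllables(
    syllables: list[Syllable],
    spec: SpectrogramFrames | None = None,
    cfg: ClassifierConfig | None = None,
    band_low_hz: float | None = None,
    band_high_hz: float | None = None,
) -> list[ClassifiedCall]:
    """Classify every syllable; attach peak frequency when a spectrogram
    is supplied."""
    cfg = cfg or ClassifierConfig()
    calls = []
    for syl in syllables:
        jumps = detect_jumps(syl.pitch_trace_hz, cfg, syl.hop_ms)
        call = classify_call(syl, jumps, cfg)
        if spec is not None:
            pf = peak_frequency(syl, spec, band_low_hz or 0.0,
                                band_high_hz or spec.freq_bins_hz[-1])
            call = ClassifiedCall(
                syllable=call.syllable, call_type=call.call_type,
                jumps=call.jumps, ratio=call.ratio, peak_frequency_hz=pf,
            )
        calls.append(call)
    return calls
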