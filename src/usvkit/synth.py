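"""Seeded generators of synthetic USV sessions and call-count tables.

Real mouse courtship USVs are narrowband frequency-modulated whistles in
roughly the 40-110 kHz band, emitted in bouts with variable silent gaps.
This module fabricates sessions from seven syllable archetypes — the
rule-based taxonomy the classifier implements — so every pipeline stage
can be exercised with exact ground truth:

========  =======================================================
NS        no pitch jump, duration < 25 ms
NL        no pitch jump, duration >= 25 ms
JS        one downward jump > 4 kHz, post/pre duration ratio < 0.4
JN        one downward jump > 4 kHz, ratio in [0.4, 2]
JL        one downward jump > 4 kHz, ratio > 2
JU        one upward jump > 7 kHz
MJ        more than one jump
========  =======================================================

It also simulates per-animal call-count tables drawn from a zero-inflated
Poisson with a per-animal random intercept — the data-generating process
the mixed count model in :mod:`usvkit.stats` assumes.

All randomness flows from a single :class:`numpy.random.Generator` seeded
per call: equal seeds give bit-identical waveforms and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectro import Waveform

__all__ = [
    "CALL_TYPES",
    "SyllableSpec",
    "SessionSpec",
    "CountTableSpec",
    "Annotation",
    "synth_syllable",
    "synth_session",
    "synth_count_table",
    "random_syllable_spec",
]

CALL_TYPES: tuple[str, ...] = ("NS", "NL", "JS", "JN", "JL", "JU", "MJ")

# Generated pitches are confined to the typical mouse USV band.
USV_BAND_LOW_HZ = 40_000.0
USV_BAND_HIGH_HZ = 110_000.0

DOWN_JUMP_HZ = 4_000.0
UP_JUMP_HZ = 7_000.0
DURATION_SPLIT_MS = 25.0

RAMP_MS = 0.5  # raised-cosine onset/offset ramp applied to each syllable


def _qualifying_direction(diff_hz: float) -> str | None:
    """Direction of a qualifying pitch step, or None if sub-threshold."""
    if diff_hz < -DOWN_JUMP_HZ:
        return "down"
    if diff_hz > UP_JUMP_HZ:
        return "up"
    return None


@dataclass(frozen=True)
class SyllableSpec:
    """Blueprint of one synthetic syllable.

    ``segment_pitches_hz`` and ``segment_durations_ms`` are parallel
    lists: each segment is a linear-FM tone at its centre frequency.
    The segment structure must be consistent with ``call_type`` (see the
    module docstring for the rule table).
    """

    call_type: str
    onset_s: float
    segment_durations_ms: tuple[float, ...]
    segment_pitches_hz: tuple[float, ...]
    fm_slope_hz_per_s: float = 0.0
    amplitude: float = 1.0
    band_low_hz: float = USV_BAND_LOW_HZ
    band_high_hz: float = USV_BAND_HIGH_HZ

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment_durations_ms", tuple(self.segment_durations_ms))
        object.__setattr__(self, "segment_pitches_hz", tuple(self.segment_pitches_hz))
        self._validate()

    def _validate(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        durs, pitches = self.segment_durations_ms, self.segment_pitches_hz
        if len(durs) != len(pitches):
            raise ValueError("segment durations and pitches must be parallel")
        if any(d <= 0 for d in durs):
            raise ValueError("segment durations must be positive")
        n_expected = {"NS": (1, 1), "NL": (1, 1), "JS": (2, 2), "JN": (2, 2),
                      "JL": (2, 2), "JU": (2, 2), "MJ": (3, None)}[self.call_type]
        lo, hi = n_expected
        if len(durs) < lo or (hi is not None and len(durs) > hi):
            raise ValueError(
                f"{self.call_type} requires "
                f"{lo if hi == lo else f'>={lo}'} segment(s), got {len(durs)}"
            )
        diffs = [b - a for a, b in zip(pitches, pitches[1:])]
        if self.call_type in ("JS", "JN", "JL"):
            if not diffs[0] < -DOWN_JUMP_HZ:
                raise ValueError(
                    f"{self.call_type} requires a downward jump > {DOWN_JUMP_HZ} Hz, "
                    f"got step {diffs[0]:+.0f} Hz"
                )
            ratio = durs[1] / durs[0]
            bounds = {"JS": ratio < 0.4, "JN": 0.4 <= ratio <= 2.0, "JL": ratio > 2.0}
            if not bounds[self.call_type]:
                raise ValueError(
                    f"duration ratio {ratio:.3f} inconsistent with {self.call_type}"
                )
        elif self.call_type == "JU":
            if not diffs[0] > UP_JUMP_HZ:
                raise ValueError(
                    f"JU requires an upward jump > {UP_JUMP_HZ} Hz, got {diffs[0]:+.0f} Hz"
                )
        elif self.call_type == "MJ":
            if any(_qualifying_direction(d) is None for d in diffs):
                raise ValueError("every MJ segment boundary must be a qualifying jump")
        total_ms = sum(durs)
        if self.call_type == "NS" and total_ms > DURATION_SPLIT_MS:
            raise ValueError(f"NS duration {total_ms} ms exceeds {DURATION_SPLIT_MS} ms")
        if self.call_type == "NL" and total_ms < DURATION_SPLIT_MS:
            raise ValueError(f"NL duration {total_ms} ms is below {DURATION_SPLIT_MS} ms")
        for p in pitches:
            if not self.band_low_hz <= p <= self.band_high_hz:
                raise ValueError(
                    f"pitch {p} Hz outside the configured USV band "
                    f"[{self.band_low_hz}, {self.band_high_hz}] Hz"
                )
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"amplitude must be in (0, 1], got {self.amplitude}")

    @property
    def duration_s(self) -> float:
        return sum(self.segment_durations_ms) / 1e3

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Annotation:
    """Ground-truth record for one placed syllable."""

    onset_s: float
    offset_s: float
    call_type: str
    segment_pitches_hz: tuple[float, ...]
    segment_durations_ms: tuple[float, ...]


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic recording session.

    ``gap_median_s``/``gap_sigma`` parameterize the log-normal silent gap
    between the offset of one syllable and the onset of the next.  Gaps
    below ``min_gap_s`` (12 ms by default) are resampled so ground-truth
    syllables are never fused by the detector's 10 ms merge rule; set
    ``allow_short_gaps=True`` to generate deliberate sub-10 ms gaps for
    merge testing.
    """

    duration_s: float = 300.0
    sample_rate_hz: float = 250_000.0
    n_syllables: int = 100
    type_weights: tuple[float, ...] = (1 / 7,) * 7
    gap_median_s: float = 0.15
    gap_sigma: float = 0.6
    snr_db: float = 20.0
    seed: int = 0
    min_gap_s: float = 0.012
    allow_short_gaps: bool = False
    band_low_hz: float = USV_BAND_LOW_HZ
    band_high_hz: float = USV_BAND_HIGH_HZ

    def __post_init__(self) -> None:
        object.__setattr__(self, "type_weights", tuple(self.type_weights))
        if len(self.type_weights) != len(CALL_TYPES):
            raise ValueError(f"type_weights must have {len(CALL_TYPES)} entries")
        if any(w < 0 for w in self.type_weights):
            raise ValueError("type_weights must be non-negative")
        if abs(sum(self.type_weights) - 1.0) > 1e-9:
            raise ValueError("type_weights must sum to 1")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.n_syllables < 0:
            raise ValueError("n_syllables must be >= 0")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")


@dataclass(frozen=True)
class CountTableSpec:
    """Parameters of a simulated per-animal call-count table.

    Counts follow a zero-inflated Poisson with a log-linear mean::

        count ~ pi * delta_0 + (1 - pi) * Poisson(exp(X beta + b_animal))
        b_animal ~ Normal(0, random_intercept_sd**2)

    ``X beta`` uses treatment coding: intercept + group effect (second
    group) + call-type effects + group-by-type interaction; the first
    entry of each effect vector is the reference level and must be 0.
    """

    n_animals_per_group: tuple[int, int] = (7, 4)
    intercept: float = math.log(10.0)
    group_effect: float = 0.5
    type_effects: tuple[float, ...] = (0.0, 0.3, -0.3, 0.5, -0.5, 0.2, -0.2)
    interaction_effects: tuple[float, ...] = (0.0, 0.2, -0.2, 0.1, -0.1, 0.15, -0.15)
    zero_inflation_prob: float = 0.3
    random_intercept_sd: float = 0.5
    seed: int = 0
    group_labels: tuple[str, str] = ("WT", "KO")

    def __post_init__(self) -> None:
        object.__setattr__(self, "type_effects", tuple(self.type_effects))
        object.__setattr__(self, "interaction_effects", tuple(self.interaction_effects))
        if len(self.type_effects) != len(CALL_TYPES):
            raise ValueError(f"type_effects must have {len(CALL_TYPES)} entries")
        if len(self.interaction_effects) != len(CALL_TYPES):
            raise ValueError(f"interaction_effects must have {len(CALL_TYPES)} entries")
        if not 0 <= self.zero_inflation_prob < 1:
            raise ValueError(
                f"zero_inflation_prob must be in [0, 1), got {self.zero_inflation_prob}"
            )
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if any(n < 1 for n in self.n_animals_per_group):
            raise ValueError("each group needs at least one animal")


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def synth_syllable(spec: SyllableSpec, sample_rate_hz: float) -> Waveform:
    """Render one syllable as a phase-continuous multi-segment FM tone.

    Within each segment the instantaneous frequency is the segment pitch
    plus a linear FM term centred on the segment midpoint; 0.5 ms
    raised-cosine ramps taper the syllable onset and offset.

    Raises
    ------
    ValueError
        If any instantaneous frequency would reach the Nyquist frequency.
    """
    nyq = sample_rate_hz / 2.0
    inst_freq_parts = []
    for pitch, dur_ms in zip(spec.segment_pitches_hz, spec.segment_durations_ms):
        n = max(1, int(round(dur_ms * 1e-3 * sample_rate_hz)))
        t = np.arange(n) / sample_rate_hz
        f = pitch + spec.fm_slope_hz_per_s * (t - t[-1] / 2.0)
        if f.max() >= nyq:
            raise ValueError(
                f"instantaneous frequency {f.max():.0f} Hz reaches Nyquist "
                f"({nyq:.0f} Hz) — raise the sample rate or lower the pitch"
            )
        if f.min() <= 0:
            raise ValueError("instantaneous frequency must stay positive")
        inst_freq_parts.append(f)
    inst_freq = np.concatenate(inst_freq_parts)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / sample_rate_hz
    samples = spec.amplitude * np.sin(phase)
    n_ramp = min(int(round(RAMP_MS * 1e-3 * sample_rate_hz)), len(samples) // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        samples[:n_ramp] *= ramp
        samples[-n_ramp:] *= ramp[::-1]
    return Waveform(samples=samples, sample_rate_hz=sample_rate_hz)


# Archetype sampling ranges keep every generated syllable comfortably away
# from the classifier's decision boundaries (25 ms split, ratio 0.4 / 2.0,
# 4 / 7 kHz jump thresholds), so ground-truth labels are unambiguous.
def random_syllable_spec(
    call_type: str,
    onset_s: float,
    rng: np.random.Generator,
    band_low_hz: float = USV_BAND_LOW_HZ,
    band_high_hz: float = USV_BAND_HIGH_HZ,
    amplitude: float = 1.0,
) -> SyllableSpec:
    """Draw a random syllable blueprint of the requested type."""
    lo, hi = band_low_hz, band_high_hz
    u = rng.uniform
    if call_type == "NS":
        durs = (u(6.0, 20.0),)
        pitches = (u(lo + 2e3, hi - 2e3),)
    elif call_type == "NL":
        durs = (u(30.0, 80.0),)
        pitches = (u(lo + 2e3, hi - 2e3),)
    elif call_type in ("JS", "JN", "JL"):
        jump = u(5_500.0, 10_000.0)
        p0 = u(lo + jump + 2e3, hi - 2e3)
        pitches = (p0, p0 - jump)
        if call_type == "JS":
            pre = u(28.0, 45.0)
            post = pre * u(0.20, 0.32)
        elif call_type == "JN":
            pre = u(12.0, 25.0)
            post = pre * u(0.7, 1.4)
        else:  # JL
            pre = u(7.0, 12.0)
            post = pre * u(2.8, 4.5)
        durs = (pre, post)
    elif call_type == "JU":
        jump = u(8_500.0, 13_000.0)
        p0 = u(lo + 2e3, hi - jump - 2e3)
        pitches = (p0, p0 + jump)
        durs = (u(8.0, 30.0), u(8.0, 30.0))
    elif call_type == "MJ":
        j1 = u(5_500.0, 9_000.0)
        j2 = u(5_500.0, 9_000.0)
        p0 = u(lo + j1 + j2 + 2e3, hi - 2e3)
        pitches = (p0, p0 - j1, p0 - j1 - j2)
        durs = (u(7.0, 16.0), u(7.0, 16.0), u(7.0, 16.0))
    else:
        raise ValueError(f"unknown call type {call_type!r}")
    return SyllableSpec(
        call_type=call_type,
        onset_s=onset_s,
        segment_durations_ms=durs,
        segment_pitches_hz=pitches,
        fm_slope_hz_per_s=u(-30_000.0, 30_000.0),
        amplitude=amplitude,
        band_low_hz=lo,
        band_high_hz=hi,
    )


def _noise_sigma(snr_db: float, signal_rms: float, band_low_hz: float,
                 band_high_hz: float, sample_rate_hz: float) -> float:
    """White-noise std for a target in-band SNR over a syllable's extent.

    SNR is the ratio of the tone's RMS to the RMS of the noise component
    inside the analysis band; white noise of std sigma carries the band
    fraction ``(f_hi - f_lo) / nyquist`` of its power there.
    """
    band_fraction = (band_high_hz - band_low_hz) / (sample_rate_hz / 2.0)
    inband_rms = signal_rms * 10.0 ** (-snr_db / 20.0)
    return inband_rms / math.sqrt(band_fraction)


def synth_session(spec: SessionSpec) -> tuple[Waveform, list[Annotation]]:
    """Generate one session: placed syllables plus broadband noise.

    Syllable types are drawn from ``type_weights``; silent gaps between
    consecutive syllables are log-normal.  The returned annotations are
    sorted by onset and non-overlapping.  Identical seeds give
    bit-identical output.

    Raises
    ------
    ValueError
        If the expected occupied time exceeds the session duration
        (infeasible density), naming the limiting parameter.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    n_total = int(round(spec.duration_s * fs))

    mean_gap = spec.gap_median_s * math.exp(spec.gap_sigma**2 / 2.0)
    mean_syllable = 0.035  # ~mean archetype duration, seconds
    expected_occupied = spec.n_syllables * (mean_gap + mean_syllable)
    if spec.n_syllables > 0 and expected_occupied >= spec.duration_s:
        raise ValueError(
            f"infeasible density: n_syllables={spec.n_syllables} with "
            f"gap_median_s={spec.gap_median_s} expects "
            f"{expected_occupied:.1f} s of audio but duration_s is "
            f"{spec.duration_s} — lower n_syllables or gap_median_s"
        )

    def draw_gap() -> float:
        g = rng.lognormal(mean=math.log(spec.gap_median_s), sigma=spec.gap_sigma)
        if not spec.allow_short_gaps:
            while g < spec.min_gap_s:
                g = rng.lognormal(mean=math.log(spec.gap_median_s), sigma=spec.gap_sigma)
        return g

    samples = np.zeros(n_total)
    annotations: list[Annotation] = []
    cursor = draw_gap()
    for _ in range(spec.n_syllables):
        call_type = CALL_TYPES[rng.choice(len(CALL_TYPES), p=spec.type_weights)]
        syl = random_syllable_spec(
            call_type, cursor, rng, spec.band_low_hz, spec.band_high_hz
        )
        tone = synth_syllable(syl, fs)
        start = int(round(syl.onset_s * fs))
        stop = start + len(tone.samples)
        if stop > n_total:
            raise ValueError(
                f"infeasible density: syllables overran duration_s="
                f"{spec.duration_s} s at syllable {len(annotations) + 1} — "
                f"lower n_syllables or gap_median_s"
            )
        samples[start:stop] += tone.samples
        annotations.append(
            Annotation(
                onset_s=start / fs,
                offset_s=stop / fs,
                call_type=call_type,
                segment_pitches_hz=syl.segment_pitches_hz,
                segment_durations_ms=syl.segment_durations_ms,
            )
        )
        cursor = stop / fs + draw_gap()

    sigma = _noise_sigma(
        spec.snr_db, 1.0 / math.sqrt(2.0),
        spec.band_low_hz, spec.band_high_hz, fs,
    )
    samples += rng.normal(0.0, sigma, size=n_total)
    return Waveform(samples=samples, sample_rate_hz=fs), annotations


# ---------------------------------------------------------------------------
# Count-table synthesis
# ---------------------------------------------------------------------------

def synth_count_table(spec: CountTableSpec) -> pd.DataFrame:
    """Simulate a long-format (animal, group, call_type, count) table.

    One row per animal and call type.  Counts are zero-inflated Poisson
    with a shared per-animal normal random intercept on the log scale.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    animal_idx = 0
    for g_idx, (label, n_animals) in enumerate(
        zip(spec.group_labels, spec.n_animals_per_group)
    ):
        for _ in range(n_animals):
            animal_idx += 1
            b = rng.normal(0.0, spec.random_intercept_sd)
            for t_idx, call_type in enumerate(CALL_TYPES):
                eta = (
                    spec.intercept
                    + spec.group_effect * g_idx
                    + spec.type_effects[t_idx]
                    + spec.interaction_effects[t_idx] * g_idx
                )
                if rng.uniform() < spec.zero_inflation_prob:
                    count = 0
                else:
                    count = int(rng.poisson(math.exp(eta + b)))
                rows.append(
                    {
                        "animal": f"m{animal_idx:03d}",
                        "group": label,
                        "call_type": call_type,
                        "count": count,
                    }
                )
    return pd.DataFrame(rows)
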