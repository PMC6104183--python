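"""Syllable detection: purity thresholding, gap merging, exclusion rules.

Syllables are detected as maximal runs of STFT frames whose spectral
purity strictly exceeds a threshold (0.15 by default).  Candidate runs
separated by silent gaps shorter than 10 ms are merged, then extremely
short (< 3 ms) or noisy (mean purity < 0.3) candidates are dropped.
Merging runs before duration filtering so fragments belonging to one
call are rescued before the length test.

Intervals are half-open ``[onset, offset)`` in seconds.  Frame-to-time
conversion uses frame centres: a syllable spanning frames ``i..j`` has
``onset = t_i`` and ``offset = t_j`` (duration ``(n_frames - 1) * hop``;
a single-frame run is given one hop of width).  The first and last
suprathreshold frames overlap the call only partially, so the span of
their centres is a nearly unbiased estimate of the call's extent,
whereas extending the interval by the frames' full hop widths would
systematically widen it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectro import FrameFeatures

__all__ = ["DetectorConfig", "Syllable", "detect_candidates", "merge_candidates",
           "filter_syllables", "detect_syllables"]


@dataclass(frozen=True)
class DetectorConfig:
    """Detection thresholds.

    purity_threshold
        Frames with purity strictly above this enter a candidate (0.15).
    max_merge_gap_ms
        Candidates separated by strictly less than this are fused (10 ms).
    min_duration_ms
        Merged candidates shorter than this are excluded (3 ms) —
        the "extremely short call" rule.
    min_mean_purity
        Merged candidates with mean purity below this are excluded
        (0.3) — the "noise" rule.
    """

    purity_threshold: float = 0.15
    max_merge_gap_ms: float = 10.0
    min_duration_ms: float = 3.0
    min_mean_purity: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.purity_threshold < 1:
            raise ValueError("purity_threshold must be in (0, 1)")
        if self.max_merge_gap_ms <= 0 or self.min_duration_ms <= 0:
            raise ValueError("gap and duration thresholds must be positive")
        if not 0 <= self.min_mean_purity <= 1:
            raise ValueError("min_mean_purity must be in [0, 1]")


@dataclass(frozen=True)
class Syllable:
    """A detected time interval with its pitch trace.

    ``start_frame``/``stop_frame`` index a contiguous half-open frame
    range of the source spectrogram; ``pitch_trace_hz`` and
    ``purity_trace`` run over exactly those frames.
    """

    onset_s: float
    offset_s: float
    start_frame: int
    stop_frame: int
    pitch_trace_hz: np.ndarray
    purity_trace: np.ndarray
    hop_ms: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("offset must exceed onset")
        if len(self.pitch_trace_hz) != self.stop_frame - self.start_frame:
            raise ValueError("pitch trace length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.stop_frame - self.start_frame

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1e3

    @property
    def mean_purity(self) -> float:
        return float(np.mean(self.purity_trace))


def _make_syllable(features: FrameFeatures, start: int, stop: int) -> Syllable:
    hop_s = features.hop_ms / 1e3
    onset = float(features.frame_times_s[start])
    offset = float(features.frame_times_s[stop - 1]) if stop - start > 1 else onset + hop_s
    return Syllable(
        onset_s=onset,
        offset_s=offset,
        start_frame=start,
        stop_frame=stop,
        pitch_trace_hz=features.pitch_hz[start:stop].copy(),
        purity_trace=features.purity[start:stop].copy(),
        hop_ms=features.hop_ms,
    )


def detect_candidates(features: FrameFeatures, cfg: DetectorConfig) -> list[Syllable]:
    """Maximal runs of frames with purity strictly above the threshold.

    A frame whose purity equals the threshold exactly does not qualify.
    Returns candidates sorted by onset, mutually disjoint.
    """
    if features.n_frames == 0:
        raise ValueError("no frames to detect on")
    above = features.purity > cfg.purity_threshold
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [_make_syllable(features, int(a), int(b)) for a, b in zip(starts, stops)]


def merge_candidates(
    cands: list[Syllable],
    cfg: DetectorConfig,
    features: FrameFeatures | None = None,
) -> list[Syllable]:
    """Fuse candidates separated by a gap strictly below 10 ms.

    Single left-to-right pass; the operation is idempotent.  When
    ``features`` is supplied, the pitch and purity of the bridged gap
    frames are taken from it; otherwise the traces are concatenated.

    Raises
    ------
    ValueError
        If candidates are not sorted and disjoint.
    """
    for a, b in zip(cands, cands[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError("candidates must be sorted and disjoint")
    if not cands:
        return []
    merged: list[Syllable] = [cands[0]]
    for nxt in cands[1:]:
        prev = merged[-1]
        gap_ms = (nxt.onset_s - prev.offset_s) * 1e3
        # strict "less than": a gap equal to the threshold up to float
        # representation error (sub-nanosecond) must not merge
        if gap_ms < cfg.max_merge_gap_ms - 1e-6:
            if features is not None:
                merged[-1] = _make_syllable(features, prev.start_frame, nxt.stop_frame)
            else:
                merged[-1] = replace(
                    prev,
                    offset_s=nxt.offset_s,
                    stop_frame=prev.stop_frame + nxt.n_frames,
                    pitch_trace_hz=np.concatenate(
                        [prev.pitch_trace_hz, nxt.pitch_trace_hz]
                    ),
                    purity_trace=np.concatenate([prev.purity_trace, nxt.purity_trace]),
                )
        else:
            merged.append(nxt)
    return merged


def filter_syllables(cands: list[Syllable], cfg: DetectorConfig) -> list[Syllable]:
    """Drop extremely short or noisy candidates; order preserved."""
    return [
        s
        for s in cands
        if s.duration_ms >= cfg.min_duration_ms - 1e-6
        and s.mean_purity >= cfg.min_mean_purity
    ]


def detect_syllables(
    features: FrameFeatures, cfg: DetectorConfig | None = None
) -> list[Syllable]:
    """Full detection chain: threshold, merge, exclude."""
    cfg = cfg or DetectorConfig()
    cands = detect_candidates(features, cfg)
    merged = merge_candidates(cands, cfg, features=features)
    return filter_syllables(merged, cfg)
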