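"""WAV and CSV I/O, pipeline configuration, and the end-to-end driver.

The pipeline is the deterministic composition

    spectrogram -> frame features -> detect/merge/filter -> classify
    -> summarize

and every stage's input/output cardinality is logged, so a session run
leaves an audit trail (frames, candidates, merged, excluded, classified).
All CSV artifacts are comma-separated, UTF-8, '.'-decimal with a header
row; identical (file, config) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import ast
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import classify as _classify
from . import segment as _segment
from . import spectro as _spectro
from . import summarize as _summarize
from .synth import Annotation

logger = logging.getLogger("usvkit")

__all__ = [
    "PipelineConfig",
    "read_wav",
    "write_wav",
    "write_annotations",
    "read_annotations",
    "write_features",
    "write_syllables",
    "write_calls",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the detection/classification chain, flat.

    Serializes to a ``key = value`` text file; unknown keys are rejected
    on load and round trips are lossless.
    """

    window_ms: float = _spectro.DEFAULT_WINDOW_MS
    hop_ms: float = _spectro.DEFAULT_HOP_MS
    band_low_hz: float = _spectro.DEFAULT_BAND_LOW_HZ
    band_high_hz: float = _spectro.DEFAULT_BAND_HIGH_HZ
    purity_threshold: float = 0.15
    max_merge_gap_ms: float = 10.0
    min_duration_ms: float = 3.0
    min_mean_purity: float = 0.3
    down_jump_hz: float = 4000.0
    up_jump_hz: float = 7000.0
    duration_split_ms: float = 25.0
    ratio_low: float = 0.4
    ratio_high: float = 2.0
    pitch_median_window_frames: int = 3
    seed: int = 0

    def detector(self) -> _segment.DetectorConfig:
        return _segment.DetectorConfig(
            purity_threshold=self.purity_threshold,
            max_merge_gap_ms=self.max_merge_gap_ms,
            min_duration_ms=self.min_duration_ms,
            min_mean_purity=self.min_mean_purity,
        )

    def classifier(self) -> _classify.ClassifierConfig:
        return _classify.ClassifierConfig(
            down_jump_hz=self.down_jump_hz,
            up_jump_hz=self.up_jump_hz,
            duration_split_ms=self.duration_split_ms,
            ratio_low=self.ratio_low,
            ratio_high=self.ratio_high,
            pitch_median_window_frames=self.pitch_median_window_frames,
        )

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            target = cls.__dataclass_fields__[key].default
            kwargs[key] = type(target)(ast.literal_eval(value.strip()))
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> _spectro.Waveform:
    """Read a mono WAV file, normalizing integer PCM to [-1, 1].

    Supports PCM 16/24/32-bit and IEEE float encodings.  Stereo input is
    an error, never a silent downmix.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return _spectro.Waveform(samples=samples, sample_rate_hz=float(rate))


def write_wav(
    path: str | Path, wave: _spectro.Waveform, encoding: str = "float32"
) -> None:
    """Write a mono WAV as IEEE float32 (default) or 16-bit PCM."""
    if encoding == "float32":
        wavfile.write(str(path), int(wave.sample_rate_hz), wave.samples.astype(np.float32))
    elif encoding == "pcm16":
        clipped = np.clip(wave.samples, -1.0, 32767 / 32768)
        wavfile.write(
            str(path), int(wave.sample_rate_hz),
            np.round(clipped * 32768.0).astype(np.int16),
        )
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


# ---------------------------------------------------------------------------
# CSV artifacts
# ---------------------------------------------------------------------------


def write_annotations(path: str | Path, annotations: list[Annotation], seed: int) -> None:
    """Ground-truth annotation CSV (semicolon-joined segment lists)."""
    df = pd.DataFrame(
        {
            "onset_s": [a.onset_s for a in annotations],
            "offset_s": [a.offset_s for a in annotations],
            "call_type": [a.call_type for a in annotations],
            "n_segments": [len(a.segment_pitches_hz) for a in annotations],
            "segment_pitches_hz": [
                ";".join(repr(p) for p in a.segment_pitches_hz) for a in annotations
            ],
            "segment_durations_ms": [
                ";".join(repr(d) for d in a.segment_durations_ms) for a in annotations
            ],
            "seed": seed,
        }
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [
        Annotation(
            onset_s=row.onset_s,
            offset_s=row.offset_s,
            call_type=row.call_type,
            segment_pitches_hz=tuple(
                float(p) for p in str(row.segment_pitches_hz).split(";")
            ),
            segment_durations_ms=tuple(
                float(d) for d in str(row.segment_durations_ms).split(";")
            ),
        )
        for row in df.itertuples()
    ]


def write_features(path: str | Path, features: _spectro.FrameFeatures) -> None:
    pd.DataFrame(
        {
            "frame_time_s": features.frame_times_s,
            "purity": features.purity,
            "pitch_hz": features.pitch_hz,
            "total_power": features.total_power,
        }
    ).to_csv(path, index=False)


def write_syllables(path: str | Path, syllables: list[_segment.Syllable]) -> None:
    pd.DataFrame(
        {
            "onset_s": [s.onset_s for s in syllables],
            "offset_s": [s.offset_s for s in syllables],
            "duration_ms": [s.duration_ms for s in syllables],
            "n_frames": [s.n_frames for s in syllables],
            "mean_purity": [s.mean_purity for s in syllables],
        }
    ).to_csv(path, index=False)


def write_calls(path: str | Path, calls: list[_classify.ClassifiedCall]) -> None:
    pd.DataFrame(
        {
            "onset_s": [c.syllable.onset_s for c in calls],
            "offset_s": [c.syllable.offset_s for c in calls],
            "duration_ms": [c.duration_ms for c in calls],
            "call_type": [c.call_type for c in calls],
            "n_jumps": [len(c.jumps) for c in calls],
            "ratio": [c.ratio if c.ratio is not None else "" for c in calls],
            "peak_frequency_hz": [c.peak_frequency_hz for c in calls],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(
    wave: _spectro.Waveform | str | Path,
    cfg: PipelineConfig | None = None,
    animal_id: str = "animal",
    group: str = "group",
    out_dir: str | Path | None = None,
) -> tuple[list[_classify.ClassifiedCall], _summarize.SessionSummary]:
    """Run detection, classification and summarization on one session.

    ``wave`` may be a Waveform or a WAV path.  When ``out_dir`` is given,
    the detected-syllable and classified-call CSVs are written there.
    The run is deterministic: identical input and configuration give
    identical outputs.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(wave, _spectro.Waveform):
        wave = read_wav(wave)
    spec = _spectro.compute_spectrogram(wave, cfg.window_ms, cfg.hop_ms)
    features = _spectro.frame_features(spec, cfg.band_low_hz, cfg.band_high_hz)
    logger.info("spectro: %d frames", features.n_frames)
    det = cfg.detector()
    cands = _segment.detect_candidates(features, det)
    merged = _segment.merge_candidates(cands, det, features=features)
    kept = _segment.filter_syllables(merged, det)
    logger.info(
        "segment: %d candidates -> %d merged -> %d retained (%d excluded)",
        len(cands), len(merged), len(kept), len(merged) - len(kept),
    )
    calls = _classify.classify_syllables(
        kept, spec=spec, cfg=cfg.classifier(),
        band_low_hz=cfg.band_low_hz, band_high_hz=cfg.band_high_hz,
    )
    summary = _summarize.summarize_session(calls, animal_id=animal_id, group=group)
    logger.info("classify: %d calls, %d total in summary", len(calls), summary.total_calls)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_syllables(out / "syllables.csv", kept)
        write_calls(out / "calls.csv", calls)
    return calls, summary
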