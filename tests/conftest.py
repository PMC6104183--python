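import numpy as np
import pytest

from usvkit import FrameFeatures, Syllable


def make_features(
    purity,
    pitch=None,
    hop_ms: float = 1.0,
    band_low_hz: float = 25_000.0,
    band_high_hz: float = 120_000.0,
) -> FrameFeatures:
    """Hand-built frame features for detector unit tests."""
    purity = np.asarray(purity, dtype=np.float64)
    n = len(purity)
    if pitch is None:
        pitch = np.full(n, 70_000.0)
    return FrameFeatures(
        purity=purity,
        pitch_hz=np.asarray(pitch, dtype=np.float64),
        total_power=np.where(purity > 0, 1.0, 0.0),
        zero_power=purity == 0,
        frame_times_s=np.arange(n) * hop_ms / 1e3,
        band_low_hz=band_low_hz,
        band_high_hz=band_high_hz,
        hop_ms=hop_ms,
    )


def make_syllable(
    onset_s: float,
    offset_s: float,
    n_frames: int = 10,
    start_frame: int = 0,
    pitch_hz: float = 70_000.0,
    purity: float = 0.8,
    hop_ms: float = 1.0,
) -> Syllable:
    """Hand-built syllable with a constant pitch trace."""
    return Syllable(
        onset_s=onset_s,
        offset_s=offset_s,
        start_frame=start_frame,
        stop_frame=start_frame + n_frames,
        pitch_trace_hz=np.full(n_frames, pitch_hz),
        purity_trace=np.full(n_frames, purity),
        hop_ms=hop_ms,
    )


@pytest.fixture(scope="session")
def short_session():
    """One small synthetic session shared across tests (seeded)."""
    from usvkit import SessionSpec, synth_session

    spec = SessionSpec(duration_s=6.0, n_syllables=12, snr_db=20.0, seed=42)
    wave, annotations = synth_session(spec)
    return spec, wave, annotations
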